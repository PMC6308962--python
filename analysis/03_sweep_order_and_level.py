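"""Sweep the Daubechies order (db1..db8 at level 5) and then the
decomposition level (1..5) for the selected order.

Writes results/order_sweep.csv and results/level_sweep.csv and reports the
de-noising parameters selected by the Rc2 / RMSEC / MAPEc rule.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_cohort  # noqa: E402

from tracheidnir.pipeline import sweep_level, sweep_order  # noqa: E402


def main() -> None:
    data = load_cohort()

    orders = sweep_order(data)
    orders.table.to_csv(RESULTS / "order_sweep.csv", index=False)
    print("Daubechies order sweep (level 5):")
    print(orders.table[["label", "Rc2", "RMSEC", "MAPEc"]]
          .round(3).to_string(index=False))
    best_wavelet = orders.best_row["label"]
    print(f"selected order: {best_wavelet}")

    levels = sweep_level(data, wavelet=best_wavelet)
    levels.table.to_csv(RESULTS / "level_sweep.csv", index=False)
    print(f"\ndecomposition level sweep ({best_wavelet}):")
    print(levels.table[["label", "Rc2", "RMSEC", "MAPEc"]]
          .round(3).to_string(index=False))
    print(f"selected de-noising parameters: {levels.best_row['label']}")


if __name__ == "__main__":
    main()
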