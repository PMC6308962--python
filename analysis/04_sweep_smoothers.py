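"""Sweep the comparator smoothers (moving average, Savitzky-Golay, loess,
lowess) over odd segment sizes 3..25.

Writes results/smoother_sweep.csv and reports, per method, the best segment
size and the endpoint trend of Rc2 between segment sizes 3 and 25.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_cohort  # noqa: E402

from tracheidnir.pipeline import sweep_smoothers  # noqa: E402


def main() -> None:
    data = load_cohort()
    res = sweep_smoothers(data)
    res.table.to_csv(RESULTS / "smoother_sweep.csv", index=False)
    for method, grp in res.table.groupby("method"):
        best = grp.sort_values(["Rc2", "RMSEC", "MAPEc"],
                               ascending=[False, True, True]).iloc[0]
        first = grp[grp.segment_size == 3].iloc[0]
        last = grp[grp.segment_size == 25].iloc[0]
        print(f"{method:<16} best segment {int(best.segment_size):>2} "
              f"(Rc2 {best.Rc2:.3f}); Rc2 drifts {first.Rc2:.3f} -> "
              f"{last.Rc2:.3f} from segment 3 to 25")
    print(f"overall best: {res.best_row['label']}")


if __name__ == "__main__":
    main()
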