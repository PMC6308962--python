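"""Screen the four candidate mother wavelets (sym5, bior5.5, rbio5.5, db5)
at decomposition level 5 with the global fixed hard threshold.

Reads results/cohort.csv (generating it if absent), de-noises the
calibration spectra with each wavelet, fits 7-component PLS and writes the
ranked table to results/wavelet_screen.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, load_cohort  # noqa: E402

from tracheidnir.pipeline import screen_wavelets  # noqa: E402


def main() -> None:
    data = load_cohort()
    res = screen_wavelets(data)
    res.table.to_csv(RESULTS / "wavelet_screen.csv", index=False)
    cols = ["label", "pcs", "Rc2", "RMSEC", "MAPEc"]
    print(res.table[cols].round(3).to_string(index=False))
    print(f"selected wavelet: {res.best_row['label']}")


if __name__ == "__main__":
    main()
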