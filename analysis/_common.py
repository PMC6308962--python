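"""Shared helpers for the analysis drivers."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def load_cohort():
    """Load results/cohort.csv, generating the default cohort if absent."""
    from tracheidnir.synthetic import (read_wide_csv, simulate_cohort,
                                       write_wide_csv)
    path = RESULTS / "cohort.csv"
    if path.exists():
        return read_wide_csv(path)
    RESULTS.mkdir(exist_ok=True)
    data = simulate_cohort(seed=SEED)
    write_wide_csv(data, path)
    return data
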