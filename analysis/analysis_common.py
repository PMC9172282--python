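"""Shared plumbing for the numbered analysis drivers.

The demonstration cohort (20 synthetic subjects, small phantom grid) is
simulated once and cached under scratch/ so the later drivers reuse it; every
driver writes its tables under results/.
"""

from __future__ import annotations

import pickle
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1
N_SUBJECTS = 20


def load_or_run_cohort():
    """Simulate-and-analyze the demonstration cohort (cached in scratch/)."""
    from votrsa import pipeline as pl

    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"cohort_seed{SEED}_n{N_SUBJECTS}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    t0 = time.time()
    cohort = pl.simulate_and_analyze_cohort(
        seed=SEED, n_subjects=N_SUBJECTS, grid="small", validation=True
    )
    print(f"simulated + analyzed {N_SUBJECTS} subjects in {time.time() - t0:.0f}s")
    with open(cache, "wb") as fh:
        pickle.dump(cohort, fh)
    return cohort


def ensure_results():
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
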