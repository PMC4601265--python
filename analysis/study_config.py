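"""Shared configuration for the numbered analysis scripts.

The study seed fixes the whole simulated cohort; every script either reads
the rearrangement tables written by ``01_simulate_cohort.py`` under
``scratch/`` or regenerates the cohort deterministically from the seed.
"""

from __future__ import annotations

from pathlib import Path

STUDY_SEED = 20250925

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def get_cohort():
    from bcrep.study import simulate_cohort

    return simulate_cohort(seed=STUDY_SEED)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
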