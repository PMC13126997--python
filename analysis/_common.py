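"""Shared plumbing for the numbered analysis scripts.

One default synthetic study (seed 1) backs the whole analysis; contrast
tables are cached as TSV under scratch/ so later scripts reuse earlier
fits.  Large raw data stays in scratch/; results/ holds only the small
summary tables the write-up quotes.
"""

from __future__ import annotations

from pathlib import Path

from lumideconv.diffexp import run_contrast
from lumideconv.io import read_contrast, write_contrast
from lumideconv.simulate import make_study

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 1

_STUDY = None


def get_study():
    global _STUDY
    if _STUDY is None:
        _STUDY = make_study(seed=SEED)
    return _STUDY


def get_contrast(ref: str, alt: str, compartment: str):
    """Fit (or reload) one NB contrast on the shared study."""
    SCRATCH.mkdir(parents=True, exist_ok=True)
    path = SCRATCH / f"contrast_{alt}_v_{ref}_{compartment}.tsv"
    if path.exists():
        return read_contrast(path)
    ct = run_contrast(get_study().bulk, ref, alt, compartment)
    write_contrast(ct, path)
    return ct


def ensure_dirs():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
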