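"""Shared fixtures: one default synthetic study and its main contrasts.

Heavy objects (the study, NB contrasts) are session-scoped so the suite
pays for each once.  Seeds are fixed for full reproducibility.
"""

import numpy as np
import pandas as pd
import pytest

from lumideconv.diffexp import run_contrast
from lumideconv.io import ContrastTable
from lumideconv.simulate import make_study

STUDY_SEED = 1
NULL_SEED = 11


@pytest.fixture(scope="session")
def study():
    """Default co-exposure study: 10 types, 2200 genes, 40 bulk samples."""
    return make_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def contrast_dh_ctrl_lac(study):
    return run_contrast(study.bulk, "CTRL", "DH", "LAC")


@pytest.fixture(scope="session")
def contrast_dh_ctrl_tiss(study):
    return run_contrast(study.bulk, "CTRL", "DH", "TISS")


@pytest.fixture(scope="session")
def contrast_dh_dep_lac(study):
    return run_contrast(study.bulk, "DEP", "DH", "LAC")


@pytest.fixture(scope="session")
def contrast_dh_hdm_lac(study):
    return run_contrast(study.bulk, "HDM", "DH", "LAC")


@pytest.fixture(scope="session")
def null_study_contrasts():
    """Combination arm compositionally identical to both singles, no synergy."""
    s = make_study({"null_combination": True}, seed=NULL_SEED)
    c1 = run_contrast(s.bulk, "DEP", "DH", "LAC")
    c2 = run_contrast(s.bulk, "HDM", "DH", "LAC")
    return s, c1, c2


def toy_contrast(data: dict) -> ContrastTable:
    """Build a minimal contrast table from {gene: (log2_fc, q)} for set-logic tests."""
    genes = list(data)
    fc = np.array([data[g][0] for g in genes], dtype=float)
    q = np.array([data[g][1] for g in genes], dtype=float)
    t = pd.DataFrame(
        {
            "log2_fc": fc,
            "p_value": q / 2,
            "q_value": q,
            "mean_expr_ref": 100.0,
            "mean_expr_alt": 100.0 * 2.0**fc,
            "des": fc * -np.log10(np.maximum(q, 1e-300)),
        },
        index=genes,
    )
    return ContrastTable(table=t, label="toy")
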