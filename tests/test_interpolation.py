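"""DES scoring, marker-set interpolation and compartment delta-DES."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lumideconv.interpolation import (
    compute_des,
    delta_des,
    interpolate_cell_types,
    marker_specificity,
)
from lumideconv.io import MarkerSetCollection, SingleCellDataset, ValidationError
from lumideconv.simulate import generate_sc, generate_signatures

from .conftest import toy_contrast


class TestDES:
    @pytest.mark.parametrize(
        "log2_fc,q,expected",
        [(0.0, 0.5, 0.0), (1.0, 0.1, 1.0), (-2.0, 0.01, -4.0)],
    )
    def test_closed_form(self, log2_fc, q, expected):
        assert compute_des(log2_fc, q) == pytest.approx(expected, abs=1e-12)

    def test_zero_q_floored_not_raised(self):
        v = compute_des(1.0, 0.0)
        assert np.isfinite(v) and v == pytest.approx(300.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        fc=st.floats(min_value=0.01, max_value=20, allow_nan=False),
        q1=st.floats(min_value=1e-10, max_value=1.0, exclude_min=False),
        q2=st.floats(min_value=1e-10, max_value=1.0),
    )
    def test_odd_in_fc_and_monotone_in_q(self, fc, q1, q2):
        assert compute_des(-fc, q1) == pytest.approx(-compute_des(fc, q1))
        lo, hi = sorted([q1, q2])
        assert compute_des(fc, lo) >= compute_des(fc, hi)


class TestInterpolation:
    def test_two_gene_mean_and_sem(self):
        ct = toy_contrast({"gA": (1.0, 0.1), "gB": (3.0, 0.1)})  # DES 1.0 and 3.0
        markers = MarkerSetCollection(sets={"AAM": ["gA", "gB"]})
        out = interpolate_cell_types(ct, markers)
        assert out.loc["AAM", "mean_des"] == pytest.approx(2.0)
        assert out.loc["AAM", "sem_des"] == pytest.approx(1.0)
        assert out.loc["AAM", "n_genes_used"] == 2

    def test_single_gene_sem_zero_and_missing_listed(self):
        ct = toy_contrast({"gA": (-2.0, 0.1)})
        markers = MarkerSetCollection(sets={"MC": ["gA", "ghost"]})
        out = interpolate_cell_types(ct, markers)
        assert out.loc["MC", "mean_des"] == pytest.approx(-2.0)
        assert out.loc["MC", "sem_des"] == 0.0
        assert out.loc["MC", "genes_missing"] == "ghost"

    def test_unmeasured_set_skipped_and_all_missing_errors(self):
        ct = toy_contrast({"gA": (1.0, 0.1)})
        markers = MarkerSetCollection(sets={"A": ["gA"], "B": ["nope"]})
        out = interpolate_cell_types(ct, markers)
        assert list(out.index) == ["A"]
        with pytest.raises(ValidationError):
            interpolate_cell_types(ct, MarkerSetCollection(sets={"B": ["nope"]}))

    def test_most_expanded_type_scores_highest(self, study, contrast_dh_ctrl_lac):
        """The cell type whose composition rises most in the combination arm
        attains the top mean DES."""
        scores = interpolate_cell_types(contrast_dh_ctrl_lac, study.markers)
        comp = study.truth.composition
        change = comp.loc[("DH", "LAC")] / comp.loc[("CTRL", "LAC")]
        assert scores["mean_des"].idxmax() == change.idxmax() == "AAM"

    def test_unshifted_types_score_below_shifted(self):
        """Types with unchanged composition sit below every truly shifted
        type in |mean DES| (small dedicated study)."""
        from lumideconv.diffexp import run_contrast
        from lumideconv.simulate import generate_bulk

        truth = generate_signatures(4, 10, 300, seed=33)
        comp = truth.composition.copy()
        comp.loc[("CTRL", "LAC")] = [0.1, 0.2, 0.3, 0.4]
        comp.loc[("DH", "LAC")] = [0.3, 0.2, 0.3, 0.2]  # types 2,3 unchanged
        truth.composition = comp
        bulk = generate_bulk(truth, 5, seed=34, groups=("CTRL", "DH"), compartments=("LAC",))
        ct = run_contrast(bulk, "CTRL", "DH", "LAC")
        markers = MarkerSetCollection(sets={k: list(v) for k, v in truth.marker_sets.items()})
        scores = interpolate_cell_types(ct, markers)["mean_des"].abs()
        types = list(truth.signature_matrix.columns)
        shifted_min = min(scores[types[0]], scores[types[3]])
        assert scores[types[1]] < shifted_min
        assert scores[types[2]] < shifted_min


class TestDeltaDES:
    def test_values_and_ordering(self):
        lac = toy_contrast({"shared": (4.0, 1e-4), "lonly": (8.0, 1e-8), "flat": (5.0, 1e-5)})
        tiss = toy_contrast({"shared": (4.0, 1e-4), "lonly": (0.0, 1.0), "flat": (5.0, 1e-5)})
        out = delta_des(lac, tiss)
        assert out.loc["flat", "delta"] == pytest.approx(0.0)
        assert out.loc["shared", "delta"] == pytest.approx(0.0)
        assert out.index[0] == "lonly"  # compartment-exclusive responder first
        # zero-delta ties broken lexicographically
        assert list(out.index[1:]) == ["flat", "shared"]

    def test_antisymmetry(self, contrast_dh_ctrl_lac, contrast_dh_ctrl_tiss):
        fwd = delta_des(contrast_dh_ctrl_lac, contrast_dh_ctrl_tiss)
        rev = delta_des(contrast_dh_ctrl_tiss, contrast_dh_ctrl_lac)
        merged = fwd["delta"].sort_index() + rev["delta"].sort_index()
        np.testing.assert_allclose(merged, 0.0, atol=1e-9)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            delta_des(toy_contrast({"a": (1, 0.1)}), toy_contrast({"b": (1, 0.1)}))


class TestMarkerSpecificity:
    def _tiny_sc(self):
        import anndata

        # 4 types x 3 cells, equal per-cell depth so per-cell normalization
        # is a no-op: geneX exclusive to T1, geneU uniform across types
        X = np.zeros((12, 3), dtype=np.int64)
        types = np.repeat(["T1", "T2", "T3", "T4"], 3)
        X[types == "T1", 0] = 5          # geneX
        X[:, 1] = 5                      # geneU
        X[types != "T1", 2] = 5          # filler equalizing depth
        obs = pd.DataFrame(
            {
                "cell_type": types,
                "sample_id": "s1",
                "group": "CTRL",
            },
            index=[f"c{i}" for i in range(12)],
        )
        ad = anndata.AnnData(
            X=X, obs=obs, var=pd.DataFrame(index=["geneX", "geneU", "filler"])
        )
        ad.uns["total_lavage_cells_per_lung"] = {"s1": 1000}
        return SingleCellDataset(adata=ad)

    def test_exclusive_and_uniform_genes(self):
        sc = self._tiny_sc()
        spec = marker_specificity(
            sc, MarkerSetCollection(sets={"T1": ["geneX"], "T2": ["geneU"]})
        )
        assert spec["T1"] == pytest.approx(1.0)
        assert spec["T2"] == pytest.approx(0.25)

    def test_set_without_matching_type_skipped(self):
        sc = self._tiny_sc()
        spec = marker_specificity(
            sc, MarkerSetCollection(sets={"T1": ["geneX"], "GHOST": ["geneU"]})
        )
        assert list(spec.index) == ["T1"]

    def test_synthetic_exclusive_markers_near_perfect(self, study):
        spec = marker_specificity(study.sc, study.markers)
        assert (spec >= 0.95).all()
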