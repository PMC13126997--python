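"""NB differential expression: exactness on clean cases, calibration under
noise, agreement with independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lumideconv.diffexp import (
    adjust_bh,
    call_degs,
    compute_rpkm,
    compute_size_factors,
    fit_gene_nb,
    fold_over_control,
    run_contrast,
    sensitivity_filter,
)
from lumideconv.io import ExpressionMatrix, SampleInfo, ValidationError

from .oracles import bh_stepup, median_of_ratios


def _matrix(counts: np.ndarray, groups=None) -> ExpressionMatrix:
    n_genes, n_samples = counts.shape
    groups = groups or ["CTRL"] * n_samples
    samples = [
        SampleInfo(f"s{i}", groups[i], "LAC", i + 1) for i in range(n_samples)
    ]
    df = pd.DataFrame(
        counts, index=[f"g{j}" for j in range(n_genes)], columns=[s.sample_id for s in samples]
    )
    lengths = pd.Series(1000, index=df.index)
    return ExpressionMatrix(counts=df, gene_lengths_bp=lengths, samples=samples)


class TestSizeFactors:
    def test_doubled_sample_gets_factor_two(self):
        c = np.array([[10, 20], [5, 10], [50, 100]])
        f = compute_size_factors(_matrix(c))
        np.testing.assert_allclose(f.iloc[1] / f.iloc[0], 2.0)
        np.testing.assert_allclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_identical_samples_all_one(self):
        c = np.tile([[10], [5], [50]], (1, 4))
        f = compute_size_factors(_matrix(c))
        np.testing.assert_allclose(f, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(50, size=(30, 3))
        c[0] = 0  # one all-zero gene must be ignored by both routes
        f = compute_size_factors(_matrix(c))
        np.testing.assert_allclose(f.to_numpy(), median_of_ratios(c), rtol=1e-12)

    def test_fallback_when_no_common_gene(self):
        c = np.array([[5, 0], [0, 7]])
        f = compute_size_factors(_matrix(c))
        np.testing.assert_allclose(np.exp(np.mean(np.log(f))), 1.0)


class TestFitGeneNB:
    G = np.array([0] * 5 + [1] * 5)
    SF = np.ones(10)

    def test_equal_group_means_zero_fc(self):
        y = np.full(10, 100)
        fc, se, p = fit_gene_nb(y, self.G, self.SF)
        assert abs(fc) < 1e-9

    def test_exact_double_ratio(self):
        y = np.array([100, 110, 90, 105, 95, 200, 220, 180, 210, 190])
        fc, se, p = fit_gene_nb(y, self.G, self.SF)
        assert abs(fc - 1.0) < 1e-6  # group MLE means are the arithmetic means

    def test_all_zero_gene_flagged(self):
        fc, se, p = fit_gene_nb(np.zeros(10, dtype=int), self.G, self.SF)
        assert fc == 0.0 and p == 1.0 and np.isnan(se)

    def test_one_arm_zero_finite_fc_small_p(self):
        y = np.array([0, 0, 0, 0, 0, 80, 120, 100, 90, 110])
        fc, se, p = fit_gene_nb(y, self.G, self.SF)
        assert np.isfinite(fc) and fc > 5
        assert p < 1e-4

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            fit_gene_nb(np.array([1, 2, 3]), np.array([0, 0, 1]), np.ones(3))

    def test_large_count_fc_matches_mean_ratio(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            y = rng.poisson(10000, 10)
            fc, se, p = fit_gene_nb(y, self.G, self.SF)
            ratio = np.log2(y[5:].mean() / y[:5].mean())
            assert abs(fc - ratio) < 1e-3

    def test_size_factors_shift_fc(self):
        y = np.array([100] * 10)
        sf = np.where(self.G == 1, 2.0, 1.0)
        fc, se, p = fit_gene_nb(y, self.G, sf)
        assert abs(fc + 1.0) < 1e-6  # same counts at double depth = halved expression


class TestBH:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.42]), [0.42])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=25
        )
    )
    def test_matches_oracle_and_dominates_p(self, p):
        q = adjust_bh(p)
        np.testing.assert_allclose(q, bh_stepup(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestRPKM:
    def test_unit_case(self):
        m = _matrix(np.array([[10], [999_990]]))
        m.gene_lengths_bp.loc[:] = [1000, 10_000]
        # library = 10^6 reads total
        rpkm = compute_rpkm(m)
        np.testing.assert_allclose(rpkm.iloc[0, 0], 10.0)

    def test_scale_invariance_and_zeros(self):
        rng = np.random.default_rng(3)
        c = rng.poisson(20, size=(50, 4))
        c[7] = 0
        m1 = _matrix(c)
        m2 = _matrix(c * 3)
        pd.testing.assert_frame_equal(compute_rpkm(m1), compute_rpkm(m2))
        assert (compute_rpkm(m1).iloc[7] == 0).all()

    def test_zero_library_rejected(self):
        m = _matrix(np.array([[0], [0]]))
        with pytest.raises(ValidationError):
            compute_rpkm(m)


class TestDEGCalls:
    def test_threshold_rule(self, contrast_dh_ctrl_lac):
        degs = call_degs(contrast_dh_ctrl_lac, 2.0, 0.05)
        t = contrast_dh_ctrl_lac.table
        for g in degs.genes:
            assert abs(t.loc[g, "log2_fc"]) >= 1.0
            assert t.loc[g, "q_value"] < 0.05
            assert degs.signs[g] == np.sign(t.loc[g, "log2_fc"])
        # stricter thresholds shrink the set (monotonicity)
        strict = call_degs(contrast_dh_ctrl_lac, 4.0, 0.01)
        assert set(strict.genes) <= set(degs.genes)

    def test_examples(self, contrast_dh_ctrl_lac):
        from .conftest import toy_contrast

        ct = toy_contrast({"up": (1.32, 0.01), "weak": (0.58, 0.001), "nonsig": (1.58, 0.2)})
        degs = call_degs(ct, 2.0, 0.05)
        assert list(degs.genes) == ["up"] and degs.signs["up"] == 1

    def test_sensitivity_filter_fraction(self):
        from .conftest import toy_contrast

        data = {f"g{i}": (2.0, 0.01) for i in range(10)}
        ct = toy_contrast(data)
        degs = call_degs(ct, 2.0, 0.05)
        rpkm = pd.Series(1.0, index=list(data))
        rpkm.iloc[0] = 0.005  # one gene below the detection floor
        kept, frac = sensitivity_filter(ct, degs, rpkm, floor=0.01)
        assert len(kept) == 9 and frac == 0.9


class TestFoldOverControl:
    def test_basic(self):
        np.testing.assert_allclose(fold_over_control([6.0], [1.0, 3.0]), [3.0])
        ctrl = np.array([1.0, 2.0, 3.0])
        assert fold_over_control(ctrl, ctrl).mean() == pytest.approx(1.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            fold_over_control([1.0], [0.0, 0.0])


class TestContrastLevel:
    def test_contrast_invariants(self, contrast_dh_ctrl_lac):
        t = contrast_dh_ctrl_lac.table
        assert (t["q_value"] >= t["p_value"] - 1e-12).all()
        nz = t["q_value"] < 1
        assert (np.sign(t.loc[nz, "des"]) == np.sign(t.loc[nz, "log2_fc"])).all()
        assert (t.loc[t["log2_fc"] == 0, "des"] == 0).all()

    def test_agrees_with_pydeseq2_mle(self):
        """Independent NB route: unshrunk pydeseq2 log2FC on the same counts."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(21)
        n_genes = 60
        mu = rng.lognormal(4, 1, n_genes)
        effect = np.ones(n_genes)
        effect[:20] = rng.uniform(2, 6, 20)
        rows = []
        for i in range(n_genes):
            m = np.concatenate([np.full(5, mu[i]), np.full(5, mu[i] * effect[i])])
            lam = rng.gamma(10.0, 0.1 * m)
            rows.append(rng.poisson(lam))
        counts = np.array(rows)
        m = _matrix(counts, groups=["CTRL"] * 5 + ["DH"] * 5)
        ours = run_contrast(m, "CTRL", "DH").table

        meta = pd.DataFrame({"condition": ["A"] * 5 + ["B"] * 5}, index=m.counts.columns)
        dds = DeseqDataSet(
            counts=m.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        theirs = ds.results_df["log2FoldChange"]
        r = np.corrcoef(ours["log2_fc"], theirs.loc[ours.index])[0, 1]
        assert r > 0.95
        # strong effects agree in direction and call
        strong = ours.index[:20]
        assert (np.sign(ours.loc[strong, "log2_fc"]) == np.sign(theirs.loc[strong])).all()
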