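"""Single-cell normalization, rates, per-lung scaling and group comparison."""

import anndata
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lumideconv.io import SingleCellDataset, ValidationError
from lumideconv.sc_quant import (
    cells_per_lung,
    compare_groups,
    normalize_per_cell,
    positive_cells_per_1000,
    total_mrna_per_lung,
)

from .oracles import pooled_t


def _sc(X, types, samples, groups, lavage=None, genes=None):
    X = np.asarray(X, dtype=np.int64)
    obs = pd.DataFrame(
        {"cell_type": types, "sample_id": samples, "group": groups},
        index=[f"c{i}" for i in range(X.shape[0])],
    )
    var = pd.DataFrame(index=genes or [f"g{j}" for j in range(X.shape[1])])
    ad = anndata.AnnData(X=X, obs=obs, var=var)
    ad.uns["total_lavage_cells_per_lung"] = lavage or {}
    return SingleCellDataset(adata=ad)


class TestNormalization:
    def test_half_depth_cell_doubled(self):
        sc = _sc([[2500, 2500], [5000, 5000]], ["A", "A"], ["s1", "s1"], ["CTRL", "CTRL"])
        out = normalize_per_cell(sc, target=10_000)
        np.testing.assert_allclose(np.asarray(out.adata.X)[0], [5000, 5000])
        # raw counts preserved alongside
        assert out.counts[0, 0] == 2500

    def test_totals_hit_target(self, study):
        out = normalize_per_cell(study.sc)
        totals = np.asarray(out.adata.X).sum(axis=1)
        np.testing.assert_allclose(totals, 10_000.0, atol=1e-6)

    def test_target_one_gives_proportions(self):
        sc = _sc([[3, 1]], ["A"], ["s1"], ["CTRL"])
        out = normalize_per_cell(sc, target=1)
        np.testing.assert_allclose(np.asarray(out.adata.X)[0], [0.75, 0.25])

    def test_zero_total_cell_rejected(self):
        sc = _sc([[0, 0]], ["A"], ["s1"], ["CTRL"])
        with pytest.raises(ValidationError):
            normalize_per_cell(sc)


class TestPositiveRates:
    def test_rates_per_1000(self):
        X = np.zeros((500, 1), dtype=int)
        X[:50, 0] = 3
        sc = _sc(X, ["A"] * 500, ["s1"] * 500, ["CTRL"] * 500)
        out = positive_cells_per_1000(sc, "g0")
        assert out.loc[("CTRL", "A"), "per_1000"] == pytest.approx(100.0)

    @pytest.mark.parametrize("n_pos,expected", [(0, 0.0), (10, 1000.0)])
    def test_extremes_and_bounds(self, n_pos, expected):
        X = np.zeros((10, 1), dtype=int)
        X[:n_pos, 0] = 1
        sc = _sc(X, ["A"] * 10, ["s1"] * 10, ["CTRL"] * 10)
        out = positive_cells_per_1000(sc, "g0")
        assert out["per_1000"].iloc[0] == expected
        assert ((out["per_1000"] >= 0) & (out["per_1000"] <= 1000)).all()

    def test_unknown_gene_rejected(self):
        sc = _sc([[1]], ["A"], ["s1"], ["CTRL"])
        with pytest.raises(ValidationError):
            positive_cells_per_1000(sc, "ghost")


class TestCellsPerLung:
    def test_proportion_scaling(self):
        types = ["X"] * 200 + ["Y"] * 800
        sc = _sc(
            np.ones((1000, 1)), types, ["s1"] * 1000, ["CTRL"] * 1000,
            lavage={"s1": 500_000},
        )
        out = cells_per_lung(sc).set_index("cell_type")
        assert out.loc["X", "cells_per_lung"] == pytest.approx(1e5)
        assert out.loc["Y", "cells_per_lung"] == pytest.approx(4e5)

    def test_conservation_exact(self, study):
        out = cells_per_lung(study.sc)
        sums = out.groupby("sample_id")["cells_per_lung"].sum()
        for sid, total in study.sc.lavage_totals.items():
            assert sums[sid] == pytest.approx(total, abs=1e-9)

    def test_recovers_generating_composition(self, study):
        """Per-lung proportions (cells_per_lung / lavage total) pooled over
        replicates match the generating composition within binomial 99% CIs."""
        out = cells_per_lung(study.sc)
        lavage = study.sc.lavage_totals
        obs = study.sc.adata.obs
        cells_per_sample = obs.groupby("sample_id", observed=True).size()
        comp = study.truth.composition
        for group in ("CTRL", "DH"):
            sub = out[out["group"] == group].copy()
            # invert the scaling: fraction of analysed cells, then pooled count
            sub["frac"] = [
                r.cells_per_lung / lavage[r.sample_id] for r in sub.itertuples()
            ]
            sub["count"] = [
                round(f * cells_per_sample[s]) for f, s in zip(sub["frac"], sub["sample_id"])
            ]
            pooled = sub.groupby("cell_type")["count"].sum()
            n_total = int(cells_per_sample[sub["sample_id"].unique()].sum())
            true_pi = comp.loc[(group, "LAC")]
            # joint 99% over the 10 types: Sidak-adjusted per-type level
            level = (1 - 0.01) ** (1 / len(true_pi))
            for ct in true_pi.index:
                lo, hi = stats.binom.interval(level, n_total, true_pi[ct])
                assert lo <= pooled.get(ct, 0) <= hi

    def test_missing_lavage_total_skips_sample(self):
        sc = _sc(np.ones((4, 1)), ["A"] * 4, ["s1", "s1", "s2", "s2"], ["CTRL"] * 4,
                 lavage={"s1": 1000})
        out = cells_per_lung(sc)
        assert set(out["sample_id"]) == {"s1"}


class TestTotalMrnaPerLung:
    def _sc_expr(self):
        X = np.array([[20, 80], [20, 80], [0, 100], [0, 100]])
        return _sc(X, ["A", "A", "A", "A"], ["s1"] * 4, ["CTRL"] * 4, lavage={"s1": 100_000})

    def test_mean_times_cells(self):
        sc = normalize_per_cell(self._sc_expr(), target=100)
        out = total_mrna_per_lung(sc, "g0").set_index("cell_type")
        # normalized g0: (20, 20, 0, 0) -> mean 10; 1e5 cells -> 1e6 molecules
        assert out.loc["A", "total_per_lung"] == pytest.approx(1e6)

    def test_zero_cell_exclusion_convention(self):
        sc = normalize_per_cell(self._sc_expr(), target=100)
        out = total_mrna_per_lung(sc, "g0", exclude_zero_cells=True).set_index("cell_type")
        assert out.loc["A", "mean_expr_per_cell"] == pytest.approx(20.0)

    def test_linearity_in_lavage_total(self):
        sc1 = normalize_per_cell(self._sc_expr(), target=100)
        sc2 = self._sc_expr()
        sc2.adata.uns["total_lavage_cells_per_lung"]["s1"] = 200_000
        sc2 = normalize_per_cell(sc2, target=100)
        a = total_mrna_per_lung(sc1, "g0")["total_per_lung"]
        b = total_mrna_per_lung(sc2, "g0")["total_per_lung"]
        np.testing.assert_allclose(b, 2 * a)

    def test_requires_normalization_first(self):
        with pytest.raises(ValidationError):
            total_mrna_per_lung(self._sc_expr(), "g0")


class TestCompareGroups:
    def test_closed_form_pooled_t(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, p, summary = compare_groups(a, b)
        assert t == pytest.approx(pooled_t(a, b))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=4))
        assert summary.loc["a", "mean"] == pytest.approx(2.0)

    def test_identical_groups(self):
        t, p, _ = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_negates_t_same_p(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 6.0, 9.0]
        t1, p1, _ = compare_groups(a, b)
        t2, p2, _ = compare_groups(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1.0], [2.0, 3.0])
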