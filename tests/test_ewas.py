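"""EWAS: correlation-test chain against an independent oracle,
vectorized screen consistency, Stouffer closed forms, top-CpG
selection, genomic-context summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clockforge import (cor_test_z, ewas_screen, island_association_summary,
                        region_summary, select_top_cpgs, stouffer_combine)
from clockforge.ewas import TopCpGSet


def oracle_chain(x, y, zmax=40.0):
    """Independent r -> t -> p -> z computation via scipy distribution
    functions, written before the implementation and kept separate
    from it."""
    n = len(x)
    r = stats.pearsonr(x, y).statistic
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(abs(t), n - 2)
    z = stats.norm.isf(p / 2)
    return r, t, p, np.sign(r) * min(z, zmax)


class TestCorTestZ:
    def test_orthogonal_vectors_give_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        rec = cor_test_z(x, y)
        assert rec.r == pytest.approx(0.0, abs=1e-15)
        assert rec.t == pytest.approx(0.0, abs=1e-12)
        assert rec.p == pytest.approx(1.0)
        assert rec.z == 0.0

    def test_perfect_correlation_saturates(self):
        x = np.arange(10.0)
        rec = cor_test_z(x, x)
        assert rec.z == 40.0 and rec.saturated
        rec_neg = cor_test_z(x, -x)
        assert rec_neg.z == -40.0

    def test_hand_example_six_points(self):
        x = np.arange(1.0, 7.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rec = cor_test_z(x, y)
        assert rec.r == pytest.approx(29 / 35, abs=1e-12)
        r, t, p, z = oracle_chain(x, y)
        assert rec.t == pytest.approx(t, abs=1e-10)
        assert rec.p == pytest.approx(p, abs=1e-12)
        assert rec.z == pytest.approx(z, abs=1e-10)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 51))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rec = cor_test_z(x, y)
            r, t, p, z = oracle_chain(x, y)
            assert rec.r == pytest.approx(r, abs=1e-8)
            assert rec.z == pytest.approx(z, abs=1e-8)

    def test_zero_variance_marks_invalid(self):
        rec = cor_test_z([1, 2, 3], [0.5, 0.5, 0.5])
        assert not rec.valid

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            cor_test_z([1, 2], [3, 4])


class TestEwasScreen:
    def test_equals_per_probe_loop(self, rng):
        X = pd.DataFrame(rng.uniform(size=(20, 15)),
                         columns=[f"cg{i}" for i in range(15)])
        ages = rng.uniform(0, 20, size=20)
        table = ewas_screen(X, ages)
        for probe in X.columns:
            rec = cor_test_z(ages, X[probe], probe=probe)
            assert table.loc[probe, "r"] == pytest.approx(rec.r, abs=1e-12)
            assert table.loc[probe, "z"] == pytest.approx(rec.z, abs=1e-10)

    def test_single_probe_matrix(self, rng):
        ages = rng.uniform(0, 20, size=12)
        col = rng.uniform(size=12)
        table = ewas_screen(pd.DataFrame({"cg0": col}), ages)
        rec = cor_test_z(ages, col)
        assert table.loc["cg0", "z"] == pytest.approx(rec.z, abs=1e-12)

    def test_null_calibration_permuted_ages(self, rng):
        """Permuting ages breaks all association; p < 0.01 occurs at
        the nominal rate (binomial 99% CI around 0.01)."""
        n, p = 100, 5000
        X = pd.DataFrame(rng.uniform(size=(n, p)))
        ages = rng.permutation(rng.uniform(0, 20, size=n))
        table = ewas_screen(X, ages)
        rate = (table["p"] < 0.01).mean()
        ci = 2.576 * np.sqrt(0.01 * 0.99 / p)
        assert 0.01 - ci <= rate <= 0.01 + ci

    def test_missing_betas_pairwise(self, rng):
        ages = rng.uniform(0, 20, size=15)
        col = rng.uniform(size=15)
        col[:4] = np.nan
        table = ewas_screen(pd.DataFrame({"cg0": col}), ages)
        rec = cor_test_z(ages[4:], col[4:])
        assert table.loc["cg0", "n"] == 11
        assert table.loc["cg0", "r"] == pytest.approx(rec.r, abs=1e-12)


class TestStouffer:
    def test_closed_forms(self):
        z = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "t2": [1.0, -2.0, np.nan]},
                         index=list("abc"))
        out = stouffer_combine(z)
        assert out["a"] == pytest.approx(np.sqrt(2.0))
        assert out["b"] == pytest.approx(0.0)
        assert out["c"] == pytest.approx(3.0)  # single present tissue

    def test_k_replicates_scale_sqrt_k(self):
        for k in (1, 2, 5, 9):
            z = pd.DataFrame({f"t{i}": [1.7] for i in range(k)}, index=["p"])
            assert stouffer_combine(z)["p"] == pytest.approx(1.7 * np.sqrt(k))

    def test_weights(self):
        z = pd.DataFrame({"t1": [2.0], "t2": [0.0]}, index=["p"])
        out = stouffer_combine(z, weights=[1.0, 0.0])
        assert out["p"] == pytest.approx(2.0)

    def test_all_missing_probe_rejected(self):
        z = pd.DataFrame({"t1": [np.nan]}, index=["p"])
        with pytest.raises(ValueError, match="no finite z"):
            stouffer_combine(z)


def _records(z_values, p_values=None, index=None):
    z = np.asarray(z_values, dtype=float)
    if p_values is None:
        p_values = 2 * stats.norm.sf(np.abs(z))
    idx = index or [f"cg{i:05d}" for i in range(len(z))]
    return pd.DataFrame({"z": z, "p": p_values, "valid": True},
                        index=pd.Index(idx, name="probe_id"))


class TestSelectTop:
    def test_cap_keeps_largest_z(self, rng):
        z = rng.uniform(6.5, 20, size=600)  # all p << 1e-8
        rec = _records(z)
        top = select_top_cpgs(rec, cap=500)
        assert len(top.hyper) == 500 and len(top.hypo) == 0
        brute = rec["z"].sort_values(ascending=False).index[:500]
        assert set(top.hyper) == set(brute)

    def test_no_probe_passes(self):
        top = select_top_cpgs(_records([1.0, -1.0]))
        assert top.hyper == [] and top.hypo == []

    def test_boundary_tie_breaks_lexicographically(self):
        z = [10.0] * 3
        rec = _records(z, index=["cgB", "cgA", "cgC"])
        top = select_top_cpgs(rec, cap=2)
        assert top.hyper == ["cgA", "cgB"]

    def test_row_order_invariance(self, rng):
        z = np.concatenate([rng.uniform(6, 15, 50), -rng.uniform(6, 15, 50)])
        rec = _records(z)
        top1 = select_top_cpgs(rec, cap=30)
        top2 = select_top_cpgs(rec.sample(frac=1, random_state=1), cap=30)
        assert top1.hyper == top2.hyper and top1.hypo == top2.hypo

    def test_threshold_enforced_against_brute_force(self, rng):
        z = rng.normal(scale=4, size=300)
        p = 2 * stats.norm.sf(np.abs(z))
        rec = _records(z, p)
        top = select_top_cpgs(rec, p_threshold=1e-3, cap=500)
        brute = set(rec.index[(p < 1e-3) & (z > 0)])
        assert set(top.hyper) == brute

    def test_disjoint_and_capped_invariants(self):
        with pytest.raises(ValueError):
            TopCpGSet(hyper=["a"], hypo=["a"], p_threshold=1e-8, cap=500)
        with pytest.raises(ValueError):
            TopCpGSet(hyper=["a", "b"], hypo=[], p_threshold=1e-8, cap=1)


class TestRegionSummary:
    def _annotation(self, regions, islands=None):
        idx = [f"cg{i:05d}" for i in range(len(regions))]
        return pd.DataFrame({
            "region": regions,
            "island": islands if islands is not None else [False] * len(regions),
        }, index=idx)

    def test_all_promoter_hyper_gives_proportion_one(self):
        ann = self._annotation(["promoter"] * 4)
        top = TopCpGSet(hyper=list(ann.index[:3]), hypo=[], p_threshold=1e-8, cap=500)
        out = region_summary(top, ann)
        assert out.loc["promoter", "prop_hyper"] == 1.0

    def test_balanced_intron_gives_half(self):
        ann = self._annotation(["intron"] * 4)
        top = TopCpGSet(hyper=list(ann.index[:2]), hypo=list(ann.index[2:]),
                        p_threshold=1e-8, cap=500)
        assert region_summary(top, ann).loc["intron", "prop_hyper"] == 0.5

    def test_unannotated_probe_rejected(self):
        ann = self._annotation(["exon"])
        top = TopCpGSet(hyper=["cgZZZ"], hypo=[], p_threshold=1e-8, cap=500)
        with pytest.raises(ValueError, match="cgZZZ"):
            region_summary(top, ann)

    def test_promoter_biased_panel_shows_gradient(self, cat_panel):
        """The generator places age-gain probes preferentially in
        promoters/islands; the summary must recover a higher
        hypermethylated proportion in promoters than introns."""
        from clockforge import ewas_screen as screen
        _, (matrix, sheet, annotation, truth) = cat_panel
        records = screen(matrix, sheet["age"])
        top = select_top_cpgs(records, p_threshold=1e-4, cap=500)
        out = region_summary(top, annotation)
        assert out.loc["promoter", "prop_hyper"] > out.loc["intron", "prop_hyper"]


class TestIslandSummary:
    def test_identical_distributions_null(self, rng):
        z = rng.normal(size=400)
        rec = _records(z)
        ann = pd.DataFrame({"region": ["exon"] * 400,
                            "island": [i % 2 == 0 for i in range(400)]},
                           index=rec.index)
        out = island_association_summary(rec, ann)
        assert abs(out["mean_difference"]) < 0.3
        assert out["ranksum_p"] > 0.01

    def test_constructed_shift_recovered(self, rng):
        z = rng.normal(size=400)
        island = np.array([i % 2 == 0 for i in range(400)])
        z[island] += 2.0
        rec = _records(z)
        ann = pd.DataFrame({"region": ["exon"] * 400, "island": island}, index=rec.index)
        out = island_association_summary(rec, ann)
        assert out["mean_difference"] == pytest.approx(2.0, abs=0.3)
        assert out["ranksum_p"] < 1e-10

    def test_single_probe_group_rejected(self, rng):
        rec = _records(rng.normal(size=5))
        ann = pd.DataFrame({"region": ["exon"] * 5,
                            "island": [True] + [False] * 4}, index=rec.index)
        with pytest.raises(ValueError, match="island"):
            island_association_summary(rec, ann)
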