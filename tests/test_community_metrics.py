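import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import kstest

from rstarcomp import community_metrics as cm

from conftest import community_fixture


def anosim_r_oracle(d, groups):
    """Direct-definition oracle: explicit rank computation, no shortcuts."""
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [d[i, j] for i, j in pairs]
    order = sorted(range(len(vals)), key=lambda k: vals[k])
    ranks = [0.0] * len(vals)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[k]]:
            j += 1
        mid = (k + j) / 2.0 + 1.0
        for t in range(k, j + 1):
            ranks[order[t]] = mid
        k = j + 1
    within = [ranks[k] for k, (i, j) in enumerate(pairs) if groups[i] == groups[j]]
    between = [ranks[k] for k, (i, j) in enumerate(pairs) if groups[i] != groups[j]]
    m = len(pairs)
    return (sum(between) / len(between) - sum(within) / len(within)) / (m / 2.0)


def indval_oracle(x, groups):
    """Dufrene-Legendre per-taxon IndVal by the direct formula."""
    uniq = sorted(set(groups))
    out = []
    for t in range(x.shape[1]):
        best = 0.0
        for g in uniq:
            rows = [i for i, gg in enumerate(groups) if gg == g]
            mean_g = sum(x[i, t] for i in rows) / len(rows)
            denom = 0.0
            for g2 in uniq:
                rows2 = [i for i, gg in enumerate(groups) if gg == g2]
                denom += sum(x[i, t] for i in rows2) / len(rows2)
            a = mean_g / denom if denom > 0 else 0.0
            b = sum(1 for i in rows if x[i, t] > 0) / len(rows)
            best = max(best, a * b)
        out.append(best)
    return np.array(out)


class TestRelativeAbundance:
    def test_basic(self):
        t = pd.DataFrame({"week": [1, 1], "mesocosm": ["M1", "M1"],
                          "treatment": ["G", "G"], "taxon": ["a", "b"],
                          "count": [30, 70]})
        out = cm.relative_abundance(t)
        assert list(out["proportion"]) == [0.3, 0.7]

    def test_single_taxon(self):
        t = pd.DataFrame({"week": [1], "mesocosm": ["M1"], "treatment": ["G"],
                          "taxon": ["a"], "count": [5]})
        assert cm.relative_abundance(t)["proportion"].iloc[0] == 1.0

    def test_rows_sum_to_one(self):
        out = cm.relative_abundance(community_fixture(seed=4))
        sums = out.groupby(["week", "mesocosm"])["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_all_zero_sample_errors(self):
        t = pd.DataFrame({"week": [1], "mesocosm": ["M1"], "treatment": ["G"],
                          "taxon": ["a"], "count": [0]})
        with pytest.raises(ValueError):
            cm.relative_abundance(t)


class TestDeltaRelativeAbundance:
    @staticmethod
    def _table(p1, p10, reps=4, taxon="a", other="b", total=1000):
        rows = []
        for r in range(reps):
            for wk, p in ((1, p1), (10, p10)):
                rows.append({"week": wk, "mesocosm": f"M{r}", "treatment": "G",
                             "taxon": taxon, "count": int(total * p)})
                rows.append({"week": wk, "mesocosm": f"M{r}", "treatment": "G",
                             "taxon": other, "count": int(total * (1 - p))})
        return pd.DataFrame(rows)

    def test_simple_delta(self):
        out = cm.delta_relative_abundance(self._table(0.1, 0.6), "a")
        assert out["delta"].iloc[0] == pytest.approx(0.5)
        assert len(out["replicates"].iloc[0]) == 4

    def test_unchanged_composition(self):
        out = cm.delta_relative_abundance(self._table(0.4, 0.4), "a")
        assert out["delta"].iloc[0] == pytest.approx(0.0)

    def test_absent_taxon_errors(self):
        with pytest.raises(KeyError):
            cm.delta_relative_abundance(self._table(0.1, 0.2), "zzz")

    def test_missing_week_errors(self):
        t = self._table(0.1, 0.2)
        with pytest.raises(ValueError):
            cm.delta_relative_abundance(t[t["week"] == 1], "a")


class TestPielou:
    def test_uniform_is_one(self):
        assert cm.pielou_evenness([0.25] * 4) == pytest.approx(1.0, abs=1e-12)

    def test_skewed_value(self):
        # H' = -(0.97 ln 0.97 + 3 * 0.01 ln 0.01); J = H'/ln 4
        p = [0.97, 0.01, 0.01, 0.01]
        h = -sum(q * math.log(q) for q in p)
        assert cm.pielou_evenness(p) == pytest.approx(h / math.log(4), abs=1e-12)
        assert cm.pielou_evenness(p) == pytest.approx(0.1206, abs=5e-3)

    def test_single_taxon_nan(self):
        assert math.isnan(cm.pielou_evenness([1.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds(self, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(6))
        assert 0.0 <= cm.pielou_evenness(p) <= 1.0


class TestHellinger:
    def test_quarter_row(self):
        out = cm.hellinger([[1, 1, 1, 1]])
        assert np.allclose(out, 0.5)

    def test_disjoint_row(self):
        assert np.allclose(cm.hellinger([[4, 0]]), [[1, 0]])

    def test_unit_norms(self):
        x = np.random.default_rng(2).poisson(20, (8, 5)) + 1
        norms = np.linalg.norm(cm.hellinger(x), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_zero_row_errors(self):
        with pytest.raises(ValueError):
            cm.hellinger([[0, 0]])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = community_fixture(seed=1)
        d = cm.bray_curtis(t)
        assert np.allclose(np.diag(d.values), 0.0)
        assert np.all((d.values >= 0) & (d.values <= 1))

    def test_disjoint_samples_one(self):
        rows = []
        for meso, taxon in (("M1", "a"), ("M2", "b")):
            for tx in ("a", "b"):
                rows.append({"week": 1, "mesocosm": meso, "treatment": meso,
                             "taxon": tx, "count": 10 if tx == taxon else 0})
        d = cm.bray_curtis(pd.DataFrame(rows))
        assert d.values[0, 1] == pytest.approx(1.0)


class TestAnosim:
    def test_maximal_separation(self):
        n = 6
        groups = ["A"] * 3 + ["B"] * 3
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = 0.9 if groups[i] != groups[j] else 0.1
        dm = cm.DissimilarityMatrix(d, list(range(n)), groups)
        r, p = cm.anosim(dm, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)

    def test_all_equal_dissimilarities(self):
        n = 6
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = cm.DissimilarityMatrix(d, list(range(n)), ["A"] * 3 + ["B"] * 3)
        r, _ = cm.anosim(dm, n_perm=99, seed=0)
        assert r == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        x = rng.random((n, 4))
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum()
        groups = ["A", "A", "A", "B", "B", "B"]
        dm = cm.DissimilarityMatrix(d, list(range(n)), groups)
        r, _ = cm.anosim(dm, n_perm=99, seed=seed)
        assert r == pytest.approx(anosim_r_oracle(d, groups), abs=1e-12)

    def test_r_bounded(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.random((8, 3))
            d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
            np.fill_diagonal(d, 0.0)
            d = d / d.max()
            dm = cm.DissimilarityMatrix(d, list(range(8)),
                                        ["A"] * 4 + ["B"] * 4)
            r, p = cm.anosim(dm, n_perm=99, seed=seed)
            assert -1.0 <= r <= 1.0
            assert 0.0 < p <= 1.0

    def test_single_member_group_rejected(self):
        d = np.zeros((3, 3))
        dm = cm.DissimilarityMatrix(d, [0, 1, 2], ["A", "A", "B"])
        with pytest.raises(ValueError):
            cm.anosim(dm, n_perm=9)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError):
            cm.DissimilarityMatrix(d, [0, 1], ["A", "B"])

    def test_null_p_roughly_uniform(self):
        # small version of the acceptance calibration (500 datasets there)
        rng = np.random.default_rng(0)
        pvals = []
        for i in range(100):
            x = rng.random((8, 4))
            d = np.abs(x[:, None, :] - x[None, :, :]).sum(-1)
            np.fill_diagonal(d, 0.0)
            dm = cm.DissimilarityMatrix(d / d.max(), list(range(8)),
                                        ["A"] * 4 + ["B"] * 4)
            _, p = cm.anosim(dm, n_perm=99, seed=1000 + i)
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPropertyBased:
    @given(arrays(np.float64, (5, 4),
                  elements=st.floats(0.0, 1e6, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_hellinger_rows_unit_norm(self, x):
        if np.any(x.sum(axis=1) <= 0):
            with pytest.raises(ValueError):
                cm.hellinger(x)
        else:
            norms = np.linalg.norm(cm.hellinger(x), axis=1)
            assert np.allclose(norms, 1.0, atol=1e-9)

    @given(arrays(np.float64, st.integers(2, 10),
                  elements=st.floats(1e-6, 1e3, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_pielou_bounds(self, p):
        j = cm.pielou_evenness(p)
        assert 0.0 <= j <= 1.0 + 1e-12


class TestIndval:
    def test_perfect_indicator(self):
        t = community_fixture(seed=0, n_groups=2, n_per=3, n_taxa=2)
        # make t1 exclusive to G1 and present in all its samples
        t.loc[(t["treatment"] == "G2") & (t["taxon"] == "t1"), "count"] = 0
        out = cm.indval(t, week=1, n_perm=99, seed=0)
        row = out[out["taxon"] == "t1"].iloc[0]
        assert row["indval"] == pytest.approx(1.0)
        assert row["group"] == "G1"

    def test_even_two_group_taxon(self):
        rows = []
        for g in ("G1", "G2"):
            for i in range(3):
                rows.append({"week": 1, "mesocosm": f"{g}m{i}", "treatment": g,
                             "taxon": "a", "count": 10})
        out = cm.indval(pd.DataFrame(rows), week=1, n_perm=99, seed=0)
        assert out["indval"].iloc[0] == pytest.approx(0.5)

    def test_absent_taxon(self):
        t = community_fixture(seed=0, n_taxa=3)
        t.loc[t["taxon"] == "t2", "count"] = 0
        out = cm.indval(t, week=1, n_perm=99, seed=0)
        row = out[out["taxon"] == "t2"].iloc[0]
        assert row["indval"] == 0.0 and row["p"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_oracle(self, seed):
        t = community_fixture(seed=seed, n_groups=3, n_per=3, n_taxa=6)
        out = cm.indval(t, week=1, n_perm=49, seed=seed)
        wide = cm.community_matrix(t)
        gmap = t.drop_duplicates(["week", "mesocosm"]).set_index(
            ["week", "mesocosm"])["treatment"]
        groups = [gmap.loc[l] for l in wide.index]
        oracle = indval_oracle(wide.to_numpy(float), groups)
        assert np.allclose(out.sort_values("taxon")["indval"].to_numpy(),
                           oracle[np.argsort(wide.columns)], atol=1e-12)

    def test_indval_bounded(self):
        out = cm.indval(community_fixture(seed=3, n_groups=4, n_per=2),
                        week=1, n_perm=49, seed=3)
        assert ((out["indval"] >= 0) & (out["indval"] <= 1)).all()
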