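"""Concordance statistics against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from qmprofiler import stats as st


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)


def tau_b_bruteforce(x, y):
    """Kendall tau-b by explicit pair counting with tie corrections."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def wilcoxon_bruteforce(x, y):
    """Signed-rank two-sided p by enumerating all sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    cdf = np.mean(ws <= w_obs + 1e-9)
    sf = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2 * min(cdf, sf))


def mannwhitney_bruteforce(g1, g2):
    """U two-sided p by enumerating all group assignments of pooled ranks."""
    n1 = len(g1)
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    cdf = np.mean(us <= u_obs + 1e-9)
    sf = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(cdf, sf))


# ---------------------------------------------------------------------------


class TestRichness:
    def test_counts_positive_entries(self):
        mat = pd.DataFrame({"s1": [1.0, 0.0, 2.0, 0.0, 5.0], "s2": [0.0] * 5})
        rich = st.observed_richness(mat)
        assert rich.tolist() == [3, 0]

    def test_scale_invariance(self, rng):
        mat = pd.DataFrame(rng.poisson(2.0, size=(10, 4)).astype(float))
        a = st.observed_richness(mat)
        b = st.observed_richness(mat * 7.3e9)
        pd.testing.assert_series_equal(a, b)


class TestBrayCurtis:
    def test_worked_values(self):
        assert st.bray_curtis_pair([1, 2, 3], [1, 2, 3]) == 0.0
        assert st.bray_curtis_pair([1, 0], [0, 4]) == 1.0
        assert st.bray_curtis_pair([2, 1], [1, 1]) == pytest.approx(0.2)

    def test_both_zero_pair_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert st.bray_curtis_pair([0, 0], [0, 0]) == 0.0
        assert "all-zero" in caplog.text

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            st.bray_curtis_pair([-1, 2], [1, 2])
        with pytest.raises(ValueError):
            st.bray_curtis_matrix(pd.DataFrame({"a": [-1.0], "b": [1.0]}))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        x=hst.lists(hst.floats(0, 100), min_size=2, max_size=8),
        y=hst.lists(hst.floats(0, 100), min_size=2, max_size=8),
    )
    def test_symmetry_and_range(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) == 0 or sum(y) == 0:
            return
        d = st.bray_curtis_pair(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(st.bray_curtis_pair(y, x))

    def test_matrix_matches_pairwise(self, rng):
        mat = pd.DataFrame(
            rng.uniform(0, 5, size=(6, 4)), columns=["a", "b", "c", "d"]
        )
        dm = st.bray_curtis_matrix(mat)
        assert dm["a", "b"] == pytest.approx(st.bray_curtis_pair(mat["a"], mat["b"]))
        assert dm["a", "a"] == 0.0

    def test_normalize_option_compares_compositions(self):
        mat = pd.DataFrame({"a": [2.0, 2.0], "b": [20.0, 20.0]})
        assert st.bray_curtis_matrix(mat)["a", "b"] > 0.5
        assert st.bray_curtis_matrix(mat, normalize=True)["a", "b"] == 0.0


class TestPcoa:
    def test_collinear_points(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = st.pcoa(d)
        eig = res.eigvals.to_numpy()
        assert (eig > 1e-9).sum() == 1
        coords = res.samples.to_numpy()
        recon = squareform(pdist(coords))
        np.testing.assert_allclose(recon, d, atol=1e-9)

    def test_identical_points_give_zero_coordinates(self):
        d = np.zeros((4, 4))
        res = st.pcoa(d)
        np.testing.assert_allclose(res.samples.to_numpy(), 0.0, atol=1e-12)

    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(size=(7, 3))
        d = squareform(pdist(pts))
        res = st.pcoa(d)
        recon = squareform(pdist(res.samples.to_numpy()))
        np.testing.assert_allclose(recon, d, atol=1e-6)


class TestKendallConcordance:
    def test_worked_tau(self):
        # brute force: C=5, D=1 over 6 pairs -> 4/6
        a = [1, 2, 3, 4]
        b = [1, 3, 2, 4]
        df = _concordance_frame(a, b)
        assert df["tau"].iloc[0] == pytest.approx(2 / 3, abs=1e-9)

    def test_monotone_transform_gives_tau_one(self, rng):
        x = rng.uniform(0, 1, 8)
        df = _concordance_frame(x, np.exp(3 * x))
        assert df["tau"].iloc[0] == pytest.approx(1.0)

    def test_reversed_ranks_give_tau_minus_one(self, rng):
        x = rng.uniform(0, 1, 8)
        df = _concordance_frame(x, -x)
        assert df["tau"].iloc[0] == pytest.approx(-1.0)

    def test_matches_bruteforce_with_ties(self, rng):
        for _ in range(25):
            n = rng.integers(4, 9)
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            tau, _ = sps.kendalltau(x, y, variant="b")
            assert tau == pytest.approx(tau_b_bruteforce(x, y), abs=1e-12)

    def test_constant_genus_reported_missing(self):
        a = pd.DataFrame({"s1": [1.0, 5.0], "s2": [2.0, 5.0]},
                         index=["g1", "g2"])
        b = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]},
                         index=["g1", "g2"])
        out = st.top_genus_rank_concordance(a, b, a, n_top=2)
        assert np.isnan(out.loc["g2", "tau"])
        assert np.isfinite(out.loc["g1", "tau"])

    def test_top_selection_uses_reference_relative_abundance(self):
        ref = pd.DataFrame(
            {"s1": [100.0, 10.0, 1.0], "s2": [100.0, 10.0, 1.0]},
            index=["big", "mid", "small"],
        )
        out = st.top_genus_rank_concordance(ref, ref, ref, n_top=2)
        assert list(out.index) == ["big", "mid"]
        with pytest.raises(ValueError):
            st.top_genus_rank_concordance(ref, ref, ref, n_top=5)


def _concordance_frame(a, b):
    samples = [f"s{i}" for i in range(len(a))]
    fa = pd.DataFrame([list(a)], index=["g"], columns=samples)
    fb = pd.DataFrame([list(b)], index=["g"], columns=samples)
    return st.top_genus_rank_concordance(fa, fb, fa, n_top=1)


class TestCorrelate:
    def test_pearson_perfect_linear(self):
        r, p = st.correlate([1, 2, 3, 4], [3, 5, 7, 9], "pearson")
        assert r == pytest.approx(1.0)

    def test_spearman_monotone_nonlinear(self, rng):
        x = rng.uniform(0, 3, 12)
        rho, _ = st.correlate(x, np.exp(x), "spearman")
        r, _ = st.correlate(x, np.exp(x), "pearson")
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_spearman_worked_example(self):
        rho, _ = st.correlate([1, 2, 3], [3, 1, 2], "spearman")
        assert rho == pytest.approx(-0.5)

    def test_zero_variance_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            st.correlate([1, 1, 1], [1, 2, 3], "pearson")
        with pytest.raises(ValueError):
            st.correlate([1, 2], [1, 2], "pearson")

    def test_spearman_exact_p_matches_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = st.correlate(x, y, "spearman")
        # enumerate all 120 permutations directly
        rhos = [
            np.corrcoef(x, np.array(y)[list(perm)])[0, 1]
            for perm in itertools.permutations(range(5))
        ]
        expected = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected)


class TestPairedWilcoxon:
    def test_constant_shift_exact_p(self):
        x = np.arange(6.0)
        res = st.paired_wilcoxon(x, x + 1.0)
        assert res.pvalue == pytest.approx(2 / 64)

    def test_symmetry_under_exchange(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        a = st.paired_wilcoxon(x, y)
        b = st.paired_wilcoxon(y, x)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            st.paired_wilcoxon([1.0, 2.0], [1.0, 2.0])

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(20):
            n = rng.integers(3, 9)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.all(x == y):
                continue
            res = st.paired_wilcoxon(x, y)
            w_bf, p_bf = wilcoxon_bruteforce(x, y)
            assert res.statistic == pytest.approx(w_bf)
            assert res.pvalue == pytest.approx(p_bf, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        ours = st.paired_wilcoxon(x, y)
        ref = sps.wilcoxon(x, y, mode="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact(self, rng):
        # exact path at n=12 vs the large-sample approximation on same data
        x = rng.normal(size=12)
        y = x + rng.normal(0.3, 1.0, 12)
        exact = st.paired_wilcoxon(x, y).pvalue
        d = x - y
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        n = len(d)
        mean, var = n * (n + 1) / 4, n * (n + 1) * (2 * n + 1) / 24
        z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
        approx = min(1.0, 2 * sps.norm.sf(abs(z)))
        assert abs(approx - exact) < 0.01


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = st.mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(2 / 70)

    def test_identical_groups_p_one(self):
        res = st.mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.pvalue == 1.0

    def test_label_swap_reflects_u(self, rng):
        g1 = rng.normal(size=5)
        g2 = rng.normal(size=7)
        a = st.mann_whitney_u(g1, g2)
        b = st.mann_whitney_u(g2, g1)
        assert a.statistic + b.statistic == pytest.approx(35.0)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.mann_whitney_u([], [1.0])

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 5))
            g1 = rng.integers(0, 5, n1).astype(float)
            g2 = rng.integers(0, 5, n2).astype(float)
            res = st.mann_whitney_u(g1, g2)
            u_bf, p_bf = mannwhitney_bruteforce(g1, g2)
            assert res.statistic == pytest.approx(u_bf)
            assert res.pvalue == pytest.approx(p_bf, abs=1e-12)


class TestBhAdjust:
    def test_worked_triple(self):
        np.testing.assert_allclose(
            st.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(st.bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_at_least_raw_and_order_preserving(self, ps):
        adj = st.bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestReplicateDissimilarity:
    @staticmethod
    def _profiles(rng, n_subjects=5, n_taxa=6, noise=0.0):
        cols = [f"s{i:02d}_r{r}" for i in range(n_subjects) for r in (1, 2)]
        base = rng.uniform(1, 10, size=(n_taxa, n_subjects))
        data = np.repeat(base, 2, axis=1)
        data = data * (1 + noise * rng.normal(size=data.shape))
        return pd.DataFrame(np.abs(data), columns=cols)

    def test_identical_methods_have_zero_between_distance(self, rng):
        a = self._profiles(rng, noise=0.1)
        report = st.replicate_dissimilarity_analysis({"A": a, "B": a.copy()})
        assert (report.distances["between:A|B"] == 0.0).all()

    def test_noisier_method_has_larger_within_distance(self, rng):
        quiet = self._profiles(rng, noise=0.01)
        noisy = self._profiles(rng, noise=0.4)
        report = st.replicate_dissimilarity_analysis({"Q": quiet, "N": noisy})
        assert (
            report.summary.loc["within:N", "median"]
            > report.summary.loc["within:Q", "median"]
        )
        assert {"median", "q1", "q3"} <= set(report.summary.columns)
        assert (report.tests["pvalue_bh"] >= report.tests["pvalue"] - 1e-12).all()

    def test_sample_order_permutation_invariance(self, rng):
        a = self._profiles(rng, noise=0.2)
        b = self._profiles(rng, noise=0.2)
        r1 = st.replicate_dissimilarity_analysis({"A": a, "B": b})
        perm = list(rng.permutation(a.columns))
        r2 = st.replicate_dissimilarity_analysis({"A": a[perm], "B": b[perm]})
        for g in r1.distances:
            assert r1.distances[g].median() == pytest.approx(r2.distances[g].median())

    def test_missing_replicate_rejected(self, rng):
        a = self._profiles(rng)
        with pytest.raises(ValueError, match="replicate"):
            st.replicate_dissimilarity_analysis({"A": a.iloc[:, :-1]})
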