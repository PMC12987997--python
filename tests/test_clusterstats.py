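"""Cluster-based permutation inference: graph construction, paired and
Spearman variants against brute-force enumeration oracles, bootstrap CIs,
Storey q-values."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import stats

from psgstats.clusterstats import (build_graph, cluster_mean_corr,
                                   cluster_paired_t, cluster_spearman,
                                   storey_fdr, NeighborGraph)
from psgstats.preprocess import Montage
from psgstats.synth import synthetic_cap


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the library internals
# ---------------------------------------------------------------------------

def _oracle_clusters(t, crit, adj, tail):
    """Naive same-sign connected supra-threshold components."""
    if tail == "two":
        supra = np.abs(t) >= crit
    elif tail == "right":
        supra = t >= crit
    else:
        supra = t <= -crit
    comps = []
    left = set(np.flatnonzero(supra))
    while left:
        seed = left.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            u = frontier.pop()
            for v in list(left):
                if adj[u, v] and (t[v] > 0) == (t[u] > 0):
                    left.discard(v)
                    comp.add(v)
                    frontier.append(v)
        comps.append(sorted(comp))
    return [(c, t[list(c)].sum()) for c in comps]


def _oracle_paired_p(a, b, adj, alpha=0.05, tail="two"):
    """Exhaustive sign-flip null for the paired cluster test."""
    d = a - b
    n = d.shape[0]
    crit = stats.t.ppf(1 - (alpha / 2 if tail == "two" else alpha), n - 1)

    def tmap(dd):
        return dd.mean(0) / (dd.std(0, ddof=1) / math.sqrt(n))

    obs = _oracle_clusters(tmap(d), crit, adj, tail)
    null = []
    for signs in itertools.product((1, -1), repeat=n):
        dd = d * np.array(signs)[:, None]
        cl = _oracle_clusters(tmap(dd), crit, adj, tail)
        null.append(max((abs(m) for _, m in cl), default=0.0))
    null = np.array(null)
    return [(c, m, np.mean(null >= abs(m) - 1e-12)) for c, m in obs]


def _oracle_spearman_p(x, y, adj, alpha=0.05, tail="right"):
    """Exhaustive y-permutation null for the correlation cluster test."""
    n = len(y)
    crit = stats.t.ppf(1 - (alpha / 2 if tail == "two" else alpha), n - 2)

    def tmap(yy):
        rho = np.array([stats.spearmanr(x[:, j], yy).statistic
                        for j in range(x.shape[1])])
        rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
        return rho * np.sqrt((n - 2) / (1 - rho**2))

    obs = _oracle_clusters(tmap(y), crit, adj, tail)
    null = []
    for perm in itertools.permutations(y):
        cl = _oracle_clusters(tmap(np.array(perm)), crit, adj, tail)
        null.append(max((abs(m) for _, m in cl), default=0.0))
    null = np.array(null)
    return [(c, m, np.mean(null >= abs(m) - 1e-12)) for c, m in obs]


def _line_montage(n, spacing=1.0):
    return Montage({f"E{i+1:02d}": (i * spacing, 0.0, 0.0) for i in range(n)})


class TestBuildGraph:
    def test_collinear_chain(self):
        g = build_graph(_line_montage(3), "distance", threshold=1.5)
        adj = g.adjacency
        assert adj[0, 1] and adj[1, 2] and not adj[0, 2]

    def test_threshold_below_spacing_gives_empty_graph(self):
        g = build_graph(_line_montage(4), "distance", threshold=0.5)
        assert g.adjacency.sum() == 0

    def test_cap64_auto_threshold_connected(self, cap64, eeg_labels64):
        g = build_graph(cap64, "distance", labels=eeg_labels64)
        assert 5.0 <= g.mean_degree() <= 8.0
        assert g.is_connected()

    def test_delaunay_on_cap(self, cap64, eeg_labels64):
        g = build_graph(cap64, "delaunay", labels=eeg_labels64)
        assert g.is_connected()
        assert not np.any(np.diag(g.adjacency))

    def test_delaunay_degenerate_falls_back(self):
        with pytest.warns(UserWarning, match="degenerate"):
            g = build_graph(_line_montage(4), "delaunay")
        assert g.method == "distance"


class TestPairedClusterTest:
    def test_identical_conditions_give_no_clusters(self, graph64):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, graph64.n_channels))
        # identical data has zero-variance differences on every channel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cluster_paired_t(x, x.copy(), graph64, n_perm=100, seed=1)
        assert res.clusters == []
        assert not res.sig_mask.any()

    @pytest.mark.parametrize("tail", ["two", "right"])
    def test_exact_enumeration_matches_oracle(self, tail):
        mont = synthetic_cap(4)
        labels = [l for l in mont.labels if not l.startswith("M")]
        g = build_graph(mont, labels=labels)
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = rng.standard_normal((5, 4)) + 1.0
            b = rng.standard_normal((5, 4))
            res = cluster_paired_t(a, b, g, tail=tail, exact=True)
            oracle = _oracle_paired_p(a, b, g.adjacency, tail=tail)
            assert len(res.clusters) == len(oracle)
            got = sorted((tuple(c.indices), round(c.p_value, 12))
                         for c in res.clusters)
            want = sorted((tuple(c), round(p, 12)) for c, _, p in oracle)
            assert got == want

    def test_sampled_p_matches_exact_within_mc_error(self):
        mont = synthetic_cap(6)
        labels = [l for l in mont.labels if not l.startswith("M")]
        g = build_graph(mont, labels=labels)
        rng = np.random.default_rng(7)
        checked = 0
        for trial in range(8):
            a = rng.standard_normal((6, 6)) + 0.9
            b = rng.standard_normal((6, 6))
            ex = cluster_paired_t(a, b, g, exact=True)
            mc = cluster_paired_t(a, b, g, n_perm=2000, seed=trial)
            for ce, cm in zip(ex.clusters, mc.clusters):
                se = math.sqrt(max(ce.p_value * (1 - ce.p_value), 1e-9) / 2000)
                assert abs(ce.p_value - cm.p_value) <= 3 * se + 2 / 2000
                checked += 1
        assert checked >= 5

    def test_planted_patch_recovered(self, cap64, graph64, eeg_labels64):
        from psgstats.synth import patch_near
        labels = patch_near(cap64, cap64.positions["E40"], 6)
        patch = [eeg_labels64.index(l) for l in labels]
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            a = rng.standard_normal((22, 64))
            b = rng.standard_normal((22, 64))
            a[:, patch] += 1.2
            res = cluster_paired_t(a, b, graph64, n_perm=500, seed=seed)
            for c in res.significant_clusters():
                if c.sign > 0 and len(set(c.indices) & set(patch)) >= 4:
                    hits += 1
                    break
        assert hits / n_seeds >= 0.8

    def test_needs_three_subjects(self, graph64):
        x = np.zeros((2, graph64.n_channels))
        with pytest.raises(ValueError):
            cluster_paired_t(x, x, graph64)


class TestSpearmanClusterTest:
    def test_perfect_monotone_association_minimal_p(self, cap8):
        labels = [l for l in cap8.labels if not l.startswith("M")]
        g = build_graph(cap8, labels=labels)
        assert g.is_connected()
        rng = np.random.default_rng(3)
        base = rng.standard_normal(10)
        x = np.tile(base[:, None], (1, len(labels)))
        y = -np.exp(base)          # strictly decreasing transform
        res = cluster_spearman(x, y, g, tail="left", n_perm=1000, seed=0)
        assert len(res.clusters) == 1
        assert res.clusters[0].size == len(labels)
        assert res.clusters[0].p_value == pytest.approx(1 / 1001)

    def test_exact_enumeration_matches_oracle(self):
        mont = synthetic_cap(3)
        labels = [l for l in mont.labels if not l.startswith("M")]
        g = build_graph(mont, labels=labels)
        rng = np.random.default_rng(11)
        for _ in range(4):
            x = rng.standard_normal((6, 3))
            y = x[:, 0] + 0.5 * rng.standard_normal(6)
            res = cluster_spearman(x, y, g, tail="right", exact=True)
            oracle = _oracle_spearman_p(x, y, g.adjacency, tail="right")
            got = sorted((tuple(c.indices), round(c.p_value, 12))
                         for c in res.clusters)
            want = sorted((tuple(c), round(p, 12)) for c, _, p in oracle)
            assert got == want

    def test_invariant_to_monotone_transform_of_y(self, graph64):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((12, graph64.n_channels))
        y = rng.standard_normal(12)
        r1 = cluster_spearman(x, y, graph64, n_perm=300, seed=9, tail="left")
        r2 = cluster_spearman(x, np.exp(3 * y), graph64, n_perm=300, seed=9,
                              tail="left")
        np.testing.assert_allclose(r1.stat_map, r2.stat_map, atol=1e-10)
        assert [c.p_value for c in r1.clusters] == \
            [c.p_value for c in r2.clusters]

    def test_constant_behaviour_rejected(self, graph64):
        x = np.random.default_rng(0).standard_normal((8, graph64.n_channels))
        with pytest.raises(ValueError):
            cluster_spearman(x, np.ones(8), graph64)


class TestClusterMeanCorr:
    def test_perfect_negative(self):
        x = np.array([[1.0], [2.0], [3.0]])
        with pytest.warns(UserWarning):
            rho, ci = cluster_mean_corr(x, [0], np.array([3.0, 2.0, 1.0]))
        assert rho == pytest.approx(-1.0)
        assert ci is None

    def test_identity_upper_ci_is_one(self):
        rng = np.random.default_rng(2)
        xm = rng.standard_normal(10)
        x = xm[:, None]
        rho, ci = cluster_mean_corr(x, [0], xm.copy(), n_boot=500, seed=1)
        assert rho == pytest.approx(1.0)
        assert ci[1] == pytest.approx(1.0)

    def test_bootstrap_ci_covers_point_estimate(self):
        # planted rank correlation: the CI should bracket the sample rho
        rng = np.random.default_rng(4)
        cover = 0
        n_rep = 50
        for rep in range(n_rep):
            z = rng.standard_normal(22)
            y = -0.6 * z + math.sqrt(1 - 0.36) * rng.standard_normal(22)
            x = z[:, None] + 0.1 * rng.standard_normal((22, 1))
            rho, ci = cluster_mean_corr(x, [0], y, n_boot=500,
                                        seed=rep)
            cover += ci[0] - 1e-12 <= rho <= ci[1] + 1e-12
        assert cover / n_rep >= 0.93

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            cluster_mean_corr(np.zeros((5, 3)), [], np.arange(5.0))


class TestStoreyFdr:
    def test_bh_limit_hand_example(self):
        q = storey_fdr(np.array([0.01, 0.02, 0.03, 0.04]), lam=0.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        # independent route: Benjamini-Hochberg from statsmodels
        from statsmodels.stats.multitest import multipletests
        bh = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh)

    def test_single_p(self):
        p = np.array([0.2])
        pi0 = min(1.0, max(1, int(p[0] > 0.5)) / 0.5)
        np.testing.assert_allclose(storey_fdr(p), [min(1.0, pi0 * 0.2)])

    def test_all_ones(self):
        np.testing.assert_allclose(storey_fdr(np.ones(5)), np.ones(5))

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=40)
        q = storey_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_empty_input(self):
        assert storey_fdr(np.array([])).size == 0


class TestFamilywiseValidity:
    def test_max_statistic_controls_family_error(self, graph64):
        """Two planted-null outcome vectors: the familywise rate over both
        stays at or below nominal."""
        rng = np.random.default_rng(77)
        fam_err = 0
        n_sim = 60
        for sim in range(n_sim):
            x = rng.standard_normal((22, graph64.n_channels))
            any_sig = False
            for k in range(2):
                y = rng.standard_normal(22)
                res = cluster_spearman(x, y, graph64, n_perm=300,
                                       seed=sim * 2 + k, tail="left")
                any_sig |= bool(res.significant_clusters())
            fam_err += any_sig
        assert fam_err / n_sim <= 0.13   # 2 x 0.05 nominal + MC slack
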