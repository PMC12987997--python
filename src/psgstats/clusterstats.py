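"""Sensor-space cluster-based permutation inference.

Channel-wise statistics (paired t or Spearman rho converted to t) are
thresholded at a sample-level alpha; adjacent supra-threshold channels of
common sign form clusters scored by the sum of their t-values; cluster-level
p-values come from the permutation distribution of the maximum cluster mass
(sign flips of within-subject differences, or shuffles of the behavioural
vector), which controls the familywise error over the whole map.

The tests are exposed as model classes in the statsmodels idiom:

>>> res = PairedClusterTest(x_trauma, x_neutral, graph).fit(n_perm=1000, seed=7)
>>> res.clusters[0].p_value
>>> print(res.summary())

with functional wrappers :func:`cluster_paired_t` / :func:`cluster_spearman`
for pipeline use. Storey's q-value FDR correction and bootstrap confidence
intervals for cluster-mean correlations live here as well.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import spatial, stats

from .preprocess import Montage

__all__ = [
    "NeighborGraph", "build_graph", "Cluster", "ClusterResults",
    "PairedClusterTest", "SpearmanClusterTest", "cluster_paired_t",
    "cluster_spearman", "cluster_mean_corr", "storey_fdr",
]


# ---------------------------------------------------------------------------
# neighbor graph
# ---------------------------------------------------------------------------

@dataclass
class NeighborGraph:
    """Symmetric channel adjacency with no self-edges."""

    labels: list[str]
    adjacency: np.ndarray  # (n, n) bool
    method: str = "distance"
    threshold: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape != (len(self.labels), len(self.labels)):
            raise ValueError("adjacency shape must match label count")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.adjacency]

    def mean_degree(self) -> float:
        return float(self.adjacency.sum(axis=1).mean())

    def is_connected(self) -> bool:
        n = self.n_channels
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(self.adjacency[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        return bool(seen.all())


def build_graph(montage: Montage, method: str = "distance",
                threshold: float | None = None,
                labels=None) -> NeighborGraph:
    """Build the channel neighbourhood used for clustering.

    ``distance``: edge iff Euclidean distance <= *threshold*.
    ``delaunay``: edges of the 2-D (x, y) Delaunay triangulation; degenerate
    layouts fall back to the distance rule with a warning.
    """
    labels = list(labels) if labels is not None else montage.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 positioned channels")
    pos = montage.coords(labels)
    n = len(labels)
    if method == "delaunay":
        try:
            tri = spatial.Delaunay(pos[:, :2])
            adj = np.zeros((n, n), dtype=bool)
            for simplex in tri.simplices:
                for i, j in itertools.combinations(simplex, 2):
                    adj[i, j] = adj[j, i] = True
            return NeighborGraph(labels, adj, "delaunay", None)
        except Exception:
            warnings.warn("Delaunay triangulation degenerate; "
                          "falling back to distance adjacency")
            method = "distance"
    if method != "distance":
        raise ValueError(f"unknown graph method {method!r}")
    if threshold is None:
        threshold = auto_threshold(montage, labels=labels)
    d = spatial.distance.squareform(spatial.distance.pdist(pos))
    adj = d <= threshold
    np.fill_diagonal(adj, False)
    return NeighborGraph(labels, adj, "distance", float(threshold))


def auto_threshold(montage: Montage, target_degree: float = 6.0,
                   labels=None) -> float:
    """Distance threshold giving roughly *target_degree* neighbours per channel."""
    labels = list(labels) if labels is not None else montage.labels
    pos = montage.coords(labels)
    d = spatial.distance.squareform(spatial.distance.pdist(pos))
    np.fill_diagonal(d, np.inf)
    k = min(int(round(target_degree)), d.shape[0] - 1)
    kth = np.sort(d, axis=1)[:, k - 1]
    return float(np.median(kth) * 1.01)


# ---------------------------------------------------------------------------
# clusters and results
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    channels: list[str]
    indices: np.ndarray
    mass: float           # sum of channel t-values
    sign: int             # +1 or -1
    p_value: float | None = None

    @property
    def size(self) -> int:
        return len(self.channels)


@dataclass
class ClusterResults:
    """Fitted cluster-permutation inference.

    Attributes
    ----------
    stat_map : per-channel sample-level t statistic (nan for dropped channels)
    effect_map : per-channel effect (mean difference, or Spearman rho)
    sig_mask : per-channel bool, supra-threshold at the sample alpha
    clusters : list of :class:`Cluster`, each with its permutation p-value
    perm_max : permutation distribution of the max cluster mass magnitude
    """

    method: str
    labels: list[str]
    stat_map: np.ndarray
    effect_map: np.ndarray
    sig_mask: np.ndarray
    clusters: list[Cluster]
    perm_max: np.ndarray
    n_perm: int
    tail: str
    alpha_sample: float
    alpha_cluster: float
    n_subjects: int
    exact: bool = False
    dropped: list[str] = field(default_factory=list)

    @property
    def p_values(self) -> np.ndarray:
        return np.array([c.p_value for c in self.clusters], dtype=float)

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= self.alpha_cluster]

    @property
    def min_p(self) -> float:
        """Smallest cluster p-value; 1.0 when no cluster formed.

        Usable directly as a map-level p-value for FDR across outcomes,
        because the max-statistic null makes it familywise-valid.
        """
        return float(self.p_values.min()) if self.clusters else 1.0

    def summary(self) -> str:
        kind = "exact enumeration" if self.exact else "Monte Carlo"
        lines = [
            f"{self.method} cluster permutation test",
            f"  subjects: {self.n_subjects}   channels: {len(self.labels)}"
            f"   tail: {self.tail}",
            f"  sample alpha: {self.alpha_sample}   cluster alpha: "
            f"{self.alpha_cluster}   permutations: {self.n_perm} ({kind})",
        ]
        if self.dropped:
            lines.append(f"  dropped zero-variance channels: "
                         f"{', '.join(self.dropped)}")
        if not self.clusters:
            lines.append("  no supra-threshold clusters")
        else:
            lines.append(f"  {'cluster':>8} {'n_ch':>5} {'sign':>5} "
                         f"{'mass':>10} {'p':>8}")
            for k, c in enumerate(self.clusters):
                star = " *" if c.p_value <= self.alpha_cluster else ""
                lines.append(f"  {k:>8d} {c.size:>5d} {c.sign:>+5d} "
                             f"{c.mass:>10.3f} {c.p_value:>8.4f}{star}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "tail": self.tail,
            "n_perm": self.n_perm,
            "alpha_sample": self.alpha_sample,
            "alpha_cluster": self.alpha_cluster,
            "n_subjects": self.n_subjects,
            "stat_map": {l: float(t) for l, t in zip(self.labels, self.stat_map)},
            "clusters": [
                {"channels": c.channels, "mass": float(c.mass),
                 "sign": int(c.sign), "p": float(c.p_value)}
                for c in self.clusters
            ],
        }


def _find_clusters(t: np.ndarray, crit: float, tail: str,
                   nbrs: list[np.ndarray], valid: np.ndarray):
    """Connected same-sign supra-threshold components and their masses.

    For one-sided tails only the hypothesized sign is clustered. Returns a
    list of (indices, mass) pairs.
    """
    if tail == "two":
        supra = np.abs(t) >= crit
    elif tail == "right":
        supra = t >= crit
    elif tail == "left":
        supra = t <= -crit
    else:
        raise ValueError(f"unknown tail {tail!r}")
    supra &= valid
    out = []
    seen = np.zeros(t.shape, dtype=bool)
    for i in np.flatnonzero(supra):
        if seen[i]:
            continue
        sign = 1 if t[i] > 0 else -1
        comp = [i]
        seen[i] = True
        stack = [i]
        while stack:
            u = stack.pop()
            for v in nbrs[u]:
                if supra[v] and not seen[v] and (t[v] > 0) == (sign > 0):
                    seen[v] = True
                    comp.append(v)
                    stack.append(v)
        idx = np.array(sorted(comp), dtype=int)
        out.append((idx, float(t[idx].sum())))
    return out


def _max_mass(t: np.ndarray, crit: float, tail: str,
              nbrs: list[np.ndarray], valid: np.ndarray) -> float:
    cl = _find_clusters(t, crit, tail, nbrs, valid)
    return max((abs(m) for _, m in cl), default=0.0)


def _perm_p(perm_max: np.ndarray, obs: float, exact: bool = False) -> float:
    """Permutation p-value.

    Monte Carlo: (1 + b) / (B + 1), which includes the observed statistic and
    fixes the minimum attainable p at 1/(B+1). Exact enumeration: b / B — the
    identity permutation is already part of the enumerated group, so no
    add-one correction is applied.
    """
    b = int(np.sum(perm_max >= abs(obs) - 1e-12))
    if exact:
        return b / len(perm_max)
    return (1 + b) / (len(perm_max) + 1)


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class _ClusterModel:
    """Shared fit machinery for the paired-t and Spearman variants."""

    method = ""

    def __init__(self, graph: NeighborGraph, alpha_sample: float = 0.05,
                 tail: str = "two"):
        if tail not in ("two", "left", "right"):
            raise ValueError("tail must be 'two', 'left' or 'right'")
        self.graph = graph
        self.alpha_sample = float(alpha_sample)
        self.tail = tail

    # subclasses define: _observed() -> (t, effect, valid, dropped),
    # _perm_stats(n_perm, seed, crit, nbrs, valid) -> ndarray,
    # _n_exact() and _exact_stats(...)

    def _crit(self) -> float:
        a = self.alpha_sample
        if self.tail == "two":
            return float(stats.t.ppf(1 - a / 2, self._df()))
        return float(stats.t.ppf(1 - a, self._df()))

    def fit(self, n_perm: int = 1000, seed=None, exact: bool = False,
            alpha_cluster: float = 0.05) -> ClusterResults:
        """Run the permutation test.

        With ``exact=True`` the full permutation group is enumerated (sign
        flips or y-shuffles) and p-values are exact up to the inclusion of
        the identity permutation.
        """
        nbrs = self.graph.neighbor_lists()
        t, effect, valid, dropped = self._observed()
        crit = self._crit()
        obs_clusters = _find_clusters(t, crit, self.tail, nbrs, valid)
        if exact:
            perm_max = self._exact_stats(crit, nbrs, valid)
        else:
            perm_max = self._perm_stats(n_perm, seed, crit, nbrs, valid)
        clusters = []
        for idx, mass in sorted(obs_clusters, key=lambda c: -abs(c[1])):
            clusters.append(Cluster(
                channels=[self.graph.labels[i] for i in idx],
                indices=idx, mass=mass, sign=1 if mass > 0 else -1,
                p_value=_perm_p(perm_max, mass, exact=exact)))
        if self.tail == "two":
            sig = np.abs(t) >= crit
        elif self.tail == "right":
            sig = t >= crit
        else:
            sig = t <= -crit
        return ClusterResults(
            method=self.method, labels=list(self.graph.labels),
            stat_map=t, effect_map=effect, sig_mask=sig & valid,
            clusters=clusters, perm_max=perm_max, n_perm=len(perm_max),
            tail=self.tail, alpha_sample=self.alpha_sample,
            alpha_cluster=alpha_cluster, n_subjects=self._n(),
            exact=exact, dropped=dropped)


class PairedClusterTest(_ClusterModel):
    """Paired within-subject contrast between two condition maps.

    Per channel, a paired t-test on ``a - b``; the permutation null flips the
    sign of each subject's difference vector, which is exchangeable under the
    null of no condition effect.
    """

    method = "paired-t"

    def __init__(self, a: np.ndarray, b: np.ndarray, graph: NeighborGraph,
                 alpha_sample: float = 0.05, tail: str = "two"):
        super().__init__(graph, alpha_sample, tail)
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("condition matrices must have equal shape")
        if a.ndim != 2 or a.shape[1] != graph.n_channels:
            raise ValueError("matrices must be subjects x channels, matching "
                             "the graph")
        if a.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        self.d = a - b

    def _n(self) -> int:
        return self.d.shape[0]

    def _df(self) -> int:
        return self._n() - 1

    def _t_of(self, d: np.ndarray, valid: np.ndarray) -> np.ndarray:
        n = d.shape[0]
        m = d.mean(axis=0)
        s = d.std(axis=0, ddof=1)
        t = np.zeros(d.shape[1])
        np.divide(m, s / math.sqrt(n), out=t, where=valid)
        return t

    def _observed(self):
        s = self.d.std(axis=0, ddof=1)
        valid = s > 0
        dropped = [self.graph.labels[i] for i in np.flatnonzero(~valid)]
        if dropped:
            warnings.warn(f"zero-variance differences on {dropped}; excluded")
        return (self._t_of(self.d, valid), self.d.mean(axis=0), valid, dropped)

    def _perm_stats(self, n_perm, seed, crit, nbrs, valid) -> np.ndarray:
        rng = np.random.default_rng(seed)
        n, nch = self.d.shape
        valid_s = self.d.std(axis=0, ddof=1) > 0
        ss = np.sum(self.d ** 2, axis=0)  # invariant under sign flips
        out = np.empty(n_perm)
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
        means = signs @ self.d / n
        var = (ss - n * means**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tmat = means / np.sqrt(var / n)
        tmat[:, ~valid_s] = 0.0
        tmat = np.nan_to_num(tmat, nan=0.0, posinf=0.0, neginf=0.0)
        for k in range(n_perm):
            out[k] = _max_mass(tmat[k], crit, self.tail, nbrs, valid)
        return out

    def _exact_stats(self, crit, nbrs, valid) -> np.ndarray:
        n = self._n()
        if n > 14:
            raise ValueError("exact enumeration limited to n <= 14 subjects")
        out = np.empty(2 ** n)
        for k, pattern in enumerate(itertools.product((1.0, -1.0), repeat=n)):
            d = self.d * np.array(pattern)[:, None]
            t = self._t_of(d, valid)
            out[k] = _max_mass(t, crit, self.tail, nbrs, valid)
        return out


class SpearmanClusterTest(_ClusterModel):
    """Rank correlation between per-channel change scores and a behaviour.

    Per channel, Spearman's rho (average ranks for ties) mapped to a t
    statistic ``t = rho * sqrt((n-2) / (1-rho^2))`` for sample-level
    thresholding; the permutation null shuffles the behavioural vector across
    subjects. Invariant to strictly monotone transforms of either variable.
    """

    method = "spearman"

    def __init__(self, x: np.ndarray, y: np.ndarray, graph: NeighborGraph,
                 alpha_sample: float = 0.05, tail: str = "two"):
        super().__init__(graph, alpha_sample, tail)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 2 or x.shape[1] != graph.n_channels:
            raise ValueError("x must be subjects x channels, matching graph")
        if y.shape != (x.shape[0],):
            raise ValueError("y must be one value per subject")
        if x.shape[0] < 5:
            raise ValueError("need at least 5 subjects")
        if np.unique(y).size < 2:
            raise ValueError("behavioural vector is constant")
        self.x = x
        self.y = y
        rx = stats.rankdata(x, axis=0)
        self._zx, self._zx_ok = _standardize_cols(rx)
        ry = stats.rankdata(y)
        self._zy = (ry - ry.mean()) / ry.std()

    def _n(self) -> int:
        return self.x.shape[0]

    def _df(self) -> int:
        return self._n() - 2

    def _rho_to_t(self, rho: np.ndarray) -> np.ndarray:
        r = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
        return r * np.sqrt(self._df() / (1 - r**2))

    def _rho_of(self, zy: np.ndarray) -> np.ndarray:
        return (zy @ self._zx) / self._n()

    def _observed(self):
        valid = self._zx_ok
        dropped = [self.graph.labels[i] for i in np.flatnonzero(~valid)]
        if dropped:
            warnings.warn(f"zero-variance channels {dropped}; excluded")
        rho = self._rho_of(self._zy)
        rho[~valid] = 0.0
        return self._rho_to_t(rho), rho, valid, dropped

    def _perm_stats(self, n_perm, seed, crit, nbrs, valid) -> np.ndarray:
        rng = np.random.default_rng(seed)
        out = np.empty(n_perm)
        for k in range(n_perm):
            zy = rng.permutation(self._zy)
            t = self._rho_to_t(self._rho_of(zy))
            t[~valid] = 0.0
            out[k] = _max_mass(t, crit, self.tail, nbrs, valid)
        return out

    def _exact_stats(self, crit, nbrs, valid) -> np.ndarray:
        n = self._n()
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 subjects")
        out = np.empty(math.factorial(n))
        for k, perm in enumerate(itertools.permutations(range(n))):
            zy = self._zy[list(perm)]
            t = self._rho_to_t(self._rho_of(zy))
            t[~valid] = 0.0
            out[k] = _max_mass(t, crit, self.tail, nbrs, valid)
        return out


def _standardize_cols(x: np.ndarray):
    s = x.std(axis=0)
    ok = s > 0
    z = np.zeros_like(x, dtype=float)
    z[:, ok] = (x[:, ok] - x[:, ok].mean(axis=0)) / s[ok]
    return z, ok


# ---------------------------------------------------------------------------
# functional wrappers (pipeline surface)
# ---------------------------------------------------------------------------

def cluster_paired_t(x_a, x_b, graph, alpha_sample=0.05, alpha_cluster=0.05,
                     n_perm=1000, tail="two", seed=None,
                     exact=False) -> ClusterResults:
    return PairedClusterTest(x_a, x_b, graph, alpha_sample, tail).fit(
        n_perm=n_perm, seed=seed, exact=exact, alpha_cluster=alpha_cluster)


def cluster_spearman(x, y, graph, alpha_sample=0.05, alpha_cluster=0.05,
                     n_perm=1000, tail="two", seed=None,
                     exact=False) -> ClusterResults:
    return SpearmanClusterTest(x, y, graph, alpha_sample, tail).fit(
        n_perm=n_perm, seed=seed, exact=exact, alpha_cluster=alpha_cluster)


# ---------------------------------------------------------------------------
# cluster-mean correlation with bootstrap CI
# ---------------------------------------------------------------------------

def cluster_mean_corr(x: np.ndarray, cluster_idx, y: np.ndarray,
                      n_boot: int = 1000, seed=None,
                      ci: float = 0.95):
    """Spearman rho of the cluster-mean signal against behaviour, with a
    percentile-bootstrap confidence interval over subjects.

    Returns ``(rho, (lo, hi))``; the CI is ``None`` (with a warning) for
    fewer than 4 subjects. Degenerate bootstrap resamples (constant vectors)
    are redrawn not at all but contribute ``nan`` and are ignored in the
    percentiles.
    """
    cluster_idx = np.asarray(cluster_idx, dtype=int)
    if cluster_idx.size == 0:
        raise ValueError("cluster must be non-empty")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x[:, cluster_idx].mean(axis=1)
    rho = _spearman(xm, y)
    n = len(y)
    if n < 4:
        warnings.warn("fewer than 4 subjects: bootstrap CI suppressed")
        return rho, None
    rng = np.random.default_rng(seed)
    boots = np.full(n_boot, np.nan)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = xm[idx], y[idx]
        if np.unique(xb).size < 2 or np.unique(yb).size < 2:
            continue
        boots[k] = _spearman(xb, yb)
    ok = boots[~np.isnan(boots)]
    lo, hi = np.percentile(ok, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    return rho, (float(lo), float(hi))


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((ra - ra.mean()) * (rb - rb.mean())) / (sa * sb))


# ---------------------------------------------------------------------------
# Storey FDR
# ---------------------------------------------------------------------------

def storey_fdr(p, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed pi0 tuning parameter *lam*.

    ``pi0 = min(1, max(1, #{p > lam}) / ((1 - lam) m))``; the numerator floor
    keeps the estimate away from a degenerate zero in very small families.
    With ``lam = 0`` this reduces to Benjamini-Hochberg. q-values are monotone
    in p and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 <= lam < 1:
        raise ValueError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = min(1.0, max(1, int(np.sum(p > lam))) / ((1 - lam) * m))
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p[i] / rank)
        q[i] = val
        prev = val
    return q
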