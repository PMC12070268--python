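"""Cluster-based permutation inference over adjacency structures.

Nonparametric family-wise error control for mass-univariate t-maps on
sensor neighbour graphs or 3-D voxel grids: suprathreshold nodes of the
same sign are grouped into connected components, each cluster is scored
by the sum of its member t-values (T_sum), and the observed clusters
are referred to a Monte Carlo null distribution of the maximal |T_sum|
obtained under exchangeability-preserving randomisations (condition
sign flips within subject for dependent designs; group relabelling for
independent designs).  The two-sided cluster p-value is

    p = (#{null >= |T_sum|} + 1) / (R + 1),

which is bounded below by 1/(R+1), and clusters with p <= alpha are
declared significant.  Referring both signs to the maximal-|T_sum|
null implements a two-tailed test with family-wise correction across
clusters of either sign.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .synthgen import SensorArray

logger = logging.getLogger(__name__)

#: cap applied to t-values of zero-variance contrasts
T_CAP = 1e6


@dataclass
class Adjacency:
    """Symmetric, irreflexive neighbour relation over channels/voxels."""

    matrix: np.ndarray          # (n, n) bool
    names: list[str] | None = None
    threshold: float | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=bool)
        if m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if not (m == m.T).all():
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(m, False)
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def sensor_adjacency(
    array: SensorArray,
    threshold: float | None = None,
    target_median_neighbors: float = 7.0,
) -> Adjacency:
    """Neighbour graph from inter-electrode (chord) distances.

    If no threshold is given, the smallest distance threshold whose
    median neighbour count reaches ``target_median_neighbors`` is
    selected and logged.
    """
    pos = array.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    if threshold is None:
        cand = np.unique(np.round(d[np.triu_indices_from(d, k=1)], 6))
        lo, hi = 0, len(cand) - 1
        threshold = cand[-1]
        while lo <= hi:
            mid = (lo + hi) // 2
            med = np.median((d <= cand[mid]).sum(axis=1) - 1)
            if med >= target_median_neighbors:
                threshold = cand[mid]
                hi = mid - 1
            else:
                lo = mid + 1
        threshold = float(threshold)
    m = d <= threshold
    np.fill_diagonal(m, False)
    logger.info(
        "sensor adjacency: threshold %.3f, median neighbour count %.1f",
        threshold, float(np.median(m.sum(axis=1))),
    )
    return Adjacency(matrix=m, names=list(array.names), threshold=threshold)


def grid_adjacency(positions_mm: np.ndarray, spacing_mm: float) -> Adjacency:
    """26-neighbourhood connectivity on a regular voxel grid."""
    tree = cKDTree(positions_mm)
    pairs = tree.query_pairs(r=spacing_mm * np.sqrt(3.0) * 1.01, output_type="ndarray")
    n = len(positions_mm)
    m = np.zeros((n, n), dtype=bool)
    m[pairs[:, 0], pairs[:, 1]] = True
    m |= m.T
    return Adjacency(matrix=m, threshold=float(spacing_mm * np.sqrt(3.0)))


@dataclass
class Cluster:
    nodes: np.ndarray           # member indices
    sign: int                   # +1 / -1
    t_sum: float
    p: float | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)
    threshold: float | None = None
    design: str | None = None
    n_randomizations: int | None = None
    alpha: float = 0.05
    null_max_abs: np.ndarray | None = None

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p is not None and c.p <= a]

    def largest(self, sign: int | None = None, significant_only: bool = True):
        pool = self.significant() if significant_only else self.clusters
        if sign is not None:
            pool = [c for c in pool if c.sign == sign]
        if not pool:
            return None
        return max(pool, key=lambda c: abs(c.t_sum))

    def to_records(self) -> list[dict]:
        return [
            dict(members=c.nodes.tolist(), sign=c.sign, t_sum=c.t_sum, p=c.p)
            for c in self.clusters
        ]


def elementwise_t(values_a: np.ndarray, values_b: np.ndarray, design: str) -> np.ndarray:
    """Classical t statistic per node.

    dependent: paired t on per-subject differences (rows paired).
    independent: two-sample pooled-variance t.
    Zero-variance contrasts yield a capped t of +/-1e6 (0 if the mean
    difference is also zero) so degenerate synthetic input stays finite.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if design == "dependent":
        if a.shape != b.shape:
            raise ValueError("paired designs need matching shapes")
        if a.shape[0] < 2:
            raise ValueError("need at least two subjects")
        d = a - b
        n = d.shape[0]
        m = d.mean(axis=0)
        s = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (s / np.sqrt(n))
        zero = s == 0
        t[zero] = np.sign(m[zero]) * T_CAP
        return t
    if design == "independent":
        na, nb = a.shape[0], b.shape[0]
        if na < 2 or nb < 2:
            raise ValueError("need at least two subjects per group")
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / denom
        zero = denom == 0
        t[zero] = np.sign((ma - mb)[zero]) * T_CAP
        return t
    raise ValueError(f"unknown design {design!r}")


def _csgraph(adjacency: Adjacency):
    return sparse.csr_matrix(adjacency.matrix)


def form_clusters(
    t_map: np.ndarray,
    threshold: float,
    adjacency: Adjacency,
    min_neighbors: int = 0,
) -> ClusterSet:
    """Group suprathreshold nodes of equal sign into connected
    components and score each by its T_sum.

    With ``min_neighbors`` > 0 (sensor-level default 2), a node enters
    clustering only if at least that many of its graph neighbours are
    suprathreshold with the same sign; this suppresses singleton
    clusters on sensor graphs.  The rule is applied in a single pass.
    """
    if threshold <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    t_map = np.asarray(t_map, float)
    adj = adjacency.matrix
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = sign * t_map > threshold
        if min_neighbors > 0:
            n_supra_neighbors = adj @ mask.astype(np.int64)
            mask = mask & (n_supra_neighbors >= min_neighbors)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = sparse.csr_matrix(adj[np.ix_(idx, idx)])
        n_comp, comp = connected_components(sub, directed=False)
        for c in range(n_comp):
            nodes = idx[comp == c]
            clusters.append(
                Cluster(nodes=nodes, sign=sign, t_sum=float(t_map[nodes].sum()))
            )
    clusters.sort(key=lambda c: -abs(c.t_sum))
    return ClusterSet(clusters=clusters, threshold=threshold)


def _default_threshold(design: str, na: int, nb: int, cluster_alpha: float) -> float:
    df = na - 1 if design == "dependent" else na + nb - 2
    return float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df))


def _max_abs_tsum(t_map, threshold, adjacency, min_neighbors) -> float:
    cs = form_clusters(t_map, threshold, adjacency, min_neighbors)
    return max((abs(c.t_sum) for c in cs.clusters), default=0.0)


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    design: str,
    adjacency: Adjacency,
    R: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    threshold: float | None = None,
    cluster_alpha: float = 0.05,
    min_neighbors: int = 2,
) -> ClusterSet:
    """Monte Carlo cluster-based permutation test.

    ``values_a``/``values_b`` are (subjects, nodes) arrays: the two
    conditions of the same subjects (dependent) or the two groups
    (independent).  The cluster-forming threshold defaults to the
    two-sided critical t at ``cluster_alpha`` with the design's df.
    """
    if R < 1:
        raise ValueError("need at least one randomization")
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if threshold is None:
        threshold = _default_threshold(design, a.shape[0], b.shape[0], cluster_alpha)
    observed = form_clusters(
        elementwise_t(a, b, design), threshold, adjacency, min_neighbors
    )
    rng = np.random.default_rng(seed)
    null = np.empty(R)
    if design == "dependent":
        d = a - b
        n = d.shape[0]
        ssq = (d**2).sum(axis=0)
        signs = rng.choice([-1.0, 1.0], size=(R, n))
        means = signs @ d / n                                 # (R, nodes)
        var = (ssq[None, :] - n * means**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = means / np.sqrt(var / n)
        bad = var <= 0
        t_all[bad] = np.sign(means[bad]) * T_CAP
        for r in range(R):
            null[r] = _max_abs_tsum(t_all[r], threshold, adjacency, min_neighbors)
    elif design == "independent":
        x = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        for r in range(R):
            perm = rng.permutation(x.shape[0])
            t_map = elementwise_t(x[perm[:na]], x[perm[na:]], "independent")
            null[r] = _max_abs_tsum(t_map, threshold, adjacency, min_neighbors)
    else:
        raise ValueError(f"unknown design {design!r}")
    for c in observed.clusters:
        c.p = float((np.sum(null >= abs(c.t_sum) - 1e-12) + 1.0) / (R + 1.0))
    observed.design = design
    observed.n_randomizations = R
    observed.alpha = alpha
    observed.null_max_abs = null
    return observed


def between_group_contrast_test(
    contrast_maps_a: np.ndarray,
    contrast_maps_b: np.ndarray,
    adjacency: Adjacency,
    R: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> ClusterSet:
    """Independent-design permutation test on per-subject overlap-effect
    (condition-contrast) maps of two groups."""
    return permutation_test(
        contrast_maps_a, contrast_maps_b, "independent", adjacency,
        R=R, seed=seed, **kwargs,
    )
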