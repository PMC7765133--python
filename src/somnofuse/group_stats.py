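"""Nonparametric electrode-space group comparison with cluster correction.

Per-channel independent-samples t statistics are thresholded at a
cluster-forming alpha, suprathreshold channels are grouped into spatial
clusters under a position-derived adjacency, and each cluster's summed t
is referred to a Monte-Carlo null of the maximal cluster statistic over
random relabelings of subjects. The most significant cluster then drives
electrode selection for the EEG-informed BOLD regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
import warnings

import numpy as np
from scipy import stats as _stats

from .core import DataError, PreconditionError


@dataclass
class ElectrodeAdjacency:
    neighbors: list[np.ndarray]
    distance_threshold: float
    isolated: np.ndarray = field(default=None)

    def __post_init__(self):
        self.isolated = np.array([len(n) == 0 for n in self.neighbors])

    @property
    def n_channels(self) -> int:
        return len(self.neighbors)


@dataclass
class Cluster:
    members: np.ndarray
    statistic: float  # sum of member t-values
    monte_carlo_p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    n_permutations: int
    cluster_alpha: float
    tail: str = "two-sided"
    flags: list[str] = field(default_factory=list)

    def most_significant(self) -> Cluster | None:
        if not self.clusters:
            return None
        return min(self.clusters, key=lambda c: (c.monte_carlo_p, -abs(c.statistic)))


def electrode_adjacency(positions: np.ndarray, distance_threshold: float) -> ElectrodeAdjacency:
    """Channels are neighbours iff their Euclidean distance <= threshold."""
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise PreconditionError("need at least 2 channels with positions")
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    neighbors = [np.flatnonzero(d[i] <= distance_threshold) for i in range(len(positions))]
    adj = ElectrodeAdjacency(neighbors, distance_threshold)
    if adj.isolated.all():
        warnings.warn("all channels isolated under this distance threshold")
    return adj


def default_distance_threshold(positions: np.ndarray, factor: float = 1.6) -> float:
    """``factor`` times the median nearest-neighbour distance — gives each
    sensor a handful of neighbours on a regular layout."""
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return factor * float(np.median(d.min(axis=1)))


def _welch_free_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance independent-samples t per channel; constant-data
    channels get t = 0."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    t = np.zeros_like(ma)
    ok = denom > 0
    t[ok] = (ma - mb)[ok] / denom[ok]
    return t


def _clusters_from_t(
    t: np.ndarray, thresh: float, adjacency: ElectrodeAdjacency
) -> list[tuple[np.ndarray, float]]:
    """Connected suprathreshold components, split by sign of t."""
    supra = np.abs(t) >= thresh
    seen = np.zeros(t.size, bool)
    out = []
    for start in np.flatnonzero(supra):
        if seen[start]:
            continue
        sign = np.sign(t[start])
        stack, members = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            members.append(i)
            for j in adjacency.neighbors[i]:
                if supra[j] and not seen[j] and np.sign(t[j]) == sign:
                    seen[j] = True
                    stack.append(j)
        members = np.array(sorted(members))
        out.append((members, float(t[members].sum())))
    return out


def cluster_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    adjacency: ElectrodeAdjacency,
    n_perm: int | str = 1000,
    cluster_alpha: float = 0.05,
    seed: int | None = 0,
) -> ClusterResult:
    """Monte-Carlo cluster test on subjects x channels group data.

    The null distribution is the maximum |cluster statistic| over random
    group relabelings, with the observed labeling always counted (so p is
    never zero). ``n_perm="exact"`` enumerates every distinct split.
    """
    group_a = np.atleast_2d(np.asarray(group_a, float))
    group_b = np.atleast_2d(np.asarray(group_b, float))
    if group_a.shape[1] != group_b.shape[1]:
        raise DataError("channel counts differ between groups")
    if min(group_a.shape[0], group_b.shape[0]) < 2:
        raise PreconditionError("need at least 2 subjects per group")
    if adjacency.n_channels != group_a.shape[1]:
        raise DataError("adjacency channel count mismatch")
    flags = []
    na, nb = group_a.shape[0], group_b.shape[0]
    df = na + nb - 2
    thresh = _stats.t.ppf(1 - cluster_alpha / 2, df)
    pooled = np.vstack([group_a, group_b])
    t_obs = _welch_free_t(group_a, group_b)
    if np.any((pooled.var(axis=0) == 0)):
        flags.append("constant_channels")
    obs_clusters = _clusters_from_t(t_obs, thresh, adjacency)

    if n_perm == "exact":
        splits = list(combinations(range(na + nb), na))
    else:
        n_perm = int(n_perm)
        if n_perm < 100:
            warnings.warn("fewer than 100 permutations: p-values are coarse")
        rng = np.random.default_rng(seed)
        splits = [tuple(range(na))]  # observed labeling first
        for _ in range(n_perm - 1):
            perm = rng.permutation(na + nb)
            splits.append(tuple(sorted(perm[:na])))
    null_max = np.empty(len(splits))
    all_idx = set(range(na + nb))
    for si, split in enumerate(splits):
        ia = np.fromiter(split, int)
        ib = np.fromiter(all_idx - set(split), int)
        t = _welch_free_t(pooled[ia], pooled[ib])
        cl = _clusters_from_t(t, thresh, adjacency)
        null_max[si] = max((abs(s) for _, s in cl), default=0.0)
    clusters = []
    for members, stat in obs_clusters:
        p = float(np.mean(null_max >= abs(stat)))
        clusters.append(Cluster(members=members, statistic=stat, monte_carlo_p=p))
    clusters.sort(key=lambda c: (c.monte_carlo_p, -abs(c.statistic)))
    return ClusterResult(
        clusters=clusters,
        t_values=t_obs,
        n_permutations=len(splits),
        cluster_alpha=cluster_alpha,
        flags=flags,
    )


def select_electrodes(
    result: ClusterResult, significance: float = 0.05
) -> tuple[np.ndarray, dict]:
    """Members of the most significant cluster at the given level.

    Returns ``(channel indices, provenance)``; the set is empty (with
    ``provenance['fallback_all_channels'] = True``) when no cluster
    reaches significance, leaving the all-channel average to the caller.
    """
    significant = [c for c in result.clusters if c.monte_carlo_p <= significance]
    if not significant:
        return np.array([], dtype=int), {
            "fallback_all_channels": True,
            "n_clusters": len(result.clusters),
            "significance": significance,
        }
    best = min(significant, key=lambda c: (c.monte_carlo_p, -abs(c.statistic)))
    return best.members.copy(), {
        "fallback_all_channels": False,
        "cluster_p": best.monte_carlo_p,
        "cluster_statistic": best.statistic,
        "significance": significance,
    }
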