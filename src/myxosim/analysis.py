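"""Cluster and pattern quantification.

Implements the cluster metrics used to characterize collective motility
patterns: contact clusters and their size distribution p(m) (probability
that a cell sits in a cluster of m cells), the mass-weighted mean cluster
size ⟨m⟩, the nematic orientation pair correlation C(r) = ⟨cos 2Δθ_r⟩,
per-site visit-frequency maps with their distribution p(N), and a
log-binned power-law exponent fit for the cluster size distribution.

All functions operate on recorded :class:`~myxosim.engine.Snapshot`
trajectories; nothing here re-simulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ._kernels import agent_pair_min_dist
from .engine import Snapshot, Trajectory
from .model_core import ModelParams

__all__ = [
    "ClusterSet",
    "PowerLawFit",
    "CLUSTER_GAP_FACTOR",
    "detect_clusters",
    "cluster_size_distribution",
    "mean_cluster_size",
    "steady_mean_cluster_size",
    "orientation_correlation",
    "visit_frequency_map",
    "powerlaw_exponent",
]

#: adjacency threshold: capsule center-lines within this multiple of W_c
#: (surfaces within 20% of W_c — "touching within tolerance")
CLUSTER_GAP_FACTOR = 1.2


@dataclass
class ClusterSet:
    """Partition of agents into contact-connected clusters."""
    time: float
    labels: np.ndarray           # (M,) cluster label per agent
    sizes: np.ndarray            # (n_clusters,) agents per cluster

    @property
    def M(self) -> int:
        return len(self.labels)

    @property
    def max_size(self) -> int:
        return int(self.sizes.max())


def detect_clusters(s: Snapshot, p: ModelParams,
                    gap_factor: float = CLUSTER_GAP_FACTOR) -> ClusterSet:
    """Contact clusters: agents are adjacent iff the minimum distance
    between their capsule center-lines is ≤ gap_factor·W_c (minimum-image
    convention); clusters are the connected components. Singletons are
    clusters of size 1."""
    pos = s.positions
    M = pos.shape[0]
    L = p.L_sim
    cutoff = gap_factor * p.W_c
    centers = pos[:, pos.shape[1] // 2, :] % L
    tree = cKDTree(centers, boxsize=L)
    cand = tree.query_pairs(p.L_c + cutoff, output_type="ndarray")
    rows, cols = [], []
    for a, b in cand:
        if agent_pair_min_dist(pos[a], pos[b], L) <= cutoff:
            rows.append(a)
            cols.append(b)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(M, M))
    n, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n)
    return ClusterSet(time=s.time, labels=labels, sizes=sizes)


def cluster_size_distribution(cs: ClusterSet) -> pd.Series:
    """p(m) = m·n_m / M — the probability that a randomly chosen cell
    belongs to a cluster of size m. Normalized: Σ_m p(m) = 1."""
    if cs.M == 0:
        raise ValueError("empty ClusterSet")
    m_vals, n_m = np.unique(cs.sizes, return_counts=True)
    pm = m_vals * n_m / cs.M
    return pd.Series(pm, index=pd.Index(m_vals, name="m"), name="p")


def pooled_csd(clustersets) -> pd.Series:
    """p(m) pooled over several ClusterSets (snapshots and/or seeds)."""
    series = [cluster_size_distribution(cs) for cs in clustersets]
    df = pd.concat(series, axis=1).fillna(0.0)
    return df.mean(axis=1).rename("p")


def mean_cluster_size(pm: pd.Series) -> float:
    """⟨m⟩ = Σ_m m·p(m), the cell-mass-weighted mean cluster size."""
    total = float(pm.sum())
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ValueError(f"p(m) not normalized (sum = {total})")
    return float((pm.index.values * pm.values).sum())


def steady_mean_cluster_size(traj: Trajectory, p: ModelParams,
                             window: float = 60.0,
                             gap_factor: float = CLUSTER_GAP_FACTOR) -> float:
    """⟨m⟩ averaged over the snapshots of the final ``window`` minutes."""
    t_last = traj.snapshots[-1].time
    vals = [mean_cluster_size(cluster_size_distribution(
                detect_clusters(s, p, gap_factor)))
            for s in traj.snapshots if s.time >= t_last - window + 1e-9]
    return float(np.mean(vals))


def mean_cluster_size_series(traj: Trajectory, p: ModelParams,
                             gap_factor: float = CLUSTER_GAP_FACTOR
                             ) -> pd.Series:
    """⟨m⟩(t) for every snapshot of a trajectory."""
    t = [s.time for s in traj.snapshots]
    v = [mean_cluster_size(cluster_size_distribution(
            detect_clusters(s, p, gap_factor))) for s in traj.snapshots]
    return pd.Series(v, index=pd.Index(t, name="time_min"), name="mean_m")


def orientation_correlation(s: Snapshot, p: ModelParams,
                            bin_width: float = 1.0) -> pd.DataFrame:
    """Nematic orientation correlation C(r) = ⟨cos 2Δθ_r⟩.

    Δθ_r is the orientation difference of an agent pair whose center
    nodes are separated by r (minimum image); pairs are binned by r.
    cos 2Δθ makes parallel and antiparallel configurations equivalent.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    L = p.L_sim
    pos = s.positions[:, s.positions.shape[1] // 2, :]
    th = s.orientations
    M = pos.shape[0]
    r_max = L / 2.0
    nbins = int(math.ceil(r_max / bin_width))
    acc = np.zeros(nbins)
    cnt = np.zeros(nbins, dtype=np.int64)
    for i in range(M - 1):
        d = pos[i + 1:] - pos[i]
        d -= L * np.round(d / L)
        r = np.hypot(d[:, 0], d[:, 1])
        c2 = np.cos(2.0 * (th[i + 1:] - th[i]))
        b = np.minimum((r / bin_width).astype(np.int64), nbins - 1)
        np.add.at(acc, b, c2)
        np.add.at(cnt, b, 1)
    mask = cnt > 0
    mid = (np.arange(nbins) + 0.5) * bin_width
    return pd.DataFrame({"r": mid[mask], "C": acc[mask] / cnt[mask],
                         "n_pairs": cnt[mask]})


def visit_frequency_map(traj: Trajectory, window: float,
                        p: ModelParams, t_start: float = None):
    """Per-site visit counts and their distribution.

    Sites are the W_c grid; at every snapshot in
    [t_start, t_start + window) each agent's center node increments its
    site once. Returns ``(heat, p_N)`` with ``heat`` the (G, G) count
    matrix and ``p_N`` the fraction of *visited* sites with count N
    (never-visited sites carry no probability mass).
    """
    if t_start is None:
        t_start = traj.snapshots[-1].time - window
    G = p.grid_n
    w = p.L_sim / G
    heat = np.zeros((G, G), dtype=np.int64)
    used = 0
    for s in traj.snapshots:
        if t_start - 1e-9 <= s.time < t_start + window - 1e-9:
            used += 1
            c = s.positions[:, s.positions.shape[1] // 2, :] % p.L_sim
            gi = np.floor(c[:, 0] / w).astype(np.int64) % G
            gj = np.floor(c[:, 1] / w).astype(np.int64) % G
            np.add.at(heat, (gi, gj), 1)
    if used == 0:
        raise ValueError("window contains no snapshots")
    counts = heat[heat > 0]
    n_vals, n_sites = np.unique(counts, return_counts=True)
    p_N = pd.Series(n_sites / counts.size,
                    index=pd.Index(n_vals, name="N"), name="p")
    return heat, p_N


@dataclass
class PowerLawFit:
    beta: float
    stderr: float
    r2: float
    n_bins: int

    @property
    def good_fit(self) -> bool:
        return self.r2 >= 0.9


def powerlaw_exponent(pm: pd.Series, m_min: int = 10,
                      bins_per_decade: int = 5) -> PowerLawFit:
    """Least-squares slope β of log p(m) vs log m over logarithmic bins.

    Only m ≥ m_min enters; requires ≥ 5 occupied bins. The fit is flagged
    poor (``good_fit`` False) when R² < 0.9 — e.g. for exponential-like
    distributions.
    """
    pm = pm[(pm.index >= m_min) & (pm.values > 0)]
    if len(pm) == 0:
        raise ValueError(f"no occupied cluster sizes at m ≥ {m_min}")
    m = pm.index.values.astype(float)
    decades = math.log10(m.max() / m_min) if m.max() > m_min else 0.0
    n_edges = max(2, int(math.ceil(decades * bins_per_decade)) + 1)
    edges = np.geomspace(m_min, m.max() * (1 + 1e-12), n_edges)
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (m >= lo) & (m < hi) if hi < edges[-1] else (m >= lo) & (m <= hi)
        if not sel.any():
            continue
        xs.append(math.log10(np.exp(np.mean(np.log(m[sel])))))
        ys.append(math.log10(np.mean(pm.values[sel])))
    if len(xs) < 5:
        raise ValueError(f"only {len(xs)} occupied logarithmic bins above "
                         f"m = {m_min}; need ≥ 5")
    x = np.asarray(xs)
    y = np.asarray(ys)
    (beta, b0), cov = np.polyfit(x, y, 1, cov=True)
    yhat = beta * x + b0
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(beta=float(beta), stderr=float(math.sqrt(cov[0, 0])),
                       r2=r2, n_bins=len(xs))
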