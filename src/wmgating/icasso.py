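"""ICASSO stability analysis of a group ICA decomposition.

The unmixing estimation is repeated on bootstrap-resampled time points
with fresh random initialisation; all resulting component estimates are
compared by the absolute Pearson correlation of their time courses
evaluated on the ORIGINAL data, clustered by average-linkage
agglomeration, and each cluster is scored by the quality index Iq
(mean intra-cluster minus mean extra-cluster similarity). The R-index
curve over candidate cluster counts selects the partition; each cluster
is represented by its centrotype (the estimate with the largest summed
similarity to its cluster mates). Components whose cluster passes the
Iq screen count as reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .groupica import infomax


@dataclass
class Estimates:
    """Component estimates from repeated ICA runs.

    ``weights[r]`` is run r's unmixing matrix; estimate ``r * n_pc + k``
    denotes component k of run r. Time courses are always evaluated on
    the original (non-resampled) aggregate so estimates are comparable
    across bootstrap resamples.
    """

    weights: np.ndarray  # (n_runs, n_pc, n_pc)
    aggregate: np.ndarray  # (n_pc, n_samples), original data

    @property
    def n_runs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pc(self) -> int:
        return self.weights.shape[1]

    def stacked_weights(self) -> np.ndarray:
        return self.weights.reshape(-1, self.n_pc)

    def time_courses(self) -> np.ndarray:
        """(n_estimates, n_samples) component time courses."""
        return self.stacked_weights() @ self.aggregate


def run_bootstrap_ica(
    aggregate: np.ndarray,
    r_runs: int = 50,
    seed: int = 0,
    bootstrap: bool = True,
    fixed_init: bool = False,
    base_w: Optional[np.ndarray] = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    block: Optional[int] = None,
) -> Estimates:
    """Repeat Infomax ``r_runs`` times on bootstrapped time points.

    Each run resamples columns with replacement (unless ``bootstrap`` is
    False) and starts from a fresh random initialisation (unless
    ``fixed_init``). If ``base_w`` is given it is prepended as run 0 so
    the base decomposition's components can inherit cluster quality.
    """
    if r_runs < 1:
        raise ValueError("need at least one run")
    aggregate = np.asarray(aggregate, dtype=float)
    n_pc, n_samp = aggregate.shape
    rng = np.random.default_rng(seed)
    ws = []
    if base_w is not None:
        ws.append(np.asarray(base_w, dtype=float))
    for r in range(r_runs):
        data = aggregate[:, rng.integers(0, n_samp, n_samp)] if bootstrap else aggregate
        run_seed = seed if fixed_init else int(
            np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31)
        )
        ws.append(infomax(data, seed=run_seed, max_iter=max_iter, tol=tol, block=block))
    return Estimates(weights=np.array(ws), aggregate=aggregate)


def similarity_matrix(estimates) -> np.ndarray:
    """Absolute Pearson correlation between all component time courses.

    Accepts an :class:`Estimates` object (similarities computed exactly
    from the aggregate's covariance, without materialising every time
    course) or a raw (n_estimates, n_samples) time-course array.
    Zero-variance estimates get similarity 0 to everything (with a
    warning) and 1 on the diagonal.
    """
    if isinstance(estimates, Estimates):
        y = estimates.aggregate
        yc = y - y.mean(axis=1, keepdims=True)
        cov = yc @ yc.T
        w = estimates.stacked_weights()
        m = w @ cov @ w.T
        var = np.diag(m).copy()
    else:
        tc = np.asarray(estimates, dtype=float)
        if tc.shape[0] < 2:
            raise ValueError("need at least two estimates")
        tcc = tc - tc.mean(axis=1, keepdims=True)
        m = tcc @ tcc.T
        var = np.diag(m).copy()
    bad = var <= 0
    if bad.any():
        warnings.warn(f"{bad.sum()} zero-variance estimate(s)", stacklevel=2)
    denom = np.sqrt(np.outer(np.where(bad, 1.0, var), np.where(bad, 1.0, var)))
    s = np.abs(m) / denom
    s[bad, :] = 0.0
    s[:, bad] = 0.0
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return s


def cluster_estimates(s: np.ndarray, n_clusters: int = 20) -> np.ndarray:
    """Average-linkage agglomerative clustering on dissimilarity 1 - S,
    cut at ``n_clusters``; returns 0-based cluster ids per estimate."""
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    if n_clusters > n:
        raise ValueError("more clusters than estimates")
    d = 1.0 - 0.5 * (s + s.T)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(np.clip(d, 0.0, None), checks=False), method="average")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return labels - 1


def iq(partition: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Cluster quality: mean intra-cluster minus mean extra-cluster
    similarity; a singleton's intra term is defined as 1."""
    partition = np.asarray(partition)
    clusters = np.unique(partition)
    out = np.empty(len(clusters))
    for i, c in enumerate(clusters):
        members = np.flatnonzero(partition == c)
        others = np.flatnonzero(partition != c)
        if len(members) > 1:
            sub = s[np.ix_(members, members)]
            intra = sub[np.triu_indices(len(members), k=1)].mean()
        else:
            intra = 1.0
        inter = s[np.ix_(members, others)].mean() if len(others) else 0.0
        out[i] = intra - inter
    return out


def _mean_dissim(d: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return float(d[np.ix_(a, b)].mean())


def r_index(
    s: np.ndarray, l_range: Sequence[int]
) -> Tuple[Dict[int, float], int]:
    """Compactness/separation score over candidate cluster counts.

    R(L) = (1/L) sum_l [mean within-cluster dissimilarity of l] /
    [min over m != l of mean between-cluster dissimilarity l<->m];
    singleton clusters contribute 0 to the numerator. The argmin of the
    curve suggests the partition. Degenerate separations (zero between-
    cluster dissimilarity) yield +inf with a warning.
    """
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    for l in l_range:
        if not 2 <= l <= n - 1:
            raise ValueError("cluster counts must lie in [2, n_estimates - 1]")
    d = 1.0 - s
    curve: Dict[int, float] = {}
    for l in l_range:
        part = cluster_estimates(s, l)
        ids = np.unique(part)
        terms = []
        # identical estimates collapse below the requested count: no
        # separation exists and the score is undefined
        degenerate = len(ids) < 2
        for c in ids if not degenerate else []:
            members = np.flatnonzero(part == c)
            if len(members) > 1:
                sub = d[np.ix_(members, members)]
                within = sub[np.triu_indices(len(members), k=1)].mean()
            else:
                within = 0.0
            between = min(
                _mean_dissim(d, members, np.flatnonzero(part == m))
                for m in ids
                if m != c
            )
            if between <= 0:
                degenerate = True
                break
            terms.append(within / between)
        if degenerate:
            warnings.warn(
                f"L={l}: zero between-cluster dissimilarity, R undefined",
                stacklevel=2,
            )
            curve[int(l)] = float("inf")
        else:
            curve[int(l)] = float(np.mean(terms))
    finite = {l: v for l, v in curve.items() if np.isfinite(v)}
    best = min(finite, key=finite.get) if finite else int(list(l_range)[0])
    return curve, best


def centrotype(partition: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per cluster, the estimate maximizing its summed similarity to the
    cluster's members (ties broken by lowest estimate index)."""
    partition = np.asarray(partition)
    clusters = np.unique(partition)
    out = np.empty(len(clusters), dtype=int)
    for i, c in enumerate(clusters):
        members = np.flatnonzero(partition == c)
        sums = s[np.ix_(members, members)].sum(axis=1)
        out[i] = members[int(np.argmax(sums))]
    return out


def select_reliable(iq_values: np.ndarray, threshold: float = 0.85) -> np.ndarray:
    """Indices of clusters passing the Iq screen."""
    iq_values = np.asarray(iq_values, dtype=float)
    keep = np.flatnonzero(iq_values >= threshold)
    if keep.size == 0:
        warnings.warn("no cluster passes the Iq threshold", stacklevel=2)
    return keep


@dataclass
class IcassoResult:
    estimates: Estimates
    S: np.ndarray
    partition: np.ndarray
    iq: np.ndarray  # per cluster
    centrotypes: np.ndarray  # estimate index per cluster
    reliable_clusters: np.ndarray
    r_index_curve: Dict[int, float] = field(default_factory=dict)
    r_index_best: Optional[int] = None
    component_iq: Optional[np.ndarray] = None  # Iq of each base component


def run_icasso(
    aggregate: np.ndarray,
    base_w: Optional[np.ndarray] = None,
    r_runs: int = 50,
    n_clusters: int = 20,
    iq_threshold: float = 0.85,
    seed: int = 0,
    bootstrap: bool = True,
    compute_r_index: bool = False,
    l_range: Optional[Sequence[int]] = None,
    max_iter: int = 200,
    block: Optional[int] = None,
) -> IcassoResult:
    """Full stability analysis; when ``base_w`` is given, each of its
    components inherits the Iq of the cluster containing it (the base
    run's estimates are indices 0..n_pc-1)."""
    est = run_bootstrap_ica(
        aggregate,
        r_runs=r_runs,
        seed=seed,
        bootstrap=bootstrap,
        base_w=base_w,
        max_iter=max_iter,
        block=block,
    )
    s = similarity_matrix(est)
    part = cluster_estimates(s, n_clusters)
    q = iq(part, s)
    cents = centrotype(part, s)
    reliable = select_reliable(q, iq_threshold)
    curve, best = ({}, None)
    if compute_r_index:
        if l_range is None:
            l_range = range(2, min(n_clusters + 5, s.shape[0] - 1) + 1)
        curve, best = r_index(s, list(l_range))
    comp_iq = None
    if base_w is not None:
        n_pc = est.n_pc
        comp_iq = np.array([q[part[k]] for k in range(n_pc)])
    return IcassoResult(
        estimates=est,
        S=s,
        partition=part,
        iq=q,
        centrotypes=cents,
        reliable_clusters=reliable,
        r_index_curve=curve,
        r_index_best=best,
        component_iq=comp_iq,
    )
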