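"""Group-level cluster-based permutation inference on decoding AUC maps.

Pointwise one-sided Wilcoxon signed-rank tests of AUC against chance
(0.5) feed a cluster-based sign-flip permutation test: contiguous
supra-threshold points (1D curves) or 4-connected cells (2D temporal-
generalization matrices) form clusters whose mass is the sum of the
member signed-rank z values; the null is built by randomly sign-flipping
each subject's whole (AUC - chance) map and recording the maximum
cluster mass, giving familywise-corrected cluster p-values.

Because the absolute differences |AUC - chance| are invariant under sign
flips, the signed-rank statistic W+ of any flipped dataset is a linear
function of which subjects are flipped; the permutation null over all
points is therefore two matrix products, not a re-ranking per draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.stats import norm, rankdata


@dataclass
class Cluster:
    members: np.ndarray  # flat indices into the point grid
    mass: float
    p_value: Optional[float] = None


@dataclass
class ClusterTestResult:
    supra_mask: np.ndarray  # bool, original point shape
    z: np.ndarray
    p_pointwise: np.ndarray
    clusters: List[Cluster]
    alpha: float = 0.05
    n_perm: int = 1000
    chance: float = 0.5
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))


def _exact_tail(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) by enumerating the signed-rank distribution with a
    generating-function DP (handles tied, half-integer ranks)."""
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        if r > 0:
            counts[r:] += counts[:-r]
    w2 = int(np.ceil(round(w_obs * 2, 8) - 1e-9))
    return float(counts[max(w2, 0) :].sum() / counts.sum())


def _exact_crit(ranks: np.ndarray, alpha: float) -> float:
    """Smallest W+ with exact tail probability strictly below alpha."""
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        if r > 0:
            counts[r:] += counts[:-r]
    tail = np.cumsum(counts[::-1])[::-1] / counts.sum()
    below = np.flatnonzero(tail < alpha)
    if below.size == 0:
        return np.inf
    return below[0] / 2.0


class _SignedRankEngine:
    """Per-point signed-rank machinery shared by the observed statistics
    and the sign-flip null (ranks of |d| are flip-invariant)."""

    def __init__(self, d: np.ndarray, exact_max_n: int = 16, alpha: float = 0.05):
        n, p = d.shape
        self.n_subj = n
        self.n_points = p
        absd = np.abs(d)
        nonzero = absd > 0
        ranks = np.zeros_like(d)
        all_nz = nonzero.all(axis=0)
        if all_nz.any():
            ranks[:, all_nz] = rankdata(absd[:, all_nz], axis=0)
        for j in np.flatnonzero(~all_nz):
            nzj = nonzero[:, j]
            if nzj.any():
                ranks[nzj, j] = rankdata(absd[nzj, j])
        self.ranks = ranks
        self.n_nz = nonzero.sum(axis=0)
        self.a = ranks * (d > 0)  # contribution when subject not flipped
        self.b = ranks * (d < 0)  # contribution when subject flipped
        nn = self.n_nz.astype(float)
        self.mu = nn * (nn + 1) / 4.0
        var = nn * (nn + 1) * (2 * nn + 1) / 24.0
        # tie correction: sum(t^3 - t)/48 over tied groups of nonzero |d|
        for j in range(p):
            rj = ranks[nonzero[:, j], j]
            if rj.size:
                _, cnt = np.unique(rj, return_counts=True)
                if (cnt > 1).any():
                    var[j] -= float(((cnt**3 - cnt).sum())) / 48.0
        self.sigma = np.sqrt(np.clip(var, 0.0, None))
        self.exact = (self.n_nz <= exact_max_n) & (self.n_nz > 0)
        self.alpha = alpha
        self._w_crit: Optional[np.ndarray] = None

    def w_plus(self, flips: Optional[np.ndarray] = None) -> np.ndarray:
        """W+ per point; ``flips`` is (n_perm, n_subj) boolean (True =
        subject's differences sign-flipped)."""
        if flips is None:
            return self.a.sum(axis=0)
        flips = np.asarray(flips, dtype=float)
        return (1.0 - flips) @ self.a + flips @ self.b

    def z_of(self, w: np.ndarray) -> np.ndarray:
        safe = np.where(self.sigma > 0, self.sigma, 1.0)
        return np.where(self.sigma > 0, (w - self.mu) / safe, 0.0)

    def p_of(self, w: np.ndarray) -> np.ndarray:
        """One-sided p (greater) per point; exact tail where n is small,
        normal approximation with tie correction otherwise. Points with
        no nonzero difference get p = 1."""
        p = np.ones_like(w, dtype=float)
        ok = (self.sigma > 0) & ~self.exact
        p[ok] = norm.sf(self.z_of(w)[ok])
        for j in np.flatnonzero(self.exact):
            nzj = self.ranks[:, j] > 0
            p[j] = _exact_tail(self.ranks[nzj, j], w[j])
        return p

    def w_crit(self) -> np.ndarray:
        """Per-point critical W+: supra-threshold iff W+ >= w_crit
        (equivalent to pointwise p < alpha under the matching tail)."""
        if self._w_crit is not None:
            return self._w_crit
        crit = np.full(self.n_points, np.inf)
        ok = (self.sigma > 0) & ~self.exact
        crit[ok] = self.mu[ok] + norm.isf(self.alpha) * self.sigma[ok] + 1e-12
        for j in np.flatnonzero(self.exact):
            nzj = self.ranks[:, j] > 0
            crit[j] = _exact_crit(self.ranks[nzj, j], self.alpha)
        self._w_crit = crit
        return crit


def pointwise_wilcoxon(
    auc_by_subject: np.ndarray,
    chance: float = 0.5,
    alternative: str = "greater",
    exact_max_n: int = 16,
) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided signed-rank test of AUC > chance at every point.

    ``auc_by_subject`` is (n_subjects, ...); zero differences are dropped
    (a point where every subject sits exactly at chance gets p = 1).
    Returns (z, p) with the original point shape.
    """
    auc = np.asarray(auc_by_subject, dtype=float)
    if auc.shape[0] < 6:
        raise ValueError("signed-rank inference needs at least 6 subjects")
    shape = auc.shape[1:]
    d = auc.reshape(auc.shape[0], -1) - chance
    if alternative == "less":
        d = -d
    elif alternative != "greater":
        raise ValueError("alternative must be 'greater' or 'less'")
    eng = _SignedRankEngine(d, exact_max_n=exact_max_n)
    w = eng.w_plus()
    return eng.z_of(w).reshape(shape), eng.p_of(w).reshape(shape)


def form_clusters(supra_mask: np.ndarray, z: np.ndarray) -> List[Cluster]:
    """Contiguous runs (1D) or 4-connected regions (2D) of supra-threshold
    points; cluster mass is the sum of member z values."""
    supra_mask = np.asarray(supra_mask, dtype=bool)
    z = np.asarray(z, dtype=float)
    if supra_mask.ndim == 1:
        structure = np.ones(3, dtype=int)
    elif supra_mask.ndim == 2:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    else:
        raise ValueError("only 1D curves and 2D matrices are supported")
    labels, n_lab = ndimage.label(supra_mask, structure=structure)
    clusters = []
    for lab in range(1, n_lab + 1):
        members = np.flatnonzero(labels.ravel() == lab)
        clusters.append(Cluster(members=members, mass=float(z.ravel()[members].sum())))
    return clusters


def _max_mass(supra: np.ndarray, z: np.ndarray, structure) -> float:
    labels, n_lab = ndimage.label(supra, structure=structure)
    if n_lab == 0:
        return 0.0
    masses = ndimage.sum_labels(z, labels, index=np.arange(1, n_lab + 1))
    return float(np.max(masses))


def permutation_test(
    auc_by_subject: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    chance: float = 0.5,
    alpha: float = 0.05,
    exact_max_n: int = 16,
) -> ClusterTestResult:
    """Cluster-based sign-flip permutation test of AUC above chance.

    Works on (n_subjects, n_times) curves or (n_subjects, n_times,
    n_times) temporal-generalization stacks. Cluster p-values use the
    +1-smoothed estimator p = (1 + #{null max mass >= observed}) /
    (n_perm + 1), so p >= 1/(n_perm + 1).
    """
    auc = np.asarray(auc_by_subject, dtype=float)
    if auc.shape[0] < 6:
        raise ValueError("signed-rank inference needs at least 6 subjects")
    shape = auc.shape[1:]
    structure = (
        np.ones(3, dtype=int)
        if len(shape) == 1
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    d = auc.reshape(auc.shape[0], -1) - chance
    eng = _SignedRankEngine(d, exact_max_n=exact_max_n, alpha=alpha)
    w_obs = eng.w_plus()
    z_obs = eng.z_of(w_obs)
    p_obs = eng.p_of(w_obs)
    crit = eng.w_crit()
    supra = (w_obs >= crit).reshape(shape)
    clusters = form_clusters(supra, z_obs.reshape(shape))

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, auc.shape[0])).astype(bool)
    w_null = eng.w_plus(flips)
    z_null = eng.z_of(w_null)
    supra_null = w_null >= crit
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        null_max[i] = _max_mass(
            supra_null[i].reshape(shape), z_null[i].reshape(shape), structure
        )
    for cl in clusters:
        cl.p_value = float((1 + np.sum(null_max >= cl.mass)) / (n_perm + 1))
    return ClusterTestResult(
        supra_mask=supra,
        z=z_obs.reshape(shape),
        p_pointwise=p_obs.reshape(shape),
        clusters=clusters,
        alpha=alpha,
        n_perm=n_perm,
        chance=chance,
        null_max_mass=null_max,
    )


def significant_clusters(result: ClusterTestResult) -> List[Cluster]:
    return [c for c in result.clusters if c.p_value is not None and c.p_value < result.alpha]
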