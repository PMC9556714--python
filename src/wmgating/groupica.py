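"""Temporal-concatenation group ICA.

Each subject's channel data are compressed and whitened with a
subject-level PCA, whitened series are concatenated in time, a single
extended-Infomax unmixing matrix W is estimated on the aggregate
(C = WX), and component time courses are reconstructed back to each
subject. Back-projection to channel space and percentage of power
accounted for (ppaf) complete the bookkeeping. Component sign and scale
are arbitrary; topographies are reported unit-norm with the
largest-magnitude channel weight positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .preprocess import EpochSet


@dataclass
class PCACompression:
    """Subject-level PCA compression (top ``n_pc`` eigenvectors of the
    channel covariance, whitened)."""

    mean: np.ndarray  # (channels,)
    basis: np.ndarray  # (channels, n_pc), orthonormal columns
    eigenvalues: np.ndarray  # (n_pc,)
    explained_fraction: float
    n_pc: int


def pca_compress(
    x: np.ndarray, n_pc: int = 20, var_threshold: float = 0.98
) -> Tuple[PCACompression, np.ndarray]:
    """Compress (channels, samples) data to ``n_pc`` whitened components.

    Returns the compression and the reduced data (n_pc, samples) with
    identity covariance on the retained, non-degenerate directions.
    Warns (does not fail) when the retained eigenvalue fraction falls
    below ``var_threshold``.
    """
    x = np.asarray(x, dtype=float)
    n_ch, n_samp = x.shape
    if n_pc > n_ch:
        raise ValueError(f"n_pc={n_pc} exceeds channel count {n_ch}")
    if n_samp <= n_pc:
        raise ValueError("need more samples than retained components")
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    cov = xc @ xc.T / (n_samp - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    explained = float(evals[:n_pc].sum() / total) if total > 0 else 1.0
    if explained < var_threshold:
        warnings.warn(
            f"retained eigenvalue fraction {explained:.3f} below "
            f"threshold {var_threshold}",
            stacklevel=2,
        )
    lam = evals[:n_pc]
    # degenerate directions (rank-deficient data) carry no signal: map to 0
    scale = np.where(lam > lam[0] * 1e-12, 1.0 / np.sqrt(np.maximum(lam, 1e-300)), 0.0)
    reduced = scale[:, None] * (evecs[:, :n_pc].T @ xc)
    comp = PCACompression(
        mean=mean,
        basis=evecs[:, :n_pc],
        eigenvalues=lam,
        explained_fraction=explained,
        n_pc=n_pc,
    )
    return comp, reduced


def concatenate_subjects(
    reduced: Sequence[np.ndarray],
) -> Tuple[np.ndarray, List[int]]:
    """Temporal concatenation of per-subject reduced data.

    Returns the aggregate (n_pc, total_samples) and per-subject sample
    offsets for back-reconstruction.
    """
    n_pcs = {r.shape[0] for r in reduced}
    if len(n_pcs) != 1:
        raise ValueError("all subjects must share the same n_pc")
    offsets = list(np.cumsum([0] + [r.shape[1] for r in reduced])[:-1])
    return np.concatenate(list(reduced), axis=1), offsets


def infomax(
    aggregate: np.ndarray,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-7,
    block: Optional[int] = None,
) -> np.ndarray:
    """Extended-Infomax unmixing of whitened aggregate data.

    Thin wrapper around :func:`mne.preprocessing.infomax` (extended,
    annealing learning rate). ``aggregate`` is (n_components, samples);
    the returned W satisfies C = W @ aggregate.
    """
    from mne.preprocessing import infomax as _mne_infomax

    aggregate = np.asarray(aggregate, dtype=float)
    if not np.all(np.isfinite(aggregate)):
        raise ValueError("aggregate contains non-finite values")
    # degenerate (zero-variance) rows arise from rank-deficient data after
    # whitening; Infomax diverges on them, so unmix the active subspace
    # only and keep identity on the rest
    var = aggregate.var(axis=1)
    active = var > max(var.max(), 0.0) * 1e-12
    if active.all():
        return _mne_infomax(
            aggregate.T,
            extended=True,
            max_iter=max_iter,
            w_change=tol,
            rng=seed,
            block=block,
            verbose="error",
        )
    n = aggregate.shape[0]
    w = np.eye(n)
    idx = np.flatnonzero(active)
    if idx.size >= 2:
        w_sub = _mne_infomax(
            aggregate[idx].T,
            extended=True,
            max_iter=max_iter,
            w_change=tol,
            rng=seed,
            block=block,
            verbose="error",
        )
        w[np.ix_(idx, idx)] = w_sub
    return w


@dataclass
class GroupICAResult:
    """Group decomposition plus everything needed to go back to channels."""

    W: np.ndarray  # (n_pc, n_pc) unmixing on the whitened aggregate
    A: np.ndarray  # (n_pc, n_pc) mixing = W^-1
    pca: List[PCACompression]
    subject_sources: List[np.ndarray]  # per subject (n_pc, samples)
    subject_topographies: List[np.ndarray]  # per subject (channels, n_pc)
    topographies: np.ndarray  # group (channels, n_pc), unit norm
    offsets: List[int]
    subject_shapes: List[Tuple[int, int]]  # (n_trials, n_samples) per subject
    subjects: List[str] = field(default_factory=list)
    n_iter: Optional[int] = None
    aggregate_est: Optional[np.ndarray] = None  # columns W was estimated on


def back_reconstruct(w: np.ndarray, reduced: Sequence[np.ndarray]) -> List[np.ndarray]:
    """Per-subject component time courses: C_s = W @ Y_s."""
    return [w @ r for r in reduced]


def _canonical_sign(topo: np.ndarray) -> float:
    k = int(np.argmax(np.abs(topo)))
    return 1.0 if topo[k] >= 0 else -1.0


def fit_groupica(
    epochs_list: Sequence[EpochSet],
    n_pc: int = 20,
    var_threshold: float = 0.98,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
    max_samples: Optional[int] = None,
    block: Optional[int] = None,
) -> GroupICAResult:
    """Run the full group decomposition on one condition's epochs.

    Trials are concatenated in time within subject before PCA; the group
    topography of each component is the sign-aligned mean of the
    per-subject topographies (basis * sqrt(eigenvalues) * A column),
    normalized to unit norm with canonical sign. When ``max_samples`` is
    set, W is estimated on that many uniformly subsampled aggregate
    columns (back-reconstruction always uses the full data).
    """
    pcas, reduced, shapes, subjects = [], [], [], []
    for ep in epochs_list:
        x = ep.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
        comp, red = pca_compress(x, n_pc=n_pc, var_threshold=var_threshold)
        pcas.append(comp)
        reduced.append(red)
        shapes.append((ep.n_trials, len(ep.times)))
        subjects.append(ep.subject)
    aggregate, offsets = concatenate_subjects(reduced)
    agg_est = aggregate
    if max_samples is not None and aggregate.shape[1] > max_samples:
        idx = np.random.default_rng(seed).choice(
            aggregate.shape[1], max_samples, replace=False
        )
        agg_est = aggregate[:, np.sort(idx)]
    w = infomax(agg_est, seed=seed, max_iter=max_iter, tol=tol, block=block)
    a = np.linalg.inv(w)
    sources = back_reconstruct(w, reduced)

    subj_topos = []
    for comp in pcas:
        dewhiten = comp.basis * np.sqrt(comp.eigenvalues)[None, :]
        subj_topos.append(dewhiten @ a)

    n_ch = subj_topos[0].shape[0]
    group = np.zeros((n_ch, n_pc))
    for k in range(n_pc):
        cols = []
        ref = None
        for st in subj_topos:
            c = st[:, k]
            nrm = np.linalg.norm(c)
            if nrm == 0:
                continue
            c = c / nrm
            if ref is None:
                ref = c
            if c @ ref < 0:
                c = -c
            cols.append(c)
        if cols:
            g = np.mean(cols, axis=0)
            nrm = np.linalg.norm(g)
            if nrm > 0:
                g = g / nrm * _canonical_sign(g / nrm)
            group[:, k] = g
    return GroupICAResult(
        W=w,
        A=a,
        pca=pcas,
        subject_sources=sources,
        subject_topographies=subj_topos,
        topographies=group,
        offsets=offsets,
        subject_shapes=shapes,
        subjects=subjects,
        aggregate_est=agg_est,
    )


def back_project(
    result: GroupICAResult,
    subset: Sequence[int],
    subject: int,
    add_mean: bool = False,
) -> np.ndarray:
    """Channel-space reconstruction from a component subset.

    Returns (channels, samples) for the given subject; with all
    components this equals the PCA-retained part of the (centered)
    subject data. An empty subset yields zeros (useful for ppaf).
    ``add_mean`` restores the subject's PCA channel mean, reconstructing
    in original units rather than centered ones.
    """
    subset = list(subset)
    n_pc = result.W.shape[0]
    for k in subset:
        if not 0 <= k < n_pc:
            raise IndexError(f"component index {k} out of range 0..{n_pc - 1}")
    topo = result.subject_topographies[subject]
    src = result.subject_sources[subject]
    if not subset:
        xhat = np.zeros((topo.shape[0], src.shape[1]))
    else:
        xhat = topo[:, subset] @ src[subset, :]
    if add_mean:
        xhat = xhat + result.pca[subject].mean[:, None]
    return xhat


def back_project_epochs(
    result: GroupICAResult, subset: Sequence[int], subject: int, template: EpochSet
) -> EpochSet:
    """Back-projection reshaped into the subject's epoch structure.

    The subject's PCA channel mean is restored so epochs from different
    condition-wise decompositions live in the same (original) units —
    decoding between them must not see each decomposition's own centering
    as a class difference.
    """
    xhat = back_project(result, subset, subject, add_mean=True)
    n_trials, n_samples = result.subject_shapes[subject]
    data = xhat.reshape(template.n_channels, n_trials, n_samples).transpose(1, 0, 2)
    out = template.select(np.ones(template.n_trials, dtype=bool))
    out.data = data
    return out


def ppaf(
    result: GroupICAResult,
    subset: Sequence[int],
    subject: int,
    original: np.ndarray,
) -> float:
    """Percentage of power accounted for by a component subset.

    ``original`` is the subject's (channels, samples) data as fed to the
    fit (trials concatenated); it is centered with the subject's PCA mean
    before comparison. ppaf = 100 * (1 - ||X - Xhat||^2 / ||X||^2).
    """
    xc = np.asarray(original, dtype=float) - result.pca[subject].mean[:, None]
    total = float(np.sum(xc**2))
    if total == 0:
        raise ValueError("ppaf undefined for zero-power data")
    xhat = back_project(result, subset, subject)
    resid = float(np.sum((xc - xhat) ** 2))
    return 100.0 * (1.0 - resid / total)


def amari_index(p: np.ndarray) -> float:
    """Permutation/scale-invariant ICA recovery error of P = W_est @ A_true.

    0 means W recovered the inverse of the true mixing up to permutation
    and scaling; normalized so a random matrix scores near 1.
    """
    p = np.abs(np.asarray(p, dtype=float))
    n = p.shape[0]
    row = (p / p.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (p / p.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * n * (n - 1)))
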