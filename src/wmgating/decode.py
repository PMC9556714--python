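"""Per-subject MVPA on back-projected component pairs.

Binary decoding of switch vs nonswitch trials (each class back-projected
through its own condition's matched component): class balancing by
random undersampling, shrinkage LDA (Ledoit-Wolf automatic lambda, since
a single component's back-projection is rank-1 across channels), 5-fold
stratified cross-validation repeated twice, time-resolved AUC, and the
temporal-generalization matrix (train at t, test at every t').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold


def undersample(
    trials_a: np.ndarray, trials_b: np.ndarray, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Balance two trial sets to the smaller class by uniform random
    removal from the larger one. The smaller (or equal-sized) class is
    returned unchanged."""
    a, b = np.asarray(trials_a), np.asarray(trials_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")
    n = min(len(a), len(b))
    rng = np.random.default_rng(seed)
    if len(a) > n:
        a = a[np.sort(rng.choice(len(a), n, replace=False))]
    if len(b) > n:
        b = b[np.sort(rng.choice(len(b), n, replace=False))]
    return a, b


def lda_train(
    features: np.ndarray, labels: np.ndarray, shrinkage="auto"
) -> Tuple[np.ndarray, float]:
    """Fit a binary shrinkage-LDA; returns (weights, intercept).

    Decision scores are ``features @ weights + intercept``; only their
    ranking matters for AUC.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("LDA training requires exactly two classes")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def _auc_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank-based AUC of each column of ``scores`` for binary y (1 = positive)."""
    y = np.asarray(y, dtype=bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(scores, axis=0)
    return (ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@dataclass
class DecodingResult:
    times: np.ndarray  # ms, within the post-stimulus decoding window
    auc_t: np.ndarray  # (n_times,)
    tg: np.ndarray  # (n_times, n_times) train x test
    subject: str = ""
    pair: Optional[object] = None
    cv_spec: Dict = field(default_factory=dict)


def _lda_all_times(
    x_tr: np.ndarray, y_tr: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Shrinkage-LDA weights for every time point at once.

    Pooled within-class covariance per time point with Ledoit-Wolf
    automatic shrinkage toward the scaled identity; returns weights
    (n_times, channels) and intercepts (n_times,).
    """
    y_tr = np.asarray(y_tr).astype(bool)
    n, p, _ = x_tr.shape
    m1 = x_tr[y_tr].mean(axis=0)  # (ch, T)
    m0 = x_tr[~y_tr].mean(axis=0)
    z = x_tr.copy()
    z[y_tr] -= m1
    z[~y_tr] -= m0
    s = np.einsum("ict,idt->tcd", z, z) / n
    eye = np.eye(p)
    mu = np.einsum("tcc->t", s) / p
    d2 = ((s - mu[:, None, None] * eye) ** 2).sum(axis=(1, 2)) / p
    norms2 = (z**2).sum(axis=1)  # (n, T)
    b2 = (np.sum(norms2**2, axis=0) - n * (s**2).sum(axis=(1, 2))) / (n * n * p)
    lam = np.where(d2 > 0, np.clip(b2 / np.where(d2 > 0, d2, 1.0), 0.0, 1.0), 1.0)
    shrunk = (1 - lam)[:, None, None] * s + (lam * mu)[:, None, None] * eye
    shrunk += 1e-12 * np.maximum(mu, 1e-30)[:, None, None] * eye
    w = np.linalg.solve(shrunk, (m1 - m0).T[..., None])[..., 0]  # (T, ch)
    b = -np.einsum("tc,ct->t", w, (m1 + m0) / 2.0)
    return w, b


def _cv_aucs(
    x: np.ndarray,
    y: np.ndarray,
    folds: int,
    repeats: int,
    seed: int,
    diag_only: bool,
) -> np.ndarray:
    """Core CV loop shared by the time course and the TG matrix.

    ``x`` is (trials, channels, times). Fold assignment for repeat r uses
    random_state seed + r, so the TG diagonal and the time course agree
    exactly under a shared seed.
    """
    n_trials, _, n_times = x.shape
    if n_trials < folds:
        raise ValueError("fewer trials than folds")
    acc = np.zeros((n_times, n_times)) if not diag_only else np.zeros(n_times)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in skf.split(np.zeros(n_trials), y):
            x_tr, y_tr = x[train_idx], y[train_idx]
            x_te, y_te = x[test_idx], y[test_idx]
            w, b = _lda_all_times(x_tr, y_tr)
            if diag_only:
                scores = np.einsum("ict,tc->it", x_te, w) + b[None, :]
                acc += _auc_columns(scores, y_te)
            else:
                # scores[i, s, t']: classifier trained at s applied at t'
                scores = np.einsum("ict,sc->ist", x_te, w) + b[None, :, None]
                flat = scores.reshape(len(x_te), -1)
                acc += _auc_columns(flat, y_te).reshape(n_times, n_times)
    acc /= folds * repeats
    return acc


def decode_timecourse(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    folds: int = 5,
    repeats: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Time-resolved AUC: at each sample, features are the channel vector,
    stratified k-fold CV repeated with re-randomized folds, AUC averaged
    over folds x repeats. Classes must already be balanced."""
    x = np.concatenate([epochs_a, epochs_b], axis=0)
    y = np.r_[np.ones(len(epochs_a), dtype=int), np.zeros(len(epochs_b), dtype=int)]
    return _cv_aucs(x, y, folds, repeats, seed, diag_only=True)


def temporal_generalization(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    folds: int = 5,
    repeats: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Temporal-generalization AUC matrix (train time x test time) with
    the same fold assignments as :func:`decode_timecourse` under the same
    seed, so its diagonal equals the time-resolved AUC exactly."""
    x = np.concatenate([epochs_a, epochs_b], axis=0)
    y = np.r_[np.ones(len(epochs_a), dtype=int), np.zeros(len(epochs_b), dtype=int)]
    return _cv_aucs(x, y, folds, repeats, seed, diag_only=False)


def decode_pair(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    times: np.ndarray,
    tmin: float = 0.0,
    tmax: float = 1500.0,
    folds: int = 5,
    repeats: int = 2,
    seed: int = 0,
    decim: int = 1,
    subject: str = "",
    pair=None,
) -> DecodingResult:
    """Balance classes, restrict to the post-stimulus window, and compute
    the TG matrix; the reported time course is its diagonal (identical to
    :func:`decode_timecourse` under the shared fold seed)."""
    times = np.asarray(times, dtype=float)
    sel = np.flatnonzero((times >= tmin) & (times <= tmax))[::decim]
    a, b = undersample(epochs_a[:, :, sel], epochs_b[:, :, sel], seed=seed)
    tg = temporal_generalization(a, b, folds=folds, repeats=repeats, seed=seed)
    return DecodingResult(
        times=times[sel],
        auc_t=np.diag(tg).copy(),
        tg=tg,
        subject=subject,
        pair=pair,
        cv_spec={"folds": folds, "repeats": repeats, "seed": seed, "decim": decim},
    )
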