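"""Cross-condition component matching by topography correlation.

Reliable components from two condition-wise decompositions are paired
when the absolute Pearson correlation between their channel
topographies reaches the threshold. Matching is resolved greedily and
one-to-one (a candidate joins only its best template) so the reported
pairs are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ComponentPair:
    condition_a: str
    condition_b: str
    ic_a: int
    ic_b: int
    similarity: float
    iq_a: Optional[float] = None
    iq_b: Optional[float] = None


def _abs_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0, keepdims=True)
    bc = b - b.mean(axis=0, keepdims=True)
    an = np.linalg.norm(ac, axis=0)
    bn = np.linalg.norm(bc, axis=0)
    an = np.where(an == 0, 1.0, an)
    bn = np.where(bn == 0, 1.0, bn)
    return np.abs((ac / an).T @ (bc / bn))


def match_topographies(
    templates: np.ndarray,
    candidates: np.ndarray,
    threshold: float = 0.9,
    max_per_group: int = 3,
    condition_a: str = "A",
    condition_b: str = "B",
) -> List[ComponentPair]:
    """Pair template components (condition A) with candidates (condition B).

    Both arguments are (channels, n_components) topography matrices.
    Candidates with |r| >= threshold are shortlisted per template (best
    ``max_per_group``), then a greedy pass over all shortlisted matches
    in descending similarity keeps only one-to-one assignments.
    """
    templates = np.asarray(templates, dtype=float)
    candidates = np.asarray(candidates, dtype=float)
    if templates.shape[0] != candidates.shape[0]:
        raise ValueError("channel counts differ between template and candidate sets")
    r = _abs_corr(templates, candidates)
    shortlisted = []
    for i in range(r.shape[0]):
        js = np.flatnonzero(r[i] >= threshold)
        js = js[np.argsort(-r[i, js])][:max_per_group]
        shortlisted.extend((float(r[i, j]), i, int(j)) for j in js)
    shortlisted.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_t, used_c = set(), set()
    pairs = []
    for sim, i, j in shortlisted:
        if i in used_t or j in used_c:
            continue
        used_t.add(i)
        used_c.add(j)
        pairs.append(
            ComponentPair(
                condition_a=condition_a,
                condition_b=condition_b,
                ic_a=i,
                ic_b=j,
                similarity=sim,
            )
        )
    pairs.sort(key=lambda p: (p.ic_a, p.ic_b))
    return pairs


def attach_iq(
    pairs: Sequence[ComponentPair],
    iq_a: Sequence[float],
    iq_b: Sequence[float],
) -> List[ComponentPair]:
    """Annotate pairs with each side's ICASSO stability."""
    out = []
    for p in pairs:
        out.append(
            ComponentPair(
                condition_a=p.condition_a,
                condition_b=p.condition_b,
                ic_a=p.ic_a,
                ic_b=p.ic_b,
                similarity=p.similarity,
                iq_a=float(iq_a[p.ic_a]),
                iq_b=float(iq_b[p.ic_b]),
            )
        )
    return out


def filter_pairs_by_iq(
    pairs: Sequence[ComponentPair], iq_threshold: float = 0.85
) -> List[ComponentPair]:
    """Drop pairs where either side fails the stability screen."""
    return [
        p
        for p in pairs
        if (p.iq_a is None or p.iq_a >= iq_threshold)
        and (p.iq_b is None or p.iq_b >= iq_threshold)
    ]


def pair_report(pairs: Sequence[ComponentPair]) -> pd.DataFrame:
    """One row per matched pair: indices, per-side stability, similarity."""
    cols = ["pair", "condition_a", "ic_a", "iq_a", "condition_b", "ic_b", "iq_b", "similarity"]
    rows = [
        {
            "pair": k + 1,
            "condition_a": p.condition_a,
            "ic_a": p.ic_a,
            "iq_a": p.iq_a,
            "condition_b": p.condition_b,
            "ic_b": p.ic_b,
            "iq_b": p.iq_b,
            "similarity": p.similarity,
        }
        for k, p in enumerate(pairs)
    ]
    return pd.DataFrame(rows, columns=cols)
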