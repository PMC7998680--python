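"""Pairwise association measures over taxa.

Five measures are computed over all unordered taxon pairs of a count
table: Pearson and Spearman correlation (similarity polarity), Steinhaus
similarity, and Bray-Curtis and symmetric Kullback-Leibler dissimilarity.
Steinhaus and Bray-Curtis are exact complements (S = 1 - BC) on
non-negative data.  Scores are computed on absolute counts by default; a
per-sample normalisation switch exists for sensitivity analyses.

Undefined scores (zero-variance vectors for the correlations, all-zero
pairs for the dissimilarities) are recorded as NaN, never as 0, and cannot
support an edge downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .tables_io import OtuTable, ValidationError

METHODS = ("pearson", "spearman", "steinhaus", "bray_curtis", "kl_sym")

POLARITY = {
    "pearson": "similarity",
    "spearman": "similarity",
    "steinhaus": "similarity",
    "bray_curtis": "dissimilarity",
    "kl_sym": "dissimilarity",
}

_SELF_SCORE = {
    "pearson": 1.0,
    "spearman": 1.0,
    "steinhaus": 1.0,
    "bray_curtis": 0.0,
    "kl_sym": 0.0,
}


@dataclass
class AssociationMatrix:
    method: str
    scores: np.ndarray  # symmetric, NaN where undefined
    polarity: str
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        n = len(self.taxon_ids)
        if self.scores.shape != (n, n):
            raise ValidationError("score matrix shape mismatch")


def _check_pair(x, y, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if len(x) < min_len:
        raise ValidationError(f"need at least {min_len} observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values")
    return x, y


def pearson_pair(x, y) -> float:
    """Product-moment correlation; NaN if either vector has zero variance."""
    x, y = _check_pair(x, y, min_len=3)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def spearman_pair(x, y) -> float:
    """Rank correlation with mid-ranks for ties."""
    x, y = _check_pair(x, y, min_len=3)
    return pearson_pair(rankdata(x), rankdata(y))


def _check_nonneg(x, y) -> tuple[np.ndarray, np.ndarray]:
    x, y = _check_pair(x, y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("negative values not allowed")
    if x.sum() + y.sum() == 0:
        raise ValidationError("both vectors are all-zero")
    return x, y


def bray_curtis_pair(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x, y = _check_nonneg(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def steinhaus_pair(x, y) -> float:
    """Steinhaus similarity 2 sum min(x, y) / sum(x+y) = 1 - Bray-Curtis."""
    x, y = _check_nonneg(x, y)
    return float(2.0 * np.minimum(x, y).sum() / (x + y).sum())


def kl_sym_pair(x, y, pseudocount: float = 1.0) -> float:
    """Symmetric Kullback-Leibler divergence KL(p||q) + KL(q||p).

    A pseudocount is added to every entry before normalising each vector to
    a probability distribution, so the divergence is finite in the presence
    of zeros (ubiquitous in OTU tables).  Natural log.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    x, y = _check_pair(x, y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("negative values not allowed")
    p = x + pseudocount
    q = y + pseudocount
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum((p - q) * (np.log(p) - np.log(q))))


def association_matrix(
    table: OtuTable,
    method: str,
    *,
    normalize: bool = False,
    pseudocount: float = 1.0,
) -> AssociationMatrix:
    """Score all unordered taxon pairs of ``table`` with one measure.

    Vectorised over the whole matrix; equal to looping the pairwise
    functions over every pair.  ``normalize`` divides each sample column by
    its total first (off by default: scoring uses absolute counts).
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if table.n_samples < 3:
        raise ValidationError("need at least 3 samples")
    if table.n_taxa < 2:
        raise ValidationError("need at least 2 taxa")
    data = table.counts.astype(float)
    if normalize:
        totals = data.sum(axis=0)
        if np.any(totals <= 0):
            raise ValidationError("cannot normalize all-zero sample")
        data = data / totals

    if method in ("pearson", "spearman"):
        rows = rankdata(data, axis=1) if method == "spearman" else data
        centered = rows - rows.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        defined = norms > 0
        safe = np.where(defined, norms, 1.0)
        unit = centered / safe[:, None]
        scores = np.clip(unit @ unit.T, -1.0, 1.0)
        scores[~defined, :] = np.nan
        scores[:, ~defined] = np.nan
    elif method in ("bray_curtis", "steinhaus"):
        totals = data.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            bc = squareform(pdist(data, metric="braycurtis"))
        # pairs of all-zero rows are undefined
        zero = totals == 0
        bc[np.ix_(zero, zero)] = np.nan
        scores = 1.0 - bc if method == "steinhaus" else bc
    else:  # kl_sym
        p = data + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        logp = np.log(p)
        a = (p * logp).sum(axis=1)
        scores = a[:, None] + a[None, :] - p @ logp.T - logp @ p.T
        scores = np.maximum(scores, 0.0)

    scores = (scores + scores.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(scores, _SELF_SCORE[method])
    return AssociationMatrix(method, scores, POLARITY[method], list(table.taxon_ids))
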