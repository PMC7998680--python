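"""Ensemble edge selection, bootstrap significance, Brown merging, BH filtering.

The construction follows the CoNet recipe.  Each association measure
nominates its ``top_k`` highest- and ``top_k`` lowest-scoring taxon pairs
as candidate edges; the score direction plus the measure's polarity fixes
the edge sign (high similarity / low dissimilarity = co-presence, the
reverse = mutual exclusion).  A pair survives the vote when at least
``min_support`` measures nominate it with the same sign.

Per-measure p-values come from a bootstrap-versus-permutation comparison:
the score is recomputed on ``n_bootstrap`` resamples of the samples
(columns) to fit a Normal(mean, sd), and the null score is the mean score
under column permutations of one member of the pair (a data-dependent
null: Bray-Curtis or KL between independent vectors is far from zero).
The two-sided tail probability of the null score under the fitted normal
is the measure's p-value.  Measure p-values for one edge are merged by
Brown's method, with the covariance between the -2 ln p statistics
estimated from pseudo-p-values on shared bootstrap resamples; with zero
covariance the merge reduces exactly to Fisher's method.  Finally the
merged p-values are Benjamini-Hochberg adjusted and edges with q < alpha
are kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata

from .filters import FilterParams, prevalence_filter, remove_rare_otus
from .measures import METHODS, AssociationMatrix, association_matrix
from .tables_io import NetworkRecord, OtuTable, SampleMetadata, ValidationError

P_FLOOR = 1e-300


@dataclass
class EnsembleParams:
    """Run parameters of the ensemble construction.

    Defaults mirror a full-scale run on a ~900-OTU table; ``top_k`` should
    be scaled with the number of available pairs on smaller tables (the
    defaults nominate roughly 0.7% of all pairs per direction at full
    scale).
    """

    top_k: int = 3000
    min_support: int = 3
    n_bootstrap: int = 100
    n_permutation: int = 100
    alpha: float = 0.05
    seed: int = 0
    two_sided: bool = True
    null_model: str = "combined"

    def __post_init__(self) -> None:
        if self.null_model not in ("combined", "bootstrap_only"):
            raise ValidationError("null_model must be 'combined' or 'bootstrap_only'")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not (1 <= self.min_support <= len(METHODS)):
            raise ValidationError(
                f"min_support must lie in [1, {len(METHODS)}] (one vote per measure)"
            )
        if self.n_bootstrap < 2:
            raise ValidationError("n_bootstrap must be >= 2")
        if self.n_permutation < 1:
            raise ValidationError("n_permutation must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class EdgeCandidate:
    pair: tuple[str, str]
    method: str
    score: float
    sign: str  # "copresence" | "exclusion"


@dataclass
class EnsembleEdge:
    pair: tuple[str, str]
    sign: str
    supporting_methods: frozenset[str]
    p_method: dict[str, float]
    p_brown: float
    q_bh: float | None = None
    boot_mean: dict[str, float] = field(default_factory=dict)
    boot_sd: dict[str, float] = field(default_factory=dict)
    sources: frozenset[str] | None = None

    def __post_init__(self) -> None:
        a, b = self.pair
        if a > b:
            self.pair = (b, a)


@dataclass
class BootstrapResult:
    p: float
    boot_mean: float
    boot_sd: float
    pseudo_p: np.ndarray  # per-replicate pseudo-p-values (for Brown covariance)


# ---------------------------------------------------------------------------
# Candidate selection and voting

def _ordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def select_candidates(mat: AssociationMatrix, top_k: int) -> list[EdgeCandidate]:
    """Nominate the ``top_k`` highest and ``top_k`` lowest scoring pairs.

    For similarity measures high scores mean co-presence and low scores
    mutual exclusion; for dissimilarity measures the mapping is reversed.
    Ties at the cutoff break lexicographically on the taxon pair, so the
    selection is deterministic.  Undefined (NaN) scores never qualify.
    """
    ids = mat.taxon_ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    vals = mat.scores[iu]
    finite = np.isfinite(vals)
    pairs = [
        (_ordered(ids[i], ids[j]), float(v))
        for i, j, v in zip(iu[0][finite], iu[1][finite], vals[finite])
    ]
    if mat.polarity == "similarity":
        high_sign, low_sign = "copresence", "exclusion"
    else:
        high_sign, low_sign = "exclusion", "copresence"
    top = sorted(pairs, key=lambda t: (-t[1], t[0]))[:top_k]
    bottom = sorted(pairs, key=lambda t: (t[1], t[0]))[:top_k]
    out = [EdgeCandidate(p, mat.method, s, high_sign) for p, s in top]
    out += [EdgeCandidate(p, mat.method, s, low_sign) for p, s in bottom]
    return out


def vote(
    candidates: Iterable[EdgeCandidate] | Iterable[Sequence[EdgeCandidate]],
    min_support: int,
) -> list[tuple[tuple[str, str], str, frozenset[str]]]:
    """Keep pairs nominated with one consistent sign by >= min_support measures.

    Co-presence and exclusion nominations for the same pair are counted
    separately; the pair is retained under the strictly more supported
    sign, provided that sign reaches ``min_support``.  A sign tie drops
    the pair (conflicting evidence).
    """
    flat: list[EdgeCandidate] = []
    for item in candidates:
        if isinstance(item, EdgeCandidate):
            flat.append(item)
        else:
            flat.extend(item)
    support: dict[tuple[tuple[str, str], str], set[str]] = {}
    for c in flat:
        support.setdefault((c.pair, c.sign), set()).add(c.method)
    results = []
    for pair in sorted({p for p, _ in support}):
        cop = support.get((pair, "copresence"), set())
        exc = support.get((pair, "exclusion"), set())
        if len(cop) >= min_support and len(cop) > len(exc):
            results.append((pair, "copresence", frozenset(cop)))
        elif len(exc) >= min_support and len(exc) > len(cop):
            results.append((pair, "exclusion", frozenset(exc)))
    return results


# ---------------------------------------------------------------------------
# Batched pair scoring (bootstrap/permutation replicates)

def _scores_batch(a: np.ndarray, b: np.ndarray, method: str, pseudocount: float = 1.0) -> np.ndarray:
    """Score m replicate pairs at once; rows of ``a``/``b`` are replicates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method in ("pearson", "spearman"):
        if method == "spearman":
            a = rankdata(a, axis=1)
            b = rankdata(b, axis=1)
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ac * bc).sum(axis=1) / denom
        return np.where(denom > 0, np.clip(r, -1.0, 1.0), np.nan)
    if method in ("bray_curtis", "steinhaus"):
        denom = (a + b).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            bcur = np.abs(a - b).sum(axis=1) / denom
        bcur = np.where(denom > 0, bcur, np.nan)
        return 1.0 - bcur if method == "steinhaus" else bcur
    if method == "kl_sym":
        p = a + pseudocount
        q = b + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        q = q / q.sum(axis=1, keepdims=True)
        return np.sum((p - q) * (np.log(p) - np.log(q)), axis=1)
    raise ValidationError(f"unknown method {method!r}")


def _tail_p(delta: np.ndarray | float, sd: float, two_sided: bool) -> np.ndarray | float:
    z = np.abs(delta) / sd
    return 2.0 * norm.sf(z) if two_sided else norm.sf(z)


def bootstrap_p(
    table: OtuTable,
    pair: tuple[str, str],
    method: str,
    params: EnsembleParams,
    *,
    boot_indices: np.ndarray | None = None,
    perm_indices: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> BootstrapResult:
    """Bootstrap-versus-permutation p-value for one (pair, measure).

    Columns (samples) are resampled with replacement to fit a normal to
    the score's bootstrap distribution; the null score is the mean score
    over column permutations of the second vector.  Degenerate resamples
    (zero variance for correlations) are redrawn a bounded number of
    times, then dropped; fewer than two usable replicates flags the result
    with p = NaN.

    Under the default ``null_model="combined"`` the normal tail is taken
    at the standardised distance between the bootstrap mean and the
    permutation-null mean using sqrt(sd_boot^2 + sd_perm^2): the null
    score is itself an estimate with sampling spread, and ignoring that
    spread overstates significance for pairs that were pre-selected for
    extreme scores.  ``null_model="bootstrap_only"`` uses the bootstrap
    standard deviation alone.
    """
    idx = {t: i for i, t in enumerate(table.taxon_ids)}
    ia = pair[0] if isinstance(pair[0], (int, np.integer)) else idx[pair[0]]
    ib = pair[1] if isinstance(pair[1], (int, np.integer)) else idx[pair[1]]
    x = table.counts[int(ia)].astype(float)
    y = table.counts[int(ib)].astype(float)
    n = len(x)
    rng = np.random.default_rng([params.seed & 0x7FFFFFFF, int(ia), int(ib)])
    if boot_indices is None:
        boot_indices = rng.integers(0, n, size=(params.n_bootstrap, n))
    if perm_indices is None:
        perm_indices = np.array([rng.permutation(n) for _ in range(params.n_permutation)])

    boot = _scores_batch(x[boot_indices], y[boot_indices], method, pseudocount)
    bad = ~np.isfinite(boot)
    for _ in range(5):
        if not bad.any():
            break
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        boot[bad] = _scores_batch(x[redraw], y[redraw], method, pseudocount)
        bad = ~np.isfinite(boot)
    boot = boot[np.isfinite(boot)]
    if len(boot) < 2:
        return BootstrapResult(float("nan"), float("nan"), float("nan"), np.array([]))

    xm = np.broadcast_to(x, (len(perm_indices), n))
    null_scores = _scores_batch(xm, y[perm_indices], method, pseudocount)
    null_scores = null_scores[np.isfinite(null_scores)]
    if len(null_scores) == 0:
        return BootstrapResult(float("nan"), float("nan"), float("nan"), np.array([]))
    theta0 = float(null_scores.mean())

    mu = float(boot.mean())
    sd = float(boot.std(ddof=1))
    if params.null_model == "combined" and len(null_scores) > 1:
        sd_eff = float(np.sqrt(sd**2 + null_scores.std(ddof=1) ** 2))
    else:
        sd_eff = sd
    if sd_eff == 0.0:
        p = 1.0 if mu == theta0 else 0.0
        pseudo = np.where(boot == theta0, 1.0, 0.0)
    else:
        p = float(_tail_p(theta0 - mu, sd_eff, params.two_sided))
        pseudo = np.asarray(_tail_p(boot - theta0, sd_eff, params.two_sided))
    return BootstrapResult(p, mu, sd, pseudo)


# ---------------------------------------------------------------------------
# P-value combination and FDR

def brown_merge(
    p_method: Mapping[str, float],
    pseudo_p: Mapping[str, np.ndarray] | None = None,
    *,
    p_floor: float = P_FLOOR,
) -> float:
    """Combine dependent p-values with Brown's scaled chi-square method.

    ``pseudo_p`` carries per-replicate pseudo-p-values computed on shared
    bootstrap resamples; the covariance of the -2 ln p statistics is
    estimated through their empirical correlation (clamped to [0, 1] and
    scaled by the theoretical variance 4 of -2 ln U).  Without replicate
    information the covariances are zero and the merge is exactly Fisher's
    method.  A single p-value is returned unchanged.
    """
    methods = sorted(p_method)
    k = len(methods)
    if k == 0:
        raise ValidationError("need at least one p-value")
    ps = np.clip([p_method[m] for m in methods], p_floor, 1.0)
    if k == 1:
        return float(ps[0])
    x_stat = -2.0 * float(np.sum(np.log(ps)))
    mean_x = 2.0 * k
    cov_sum = 0.0
    if pseudo_p is not None:
        w = {}
        for m in methods:
            arr = np.asarray(pseudo_p.get(m, []), dtype=float)
            if arr.size:
                w[m] = -2.0 * np.log(np.clip(arr, p_floor, 1.0))
        for m1, m2 in itertools.combinations(methods, 2):
            if m1 in w and m2 in w and len(w[m1]) == len(w[m2]) and len(w[m1]) >= 2:
                s1, s2 = w[m1].std(), w[m2].std()
                if s1 > 0 and s2 > 0:
                    r = float(np.corrcoef(w[m1], w[m2])[0, 1])
                    cov_sum += 4.0 * min(max(r, 0.0), 1.0)
                elif np.allclose(w[m1], w[m2]):
                    cov_sum += 4.0  # identical degenerate replicates: full dependence
    var_x = 4.0 * k + 2.0 * cov_sum
    c = var_x / (2.0 * mean_x)
    df = 2.0 * mean_x**2 / var_x
    return float(chi2.sf(x_stat / c, df))


def bh_adjust(
    p_values: Sequence[float],
    alpha: float = 0.05,
    n_total: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and strict keep mask.

    Returns ``(q, keep)`` where ``q[i] = min_{j: p_(j) >= p_(i)} p_(j) m / j``
    with monotonicity enforced, and ``keep = q < alpha`` (strict).

    ``n_total`` sets the effective number of tests when the supplied list
    is a screened subset of a larger family: the remaining
    ``n_total - len(p)`` hypotheses count as p = 1.  Candidate selection
    screens every taxon pair, so the full pipeline corrects for all
    screened pairs rather than only the voted survivors — otherwise the
    correction would inherit the selection bias of the screen.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = max(len(p), n_total or 0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(len(p))
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < alpha


# ---------------------------------------------------------------------------
# Full pipeline

def infer_network(
    table: OtuTable,
    meta: SampleMetadata,
    treatment: str,
    filter_params: FilterParams | None = None,
    ensemble_params: EnsembleParams | None = None,
    *,
    normalize: bool = False,
    pseudocount: float = 1.0,
) -> NetworkRecord:
    """Run the full ensemble construction for one treatment arm.

    Composes the prevalence filter, the five association matrices,
    candidate selection, sign-consistent voting, per-measure bootstrap
    p-values (on bootstrap resamples shared across measures), Brown
    merging, and BH filtering.  The result is deterministic given the
    inputs and ``ensemble_params.seed``.
    """
    filter_params = filter_params or FilterParams()
    params = ensemble_params or EnsembleParams()

    work = remove_rare_otus(table) if filter_params.remove_singletons_doubletons else table
    work = prevalence_filter(work, meta, filter_params, treatment)
    if work.n_samples < 3:
        raise ValidationError("fewer than 3 samples after filtering")
    if work.n_taxa < 2:
        raise ValidationError("fewer than 2 taxa after filtering")

    mats = {
        m: association_matrix(work, m, normalize=normalize, pseudocount=pseudocount)
        for m in METHODS
    }
    candidates = {m: select_candidates(mats[m], params.top_k) for m in METHODS}
    voted = vote(candidates.values(), params.min_support)

    n = work.n_samples
    rng = np.random.default_rng(params.seed & 0x7FFFFFFF)
    boot_idx = rng.integers(0, n, size=(params.n_bootstrap, n))
    perm_idx = np.array([rng.permutation(n) for _ in range(params.n_permutation)])

    edges: list[EnsembleEdge] = []
    for pair, sign, methods in voted:
        p_map: dict[str, float] = {}
        mu_map: dict[str, float] = {}
        sd_map: dict[str, float] = {}
        pseudo: dict[str, np.ndarray] = {}
        for m in sorted(methods):
            res = bootstrap_p(
                work, pair, m, params,
                boot_indices=boot_idx, perm_indices=perm_idx, pseudocount=pseudocount,
            )
            if np.isfinite(res.p):
                p_map[m] = res.p
                mu_map[m] = res.boot_mean
                sd_map[m] = res.boot_sd
                pseudo[m] = res.pseudo_p
        if len(p_map) < params.min_support:
            continue  # support collapsed once degenerate measures were flagged
        p_brown = brown_merge(p_map, pseudo)
        edges.append(
            EnsembleEdge(pair, sign, frozenset(p_map), p_map, p_brown,
                         boot_mean=mu_map, boot_sd=sd_map)
        )

    n_screened = work.n_taxa * (work.n_taxa - 1) // 2
    q, keep = bh_adjust([e.p_brown for e in edges], params.alpha, n_total=n_screened)
    kept = []
    for e, qi, ok in zip(edges, q, keep):
        e.q_bh = float(qi)
        if ok:
            kept.append(e)

    nodes = {t for e in kept for t in e.pair}
    attributes = {
        "treatment": treatment,
        "top_k": params.top_k,
        "min_support": params.min_support,
        "n_bootstrap": params.n_bootstrap,
        "n_permutation": params.n_permutation,
        "alpha": params.alpha,
        "seed": params.seed,
        "normalize": normalize,
        "pseudocount": pseudocount,
        "stage_counts": {
            "taxa_after_filters": work.n_taxa,
            "samples": work.n_samples,
            "candidates_per_method": {m: len(candidates[m]) for m in METHODS},
            "edges_after_vote": len(voted),
            "edges_tested": len(edges),
            "edges_after_bh": len(kept),
        },
    }
    return NetworkRecord(nodes, kept, attributes)
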