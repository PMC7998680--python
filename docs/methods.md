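# Methods

This note documents the models and procedures implemented in `otunet`,
the parameters that matter, the choices made where the design was
genuinely open, and the limits of what the synthetic benchmarks show.

## Ensemble network construction

Input is an OTU table of absolute sequence counts (taxa × samples) plus
sample metadata mapping each sample to a patient, a treatment arm and a
timepoint.  One network is inferred per treatment arm.

**Filtering.**  Singleton/doubleton removal drops taxa whose *total*
count over the whole table is ≤ 2 (the whole-table reading of
"singletons and doubletons"; a per-sample reading would remove far more
and is not what mothur-era workflows did).  The per-arm prevalence
filter keeps a taxon only if it is detected (count > 0) in at least
`min_patients_present` (default 3) distinct patients *and* in at least
`min_occurrence_fraction` (default 0.6) of the arm's samples.  Both
thresholds are inclusive.  An absolute-count override
(`min_occurrence_count`) exists because a fraction-of-samples rule and
an absolute-observations rule genuinely differ on small arms and both
are in circulation.

**Association measures.**  Five measures are computed on raw counts over
all taxon pairs: Pearson, Spearman (mid-ranks for ties), Steinhaus
similarity, Bray–Curtis dissimilarity and symmetric Kullback–Leibler
divergence.  Steinhaus and Bray–Curtis are exact complements
(S = 1 − BC), so the ensemble effectively carries four independent
views; both are kept because the ensemble contract is defined over the
five named measures.  KL requires a pseudocount (default 1 count added
to every entry before per-vector normalisation) because OTU tables are
full of zeros and KL is undefined at 0.  Zero-variance vectors make the
correlations undefined; undefined scores propagate as missing (NaN),
never as 0, and cannot nominate or support an edge.  A per-sample
normalisation switch exists (`normalize`) but defaults off: the scores
are defined on absolute counts.

**Candidate selection and voting.**  Each measure nominates its `top_k`
highest- and `top_k` lowest-scoring pairs.  For similarity-polarity
measures high scores mean co-presence and low scores mutual exclusion;
dissimilarity measures are read the other way.  This sign convention is
not stated explicitly anywhere authoritative, but it is the only mapping
that makes "positive and negative edges" coherent across correlations
and dissimilarities.  Ties at the cutoff break lexicographically on the
taxon pair, making selection deterministic.  A pair survives the vote
when at least `min_support` (default 3) measures nominate it with the
*same* sign; co-presence and exclusion nominations are counted
separately, the strictly larger camp wins, and a tie drops the pair —
mixing co-presence and exclusion evidence for one pair would be
incoherent.

`top_k` defaults to 3000, which on a ~940-taxon table nominates roughly
0.68% of all pairs per direction.  On smaller tables the same *density*
is the sensible setting; `otunet.validation.scaled_top_k(n_taxa)`
implements that proportionality (e.g. 12 of the 1770 pairs of a
60-taxon table).  Setting `top_k` at or above the number of pairs makes
every pair a candidate in both directions and the sign vote then cancels
itself; `top_k` is a screen, not a formality.

**Per-measure significance.**  For each voted edge and each supporting
measure, the score is recomputed on `n_bootstrap` (default 100)
resamples of the samples (columns, never taxa — samples are the
replicates) to give a bootstrap distribution with mean μ̂ and sd σ̂
(ddof 1).  The null score θ₀ is the mean score over `n_permutation`
(default 100) column permutations of one member of the pair.  The null
is data-dependent on purpose: independent count vectors have a
Bray–Curtis around their abundance offset and a KL far from 0, so a
fixed null of 0 would be wrong for the dissimilarities.  Bootstrap
resample indices and permutations are drawn once per network run and
shared across measures, so the dependence between measures is visible
to the merging step.  Degenerate resamples (zero variance under a
correlation) are redrawn a bounded number of times and then dropped;
fewer than two usable replicates flags the measure as missing for that
edge, and an edge whose usable measures fall below `min_support` is
discarded.

The p-value is the two-sided normal tail at the standardised distance
between μ̂ and θ₀.  Two standardisations are available:

* `null_model="combined"` (default): sd = √(σ̂² + σ̂_perm²), where
  σ̂_perm is the sd of the permutation scores.  θ₀ is an estimate with
  its own sampling spread; treating it as exact overstates certainty,
  and the overstatement is worst precisely for the pairs the screen
  pre-selected for extreme scores.
* `null_model="bootstrap_only"`: sd = σ̂ alone, the textbook
  "bootstrap mean and sd as the parameters of the normal" reading.

The combined form is the default because it is what makes the
false-positive calibration below come out right; the bootstrap-only
form is kept for comparability.  If sd = 0 the p-value degenerates to 0
(μ̂ ≠ θ₀) or 1 (μ̂ = θ₀).

**Merging and FDR.**  Measure p-values for one edge are combined with
Brown's method: X = −2 Σ ln pₘ is approximated by a scaled χ² with
scale c = Var/(2E) and df f = 2E²/Var, E = 2k,
Var = 4k + 2 Σ cov(−2 ln pₘ, −2 ln pₘ′).  Covariances are estimated
from per-replicate pseudo-p-values on the shared bootstrap resamples,
via their empirical correlation clamped to [0, 1] and scaled by the
theoretical variance 4 of −2 ln U.  With all covariances 0 the merge
reduces *exactly* to Fisher's method, and a perfectly duplicated
measure collapses to the single-measure p-value.  P-values are floored
at 1e−300 before logs.

Benjamini–Hochberg runs over the merged p-values with the effective
family size set to the number of *screened* pairs, C(n_taxa_filtered, 2)
— not the handful of voted survivors.  The screen looks at every pair;
correcting only over the survivors re-imports the screen's selection
bias (on structure-free tables ~70% of voted pairs would survive BH at
α = 0.05; over the screened family, none do).  The standalone
`bh_adjust` function defaults to the classical m = len(p) and takes the
screened size as an explicit `n_total` argument.  Edges are kept at
strict q < α (default 0.05).

## Topology

Modules come from greedy modularity maximisation
(Clauset–Newman–Moore via networkx) on the unweighted, sign-blind
graph — the algorithm family that fast-greedy/GLay-style community
tools wrap.  Nodes enter in sorted order so tie-breaking is
deterministic; isolated nodes become singleton modules; module ids are
contiguous from 0, ordered by decreasing size.  Edge signs and
p-values ride along as attributes but play no role in community
structure (there is no agreed signed-modularity convention to follow).

Within-module degree z uses the population (ddof 0) standard deviation
of the module's within-degrees, with z = 0 when that sd is 0, so
degenerate modules cannot produce infinities.  The participation
coefficient is Pᵢ = 1 − Σₜ (kᵢₜ/kᵢ)² over all modules t, with Pᵢ = 0
for isolated nodes.  Role thresholds are z = 2.5 and Pᵢ = 0.62 with
boundary values falling in the ≤ class (a node at exactly z = 2.5,
Pᵢ = 0.62 is peripheral).

The difference merge of k networks keeps every signed edge present in
at least one but not all of them, tagged with its source networks; the
node set is the endpoints of surviving edges.  The same pair may
legitimately survive twice with opposite signs (a sign flip between
treatment arms); network records and both serialisation formats
(edge-list TSV, GraphML via a multigraph) allow that.

## Alpha diversity

Shannon uses the natural log; Simpson is reported as the complement
1 − Σpᵢ² (in [0, 1)); Chao1 defaults to the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)), with the classic F₁²/(2F₂) form available
(it is infinite when F₂ = 0 and F₁ > 0, which the bias-corrected form
avoids).  These match the conventions of the vegan functions most
workflows cite.  All-zero columns are an error, not a 0.

## Synthetic data generator

The generator emulates the data *shape* of a three-arm longitudinal
skin-microbiome trial: arms synbiotic/prebiotic/placebo with 7/8/7
patients, each sampled at days 0, 9, 11 and 14 (88 samples); a
~940-taxon inventory; one dominant *Staphylococcus*-like taxon whose
expected relative abundance is drawn per sample uniformly from
(0.33, 0.66); sequencing depth lognormal around `depth_mean` (default
20 000 reads, CV 0.15, floored at 1).

Each taxon has a base log-abundance drawn N(0, 1.5) (the
rank-abundance backbone) plus per-sample log-noise N(0, 1); counts are
multinomial at the sample's depth over the exponentiated latents.  The
dominant taxon's weight is set per sample so its *expected* share is
exactly the drawn fraction.

Planted structure is imposed on the latent scale, variance-preserving:
a pair with coupling ρ replaces each member's noise by
√(1−ρ²)·ε ± ρ·g with a shared standard-normal factor g, giving latent
correlation ±ρ² while leaving every marginal unchanged.  Two modelling
points deserve emphasis because both were learned the hard way:

* **Pair members share one base abundance.**  Profile-based measures
  (Bray–Curtis, Steinhaus, KL) are blind to couplings between taxa
  whose expected abundances differ by orders of magnitude — the
  abundance offset dominates the profile comparison.  Ecological
  co-presence and mutual exclusion are interactions between taxa
  living at comparable scales, and planting them that way is what
  makes a 3-of-5 ensemble vote achievable at all.
* **Couplings must not inflate variance.**  An additive shared factor
  on top of the backbone lets a coupled pair bloom past the rest of
  the community; under multinomial closure every such bloom depresses
  all other taxa simultaneously and fills the table with strong
  common-mode correlations that are *real* in count space but not
  planted.  Variance-preserving coupling plants dependence without
  touching composition.

Module blocks work the same way with a per-block factor (default
within-block coupling 0.8); an optional hub taxon spreads one 0.9
coupling budget evenly over its blocks' factors, so it correlates with
each block without belonging fully to any.  `simulate_null_table` is
the same backbone with no dominant taxon and no planted structure.

What the generator does **not** emulate: temporal autocorrelation
within a patient (timepoints are exchangeable draws; an explicit
dynamics model would be a separate effort), taxonomy assignment error,
read-level artefacts, overdispersion beyond the lognormal latent, and
patient-level dominance trajectories (the dominant fraction is i.i.d.
per sample).  Benchmarks passing on these tables show the pipeline
recovers the dependence structures it is designed for under a
realistic compositional regime — not that it would recover them from
any particular real data set.

## Validation experiments and problem sizes

The acceptance script and the acceptance tests recompute, from scratch:

* **Planted recovery** — 60 taxa, one arm of 38 patients × 4
  timepoints (152 samples), 5 co-presence + 5 exclusion pairs at
  ρ = 1, `top_k = scaled_top_k(60) = 12`.  Measured: precision and
  recall of the final edge set against truth (≥ 0.8 expected, typically
  0.9–1.0), and that every recovered planted edge carries the planted
  sign.
* **False-positive control** — 10 structure-free tables (50 taxa ×
  100 samples), `top_k = 8`.  Measured: fraction of voted pairs
  surviving BH at α = 0.05 (≤ 5% expected; observed 0 with the default
  null model and screened-family correction).
* **Module recovery** — 3 planted blocks of 15 nodes (edge probability
  0.8 within, 0.02 between): adjusted Rand index of the detected
  partition (≥ 0.9 expected), and an engineered cross-block node
  classified connector or network hub.
* **Study-shaped run** — a 60-taxon table over the full 7/8/7 × 4
  design, per-arm networks, difference merge and diversity summaries,
  to exercise the exact trial layout end to end.

These sizes keep every experiment in seconds while leaving each
property comfortably measurable.

## Known limitations

* No renormalised-permutation ("ReBoot"-style) null: compositional
  common-mode correlations that are genuinely present in count space
  are detected as edges, exactly as the measures see them.  The
  generator's variance-preserving design keeps that regime realistic
  rather than pathological, but on real data with strong dominance
  swings, compositional edges will appear.
* The screened-family BH correction is deliberately conservative: with
  very small arms (tens of samples) and hundreds of thousands of
  screened pairs, essentially no edge can reach q < 0.05.  That is an
  honest statement about the information in such a design, but it
  means full-inventory runs on small arms yield sparse or empty
  networks rather than the thousands of edges an uncorrected-family
  workflow reports.
* GLay itself (a Cytoscape plugin) is approximated by its underlying
  greedy-modularity family; exact plugin output is not reproducible
  from a description.
* Spearman's mid-rank treatment makes heavily zero-tied taxa look more
  similar than a presence/absence view would suggest; the prevalence
  filter is what keeps such taxa out.
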