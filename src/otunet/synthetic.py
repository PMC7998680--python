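"""Synthetic OTU tables with planted association structure.

The generator emulates the data shape of a longitudinal skin-microbiome
trial: three bath-treatment arms (synbiotic/prebiotic/placebo, 7/8/7
patients) sampled at days 0, 9, 11 and 14, a dominant Staphylococcus-like
taxon holding one-third to two-thirds of the reads in every sample, and a
long lognormal tail of minor taxa.

The count model is the standard compositional simulation: each taxon gets
a latent log-abundance per sample (lognormal backbone), planted
co-presence/mutual-exclusion pairs and module blocks share latent Gaussian
factors, and reads are drawn multinomially at a per-sample depth.  Coupling
acts on the latent log scale, so counts stay valid at any sequencing depth,
and the multinomial closure reproduces the spurious-correlation regime that
ensemble scoring (correlations mixed with dissimilarities) is designed to
survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tables_io import OtuTable, SampleMetadata, SampleRecord, ValidationError

# Latent-scale constants.  Couplings are variance-preserving: a planted
# pair replaces a rho-fraction of each member's log-scale noise with a
# shared factor, so the latent correlation is +/- rho^2 while every
# marginal keeps sd _NOISE_SD.  Planting dependence without inflating
# variance keeps the community composition realistic (a coupled pair never
# blooms past the backbone and so never induces common-mode artifacts in
# everybody else's relative abundance).
_NOISE_SD = 1.0
_BASE_SD = 1.5
_DEPTH_CV = 0.15

_STAPH_LINEAGE = "Bacteria;Firmicutes;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus"


def _default_groups() -> list[tuple[str, int]]:
    return [("synbiotic", 7), ("prebiotic", 8), ("placebo", 7)]


def _default_timepoints() -> list[int]:
    return [0, 9, 11, 14]


@dataclass
class PlantedDesign:
    """Ground-truth design for :func:`simulate_table`.

    Pairs may be given as taxon indices or taxon ids ("Otu0001"-style,
    1-based zero-padded).  ``module_blocks`` entries are ``(members, rho)``;
    a bare member collection gets the default within-block coupling 0.8.
    ``hub_spec`` names one taxon plus the block indices it loads onto.
    """

    n_taxa: int = 937
    groups: list[tuple[str, int]] = field(default_factory=_default_groups)
    timepoints: list[int] = field(default_factory=_default_timepoints)
    depth_mean: float = 20000.0
    dominant_taxon_fraction_range: tuple[float, float] = (0.33, 0.66)
    copresence_pairs: list[tuple] = field(default_factory=list)
    exclusion_pairs: list[tuple] = field(default_factory=list)
    module_blocks: list = field(default_factory=list)
    hub_spec: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValidationError("n_taxa must be positive")
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ValidationError("each group needs at least one patient")
        if not self.timepoints:
            raise ValidationError("at least one timepoint required")
        lo, hi = self.dominant_taxon_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("dominant fraction range must satisfy 0 < low < high < 1")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")
        self.copresence_pairs = [self._norm_pair(p) for p in self.copresence_pairs]
        self.exclusion_pairs = [self._norm_pair(p) for p in self.exclusion_pairs]
        seen: set[tuple[str, str]] = set()
        for i, j, rho in self.copresence_pairs + self.exclusion_pairs:
            if not (0.0 < rho <= 1.0):
                raise ValidationError(f"coupling strength {rho} outside (0, 1]")
            if (i, j) in seen:
                raise ValidationError(f"pair ({i}, {j}) planted more than once")
            seen.add((i, j))
        blocks = []
        for entry in self.module_blocks:
            if (
                isinstance(entry, tuple)
                and len(entry) == 2
                and isinstance(entry[1], (int, float))
            ):
                members, rho = entry
            else:
                members, rho = entry, 0.8
            members = [self._norm_taxon(t) for t in members]
            if not (0.0 < rho <= 1.0):
                raise ValidationError(f"block coupling {rho} outside (0, 1]")
            blocks.append((members, float(rho)))
        self.module_blocks = blocks
        if self.hub_spec is not None:
            taxon, block_ids = self.hub_spec
            block_ids = sorted(set(int(b) for b in block_ids))
            if any(b < 0 or b >= len(self.module_blocks) for b in block_ids):
                raise ValidationError("hub_spec references a nonexistent block")
            self.hub_spec = (self._norm_taxon(taxon), block_ids)

    def taxon_ids(self) -> list[str]:
        width = max(4, len(str(self.n_taxa)))
        return [f"Otu{i + 1:0{width}d}" for i in range(self.n_taxa)]

    def _norm_taxon(self, t) -> str:
        ids = self.taxon_ids()
        if isinstance(t, (int, np.integer)):
            if not 0 <= t < self.n_taxa:
                raise ValidationError(f"taxon index {t} out of range")
            return ids[int(t)]
        if str(t) not in ids:
            raise ValidationError(f"unknown taxon id {t!r}")
        return str(t)

    def _norm_pair(self, pair) -> tuple[str, str, float]:
        i, j, rho = pair
        a, b = self._norm_taxon(i), self._norm_taxon(j)
        if a == b:
            raise ValidationError("planted pair must join two distinct taxa")
        if a > b:
            a, b = b, a
        return (a, b, float(rho))

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups) * len(self.timepoints)


def _taxonomy(ids: Sequence[str]) -> dict[str, str]:
    tax = {}
    for i, t in enumerate(ids):
        if i == 0:
            tax[t] = _STAPH_LINEAGE
        else:
            tax[t] = f"Bacteria;PhylumSim;ClassSim;OrderSim;FamilySim;Genus{i:04d}"
    return tax


def _draw_depths(rng: np.random.Generator, n: int, depth_mean: float) -> np.ndarray:
    sigma = float(np.sqrt(np.log1p(_DEPTH_CV**2)))
    mu = np.log(depth_mean) - sigma**2 / 2.0
    return np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n))).astype(np.int64)


def simulate_table(design: PlantedDesign) -> tuple[OtuTable, SampleMetadata, list[tuple[str, str, str]]]:
    """Simulate a count table, its metadata, and the planted-truth edge list.

    Returns ``(table, metadata, truth)`` where ``truth`` lists
    ``(taxon_a, taxon_b, sign)`` with sign in {"copresence", "exclusion"}
    for every planted pair.  Identical seeds give identical output.
    """
    rng = np.random.default_rng(design.seed)
    taxa = design.taxon_ids()
    tindex = {t: i for i, t in enumerate(taxa)}
    n_taxa, n_samples = design.n_taxa, design.n_samples

    # sample bookkeeping
    sample_ids: list[str] = []
    records: dict[str, SampleRecord] = {}
    p = 0
    for treatment, n_pat in design.groups:
        for _ in range(n_pat):
            p += 1
            pid = f"P{p:02d}"
            for day in design.timepoints:
                sid = f"{pid}D{day:02d}"
                sample_ids.append(sid)
                records[sid] = SampleRecord(pid, treatment, day)

    base = rng.normal(0.0, _BASE_SD, size=n_taxa)
    # members of a planted pair share one base abundance: ecological
    # co-presence/exclusion couples taxa living at a comparable scale, and
    # profile-based measures (Bray-Curtis, KL) are blind to couplings
    # between taxa whose expected abundances differ by orders of magnitude
    for a, b, _rho in design.copresence_pairs + design.exclusion_pairs:
        shared = rng.normal(0.0, _BASE_SD)
        base[tindex[a]] = shared
        base[tindex[b]] = shared
    noise = rng.normal(0.0, 1.0, size=(n_taxa, n_samples))
    # variance-preserving couplings: eps' = sqrt(1 - rho^2) * eps +/- rho * g
    for a, b, rho in design.copresence_pairs:
        g = rng.normal(0.0, 1.0, size=n_samples)
        shrink = np.sqrt(1.0 - rho**2)
        noise[tindex[a]] = shrink * noise[tindex[a]] + rho * g
        noise[tindex[b]] = shrink * noise[tindex[b]] + rho * g
    for a, b, rho in design.exclusion_pairs:
        g = rng.normal(0.0, 1.0, size=n_samples)
        shrink = np.sqrt(1.0 - rho**2)
        noise[tindex[a]] = shrink * noise[tindex[a]] + rho * g
        noise[tindex[b]] = shrink * noise[tindex[b]] - rho * g
    block_factors = []
    for members, rho in design.module_blocks:
        g = rng.normal(0.0, 1.0, size=n_samples)
        block_factors.append(g)
        shrink = np.sqrt(1.0 - rho**2)
        for t in members:
            noise[tindex[t]] = shrink * noise[tindex[t]] + rho * g
    if design.hub_spec is not None:
        hub, block_ids = design.hub_spec
        # the hub spreads one rho-budget evenly over all its blocks, so it
        # correlates with each without belonging fully to any one
        w = 0.9 / np.sqrt(len(block_ids))
        shrink = np.sqrt(max(0.0, 1.0 - len(block_ids) * w**2))
        h = shrink * noise[tindex[hub]]
        for b in block_ids:
            h = h + w * block_factors[b]
        noise[tindex[hub]] = h

    latent = base[:, None] + _NOISE_SD * noise

    weights = np.exp(latent)
    # dominant taxon: target relative abundance drawn per sample
    frac = rng.uniform(*design.dominant_taxon_fraction_range, size=n_samples)
    if n_taxa > 1:
        other_mass = weights[1:, :].sum(axis=0)
        weights[0, :] = frac / (1.0 - frac) * other_mass
    probs = weights / weights.sum(axis=0, keepdims=True)

    depths = _draw_depths(rng, n_samples, design.depth_mean)
    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depths[s], probs[:, s])

    truth = [(a, b, "copresence") for a, b, _ in design.copresence_pairs]
    truth += [(a, b, "exclusion") for a, b, _ in design.exclusion_pairs]
    table = OtuTable(taxa, sample_ids, counts, _taxonomy(taxa))
    return table, SampleMetadata(records), truth


def simulate_null_table(n_taxa: int, n_samples: int, depth_mean: float, seed: int) -> OtuTable:
    """Table of mutually independent taxa (no planted structure, no dominant taxon).

    Serves as the negative control for false-positive-rate estimation.
    """
    if n_taxa < 1 or n_samples < 1:
        raise ValidationError("n_taxa and n_samples must be positive")
    if depth_mean <= 0:
        raise ValidationError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, _BASE_SD, size=n_taxa)
    latent = base[:, None] + rng.normal(0.0, _NOISE_SD, size=(n_taxa, n_samples))
    weights = np.exp(latent)
    probs = weights / weights.sum(axis=0, keepdims=True)
    depths = _draw_depths(rng, n_samples, depth_mean)
    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depths[s], probs[:, s])
    width = max(4, len(str(n_taxa)))
    taxa = [f"Otu{i + 1:0{width}d}" for i in range(n_taxa)]
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    return OtuTable(taxa, samples, counts)
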