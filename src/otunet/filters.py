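"""OTU-table filters and alpha-diversity indices.

Rare-OTU removal drops taxa whose total count over the whole table is at
most two ("singletons and doubletons" in the whole-table sense).  The
prevalence filter mirrors per-treatment network preprocessing: a taxon
must be detected in a minimum number of distinct patients of the treatment
arm and in a minimum fraction of that arm's samples.  Both thresholds are
inclusive.

Diversity indices follow the vegan conventions: Shannon with natural log,
Simpson as the complement 1 - sum(p^2), and Chao1 from singleton/doubleton
frequency counts (bias-corrected form as default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import OtuTable, SampleMetadata, ValidationError


@dataclass
class FilterParams:
    remove_singletons_doubletons: bool = True
    min_patients_present: int = 3
    min_occurrence_fraction: float = 0.6
    min_occurrence_count: int | None = None  # absolute override for the fraction rule

    def __post_init__(self) -> None:
        if self.min_patients_present < 0:
            raise ValidationError("min_patients_present must be >= 0")
        if not (0.0 <= self.min_occurrence_fraction <= 1.0):
            raise ValidationError("min_occurrence_fraction must lie in [0, 1]")
        if self.min_occurrence_count is not None and self.min_occurrence_count < 0:
            raise ValidationError("min_occurrence_count must be >= 0")


def remove_rare_otus(table: OtuTable, max_total: int = 2) -> OtuTable:
    """Drop taxa with total abundance <= ``max_total`` across all samples."""
    totals = table.counts.sum(axis=1)
    return table.select_taxa(totals > max_total)


def prevalence_filter(
    table: OtuTable,
    meta: SampleMetadata,
    params: FilterParams,
    treatment: str,
) -> OtuTable:
    """Restrict to one treatment arm and keep sufficiently prevalent taxa.

    A taxon is kept iff it is detected (count > 0) in at least
    ``min_patients_present`` distinct patients of the arm AND in at least
    ``min_occurrence_fraction`` of the arm's samples (or at least
    ``min_occurrence_count`` samples when the absolute override is set).
    """
    samples = meta.samples_for_treatment(treatment)
    samples = [s for s in samples if s in set(table.sample_ids)]
    if not samples:
        raise ValidationError(f"no samples for treatment {treatment!r}")
    sub = table.select_samples(samples)
    present = sub.counts > 0

    patients = np.array([meta.patient_of(s) for s in samples])
    unique_patients = pd.unique(patients)
    per_patient = np.column_stack(
        [present[:, patients == p].any(axis=1) for p in unique_patients]
    )
    n_patients = per_patient.sum(axis=1)

    occurrence = present.sum(axis=1)
    if params.min_occurrence_count is not None:
        occ_threshold = params.min_occurrence_count
    else:
        # inclusive >= fraction * n, with a tolerance so 0.6 * 5 == 3 keeps 3
        occ_threshold = params.min_occurrence_fraction * len(samples) - 1e-9
    keep = (n_patients >= params.min_patients_present) & (occurrence >= occ_threshold)
    return sub.select_taxa(keep)


# ---------------------------------------------------------------------------
# Alpha diversity

def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D counts vector")
    if np.any(x < 0):
        raise ValidationError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValidationError("all-zero counts column")
    return x[x > 0] / total


def shannon(counts) -> float:
    """Shannon entropy -sum(p ln p) over positive proportions (natural log)."""
    p = _proportions(counts)
    return float(-np.sum(p * np.log(p)))


def simpson(counts) -> float:
    """Simpson diversity as the complement 1 - sum(p^2); lies in [0, 1)."""
    p = _proportions(counts)
    return float(1.0 - np.sum(p**2))


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from observed richness and singleton/doubleton counts.

    Classic: S_obs + F1^2 / (2 F2); bias-corrected:
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)).  The classic form is infinite when
    F2 = 0 and F1 > 0; callers wanting a finite estimate in that regime
    should use the bias-corrected default.
    """
    x = np.asarray(counts, dtype=float)
    _proportions(x)  # validation only
    s_obs = int(np.count_nonzero(x))
    f1 = int(np.count_nonzero(x == 1))
    f2 = int(np.count_nonzero(x == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float(s_obs) if f1 == 0 else math.inf
    return s_obs + f1**2 / (2.0 * f2)


def diversity_table(table: OtuTable, bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample alpha-diversity summary (columns sample_id, shannon, simpson, chao1)."""
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        rows.append(
            {
                "sample_id": sid,
                "shannon": shannon(col),
                "simpson": simpson(col),
                "chao1": chao1(col, bias_corrected=bias_corrected),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "shannon", "simpson", "chao1"])
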