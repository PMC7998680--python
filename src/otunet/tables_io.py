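"""Data model and readers/writers for OTU tables, metadata and networks.

Two on-disk dialects are supported for count tables: a plain taxa-by-samples
TSV (first column ``taxon_id``, optional trailing ``taxonomy`` column) and a
mothur ``.shared``-style layout (samples as rows behind ``label``, ``Group``
and ``numOtus`` columns).  Networks round-trip through an edge-list TSV and
GraphML; both carry the full per-edge statistics so that
``read_network(write_network(x)) == x`` holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

TREATMENTS = ("synbiotic", "prebiotic", "placebo")
TIMEPOINTS = (0, 9, 11, 14)


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violates a model invariant."""


@dataclass
class OtuTable:
    """Integer count matrix, taxa as rows and samples as columns.

    Counts are stored as absolute sequence counts; relative abundances are
    derived views (see :func:`relative_abundance`), never stored.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.taxon_ids)} taxa, {len(self.sample_ids)} samples)"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_taxa(self, keep: Iterable[str] | np.ndarray) -> "OtuTable":
        """Restrict to the given taxa (boolean mask or id iterable), preserving order."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = [i for i, t in enumerate(self.taxon_ids) if t in wanted]
        taxa = [self.taxon_ids[i] for i in idx]
        tax = {t: self.taxonomy[t] for t in taxa if t in self.taxonomy} if self.taxonomy else None
        return OtuTable(taxa, list(self.sample_ids), self.counts[np.asarray(idx, dtype=int), :], tax)

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in wanted]
        return OtuTable(list(self.taxon_ids), wanted, self.counts[:, idx], self.taxonomy)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and (self.taxonomy or None) == (other.taxonomy or None)
        )


@dataclass(frozen=True)
class SampleRecord:
    patient_id: str
    treatment: str
    timepoint_days: int


@dataclass
class SampleMetadata:
    """Maps each sample to its patient, bath-treatment arm and sampling day."""

    records: dict[str, SampleRecord]

    def __post_init__(self) -> None:
        patient_treatment: dict[str, str] = {}
        for sid, rec in self.records.items():
            if rec.treatment not in TREATMENTS:
                raise ValidationError(f"unknown treatment {rec.treatment!r} for sample {sid!r}")
            prev = patient_treatment.setdefault(rec.patient_id, rec.treatment)
            if prev != rec.treatment:
                raise ValidationError(
                    f"patient {rec.patient_id!r} assigned to both {prev!r} and {rec.treatment!r}"
                )

    def samples_for_treatment(self, treatment: str) -> list[str]:
        treatment = treatment.strip().lower()
        if treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {treatment!r}")
        return [s for s, r in self.records.items() if r.treatment == treatment]

    def patients_for_treatment(self, treatment: str) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples_for_treatment(treatment):
            seen.setdefault(self.records[s].patient_id)
        return list(seen)

    def patient_of(self, sample_id: str) -> str:
        return self.records[sample_id].patient_id


@dataclass
class NetworkRecord:
    """A signed co-occurrence network plus the parameters that produced it."""

    nodes: set[str]
    edges: list  # list[EnsembleEdge]
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        seen: set[tuple[tuple[str, str], str]] = set()
        for e in self.edges:
            a, b = e.pair
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge endpoint not in node set: {e.pair}")
            # duplicates are keyed on (pair, sign): a difference-merged network
            # may legitimately carry both signs of one pair (a sign flip)
            key = ((a, b) if a < b else (b, a), e.sign)
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkRecord):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and sorted(self.edges, key=lambda e: e.pair) == sorted(other.edges, key=lambda e: e.pair)
            and self.attributes == other.attributes
        )


# ---------------------------------------------------------------------------
# OTU table I/O

def read_otu_table(path: str | Path, dialect: str = "tsv") -> OtuTable:
    """Read a count table in ``tsv`` or ``mothur_shared`` dialect."""
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "mothur_shared":
        return _read_mothur_shared(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_counts_frame(df: pd.DataFrame) -> np.ndarray:
    arr = df.to_numpy()
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(numeric)):
        bad = arr[~np.isfinite(numeric)][0]
        raise ValidationError(f"non-numeric count {bad!r}")
    if np.any(numeric != np.floor(numeric)):
        raise ValidationError("non-integer count")
    if numeric.size and numeric.min() < 0:
        raise ValidationError("negative count")
    return numeric.astype(np.int64)


def _read_tsv(path: Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns[0] != "taxon_id":
        raise FormatError(f"expected first column 'taxon_id', got {df.columns[0]!r}")
    taxonomy = None
    if df.columns[-1] == "taxonomy":
        taxonomy = dict(zip(df["taxon_id"], df["taxonomy"]))
        df = df.drop(columns=["taxonomy"])
    taxa = df["taxon_id"].tolist()
    samples = list(df.columns[1:])
    counts = _check_counts_frame(df.iloc[:, 1:])
    return OtuTable(taxa, samples, counts, taxonomy)


def _read_mothur_shared(path: Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    expected = ["label", "Group", "numOtus"]
    if list(df.columns[:3]) != expected:
        raise FormatError(
            f"mothur shared file must start with columns {expected}, got {list(df.columns[:3])}"
        )
    samples = df["Group"].tolist()
    taxa = list(df.columns[3:])
    counts = _check_counts_frame(df.iloc[:, 3:]).T  # samples-as-rows -> taxa x samples
    return OtuTable(taxa, samples, counts)


def write_otu_table(table: OtuTable, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        df = table.to_dataframe().reset_index(names="taxon_id")
        if table.taxonomy:
            df["taxonomy"] = [table.taxonomy.get(t, "") for t in table.taxon_ids]
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "mothur_shared":
        body = pd.DataFrame(table.counts.T, columns=table.taxon_ids)
        body.insert(0, "label", "0.03")
        body.insert(1, "Group", table.sample_ids)
        body.insert(2, "numOtus", table.n_taxa)
        body.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Metadata I/O

_META_COLUMNS = ["sample_id", "patient_id", "treatment", "timepoint_days"]


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing columns {missing}")
    records: dict[str, SampleRecord] = {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        if sid in records:
            raise ValidationError(f"duplicate sample id {sid!r}")
        treatment = str(row.treatment).strip().lower()
        if treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {row.treatment!r}")
        try:
            day = int(row.timepoint_days)
        except ValueError as exc:
            raise ValidationError(f"non-integer timepoint {row.timepoint_days!r}") from exc
        records[sid] = SampleRecord(str(row.patient_id), treatment, day)
    return SampleMetadata(records)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    rows = [
        {"sample_id": s, "patient_id": r.patient_id, "treatment": r.treatment,
         "timepoint_days": r.timepoint_days}
        for s, r in meta.records.items()
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy aggregation

def _lineage_levels(lineage: str) -> list[str]:
    # strip SILVA-style confidence suffixes such as "Bacteria(100)"
    levels = []
    for part in lineage.split(";"):
        part = part.strip()
        if not part:
            continue
        if part.endswith(")") and "(" in part:
            part = part[: part.rindex("(")]
        levels.append(part)
    return levels


def aggregate_by_rank(table: OtuTable, rank: int) -> OtuTable:
    """Sum counts over taxa sharing the lineage prefix at depth ``rank``.

    ``rank`` is a 0-based depth index (e.g. 5 is genus in a standard
    domain-to-genus SILVA lineage).  Taxa whose lineage is shorter than the
    requested depth are grouped under their full available lineage.
    """
    if table.taxonomy is None:
        raise ValidationError("table has no taxonomy")
    groups: dict[str, list[int]] = {}
    for i, taxon in enumerate(table.taxon_ids):
        lineage = table.taxonomy.get(taxon)
        if lineage is None or not lineage.strip():
            raise ValidationError(f"missing taxonomy for taxon {taxon!r}")
        levels = _lineage_levels(lineage)
        prefix = ";".join(levels[: rank + 1])
        groups.setdefault(prefix, []).append(i)
    names = list(groups)
    counts = np.vstack([table.counts[groups[g], :].sum(axis=0) for g in names]) if names else np.zeros((0, table.n_samples), dtype=np.int64)
    return OtuTable(names, list(table.sample_ids), counts, {g: g for g in names})


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1; all-zero columns stay 0)."""
    totals = table.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, table.counts / np.where(totals > 0, totals, 1.0), 0.0)
    return pd.DataFrame(rel, index=table.taxon_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Network I/O

_EDGE_COLUMNS = [
    "taxon_a", "taxon_b", "sign", "n_support", "supporting_methods",
    "p_brown", "q_bh", "p_methods", "boot_stats", "sources",
]


def _edge_row(e) -> dict:
    a, b = e.pair
    return {
        "taxon_a": a,
        "taxon_b": b,
        "sign": e.sign,
        "n_support": len(e.supporting_methods),
        "supporting_methods": ",".join(sorted(e.supporting_methods)),
        "p_brown": repr(float(e.p_brown)),
        "q_bh": repr(float(e.q_bh)) if e.q_bh is not None else "",
        "p_methods": json.dumps({m: e.p_method[m] for m in sorted(e.p_method)}),
        "boot_stats": json.dumps(
            {m: [e.boot_mean[m], e.boot_sd[m]] for m in sorted(e.boot_mean)}
        ),
        "sources": ",".join(sorted(e.sources)) if e.sources else "",
    }


def _edge_from_row(row: Mapping) -> "object":
    from .ensemble import EnsembleEdge  # local import: avoids a module cycle

    p_methods = json.loads(row["p_methods"]) if row["p_methods"] else {}
    boot = json.loads(row["boot_stats"]) if row["boot_stats"] else {}
    support = frozenset(row["supporting_methods"].split(",")) if row["supporting_methods"] else frozenset()
    sources = frozenset(row["sources"].split(",")) if row.get("sources") else None
    return EnsembleEdge(
        pair=(row["taxon_a"], row["taxon_b"]),
        sign=row["sign"],
        supporting_methods=support,
        p_method={m: float(v) for m, v in p_methods.items()},
        p_brown=float(row["p_brown"]),
        q_bh=float(row["q_bh"]) if row["q_bh"] not in ("", None) else None,
        boot_mean={m: v[0] for m, v in boot.items()},
        boot_sd={m: v[1] for m, v in boot.items()},
        sources=sources,
    )


def write_network(net: NetworkRecord, path: str | Path, format: str = "edge_tsv") -> None:
    path = Path(path)
    if format == "edge_tsv":
        lines = [
            "#attributes\t" + json.dumps(net.attributes, sort_keys=True),
            "#nodes\t" + ",".join(sorted(net.nodes)),
            "\t".join(_EDGE_COLUMNS),
        ]
        for e in sorted(net.edges, key=lambda e: e.pair):
            row = _edge_row(e)
            lines.append("\t".join(str(row[c]) for c in _EDGE_COLUMNS))
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        g = nx.MultiGraph()  # a difference network may carry both signs of a pair
        g.graph["attributes"] = json.dumps(net.attributes, sort_keys=True)
        for n in sorted(net.nodes):
            g.add_node(n)
        for e in sorted(net.edges, key=lambda e: e.pair):
            row = _edge_row(e)
            a, b = e.pair
            g.add_edge(a, b, **{k: str(row[k]) for k in _EDGE_COLUMNS[2:]})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_tsv") -> NetworkRecord:
    path = Path(path)
    if format == "edge_tsv":
        attributes: dict = {}
        nodes: set[str] = set()
        header: list[str] | None = None
        edges = []
        for line in path.read_text().splitlines():
            if line.startswith("#attributes\t"):
                attributes = json.loads(line.split("\t", 1)[1])
            elif line.startswith("#nodes\t"):
                listed = line.split("\t", 1)[1]
                nodes = set(listed.split(",")) if listed else set()
            elif line.startswith("#") or not line.strip():
                continue
            elif header is None:
                header = line.split("\t")
                if header[:2] != ["taxon_a", "taxon_b"]:
                    raise FormatError("edge TSV header must start with taxon_a, taxon_b")
            else:
                cells = line.split("\t")
                row = dict(zip(header, cells + [""] * (len(header) - len(cells))))
                edges.append(_edge_from_row(row))
        if header is None:
            raise FormatError("missing edge TSV header")
        nodes |= {t for e in edges for t in e.pair}
        return NetworkRecord(nodes, edges, attributes)
    if format == "graphml":
        g = nx.read_graphml(path)
        attributes = json.loads(g.graph.get("attributes", "{}"))
        edges = []
        for a, b, data in g.edges(data=True):
            row = {"taxon_a": a, "taxon_b": b}
            row.update({k: data.get(k, "") for k in _EDGE_COLUMNS[2:]})
            edges.append(_edge_from_row(row))
        return NetworkRecord(set(g.nodes), edges, attributes)
    raise ValueError(f"unknown network format {format!r}")
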