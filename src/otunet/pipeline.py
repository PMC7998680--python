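"""Run configuration and the end-to-end per-treatment pipeline.

A run executes the stages filter -> infer -> modules -> roles -> summary
for one treatment arm and writes five text artifacts (edge list,
partition, role table, summary, log).  Every output starts with a comment
line naming the configuration hash and seed, and a re-run with the same
configuration and seed reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ensemble import EnsembleParams, infer_network
from .filters import FilterParams
from .tables_io import (
    ValidationError,
    read_metadata,
    read_otu_table,
    write_network,
)
from .topology import (
    RoleThresholds,
    classify_roles,
    detect_modules,
    network_summary,
    z_pi,
)


@dataclass
class RunConfig:
    table: str
    metadata: str
    output_dir: str
    treatment: str
    seed: int
    filter_params: FilterParams = field(default_factory=FilterParams)
    ensemble_params: EnsembleParams | None = None
    role_thresholds: RoleThresholds = field(default_factory=RoleThresholds)
    table_dialect: str = "tsv"
    normalize: bool = False
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.ensemble_params is None:
            self.ensemble_params = EnsembleParams(seed=self.seed)

    def to_flat_dict(self) -> dict:
        d = {
            "table": self.table,
            "metadata": self.metadata,
            "output_dir": self.output_dir,
            "treatment": self.treatment,
            "seed": self.seed,
            "table_dialect": self.table_dialect,
            "normalize": self.normalize,
            "pseudocount": self.pseudocount,
        }
        d.update(asdict(self.filter_params))
        d.update({k: v for k, v in asdict(self.ensemble_params).items() if k != "seed"})
        d.update(asdict(self.role_thresholds))
        return d


_FILTER_KEYS = {"remove_singletons_doubletons", "min_patients_present",
                "min_occurrence_fraction", "min_occurrence_count"}
_ENSEMBLE_KEYS = {"top_k", "min_support", "n_bootstrap", "n_permutation",
                  "alpha", "two_sided"}
_ROLE_KEYS = {"z_cut", "pi_cut"}
_TOP_KEYS = {"table", "metadata", "output_dir", "treatment", "seed",
             "table_dialect", "normalize", "pseudocount"}


def default_config_dict() -> dict:
    return RunConfig(
        table="table.tsv", metadata="metadata.tsv", output_dir="out",
        treatment="synbiotic", seed=0,
    ).to_flat_dict()


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a flat key-value YAML config; ``seed`` overrides the file's value."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a flat key-value mapping")
    unknown = set(raw) - _TOP_KEYS - _FILTER_KEYS - _ENSEMBLE_KEYS - _ROLE_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if seed is None:
        seed = raw.get("seed")
    if seed is None:
        raise ValidationError("a seed is required (config key 'seed' or --seed)")
    fp = FilterParams(**{k: raw[k] for k in _FILTER_KEYS if k in raw})
    ep = EnsembleParams(seed=int(seed), **{k: raw[k] for k in _ENSEMBLE_KEYS if k in raw})
    rt = RoleThresholds(**{k: raw[k] for k in _ROLE_KEYS if k in raw})
    return RunConfig(
        table=str(raw.get("table", "table.tsv")),
        metadata=str(raw.get("metadata", "metadata.tsv")),
        output_dir=str(raw.get("output_dir", "out")),
        treatment=str(raw.get("treatment", "synbiotic")),
        seed=int(seed),
        filter_params=fp,
        ensemble_params=ep,
        role_thresholds=rt,
        table_dialect=str(raw.get("table_dialect", "tsv")),
        normalize=bool(raw.get("normalize", False)),
        pseudocount=float(raw.get("pseudocount", 1.0)),
    )


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_flat_dict(), sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _stamp(config: RunConfig) -> str:
    return f"# config_hash={config_hash(config)} seed={config.seed}\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full per-treatment workflow; returns the summary record.

    Writes network.tsv, partition.tsv, roles.tsv, summary.tsv and run.log
    into ``config.output_dir``.  Partial outputs are removed if any stage
    fails.  With ``treatment: all`` the three arms are run into
    subdirectories and their difference-merged network is written as
    ``difference.tsv`` at the top level.
    """
    if config.treatment.strip().lower() == "all":
        return _run_all(config)
    table_path = Path(config.table)
    meta_path = Path(config.metadata)
    if not table_path.exists():
        raise FileNotFoundError(f"table not found: {table_path}")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata not found: {meta_path}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config)
    written: list[Path] = []

    def emit(name: str, body: str) -> Path:
        p = out_dir / name
        p.write_text(stamp + body)
        written.append(p)
        return p

    try:
        table = read_otu_table(table_path, dialect=config.table_dialect)
        meta = read_metadata(meta_path)
        net = infer_network(
            table, meta, config.treatment,
            config.filter_params, config.ensemble_params,
            normalize=config.normalize, pseudocount=config.pseudocount,
        )
        partition = detect_modules(net)
        topologies = classify_roles(z_pi(net, partition), config.role_thresholds)
        summary = network_summary(net, partition, topologies, table.taxonomy)

        net_path = out_dir / "network.tsv"
        write_network(net, net_path, format="edge_tsv")
        net_path.write_text(stamp + net_path.read_text())
        written.append(net_path)

        emit("partition.tsv", "node\tmodule\n" + "".join(
            f"{n}\t{m}\n" for n, m in sorted(partition.assignment.items())
        ))
        emit("roles.tsv", summary["role_table"].to_csv(sep="\t", index=False))

        counts = net.attributes.get("stage_counts", {})
        summary_lines = [
            f"n_nodes\t{summary['n_nodes']}",
            f"n_edges\t{summary['n_edges']}",
            f"n_modules\t{summary['n_modules']}",
        ]
        summary_lines += [f"role_{r}\t{c}" for r, c in summary["role_counts"].items()]
        emit("summary.tsv", "\n".join(summary_lines) + "\n")

        log_lines = ["parameters:"]
        log_lines += [f"  {k}: {v}" for k, v in sorted(config.to_flat_dict().items())]
        log_lines.append("stage_counts:")
        log_lines += [f"  {k}: {json.dumps(v, sort_keys=True)}" for k, v in counts.items()]
        log_lines.append(f"modularity: {partition.modularity!r}")
        emit("run.log", "\n".join(log_lines) + "\n")
        return summary
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_all(config: RunConfig) -> dict:
    """Run every treatment arm, then difference-merge the three networks."""
    from dataclasses import replace

    from .tables_io import TREATMENTS, read_network
    from .topology import diff_merge

    out_dir = Path(config.output_dir)
    summaries: dict[str, dict] = {}
    nets = []
    for arm in TREATMENTS:
        sub = replace(
            config, treatment=arm, output_dir=str(out_dir / arm),
            ensemble_params=replace(config.ensemble_params),
        )
        summaries[arm] = run_pipeline(sub)
        nets.append(read_network(out_dir / arm / "network.tsv"))
    merged = diff_merge(nets)
    diff_path = out_dir / "difference.tsv"
    write_network(merged, diff_path, format="edge_tsv")
    diff_path.write_text(_stamp(config) + diff_path.read_text())
    summaries["difference_edges"] = merged.n_edges
    return summaries
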