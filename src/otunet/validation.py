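"""Ground-truth validation experiments for the inference pipeline.

These experiments measure the properties the pipeline is designed to have
— planted-edge recovery, false-positive control on null tables, and
module/role recovery — at desk scale.  Candidate-list sizes are scaled to
the edge density of a full-size run (top and bottom 3000 of the ~440k
pairs of a ~940-taxon table, i.e. about 0.68% of pairs per direction).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .ensemble import EnsembleParams, infer_network
from .filters import FilterParams
from .synthetic import PlantedDesign, simulate_null_table, simulate_table
from .tables_io import NetworkRecord, SampleMetadata, SampleRecord
from .topology import classify_roles, detect_modules, z_pi

# reference edge density: 3000 of C(937, 2) pairs per direction
_REFERENCE_DENSITY = 3000.0 / (937 * 936 / 2)


def scaled_top_k(n_taxa: int) -> int:
    """Candidate-list size matching the reference edge density for n_taxa."""
    n_pairs = n_taxa * (n_taxa - 1) // 2
    return max(1, round(_REFERENCE_DENSITY * n_pairs))


def planted_recovery_experiment(
    seed: int,
    *,
    n_taxa: int = 60,
    n_patients: int = 38,
    depth_mean: float = 10000.0,
    rho: float = 1.0,
) -> dict:
    """Recover 5 planted co-presence + 5 exclusion pairs from one arm.

    38 patients at 4 timepoints give 152 samples.  Returns precision and
    recall of the inferred edge set against the planted truth, and whether
    every recovered planted edge carries the planted sign.
    """
    taxa = list(range(5, n_taxa))
    cop = [(taxa[2 * k], taxa[2 * k + 1], rho) for k in range(5)]
    exc = [(taxa[10 + 2 * k], taxa[11 + 2 * k], rho) for k in range(5)]
    design = PlantedDesign(
        n_taxa=n_taxa,
        groups=[("placebo", n_patients)],
        timepoints=[0, 9, 11, 14],
        depth_mean=depth_mean,
        copresence_pairs=cop,
        exclusion_pairs=exc,
        seed=seed,
    )
    table, meta, truth = simulate_table(design)
    params = EnsembleParams(top_k=scaled_top_k(n_taxa), seed=seed)
    net = infer_network(table, meta, "placebo", FilterParams(), params)
    truth_map = {(a, b): s for a, b, s in truth}
    recovered = {e.pair: e.sign for e in net.edges}
    tp = sum(1 for p, s in recovered.items() if truth_map.get(p) == s)
    signs_correct = all(
        truth_map[p] == s for p, s in recovered.items() if p in truth_map
    )
    return {
        "n_samples": table.n_samples,
        "n_edges": len(recovered),
        "n_true": len(truth_map),
        "true_positives": tp,
        "precision": tp / len(recovered) if recovered else 0.0,
        "recall": tp / len(truth_map),
        "signs_correct": signs_correct,
    }


def null_fp_experiment(
    seeds: list[int],
    *,
    n_taxa: int = 50,
    n_samples: int = 100,
    depth_mean: float = 10000.0,
) -> dict:
    """Fraction of voted pairs surviving BH on structure-free tables."""
    tested = kept = 0
    per_seed = []
    for seed in seeds:
        table = simulate_null_table(n_taxa, n_samples, depth_mean, seed)
        records = {
            s: SampleRecord(f"P{i:03d}", "placebo", 0)
            for i, s in enumerate(table.sample_ids)
        }
        meta = SampleMetadata(records)
        params = EnsembleParams(top_k=scaled_top_k(n_taxa), seed=seed)
        net = infer_network(table, meta, "placebo", FilterParams(), params)
        v = net.attributes["stage_counts"]["edges_tested"]
        tested += v
        kept += net.n_edges
        per_seed.append((v, net.n_edges))
    return {
        "tested": tested,
        "kept": kept,
        "fraction": kept / tested if tested else 0.0,
        "per_seed": per_seed,
    }


def planted_block_graph(
    seed: int,
    *,
    n_blocks: int = 3,
    block_size: int = 15,
    p_within: float = 0.8,
    p_between: float = 0.02,
    with_hub: bool = False,
) -> tuple[nx.Graph, dict[str, int]]:
    """Random modular graph with known block membership (optional cross-block hub)."""
    rng = np.random.default_rng(seed)
    nodes = [f"T{i:02d}" for i in range(n_blocks * block_size)]
    membership = {n: i // block_size for i, n in enumerate(nodes)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            p = p_within if membership[a] == membership[b] else p_between
            if rng.random() < p:
                g.add_edge(a, b)
    if with_hub:
        g.add_node("HUB")
        for blk in range(n_blocks):
            members = [n for n in nodes if membership[n] == blk]
            for n in members[: max(3, block_size // 3)]:
                g.add_edge("HUB", n)
    return g, membership


def module_recovery_experiment(seed: int) -> dict:
    """ARI of greedy-modularity modules against planted blocks, plus hub role."""
    g, membership = planted_block_graph(seed)
    partition = detect_modules(g)
    nodes = sorted(membership)
    truth = [membership[n] for n in nodes]
    pred = [partition.assignment[n] for n in nodes]
    ari = float(adjusted_rand_score(truth, pred))

    g2, _ = planted_block_graph(seed, with_hub=True)
    part2 = detect_modules(g2)
    tops = classify_roles(z_pi(g2, part2))
    hub_role = next(t.role for t in tops if t.node == "HUB")
    return {"ari": ari, "n_modules": partition.n_modules, "hub_role": hub_role}
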