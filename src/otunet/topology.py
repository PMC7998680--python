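"""Module detection, Guimera-Amaral connectivity roles, network differencing.

Communities are found by greedy modularity maximisation (the
Clauset-Newman-Moore family that fast-greedy/GLay-style tools wrap) on the
unweighted, sign-blind graph.  For each node the within-module degree
z-score and the participation coefficient Pi are computed; nodes are
classified into the four Olesen-style roles by the conventional thresholds
z = 2.5 and Pi = 0.62 (boundary values fall in the "<=" class):

    peripheral:  z <= 2.5, Pi <= 0.62
    connector:   z <= 2.5, Pi >  0.62
    module hub:  z >  2.5, Pi <= 0.62
    network hub: z >  2.5, Pi >  0.62
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ensemble import EnsembleEdge
from .tables_io import NetworkRecord, ValidationError


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    n_modules: int
    modularity: float

    def members(self, module_id: int) -> set[str]:
        return {n for n, m in self.assignment.items() if m == module_id}


@dataclass
class NodeTopology:
    node: str
    degree: int
    within_module_degree: int
    module: int
    z: float
    pi: float
    role: str | None = None


@dataclass
class RoleThresholds:
    z_cut: float = 2.5
    pi_cut: float = 0.62

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z_cut) and np.isfinite(self.pi_cut)):
            raise ValidationError("role thresholds must be finite")


def _as_graph(net: NetworkRecord | nx.Graph) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    for e in sorted(net.edges, key=lambda e: e.pair):
        g.add_edge(*e.pair, sign=e.sign)
    return g


def detect_modules(net: NetworkRecord | nx.Graph, seed: int | None = None) -> ModulePartition:
    """Greedy modularity communities on the sign-blind, unweighted graph.

    Nodes are inserted in sorted order so ties in the merge heap resolve
    deterministically; isolated nodes end up as singleton modules.  Module
    ids are contiguous from 0, ordered by decreasing size then by first
    member.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        return ModulePartition({}, 0, 0.0)
    if g.number_of_edges() == 0:
        communities = [{n} for n in sorted(g.nodes)]
    else:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    communities.sort(key=lambda c: (-len(c), min(c)))
    assignment = {n: i for i, c in enumerate(communities) for n in c}
    mod = nx.community.modularity(g, communities) if g.number_of_edges() else 0.0
    return ModulePartition(assignment, len(communities), float(mod))


def within_module_z(within_degrees) -> np.ndarray:
    """Standardise a module's within-degrees with the population sd.

    Returns 0 for every node when the module's within-degrees are all
    equal (population sd 0), so degenerate modules never produce
    infinities.
    """
    ks = np.asarray(within_degrees, dtype=float)
    sd = ks.std(ddof=0)
    if sd == 0:
        return np.zeros_like(ks)
    return (ks - ks.mean()) / sd


def z_pi(net: NetworkRecord | nx.Graph, partition: ModulePartition) -> list[NodeTopology]:
    """Within-module degree z and participation coefficient Pi per node.

    z standardises a node's within-module degree against its module's
    distribution using the population standard deviation; a module whose
    members all share one within-degree gives z = 0 by convention.
    Pi = 1 - sum_t (k_it / k_i)^2 over all modules t; an isolated node has
    Pi = 0.
    """
    g = _as_graph(net)
    missing = [n for n in g.nodes if n not in partition.assignment]
    if missing:
        raise ValidationError(f"nodes missing from partition: {sorted(missing)[:5]}")

    within: dict[str, int] = {}
    per_module_links: dict[str, dict[int, int]] = {}
    for node in g.nodes:
        own = partition.assignment[node]
        links: dict[int, int] = {}
        for nb in g.neighbors(node):
            m = partition.assignment[nb]
            links[m] = links.get(m, 0) + 1
        within[node] = links.get(own, 0)
        per_module_links[node] = links

    by_module: dict[int, list[str]] = {}
    for node in g.nodes:
        by_module.setdefault(partition.assignment[node], []).append(node)
    z_of: dict[str, float] = {}
    for members in by_module.values():
        zs = within_module_z([within[n] for n in members])
        z_of.update(zip(members, zs))

    out = []
    for node in sorted(g.nodes):
        mod_id = partition.assignment[node]
        k = g.degree(node)
        k_s = within[node]
        z = z_of[node]
        if k > 0:
            pi = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
        else:
            pi = 0.0
        out.append(NodeTopology(node, int(k), int(k_s), mod_id, float(z), float(pi)))
    return out


ROLES = ("peripheral", "connector", "module_hub", "network_hub")


def classify_roles(
    topologies: list[NodeTopology],
    thresholds: RoleThresholds | None = None,
) -> list[NodeTopology]:
    """Fill in the role quadrant for every node (boundaries are inclusive below)."""
    th = thresholds or RoleThresholds()
    for t in topologies:
        low_z = t.z <= th.z_cut
        low_pi = t.pi <= th.pi_cut
        if low_z and low_pi:
            t.role = "peripheral"
        elif low_z:
            t.role = "connector"
        elif low_pi:
            t.role = "module_hub"
        else:
            t.role = "network_hub"
    return topologies


def diff_merge(nets: list[NetworkRecord]) -> NetworkRecord:
    """Difference-merge: keep signed edges NOT shared by all input networks.

    An edge is identified by (unordered pair, sign).  Edges present in at
    least one but not every input survive, each tagged with the set of
    source networks (their ``treatment`` attribute, or a positional name)
    that contain it.  The merged node set contains only the endpoints of
    surviving edges, so the merge highlights treatment-specific rewiring.
    """
    if len(nets) < 2:
        raise ValidationError("difference merge needs at least two networks")
    names = []
    for i, net in enumerate(nets):
        names.append(str(net.attributes.get("treatment") or f"network_{i}"))
    if len(set(names)) != len(names):
        names = [f"{nm}_{i}" for i, nm in enumerate(names)]

    occurrences: dict[tuple[tuple[str, str], str], list[tuple[str, EnsembleEdge]]] = {}
    for name, net in zip(names, nets):
        for e in net.edges:
            occurrences.setdefault((e.pair, e.sign), []).append((name, e))

    merged: list[EnsembleEdge] = []
    for (pair, sign), occ in sorted(occurrences.items()):
        sources = frozenset(nm for nm, _ in occ)
        if len(sources) == len(nets):
            continue  # shared by every network: not a difference
        proto = occ[0][1]
        merged.append(
            EnsembleEdge(
                pair, sign, proto.supporting_methods, dict(proto.p_method),
                proto.p_brown, proto.q_bh, dict(proto.boot_mean),
                dict(proto.boot_sd), sources,
            )
        )
    nodes = {t for e in merged for t in e.pair}
    return NetworkRecord(nodes, merged, {"merge": "difference", "sources": names})


def network_summary(
    net: NetworkRecord,
    partition: ModulePartition,
    topologies: list[NodeTopology],
    taxonomy: dict[str, str] | None = None,
) -> dict:
    """Headline counts plus a per-node role table.

    The role table mirrors the usual reporting layout: treatment, OTU,
    module role, taxon (last lineage level when taxonomy is available).
    """
    treatment = str(net.attributes.get("treatment", ""))
    role_counts = {r: 0 for r in ROLES}
    rows = []
    for t in sorted(topologies, key=lambda t: t.node):
        role_counts[t.role] += 1
        lineage = (taxonomy or {}).get(t.node, "")
        taxon = lineage.split(";")[-1] if lineage else ""
        rows.append(
            {
                "treatment": treatment,
                "otu": t.node,
                "module": t.module,
                "degree": t.degree,
                "z": t.z,
                "pi": t.pi,
                "role": t.role,
                "taxon": taxon,
            }
        )
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_modules": partition.n_modules,
        "role_counts": role_counts,
        "role_table": pd.DataFrame(
            rows, columns=["treatment", "otu", "module", "degree", "z", "pi", "role", "taxon"]
        ),
    }
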