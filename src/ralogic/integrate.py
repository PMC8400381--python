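"""Global network construction: symbol normalisation, complex expansion,
entity deduplication, TF matching, merging, subnetwork extraction and
DEG/variant overlay projection."""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .netio import (
    NetworkNode,
    NodeKind,
    Origin,
    OverlayTable,
    Sign,
    SignedEdge,
    SignedNetwork,
)

__all__ = [
    "IntegrateError",
    "ComplexMembership",
    "NetworkOverlay",
    "MergeSummary",
    "normalize_symbol",
    "expand_complexes",
    "deduplicate_entities",
    "match_tfs",
    "merge_networks",
    "extract_upstream",
    "extract_downstream_to_first_tf",
    "select_degs",
    "filter_variants",
    "project_overlay",
]

# Markers a NetworkOverlay may carry.
MARKERS = ("DEG_RESPONSE", "DEG_TREATMENT", "VARIANT_CARRIER")

ComplexMembership = dict  # complex node id -> list of member symbols


class IntegrateError(ValueError):
    pass


@dataclass
class NetworkOverlay:
    """Per-marker node sets (optionally with payloads) plus a match report."""

    markers: dict[str, set[str]] = field(default_factory=dict)
    payloads: dict[str, dict[str, dict]] = field(default_factory=dict)
    report: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class MergeSummary:
    n_nodes: int
    n_edges: int
    sign_counts: dict[str, int]
    n_shared_nodes: int


_COMPARTMENT_RE = re.compile(r"@.*$", re.DOTALL)


def normalize_symbol(raw: str) -> str:
    """Canonical symbol: uppercase, trimmed, internal whitespace -> ``_``,
    ``@compartment`` suffix removed (everything from the first ``@``)."""
    text = raw.strip()
    text = _COMPARTMENT_RE.sub("", text).strip()
    text = re.sub(r"\s+", "_", text)
    if not text:
        raise IntegrateError(f"symbol {raw!r} is empty after normalisation")
    return text.upper()


def expand_complexes(net: SignedNetwork, membership: Mapping[str, list[str]]) -> SignedNetwork:
    """Recreate complex reactants: each member gets an ACTIVATION edge into
    its complex node; every pre-existing edge is preserved."""
    for cid in membership:
        node = net.nodes.get(cid)
        if node is None or node.kind is not NodeKind.COMPLEX:
            raise IntegrateError(f"membership key {cid!r} is not a COMPLEX node")
        if not membership[cid]:
            raise IntegrateError(f"complex {cid!r} has an empty member list")
    out = SignedNetwork(net.nodes.values(), net.edges)
    for cid in sorted(membership):
        for member in membership[cid]:
            out.add_node(NetworkNode(id=member, label=member, kind=NodeKind.PROTEIN))
            out.add_edge(SignedEdge(member, cid, Sign.ACTIVATION, provenance="complex"))
    return out


def deduplicate_entities(net: SignedNetwork, alias_groups: Iterable[set[str]]) -> SignedNetwork:
    """Collapse each alias group onto its lexicographically smallest member,
    re-targeting edges, dropping duplicates and collapse-induced self-edges."""
    groups = [set(g) for g in alias_groups]
    seen: set[str] = set()
    rename: dict[str, str] = {}
    for group in groups:
        if seen & group:
            raise IntegrateError("alias groups are not pairwise disjoint")
        unknown = group - net.node_ids()
        if unknown:
            raise IntegrateError(f"alias group contains unknown ids {sorted(unknown)}")
        seen |= group
        keep = min(group)
        for alias in group:
            rename[alias] = keep
    out = SignedNetwork()
    for nid in sorted(net.nodes):
        if rename.get(nid, nid) == nid:
            out.add_node(net.nodes[nid])
    for edge in net.edges:
        source = rename.get(edge.source, edge.source)
        target = rename.get(edge.target, edge.target)
        if source == target and edge.source != edge.target:
            continue  # self-edge arising purely from collapsing
        out.add_edge(SignedEdge(source, target, edge.sign, edge.provenance))
    return out


def match_tfs(coreg_tfs: set[str], map_nodes: set[str]) -> set[str]:
    """Exact intersection of normalised symbol sets."""
    return set(coreg_tfs) & set(map_nodes)


def merge_networks(
    coreg: SignedNetwork, signalling: SignedNetwork
) -> tuple[SignedNetwork, MergeSummary]:
    """Union of nodes (origin BOTH when shared) and edges (triple-dedup)."""
    merged = SignedNetwork()
    shared = coreg.node_ids() & signalling.node_ids()
    for nid in sorted(coreg.node_ids() | signalling.node_ids()):
        if nid in shared:
            base = coreg.nodes[nid]
            kind = base.kind if base.kind is not NodeKind.PROTEIN else signalling.nodes[nid].kind
            merged.add_node(NetworkNode(nid, base.label or nid, kind, Origin.BOTH))
        elif nid in coreg.nodes:
            node = coreg.nodes[nid]
            merged.add_node(NetworkNode(nid, node.label, node.kind, Origin.COREG))
        else:
            node = signalling.nodes[nid]
            merged.add_node(NetworkNode(nid, node.label, node.kind, Origin.MAP))
    for edge in list(coreg.edges) + list(signalling.edges):
        merged.add_edge(edge)
    summary = MergeSummary(
        n_nodes=len(merged.nodes),
        n_edges=len(merged.edges),
        sign_counts=merged.sign_counts(),
        n_shared_nodes=len(shared),
    )
    return merged, summary


def _check_seeds(net: SignedNetwork, seeds: Iterable[str]) -> list[str]:
    seeds = sorted(set(seeds))
    for seed in seeds:
        if seed not in net.nodes:
            raise IntegrateError(f"unknown seed node {seed!r}")
    return seeds


def extract_upstream(net: SignedNetwork, seeds: set[str]) -> SignedNetwork:
    """Induced subnetwork on nodes with a directed path to a seed (seeds
    included).  COREGULATION edges are not traversed."""
    seeds = _check_seeds(net, seeds)
    keep: set[str] = set(seeds)
    queue = deque(seeds)
    while queue:
        node = queue.popleft()
        for pred in net.predecessors(node):
            if pred not in keep:
                keep.add(pred)
                queue.append(pred)
    return net.induced_subnetwork(keep)


def extract_downstream_to_first_tf(
    net: SignedNetwork, seeds: set[str], tf_set: set[str]
) -> SignedNetwork:
    """Forward traversal from the seeds with TFs absorbing: a TF reached is
    kept but its successors are not expanded."""
    seeds = _check_seeds(net, seeds)
    keep: set[str] = set(seeds)
    queue = deque(s for s in seeds if s not in tf_set)
    while queue:
        node = queue.popleft()
        for succ in net.successors(node):
            if succ not in keep:
                keep.add(succ)
                if succ not in tf_set:
                    queue.append(succ)
    return net.induced_subnetwork(keep)


def select_degs(table: OverlayTable, fdr_threshold: float = 0.1) -> set[str]:
    """Genes with FDR strictly below the threshold."""
    if table.kind != "DEG":
        raise IntegrateError("select_degs requires a DEG table")
    rows = table.rows
    return set(rows.loc[rows["fdr"] < fdr_threshold, "gene"])


def filter_variants(
    table: OverlayTable, vda_min: float = 0.7, ei_min: float = 0.7
):
    """Keep rows with vda >= vda_min and ei >= ei_min; return (rows, genes)."""
    if table.kind != "VARIANT":
        raise IntegrateError("filter_variants requires a VARIANT table")
    rows = table.rows
    kept = rows[(rows["vda"] >= vda_min) & (rows["ei"] >= ei_min)].reset_index(drop=True)
    return kept, set(kept["gene"])


def project_overlay(
    net: SignedNetwork, marker_sets: Mapping[str, set[str]]
) -> NetworkOverlay:
    """Restrict marker sets to network nodes; report matched/unmatched counts."""
    overlay = NetworkOverlay()
    ids = net.node_ids()
    for marker, symbols in marker_sets.items():
        matched = set(symbols) & ids
        overlay.markers[marker] = matched
        overlay.report[marker] = {
            "matched": len(matched),
            "unmatched": len(set(symbols) - ids),
        }
    return overlay
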