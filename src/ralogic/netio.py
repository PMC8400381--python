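"""Canonical network/model representations and text-format I/O.

Formats: 3-column SIF (signed interactions), bnet-style rule files
("VAR, expression" per line), header-ed TSV overlay tables and a JSON graph
export.  All I/O is UTF-8 and serialization is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from . import expr as E

__all__ = [
    "NodeKind",
    "Origin",
    "Sign",
    "NetworkNode",
    "SignedEdge",
    "SignedNetwork",
    "LogicalModel",
    "OverlayTable",
    "NetioError",
    "SifParseError",
    "BnetParseError",
    "parse_sif",
    "serialize_sif",
    "parse_bnet",
    "serialize_bnet",
    "read_overlay_table",
    "write_overlay_table",
    "export_json_graph",
    "parse_json_graph",
]


class NodeKind(str, Enum):
    TF = "TF"
    TARGET_GENE = "TARGET_GENE"
    PROTEIN = "PROTEIN"
    GENE = "GENE"
    MRNA = "MRNA"
    COMPLEX = "COMPLEX"
    SIMPLE_MOLECULE = "SIMPLE_MOLECULE"
    PHENOTYPE = "PHENOTYPE"


class Origin(str, Enum):
    COREG = "COREG"
    MAP = "MAP"
    BOTH = "BOTH"


class Sign(str, Enum):
    ACTIVATION = "ACTIVATION"
    INHIBITION = "INHIBITION"
    COREGULATION = "COREGULATION"


@dataclass(frozen=True)
class NetworkNode:
    id: str
    label: str = ""
    kind: NodeKind = NodeKind.PROTEIN
    origin: Origin = Origin.MAP

    def __post_init__(self):
        if not self.id:
            raise ValueError("node id must be non-empty")


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: Sign
    provenance: str = ""

    def key(self) -> tuple[str, str, Sign]:
        return (self.source, self.target, self.sign)


class NetioError(ValueError):
    pass


class SifParseError(NetioError):
    pass


class BnetParseError(NetioError):
    pass


class SignedNetwork:
    """Directed signed network; edges unique up to (source, target, sign).

    COREGULATION edges are undirected evidence and are stored with
    ``source < target`` lexicographically.
    """

    def __init__(
        self,
        nodes: Iterable[NetworkNode] = (),
        edges: Iterable[SignedEdge] = (),
    ):
        self._nodes: dict[str, NetworkNode] = {}
        self._edges: dict[tuple[str, str, Sign], SignedEdge] = {}
        for node in nodes:
            self.add_node(node)
        for edge in edges:
            self.add_edge(edge)

    # -- construction -------------------------------------------------------
    def add_node(self, node: NetworkNode | str, **kwargs) -> NetworkNode:
        if isinstance(node, str):
            node = NetworkNode(id=node, label=kwargs.pop("label", node), **kwargs)
        existing = self._nodes.get(node.id)
        if existing is None:
            self._nodes[node.id] = node
            return node
        return existing

    def add_edge(self, edge: SignedEdge) -> None:
        if edge.sign is Sign.COREGULATION and edge.source > edge.target:
            edge = replace(edge, source=edge.target, target=edge.source)
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._nodes:
                kind = NodeKind.TF if edge.sign is Sign.COREGULATION else NodeKind.PROTEIN
                self._nodes[endpoint] = NetworkNode(id=endpoint, label=endpoint, kind=kind)
        self._edges.setdefault(edge.key(), edge)

    # -- access -------------------------------------------------------------
    @property
    def nodes(self) -> dict[str, NetworkNode]:
        return self._nodes

    @property
    def edges(self) -> list[SignedEdge]:
        return list(self._edges.values())

    def node_ids(self) -> set[str]:
        return set(self._nodes)

    def has_edge(self, source: str, target: str, sign: Sign) -> bool:
        if sign is Sign.COREGULATION and source > target:
            source, target = target, source
        return (source, target, sign) in self._edges

    def successors(self, node: str, *, signs=(Sign.ACTIVATION, Sign.INHIBITION)):
        return sorted(
            e.target for e in self._edges.values() if e.source == node and e.sign in signs
        )

    def predecessors(self, node: str, *, signs=(Sign.ACTIVATION, Sign.INHIBITION)):
        return sorted(
            e.source for e in self._edges.values() if e.target == node and e.sign in signs
        )

    def regulators(self, node: str) -> tuple[list[str], list[str]]:
        """(activators, inhibitors) of *node*, sorted."""
        return (
            self.predecessors(node, signs=(Sign.ACTIVATION,)),
            self.predecessors(node, signs=(Sign.INHIBITION,)),
        )

    def induced_subnetwork(self, keep: set[str]) -> "SignedNetwork":
        sub = SignedNetwork()
        for nid in sorted(keep):
            sub.add_node(self._nodes[nid])
        for edge in self._edges.values():
            if edge.source in keep and edge.target in keep:
                sub.add_edge(edge)
        return sub

    def without_sign(self, sign: Sign) -> "SignedNetwork":
        out = SignedNetwork(self._nodes.values())
        for edge in self._edges.values():
            if edge.sign is not sign:
                out.add_edge(edge)
        return out

    def sign_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in Sign}
        for edge in self._edges.values():
            counts[edge.sign.value] += 1
        return counts

    def validate(self) -> None:
        for edge in self._edges.values():
            for endpoint in (edge.source, edge.target):
                if endpoint not in self._nodes:
                    raise NetioError(f"edge endpoint {endpoint!r} is not a node")
            if edge.sign is Sign.COREGULATION:
                if edge.source > edge.target:
                    raise NetioError("COREGULATION edge not in canonical order")
                for endpoint in (edge.source, edge.target):
                    if self._nodes[endpoint].kind is not NodeKind.TF:
                        raise NetioError(
                            f"COREGULATION endpoint {endpoint!r} is not a TF"
                        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self._nodes == other._nodes and set(self._edges) == set(other._edges)

    def __repr__(self) -> str:
        return f"SignedNetwork({len(self._nodes)} nodes, {len(self._edges)} edges)"


@dataclass
class LogicalModel:
    """Boolean model: ordered variables, one rule each, optional clamps.

    A variable whose rule is literally itself is an input.  Clamped variables
    ignore their rule.
    """

    variables: list[str]
    rules: dict[str, E.BoolExpr]
    clamps: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        declared = set(self.variables)
        if len(self.variables) != len(declared):
            raise NetioError("duplicate variable declaration")
        for var, rule in self.rules.items():
            if var not in declared:
                raise NetioError(f"rule for undeclared variable {var!r}")
            for symbol in E.variables(rule):
                if symbol not in declared:
                    raise NetioError(
                        f"rule for {var!r} references undeclared symbol {symbol!r}"
                    )
        missing = declared - set(self.rules)
        if missing:
            raise NetioError(f"variables without rules: {sorted(missing)}")
        for var in self.clamps:
            if var not in declared:
                raise NetioError(f"clamp on undeclared variable {var!r}")

    def inputs(self) -> list[str]:
        return [v for v in self.variables if self.rules[v] == E.Var(v)]

    def copy(self) -> "LogicalModel":
        return LogicalModel(list(self.variables), dict(self.rules), dict(self.clamps))

    def is_fixed_point(self, state: Mapping[str, int]) -> bool:
        """Independent single-state check of the fixed-point condition."""
        for var in self.variables:
            if var in self.clamps:
                if state[var] != self.clamps[var]:
                    return False
            elif E.evaluate(self.rules[var], state) != state[var]:
                return False
        return True


# ----------------------------------------------------------------------------
# SIF
# ----------------------------------------------------------------------------

_SIF_TOKENS = {
    "ACTIVATION": Sign.ACTIVATION,
    "POSITIVE": Sign.ACTIVATION,
    "->": Sign.ACTIVATION,
    "INHIBITION": Sign.INHIBITION,
    "NEGATIVE": Sign.INHIBITION,
    "-|": Sign.INHIBITION,
    "COREGULATION": Sign.COREGULATION,
}


def parse_sif(text: str) -> SignedNetwork:
    """Parse a 3-column SIF document (source, interaction, target)."""
    net = SignedNetwork()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) < 3:
            raise SifParseError(f"line {lineno}: expected >=3 fields, got {len(fields)}")
        source, interaction, target = fields[0], fields[1], fields[2]
        sign = _SIF_TOKENS.get(interaction.upper())
        if sign is None:
            raise SifParseError(f"line {lineno}: unknown interaction {interaction!r}")
        net.add_edge(SignedEdge(source, target, sign))
    return net


def serialize_sif(net: SignedNetwork) -> str:
    """Deterministic tab-separated SIF; edges sorted by (source, target, sign)."""
    lines = [
        f"{e.source}\t{e.sign.value}\t{e.target}"
        for e in sorted(net.edges, key=lambda e: (e.source, e.target, e.sign.value))
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ----------------------------------------------------------------------------
# bnet
# ----------------------------------------------------------------------------


def parse_bnet(text: str) -> LogicalModel:
    """Parse "VAR, expression" lines into a LogicalModel."""
    variables: list[str] = []
    raw_rules: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.lower().startswith("targets,"):  # optional boolnet-style header
            continue
        if "," not in stripped:
            raise BnetParseError(f"line {lineno}: expected 'VAR, expression'")
        var, _, rhs = stripped.partition(",")
        var = var.strip()
        if not var:
            raise BnetParseError(f"line {lineno}: empty variable name")
        if var in raw_rules:
            raise BnetParseError(f"line {lineno}: duplicate rule for {var!r}")
        variables.append(var)
        raw_rules[var] = rhs.strip()

    rules: dict[str, E.BoolExpr] = {}
    declared = set(variables)
    for var in variables:
        try:
            rule = E.parse_expr(raw_rules[var])
        except E.ExprParseError as err:
            raise BnetParseError(f"rule for {var!r}: {err}") from err
        undeclared = E.variables(rule) - declared
        if undeclared:
            raise BnetParseError(
                f"rule for {var!r} references undeclared symbol(s) {sorted(undeclared)}"
            )
        rules[var] = rule
    return LogicalModel(variables, rules)


def serialize_bnet(model: LogicalModel) -> str:
    """One "VAR, expression" line per variable, in declaration order."""
    lines = [f"{var}, {E.to_text(model.rules[var])}" for var in model.variables]
    return "\n".join(lines) + ("\n" if lines else "")


# ----------------------------------------------------------------------------
# Overlay tables
# ----------------------------------------------------------------------------

_REQUIRED_COLUMNS = {
    "DEG": ["gene", "log2fc", "fdr"],
    "VARIANT": ["variant", "gene", "vda", "ei"],
}
_UNIT_COLUMNS = {"DEG": ["fdr"], "VARIANT": ["vda", "ei"]}


@dataclass
class OverlayTable:
    """Typed DEG or VARIANT rows plus the count of rows rejected on read."""

    kind: str  # "DEG" | "VARIANT"
    rows: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self):
        if self.kind not in _REQUIRED_COLUMNS:
            raise NetioError(f"unknown overlay kind {self.kind!r}")

    def genes(self) -> set[str]:
        return set(self.rows["gene"])


def read_overlay_table(text: str, kind: str) -> OverlayTable:
    """Read a header-ed TSV; rows with missing/out-of-range fields rejected."""
    from io import StringIO

    required = _REQUIRED_COLUMNS.get(kind)
    if required is None:
        raise NetioError(f"unknown overlay kind {kind!r}")
    df = pd.read_csv(StringIO(text), sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NetioError(f"missing required column(s) {missing} for kind {kind}")

    numeric = ["log2fc", "fdr"] if kind == "DEG" else ["vda", "ei"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = df[required].notna().all(axis=1)
    for key in ("gene", "variant"):
        if key in df.columns:
            ok &= df[key].astype(str).str.strip().ne("")
    for col in _UNIT_COLUMNS[kind]:
        ok &= df[col].between(0.0, 1.0)
    kept = df[ok].reset_index(drop=True)
    return OverlayTable(kind=kind, rows=kept, n_rejected=int((~ok).sum()))


def write_overlay_table(table: OverlayTable) -> str:
    cols = [c for c in _REQUIRED_COLUMNS[table.kind] if c in table.rows.columns]
    extra = [c for c in table.rows.columns if c not in cols]
    return table.rows[cols + extra].to_csv(sep="\t", index=False)


# ----------------------------------------------------------------------------
# JSON graph export
# ----------------------------------------------------------------------------


def export_json_graph(net: SignedNetwork, overlay: Mapping[str, set] | None = None) -> str:
    """Deterministic JSON (nodes with overlay markers, signed edges).

    *overlay* maps marker name -> set of node ids; a marker id missing from
    the network is an error.
    """
    overlay = overlay or {}
    for marker, ids in overlay.items():
        dangling = set(ids) - net.node_ids()
        if dangling:
            raise NetioError(f"overlay marker {marker!r} has dangling ids {sorted(dangling)}")
    nodes = []
    for nid in sorted(net.nodes):
        node = net.nodes[nid]
        nodes.append(
            {
                "id": node.id,
                "kind": node.kind.value,
                "origin": node.origin.value,
                "markers": sorted(m for m, ids in overlay.items() if nid in ids),
            }
        )
    edges = [
        {"source": e.source, "target": e.target, "sign": e.sign.value}
        for e in sorted(net.edges, key=lambda e: (e.source, e.target, e.sign.value))
    ]
    return json.dumps({"nodes": nodes, "edges": edges}, indent=2, sort_keys=True) + "\n"


def parse_json_graph(text: str) -> SignedNetwork:
    """Inverse of :func:`export_json_graph` (markers are not re-attached)."""
    doc = json.loads(text)
    net = SignedNetwork()
    for node in doc["nodes"]:
        net.add_node(
            NetworkNode(
                id=node["id"],
                label=node.get("label", node["id"]),
                kind=NodeKind(node["kind"]),
                origin=Origin(node["origin"]),
            )
        )
    for edge in doc["edges"]:
        net.add_edge(SignedEdge(edge["source"], edge["target"], Sign(edge["sign"])))
    return net
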