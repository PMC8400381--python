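"""Seeded generators emulating the processed inputs the pipeline consumes:
a TF co-regulatory network, a layered signalling network with complexes,
DEG tables with planted FDR structure, variant tables, and random Boolean
models for engine oracle tests.

All generators are pure functions of (spec, seed): identical inputs yield
identical outputs.  Generated identifiers use reserved prefixes (TFxx, Gxxx,
Pxxx, Vxxx, Xn) so they cannot collide with fixture symbols.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import expr as E
from .netio import (
    LogicalModel,
    NetworkNode,
    NodeKind,
    Origin,
    OverlayTable,
    Sign,
    SignedEdge,
    SignedNetwork,
)

__all__ = [
    "SyntheticSpec",
    "gen_coreg_network",
    "gen_signalling_network",
    "gen_deg_table",
    "gen_variant_table",
    "gen_random_model",
]


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_tfs: int = 19
    n_targets: int = 373
    coreg_density: float = 0.08
    inhibition_rate: float = 0.3
    n_layers: int = 4
    layer_width: int = 6
    complex_rate: float = 0.15
    n_shared_tfs: int = 6
    frac_de: float = 0.2
    n_variants: int = 200

    def __post_init__(self):
        for name in ("coreg_density", "inhibition_rate", "complex_rate", "frac_de"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_shared_tfs > self.n_tfs:
            raise ValueError("n_shared_tfs cannot exceed n_tfs")


def _tf_symbols(n: int) -> list[str]:
    return [f"TF{i:02d}" for i in range(1, n + 1)]


def gen_coreg_network(spec: SyntheticSpec) -> SignedNetwork:
    """TF->target regulation (every target regulated by >=1 TF) plus TF-TF
    COREGULATION edges drawn at ``coreg_density``."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    net = SignedNetwork()
    tfs = _tf_symbols(spec.n_tfs)
    for tf in tfs:
        net.add_node(NetworkNode(tf, tf, NodeKind.TF, Origin.COREG))
    for i in range(1, spec.n_targets + 1):
        gene = f"G{i:03d}"
        net.add_node(NetworkNode(gene, gene, NodeKind.TARGET_GENE, Origin.COREG))
        n_regs = 1 + rng.binomial(min(2, spec.n_tfs - 1), 0.3)
        for tf in rng.choice(tfs, size=n_regs, replace=False):
            sign = Sign.INHIBITION if rng.random() < spec.inhibition_rate else Sign.ACTIVATION
            net.add_edge(SignedEdge(str(tf), gene, sign, provenance="coreg"))
    for a, b in itertools.combinations(tfs, 2):
        if rng.random() < spec.coreg_density:
            net.add_edge(SignedEdge(a, b, Sign.COREGULATION, provenance="coreg"))
    return net


def gen_signalling_network(spec: SyntheticSpec, shared_tfs: list[str]):
    """Layered DAG of protein nodes feeding the shared TFs; a ``complex_rate``
    fraction of nodes are COMPLEX with 2-3 members recorded in the returned
    membership map.  Returns ``(network, membership)``."""
    if len(shared_tfs) != spec.n_shared_tfs:
        raise ValueError(
            f"expected {spec.n_shared_tfs} shared TFs, got {len(shared_tfs)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    net = SignedNetwork()
    membership: dict[str, list[str]] = {}
    layers: list[list[str]] = []
    counter = 0
    for layer_idx in range(spec.n_layers):
        layer = []
        for _ in range(spec.layer_width):
            counter += 1
            pid = f"P{counter:03d}"
            if rng.random() < spec.complex_rate:
                node = NetworkNode(pid, pid, NodeKind.COMPLEX, Origin.MAP)
                members = [f"P{counter:03d}M{k}" for k in range(1, int(rng.integers(2, 4)) + 1)]
                membership[pid] = members
            else:
                node = NetworkNode(pid, pid, NodeKind.PROTEIN, Origin.MAP)
            net.add_node(node)
            layer.append(pid)
        layers.append(layer)
    for tf in shared_tfs:
        net.add_node(NetworkNode(tf, tf, NodeKind.TF, Origin.MAP))
    layers.append(list(shared_tfs))
    # wire consecutive layers; every downstream node gets >=1 regulator so all
    # shared TFs are reachable from layer 1
    for upper, lower in zip(layers, layers[1:]):
        for target in lower:
            n_regs = 1 + int(rng.integers(0, min(2, len(upper))))
            for source in rng.choice(upper, size=n_regs, replace=False):
                sign = (
                    Sign.INHIBITION
                    if rng.random() < spec.inhibition_rate
                    else Sign.ACTIVATION
                )
                net.add_edge(SignedEdge(str(source), target, sign, provenance="map"))
    return net, membership


def gen_deg_table(genes: list[str], frac_de: float, seed: int) -> OverlayTable:
    """Exactly ``round(frac_de * len(genes))`` genes get fdr in [0, 0.1);
    the rest in [0.1, 1]."""
    if not (0.0 <= frac_de <= 1.0):
        raise ValueError("frac_de must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n_de = round(frac_de * len(genes))
    de_idx = set(rng.choice(len(genes), size=n_de, replace=False).tolist())
    records = []
    for i, gene in enumerate(genes):
        if i in de_idx:
            fdr = rng.uniform(0.0, 0.1)
        else:
            fdr = rng.uniform(0.1, 1.0)
        log2fc = float(rng.normal(0.0, 2.0))
        records.append({"gene": gene, "log2fc": log2fc, "fdr": fdr, "dataset": "synthetic"})
    return OverlayTable(kind="DEG", rows=pd.DataFrame(records, columns=["gene", "log2fc", "fdr", "dataset"]))


def gen_variant_table(genes: list[str], n_variants: int, seed: int) -> OverlayTable:
    """Variant rows with vda, ei independently uniform in [0, 1]."""
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    records = []
    for i in range(1, n_variants + 1):
        records.append(
            {
                "variant": f"V{i:05d}",
                "gene": str(rng.choice(genes)),
                "vda": float(rng.uniform()),
                "ei": float(rng.uniform()),
            }
        )
    return OverlayTable(
        kind="VARIANT",
        rows=pd.DataFrame(records, columns=["variant", "gene", "vda", "ei"]),
    )


def gen_random_model(
    n_vars: int, max_regulators: int, seed: int, activation_only: bool = False
) -> LogicalModel:
    """Random monotone Boolean model for oracle tests: each variable draws
    0..max_regulators regulators and a random monotone DNF over them (signs
    all positive when *activation_only*)."""
    if n_vars > 16:
        raise ValueError("gen_random_model supports at most 16 variables")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    variables = [f"X{i}" for i in range(1, n_vars + 1)]
    rules: dict[str, E.BoolExpr] = {}
    for var in variables:
        k = int(rng.integers(0, max_regulators + 1))
        k = min(k, n_vars)
        if k == 0:
            rules[var] = E.Var(var)
            continue
        regs = [str(r) for r in rng.choice(variables, size=k, replace=False)]
        signs = {
            r: (False if activation_only else bool(rng.random() < 0.3)) for r in regs
        }
        n_conjuncts = int(rng.integers(1, 4))
        conjuncts = []
        for _ in range(n_conjuncts):
            size = int(rng.integers(1, len(regs) + 1))
            chosen = sorted(str(r) for r in rng.choice(regs, size=size, replace=False))
            literals = tuple(
                E.Not(E.Var(r)) if signs[r] else E.Var(r) for r in chosen
            )
            conjuncts.append(literals[0] if len(literals) == 1 else E.And(literals))
        # dedup conjuncts, keep order
        unique = list(dict.fromkeys(conjuncts))
        rules[var] = unique[0] if len(unique) == 1 else E.Or(tuple(unique))
    return LogicalModel(variables, rules)
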