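"""Boolean dynamics engine.

Rule inference from signed topology, clamping perturbations, exhaustive
fixed-point enumeration (vectorised over all states), asynchronous attractor
classification, fixed-point-preserving model reduction, and reconstruction of
monotone rules from stable-state constraint tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from . import expr as E
from .netio import LogicalModel, Sign, SignedNetwork

__all__ = [
    "LogicError",
    "InfeasibleConstraints",
    "Perturbation",
    "StateConstraintTable",
    "infer_rules",
    "apply_perturbation",
    "stable_states",
    "async_attractors",
    "reduce_model",
    "reduce_with_extension",
    "solve_rules_from_constraints",
]

MAX_EXHAUSTIVE = 24  # engine limit for fixed-point enumeration
MAX_ASYNC = 16  # full asynchronous state-transition graph limit
_CHUNK = 1 << 18

Perturbation = Mapping[str, int]


class LogicError(ValueError):
    pass


class InfeasibleConstraints(LogicError):
    pass


@dataclass
class StateConstraintTable:
    """A perturbation context plus required fixed points over a variable subset.

    With ``exact`` set, the required states are ALL fixed points of the
    clamped model, projected to ``variables(required)``.
    """

    perturbation: dict[str, int] = field(default_factory=dict)
    input_clamps: dict[str, int] = field(default_factory=dict)
    required_states: list[dict[str, int]] = field(default_factory=list)
    exact: bool = True
    name: str = ""

    def context(self) -> dict[str, int]:
        merged = dict(self.input_clamps)
        for var, val in self.perturbation.items():
            if merged.get(var, val) != val:
                raise LogicError(
                    f"table {self.name!r}: conflicting clamp for {var!r}"
                )
            merged[var] = val
        return merged

    def subset(self) -> list[str]:
        if not self.required_states:
            return []
        keys = set(self.required_states[0])
        for row in self.required_states[1:]:
            if set(row) != keys:
                raise LogicError(f"table {self.name!r}: inconsistent variable subset")
        return sorted(keys)


def _make_or(operands: Sequence[E.BoolExpr]) -> E.BoolExpr:
    return operands[0] if len(operands) == 1 else E.Or(tuple(operands))


def _make_and(operands: Sequence[E.BoolExpr]) -> E.BoolExpr:
    return operands[0] if len(operands) == 1 else E.And(tuple(operands))


def infer_rules(net: SignedNetwork) -> LogicalModel:
    """Preliminary rules from signed topology:
    ``v = (OR activators) & !(OR inhibitors)``; nodes without regulators
    become inputs (``v = v``)."""
    if any(e.sign is Sign.COREGULATION for e in net.edges):
        raise LogicError("remove COREGULATION edges before rule inference")
    variables = sorted(net.nodes)
    rules: dict[str, E.BoolExpr] = {}
    for var in variables:
        activators, inhibitors = net.regulators(var)
        if not activators and not inhibitors:
            rules[var] = E.Var(var)
        elif not inhibitors:
            rules[var] = _make_or([E.Var(a) for a in activators])
        elif not activators:
            rules[var] = E.Not(_make_or([E.Var(i) for i in inhibitors]))
        else:
            rules[var] = E.And(
                (
                    _make_or([E.Var(a) for a in activators]),
                    E.Not(_make_or([E.Var(i) for i in inhibitors])),
                )
            )
    return LogicalModel(variables, rules)


def apply_perturbation(model: LogicalModel, pert) -> LogicalModel:
    """New model with clamps overridden by *pert*; rules untouched."""
    if not isinstance(pert, Mapping):
        collected: dict[str, int] = {}
        for var, val in pert:
            if collected.get(var, val) != val:
                raise LogicError(f"conflicting clamp for {var!r} in one perturbation")
            collected[var] = val
        pert = collected
    unknown = set(pert) - set(model.variables)
    if unknown:
        raise LogicError(f"perturbation targets unknown variable(s) {sorted(unknown)}")
    out = model.copy()
    out.clamps.update({v: int(bool(val)) for v, val in pert.items()})
    return out


def _state_matrix(model: LogicalModel, free: list[str], codes: np.ndarray) -> np.ndarray:
    """Bool matrix (len(codes) x n_vars) decoding free-variable bit codes."""
    n = len(model.variables)
    s = np.zeros((codes.shape[0], n), dtype=bool)
    col = {v: i for i, v in enumerate(model.variables)}
    for var, val in model.clamps.items():
        s[:, col[var]] = bool(val)
    for bit, var in enumerate(free):
        s[:, col[var]] = (codes >> bit) & 1
    return s


def _compiled_rules(model: LogicalModel):
    col = {v: i for i, v in enumerate(model.variables)}
    return {v: E.compile_expr(model.rules[v], col) for v in model.variables}


def stable_states(model: LogicalModel) -> list[dict[str, int]]:
    """All assignments with ``f(x) = x`` under clamps, sorted lexicographically
    over the variable order.  Exhaustive (vectorised over all states)."""
    free = [v for v in model.variables if v not in model.clamps]
    if len(free) > MAX_EXHAUSTIVE:
        raise LogicError(
            f"{len(free)} free variables exceed the exhaustive limit "
            f"({MAX_EXHAUSTIVE}); reduce the model first (reduce_model)"
        )
    col = {v: i for i, v in enumerate(model.variables)}
    compiled = _compiled_rules(model)
    found: list[dict[str, int]] = []
    total = 1 << len(free)
    for start in range(0, total, _CHUNK):
        codes = np.arange(start, min(start + _CHUNK, total), dtype=np.int64)
        s = _state_matrix(model, free, codes)
        fixed = np.ones(codes.shape[0], dtype=bool)
        for var in free:
            fixed &= compiled[var](s) == s[:, col[var]]
        for row in s[fixed]:
            found.append({v: int(row[col[v]]) for v in model.variables})
    found.sort(key=lambda st: tuple(st[v] for v in model.variables))
    return found


def async_attractors(model: LogicalModel):
    """Terminal SCCs of the asynchronous state-transition graph.

    Returns ``(fixed_points, complex_attractors)``: singleton terminal SCCs
    as state dicts, larger ones as sorted lists of state dicts.
    """
    free = [v for v in model.variables if v not in model.clamps]
    if len(free) > MAX_ASYNC:
        raise LogicError(
            f"{len(free)} free variables exceed the asynchronous STG limit ({MAX_ASYNC})"
        )
    col = {v: i for i, v in enumerate(model.variables)}
    compiled = _compiled_rules(model)
    total = 1 << len(free)
    codes = np.arange(total, dtype=np.int64)
    s = _state_matrix(model, free, codes)
    graph = nx.DiGraph()
    graph.add_nodes_from(range(total))
    for bit, var in enumerate(free):
        differs = compiled[var](s) != s[:, col[var]]
        sources = codes[differs]
        graph.add_edges_from(zip(sources.tolist(), (sources ^ (1 << bit)).tolist()))

    def decode(code: int) -> dict[str, int]:
        state = {v: int(model.clamps.get(v, 0)) for v in model.variables}
        for bit, var in enumerate(free):
            state[var] = (code >> bit) & 1
        return state

    cond = nx.condensation(graph)
    fixed_points: list[dict[str, int]] = []
    complex_attractors: list[list[dict[str, int]]] = []
    for scc_id in cond.nodes:
        if cond.out_degree(scc_id) > 0:
            continue
        members = cond.nodes[scc_id]["members"]
        states = sorted(
            (decode(c) for c in members),
            key=lambda st: tuple(st[v] for v in model.variables),
        )
        if len(states) == 1:
            fixed_points.append(states[0])
        else:
            complex_attractors.append(states)
    fixed_points.sort(key=lambda st: tuple(st[v] for v in model.variables))
    complex_attractors.sort(
        key=lambda att: tuple(tuple(st[v] for v in model.variables) for st in att)
    )
    return fixed_points, complex_attractors


def reduce_with_extension(model: LogicalModel, eliminate: Sequence[str]):
    """Eliminate variables by substituting their rules into their targets.

    Returns ``(reduced_model, extension)`` where *extension* maps each
    eliminated variable to its rule rewritten over the remaining variables
    (apply to a reduced fixed point to recover the full one).
    """
    eliminate = list(eliminate)
    current = model.copy()
    for var in eliminate:
        if var not in current.rules:
            raise LogicError(f"cannot eliminate unknown variable {var!r}")
        if var in current.clamps:
            raise LogicError(f"cannot eliminate clamped variable {var!r}")
        if var in E.variables(current.rules[var]):
            raise LogicError(f"cannot eliminate autoregulated variable {var!r}")
        replacement = {var: current.rules[var]}
        new_rules = {}
        for other, rule in current.rules.items():
            if other == var:
                continue
            new_rule = E.substitute(rule, replacement)
            if other in E.variables(new_rule) and other not in E.variables(rule):
                raise LogicError(
                    f"eliminating {var!r} would make {other!r} autoregulated"
                )
            new_rules[other] = new_rule
        current = LogicalModel(
            [v for v in current.variables if v != var], new_rules, dict(current.clamps)
        )
    extension: dict[str, E.BoolExpr] = {}
    remaining = set(current.variables)
    for var in eliminate:
        rule = model.rules[var]
        # rewrite over remaining variables by repeated substitution
        for _ in range(len(eliminate) + 1):
            refs = E.variables(rule) - remaining
            if not refs:
                break
            rule = E.substitute(
                rule, {r: model.rules[r] for r in refs if r in model.rules}
            )
        else:
            raise LogicError("cyclic dependency among eliminated variables")
        extension[var] = rule
    return current, extension


def reduce_model(model: LogicalModel, eliminate: Sequence[str]) -> LogicalModel:
    return reduce_with_extension(model, eliminate)[0]


# ----------------------------------------------------------------------------
# Constraint-based rule reconstruction
# ----------------------------------------------------------------------------


def _monotone_candidates(
    var: str, activators: list[str], inhibitors: list[str],
    max_conjuncts: int = 4, max_literals: int = 3,
):
    """Monotone DNF candidates over the variable's regulators, every regulator
    used at least once, ordered by (total literal count, canonical text)."""
    regulators = activators + inhibitors
    if not regulators:
        yield E.Var(var)
        return
    literal = {a: E.Var(a) for a in activators}
    literal.update({i: E.Not(E.Var(i)) for i in inhibitors})
    pool = [
        frozenset(c)
        for size in range(1, min(max_literals, len(regulators)) + 1)
        for c in itertools.combinations(sorted(regulators), size)
    ]
    candidates: list[tuple[int, str, E.BoolExpr]] = []
    for count in range(1, max_conjuncts + 1):
        for combo in itertools.combinations(pool, count):
            if any(
                a < b or b < a for a, b in itertools.combinations(combo, 2)
            ):
                continue  # not an antichain: one conjunct absorbs another
            used = frozenset().union(*combo)
            if used != frozenset(regulators):
                continue
            conjuncts = sorted(combo, key=lambda c: (len(c), tuple(sorted(c))))
            rule = _make_or(
                [_make_and([literal[r] for r in sorted(c)]) for c in conjuncts]
            )
            candidates.append((sum(len(c) for c in combo), E.to_text(rule), rule))
    candidates.sort(key=lambda item: (item[0], item[1]))
    for _, _, rule in candidates:
        yield rule


def _evaluation_constraints(tables, variables, regulators):
    """Per-variable list of (state, expected) evaluation constraints, plus
    transcription checks that required rows honour their own clamps."""
    constraints = {v: [] for v in variables}
    for table in tables:
        context = table.context()
        subset = set(table.subset())
        for row_idx, row in enumerate(table.required_states):
            for var, val in context.items():
                if var in row and row[var] != val:
                    raise InfeasibleConstraints(
                        f"table {table.name!r} row {row_idx}: {var} contradicts its clamp"
                    )
            for var in row:
                if var in context or var not in regulators:
                    continue
                if not set(regulators[var]) <= subset:
                    continue  # partial row cannot evaluate this rule
                constraints[var].append((dict(row), row[var], table.name, row_idx))
    return constraints


def solve_rules_from_constraints(
    topology: SignedNetwork,
    tables: Sequence[StateConstraintTable],
    qualitative: Sequence[StateConstraintTable] = (),
    max_iterations: int = 200,
) -> LogicalModel:
    """Find monotone rules over the signed topology whose fixed points match
    every constraint table exactly (projected to the table's variables).

    Search prefers fewer literals; infeasibility raises
    :class:`InfeasibleConstraints` naming the first violated table row.
    """
    if any(e.sign is Sign.COREGULATION for e in topology.edges):
        raise LogicError("remove COREGULATION edges before rule reconstruction")
    variables = sorted(topology.nodes)
    regulators = {v: sum(topology.regulators(v), []) for v in variables}
    all_tables = list(tables) + list(qualitative)
    constraints = _evaluation_constraints(all_tables, variables, regulators)

    candidate_lists: dict[str, list[E.BoolExpr]] = {}
    for var in variables:
        activators, inhibitors = topology.regulators(var)
        admissible = []
        first_violation = None
        for rule in _monotone_candidates(var, activators, inhibitors):
            violation = None
            for state, expected, tname, row_idx in constraints[var]:
                if E.evaluate(rule, state) != expected:
                    violation = (tname, row_idx)
                    break
            if violation is None:
                admissible.append(rule)
            elif first_violation is None:
                first_violation = violation
        if not admissible:
            tname, row_idx = first_violation or ("<none>", -1)
            raise InfeasibleConstraints(
                f"no admissible rule for {var!r}; first violated: "
                f"table {tname!r} row {row_idx}"
            )
        candidate_lists[var] = admissible

    choice = {v: 0 for v in variables}

    def build() -> LogicalModel:
        return LogicalModel(
            list(variables), {v: candidate_lists[v][choice[v]] for v in variables}
        )

    def exactness_violation(model: LogicalModel):
        """First spurious/missing fixed point, or None."""
        for table in all_tables:
            context = table.context()
            clamped = apply_perturbation(model, context)
            points = stable_states(clamped)
            subset = table.subset()
            projected = {tuple(p[v] for v in subset) for p in points}
            required = {tuple(r[v] for v in subset) for r in table.required_states}
            missing = required - projected
            if missing:
                return table, "missing", dict(zip(subset, next(iter(sorted(missing)))))
            if table.exact:
                spurious = projected - required
                if spurious:
                    full = next(
                        p for p in points
                        if tuple(p[v] for v in subset) in spurious
                    )
                    return table, "spurious", full
        return None

    # CEGIS loop: ban spurious fixed points by switching candidates.
    banned: list[tuple[frozenset, dict[str, int]]] = []

    def respects_bans() -> bool:
        model = build()
        for clamped_vars, state in banned:
            if all(
                E.evaluate(model.rules[v], state) == state[v]
                for v in variables
                if v not in clamped_vars
            ):
                return False
        return True

    for _ in range(max_iterations):
        model = build()
        violation = exactness_violation(model)
        if violation is None:
            return model
        table, kind, state = violation
        if kind == "missing":
            # required states satisfy per-variable constraints by construction
            # when the subset covers all regulators; a miss means a partial
            # table cannot be extended -> infeasible.
            raise InfeasibleConstraints(
                f"table {table.name!r}: required state {state} is not a fixed point "
                "of any admissible rule assignment"
            )
        banned.append((frozenset(table.context()), dict(state)))
        # advance the cheapest single-variable switch that breaks the ban
        switched = False
        for var in variables:
            base = choice[var]
            for idx in range(base + 1, len(candidate_lists[var])):
                choice[var] = idx
                if respects_bans():
                    switched = True
                    break
            if switched:
                break
            choice[var] = base
        if not switched:
            raise InfeasibleConstraints(
                f"table {table.name!r}: spurious fixed point {state} cannot be "
                "eliminated within the rule search space"
            )
    raise InfeasibleConstraints("constraint solving did not converge")
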