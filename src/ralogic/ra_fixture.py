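"""Packaged rheumatoid-arthritis artifacts: the 13-variable anti-TNF-response
subnetwork topology, the wild-type and knock-out stable-state constraint
tables, and the reconstructed Boolean model satisfying all of them.

The rule set was reconstructed from the constraint tables with
:func:`ralogic.logic.solve_rules_from_constraints` and is stored as bnet text
for deterministic builds; :func:`solve_ra_model` reruns the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .logic import StateConstraintTable, apply_perturbation, stable_states
from .logic import solve_rules_from_constraints
from .netio import LogicalModel, SignedNetwork, parse_bnet, parse_sif

__all__ = [
    "RA_VARIABLES",
    "RAFixture",
    "ra_topology",
    "ra_model",
    "ra_constraint_tables",
    "ra_qualitative_tables",
    "ra_fixture",
    "solve_ra_model",
    "verify_fixture",
    "VerifyReport",
]

RA_VARIABLES = [
    "TNF", "IL6", "TGFB1", "JUN", "FOS", "JUND", "NFKBIA",
    "DAXX", "ILK", "NFKB1", "MAP2K1", "MAPK1", "MAPK14",
]


def _read_data(name: str) -> str:
    return (resources.files("ralogic") / "data" / name).read_text(encoding="utf-8")


def ra_topology() -> SignedNetwork:
    """Signed topology of the packaged 13-variable subnetwork."""
    return parse_sif(_read_data("ra_subnetwork.sif"))


def ra_model() -> LogicalModel:
    """The packaged Boolean model (no clamps applied)."""
    return parse_bnet(_read_data("ra_model.bnet"))


def _parse_assignments(text: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        var, _, val = item.partition("=")
        out[var.strip()] = int(val)
    return out


def ra_constraint_tables() -> list[StateConstraintTable]:
    """The four stable-state tables (WT + three KO contexts), all exact."""
    lines = _read_data("ra_tables.tsv").splitlines()
    header = lines[0].split("\t")
    var_cols = header[4:]
    grouped: dict[str, StateConstraintTable] = {}
    for line in lines[1:]:
        fields = line.split("\t")
        name, ko, clamp = fields[0], fields[1], fields[2]
        values = fields[4:]
        table = grouped.get(name)
        if table is None:
            table = StateConstraintTable(
                perturbation=_parse_assignments(ko),
                input_clamps=_parse_assignments(clamp),
                required_states=[],
                exact=True,
                name=name,
            )
            grouped[name] = table
        table.required_states.append(
            {var: int(val) for var, val in zip(var_cols, values)}
        )
    return list(grouped.values())


def ra_qualitative_tables() -> list[StateConstraintTable]:
    """Qualitative real-time-simulation outcome used as an extra solver
    constraint: with ILK, MAP2K1 and DAXX knocked out and TNF blocked, IL6
    alone switches on NFKBIA but none of JUN/FOS/JUND."""
    return [
        StateConstraintTable(
            perturbation={"ILK": 0, "MAP2K1": 0, "DAXX": 0},
            input_clamps={"TNF": 0, "IL6": 1, "TGFB1": 0},
            required_states=[
                {"IL6": 1, "TGFB1": 0, "NFKBIA": 1, "JUN": 0, "FOS": 0, "JUND": 0}
            ],
            exact=False,
            name="IL6_only_response_KO",
        )
    ]


@dataclass
class RAFixture:
    topology: SignedNetwork
    constraint_tables: list[StateConstraintTable]
    model: LogicalModel


def ra_fixture() -> RAFixture:
    return RAFixture(ra_topology(), ra_constraint_tables(), ra_model())


def solve_ra_model() -> LogicalModel:
    """Re-derive the rules from the constraint tables (regeneration path)."""
    return solve_rules_from_constraints(
        ra_topology(), ra_constraint_tables(), ra_qualitative_tables()
    )


@dataclass
class RowResult:
    required: dict[str, int]
    found: bool


@dataclass
class TableResult:
    name: str
    rows: list[RowResult] = field(default_factory=list)
    spurious: list[dict[str, int]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(r.found for r in self.rows) and not self.spurious


@dataclass
class VerifyReport:
    tables: list[TableResult]

    @property
    def passed(self) -> bool:
        return all(t.passed for t in self.tables)

    @property
    def n_rows(self) -> int:
        return sum(len(t.rows) for t in self.tables)

    def summary(self) -> str:
        lines = []
        for table in self.tables:
            status = "PASS" if table.passed else "FAIL"
            lines.append(f"{table.name}: {status} ({len(table.rows)} required rows)")
            for row in table.rows:
                if not row.found:
                    lines.append(f"  missing fixed point: {row.required}")
            for state in table.spurious:
                lines.append(f"  spurious fixed point: {state}")
        lines.append(
            f"overall: {'PASS' if self.passed else 'FAIL'} ({self.n_rows} rows)"
        )
        return "\n".join(lines)


def verify_fixture(fixture: RAFixture | None = None) -> VerifyReport:
    """Diff the model's fixed points against every constraint table.

    Failures are reported, not raised.
    """
    fixture = fixture or ra_fixture()
    results = []
    for table in fixture.constraint_tables:
        clamped = apply_perturbation(fixture.model, table.context())
        points = stable_states(clamped)
        subset = table.subset()
        projected = {tuple(p[v] for v in subset) for p in points}
        required = {tuple(r[v] for v in subset) for r in table.required_states}
        result = TableResult(name=table.name)
        for row in table.required_states:
            result.rows.append(
                RowResult(required=dict(row), found=tuple(row[v] for v in subset) in projected)
            )
        if table.exact:
            for extra in sorted(projected - required):
                result.spurious.append(dict(zip(subset, extra)))
        results.append(result)
    return VerifyReport(tables=results)
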