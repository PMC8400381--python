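"""Stochastic activity-level simulation (Cell-Collective-style semantics).

Dosed inputs are resampled ON with probability equal to their dose at every
step; clamped variables are constant; everything else updates synchronously.
Activity is the fraction of ON observations after a burn-in window, averaged
over independent runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import expr as E
from .netio import LogicalModel

__all__ = [
    "SimulationError",
    "SimParams",
    "ActivityEstimate",
    "run_stochastic",
    "dose_response",
    "sensitivity_grid",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    steps: int = 2000
    runs: int = 50
    burn_in: int = 500

    def __post_init__(self):
        if not (self.steps > self.burn_in >= 0):
            raise SimulationError("need steps > burn_in >= 0")
        if self.runs < 1:
            raise SimulationError("need runs >= 1")


@dataclass
class ActivityEstimate:
    """Mean ON-fraction and standard error (across runs) per variable."""

    mean: dict[str, float]
    stderr: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["variable\tmean_activity\tstderr"]
        for var in self.mean:
            lines.append(f"{var}\t{self.mean[var]:.6f}\t{self.stderr[var]:.6f}")
        return "\n".join(lines) + "\n"


def _check_doses(model: LogicalModel, doses: Mapping[str, float]) -> dict[str, float]:
    out = {}
    for var, dose in doses.items():
        if var not in model.rules:
            raise SimulationError(f"dosed variable {var!r} is not in the model")
        dose = float(dose)
        if not (0.0 <= dose <= 1.0):
            raise SimulationError(f"dose for {var!r} outside [0, 1]: {dose}")
        out[var] = dose
    return out


def run_stochastic(
    model: LogicalModel,
    doses: Mapping[str, float],
    perturbation: Mapping[str, int] | None = None,
    steps: int = 2000,
    runs: int = 50,
    burn_in: int = 500,
    seed: int = 0,
    _grid_index: int = 0,
) -> ActivityEstimate:
    """Monte-Carlo activity estimate under input dosing and clamps.

    Initial state: all variables OFF except clamped-ON ones.  Per-run
    randomness derives from ``SeedSequence([seed, grid_index, run])`` so runs
    and grid points are reproducible independently.
    """
    params = SimParams(steps=steps, runs=runs, burn_in=burn_in)
    doses = _check_doses(model, doses)
    perturbation = dict(perturbation or {})
    for var in perturbation:
        if var not in model.rules:
            raise SimulationError(f"perturbed variable {var!r} is not in the model")
    overlap = set(doses) & set(perturbation)
    if overlap:
        raise SimulationError(f"variable(s) {sorted(overlap)} both dosed and clamped")

    variables = model.variables
    col = {v: i for i, v in enumerate(variables)}
    clamps = {**model.clamps, **{v: int(bool(x)) for v, x in perturbation.items()}}
    dosed = sorted(doses)
    dose_vec = np.array([doses[v] for v in dosed])
    updated = [v for v in variables if v not in clamps and v not in doses]
    compiled = {v: E.compile_expr(model.rules[v], col) for v in updated}

    # per-run pre-generated dose draws keep runs independently seeded while
    # the synchronous update stays vectorised across runs
    draws = np.empty((params.runs, params.steps, len(dosed)))
    for run in range(params.runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, _grid_index, run]))
        draws[run] = rng.random((params.steps, len(dosed)))

    state = np.zeros((params.runs, len(variables)), dtype=bool)
    for var, val in clamps.items():
        state[:, col[var]] = bool(val)
    on_counts = np.zeros((params.runs, len(variables)))
    kept = 0
    for step in range(params.steps):
        if dosed:
            state[:, [col[v] for v in dosed]] = draws[:, step, :] < dose_vec
        if updated:
            new = {v: compiled[v](state) for v in updated}
            for v in updated:
                state[:, col[v]] = new[v]
        if step >= params.burn_in:
            on_counts += state
            kept += 1
    per_run = on_counts / kept
    mean = per_run.mean(axis=0)
    stderr = per_run.std(axis=0, ddof=1) / np.sqrt(params.runs) if params.runs > 1 else np.zeros(len(variables))
    return ActivityEstimate(
        mean={v: float(mean[col[v]]) for v in variables},
        stderr={v: float(stderr[col[v]]) for v in variables},
        metadata={
            "steps": params.steps,
            "runs": params.runs,
            "burn_in": params.burn_in,
            "seed": seed,
            "grid_index": _grid_index,
            "doses": dict(sorted(doses.items())),
            "perturbation": dict(sorted(perturbation.items())),
        },
    )


def dose_response(
    model: LogicalModel,
    varied: str,
    base: Mapping[str, float],
    grid: Sequence[float],
    perturbation: Mapping[str, int] | None = None,
    steps: int = 2000,
    runs: int = 50,
    burn_in: int = 500,
    seed: int = 0,
) -> list[tuple[float, ActivityEstimate]]:
    """One stochastic estimate per grid dose of *varied* (ascending grid)."""
    if varied in (perturbation or {}):
        raise SimulationError(f"varied input {varied!r} is also perturbed")
    grid = [float(g) for g in grid]
    if any(not (0.0 <= g <= 1.0) for g in grid):
        raise SimulationError("grid doses must lie in [0, 1]")
    if sorted(grid) != grid:
        raise SimulationError("grid must be ascending")
    curve = []
    for idx, dose in enumerate(grid):
        doses = {**base, varied: dose}
        est = run_stochastic(
            model, doses, perturbation,
            steps=steps, runs=runs, burn_in=burn_in, seed=seed, _grid_index=idx,
        )
        curve.append((dose, est))
    return curve


def curve_to_tsv(curve: list[tuple[float, ActivityEstimate]], varied: str) -> str:
    lines = [f"{varied}_dose\tvariable\tmean_activity\tstderr"]
    for dose, est in curve:
        for var in est.mean:
            lines.append(f"{dose:.4f}\t{var}\t{est.mean[var]:.6f}\t{est.stderr[var]:.6f}")
    return "\n".join(lines) + "\n"


def sensitivity_grid(
    model: LogicalModel,
    input_x: str,
    input_y: str,
    clamped: Mapping[str, int] | None = None,
    grid: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    steps: int = 2000,
    runs: int = 50,
    burn_in: int = 500,
    seed: int = 0,
) -> list[list[ActivityEstimate]]:
    """|grid| x |grid| matrix of estimates varying two inputs jointly;
    cell [i][j] doses ``input_x = grid[i]``, ``input_y = grid[j]``."""
    if input_x == input_y:
        raise SimulationError("the two varied inputs must differ")
    clamped = dict(clamped or {})
    for var in (input_x, input_y):
        if var in clamped:
            raise SimulationError(f"varied input {var!r} is also clamped")
    grid = [float(g) for g in grid]
    matrix: list[list[ActivityEstimate]] = []
    for i, gx in enumerate(grid):
        row = []
        for j, gy in enumerate(grid):
            est = run_stochastic(
                model, {input_x: gx, input_y: gy}, clamped,
                steps=steps, runs=runs, burn_in=burn_in, seed=seed,
                _grid_index=i * len(grid) + j,
            )
            row.append(est)
        matrix.append(row)
    return matrix
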