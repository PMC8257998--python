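"""Thin LP helpers shared by pan-model merging and the FVA engine."""

from __future__ import annotations

import math

from cobra import Model

#: solver tolerances used throughout (feasibility / optimality)
SOLVER_TOLERANCE = 1e-9


def configure_solver(model: Model) -> None:
    model.tolerance = SOLVER_TOLERANCE


def optimize_reaction(model: Model, reaction_id: str, direction: str) -> tuple[float, str]:
    """Min- or maximize one reaction's flux; returns (value, status).

    Solver failures are reported in the status instead of raising, so a
    long screen over many reactions can continue past one bad LP.
    """
    with model:
        model.objective = model.reactions.get_by_id(reaction_id)
        model.objective_direction = direction
        value = model.slim_optimize(error_value=float("nan"))
        status = model.solver.status
    if math.isnan(value):
        return float("nan"), status if status != "optimal" else "failed"
    return float(value), "optimal"


def flux_range(model: Model, reaction_id: str) -> tuple[float, float, str, str]:
    """(min flux, max flux, min status, max status) for one reaction."""
    vmin, smin = optimize_reaction(model, reaction_id, "min")
    vmax, smax = optimize_reaction(model, reaction_id, "max")
    return vmin, vmax, smin, smax
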