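"""Growth-maximizing flux balance analysis for small metabolic networks.

Solves max c·v subject to S·v = 0 (internal metabolites only) and lb ≤ v ≤ ub
with :func:`scipy.optimize.linprog` (HiGHS).  Measured specific rates enter as
two-sided capacity constraints: the exchange flux is fixed to the measured
value within an absolute tolerance.  Because growth LPs are frequently
degenerate, a secondary LP minimizes the total absolute flux Σ|v| at the fixed
optimum, making the returned distribution unique and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicModel, stoichiometric_matrix

__all__ = [
    "CapacityConstraintSet",
    "FluxDistribution",
    "solve_fba",
    "compare_predicted_growth",
    "normalize_fluxes",
]

_FEAS_TOL = 1e-9


@dataclass
class CapacityConstraintSet:
    """Measured exchange rates (mmol·gDCW⁻¹·h⁻¹) with absolute tolerances."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def add(self, reaction_id: str, rate: float, tolerance: float = 0.0) -> None:
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        self.entries[reaction_id] = (float(rate), float(tolerance))

    def validate_against(self, model: MetabolicModel) -> None:
        exchanges = set(model.exchange_ids)
        for rid in self.entries:
            if rid not in exchanges:
                raise ValueError(
                    f"constrained reaction {rid!r} is not an exchange of model {model.id!r}"
                )

    @classmethod
    def from_rates(
        cls,
        rates: dict[str, float],
        exchange_map: dict[str, str],
        tolerance: float = 0.0,
    ) -> "CapacityConstraintSet":
        """Map species-keyed specific rates onto exchange reactions.

        *exchange_map* maps species name (e.g. ``"glucose"``) to the exchange
        reaction id (e.g. ``"EX_glc"``).
        """
        cs = cls()
        for species, rid in exchange_map.items():
            if species in rates:
                cs.add(rid, rates[species], tolerance)
        return cs


@dataclass
class FluxDistribution:
    flux: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    objective_id: str | None = None
    normalized_to: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.flux[reaction_id]


def _status_name(code: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(code, "infeasible")


def _bounds_with_constraints(
    model: MetabolicModel, constraints: CapacityConstraintSet | None
) -> list[tuple[float, float]]:
    bounds = []
    fixed = constraints.entries if constraints is not None else {}
    for r in model.reactions:
        if r.id in fixed:
            rate, tol = fixed[r.id]
            bounds.append((rate - tol, rate + tol))
        else:
            bounds.append((r.lb, r.ub))
    return bounds


def solve_fba(
    model: MetabolicModel,
    constraints: CapacityConstraintSet | None = None,
    objective_id: str | None = None,
    minimize_total_flux: bool = True,
) -> FluxDistribution:
    """Maximize *objective_id* (default: the biomass reaction) subject to
    steady state, bounds, and measured-rate capacity constraints.

    On degeneracy the reported distribution is the optimum of minimal total
    absolute flux, so identical inputs always yield the identical flux map.
    Infeasible or unbounded problems return a :class:`FluxDistribution` with
    the corresponding status and an empty flux map.
    """
    if objective_id is None:
        objective_id = model.biomass_id
    if objective_id is None:
        raise ValueError("model has no biomass reaction and no objective_id was given")
    if constraints is not None:
        constraints.validate_against(model)

    S = stoichiometric_matrix(model)
    rxn_ids = list(S.columns)
    j_obj = rxn_ids.index(objective_id)
    n = len(rxn_ids)
    A_eq = S.values
    b_eq = np.zeros(A_eq.shape[0])
    bounds = _bounds_with_constraints(model, constraints)

    c = np.zeros(n)
    c[j_obj] = -1.0
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return FluxDistribution(
            flux={},
            objective_value=float("nan"),
            status=_status_name(res.status),
            objective_id=objective_id,
        )
    opt = -res.fun
    v = res.x

    if minimize_total_flux:
        # min Σt  s.t.  S v = 0, v_obj = opt, t >= v, t >= -v
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq2 = np.hstack([A_eq, np.zeros_like(A_eq)])
        obj_row = np.zeros(2 * n)
        obj_row[j_obj] = 1.0
        A_eq2 = np.vstack([A_eq2, obj_row])
        b_eq2 = np.concatenate([b_eq, [opt]])
        eye = np.eye(n)
        A_ub = np.vstack(
            [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
        )
        b_ub = np.zeros(2 * n)
        bounds2 = bounds + [(0.0, None)] * n
        res2 = linprog(
            c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq2, b_eq=b_eq2, bounds=bounds2, method="highs"
        )
        if res2.status == 0:
            v = res2.x[:n]

    flux = {rid: float(val) for rid, val in zip(rxn_ids, v)}
    return FluxDistribution(
        flux=flux,
        objective_value=float(opt),
        status="optimal",
        objective_id=objective_id,
    )


def compare_predicted_growth(fd: FluxDistribution, measured_mu: float) -> float:
    """Signed relative deviation (predicted − measured)/measured of growth."""
    if not fd.optimal:
        raise ValueError("flux distribution is not optimal")
    if measured_mu <= 0:
        raise ValueError("measured_mu must be > 0")
    return (fd.objective_value - measured_mu) / measured_mu


def normalize_fluxes(fd: FluxDistribution, reference_id: str) -> FluxDistribution:
    """Scale every flux so the reference flux has magnitude 100.

    Conventionally the reference is the glucose exchange, giving fluxes in
    mol per 100 mol glucose taken up.  Idempotent: normalizing twice yields
    the same distribution.
    """
    if not fd.optimal:
        raise ValueError("flux distribution is not optimal")
    ref = fd.flux.get(reference_id)
    if ref is None:
        raise KeyError(reference_id)
    if ref == 0:
        raise ZeroDivisionError(f"reference flux {reference_id!r} is zero")
    scale = 100.0 / abs(ref)
    return replace(
        fd,
        flux={rid: v * scale for rid, v in fd.flux.items()},
        objective_value=fd.objective_value * scale,
        normalized_to=reference_id,
    )
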