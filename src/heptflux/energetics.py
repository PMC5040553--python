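"""Cofactor balances and maintenance-ATP estimation from a flux distribution.

For each energy/redox carrier (ATP, NADH, NADPH, FADH2) the balance collects
the carrier's production and consumption rates over all reactions of an
optimal steady-state flux distribution.  Because the carriers are internal,
balanced metabolites, production equals consumption at steady state; the
balance is informative through its per-reaction breakdown, which shows *where*
ATP is formed (substrate-level phosphorylation, oxidative phosphorylation)
and spent (biosynthesis, growth-associated polymerisation, dedicated
non-growth hydrolysis).

Non-growth-associated maintenance (NGAM) is estimated as the ATP production
remaining after subtracting biosynthetic consumption and the growth-associated
requirement gam·μ:

    ngam = ATP_production − ATP_consumption_metabolic − gam·μ

where "metabolic" consumption excludes the biomass reaction (whose ATP demand
is the growth-associated term) and any dedicated ATP-hydrolysis reaction
(whose flux is the very quantity estimated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fba import CapacityConstraintSet, FluxDistribution, solve_fba
from .model_core import MetabolicModel, ModelError

__all__ = [
    "CofactorFlows",
    "CofactorBalance",
    "MaintenanceEstimate",
    "cofactor_balance",
    "estimate_maintenance_atp",
    "estimate_maintenance_from_rates",
    "DEFAULT_GAM",
]

#: growth-associated ATP requirement, mmol ATP per gDCW of new biomass
DEFAULT_GAM = 45.0

COFACTORS = ("ATP", "NADH", "NADPH", "FADH2")


@dataclass
class CofactorFlows:
    """Production/consumption of one carrier, with per-reaction breakdown."""

    cofactor: str
    production: float
    consumption: float
    breakdown: dict[str, float] = field(default_factory=dict)  # rxn -> net rate

    @property
    def net(self) -> float:
        return self.production - self.consumption


@dataclass
class CofactorBalance:
    flows: dict[str, CofactorFlows]

    def __getitem__(self, cofactor: str) -> CofactorFlows:
        return self.flows[cofactor]


@dataclass
class MaintenanceEstimate:
    ngam: float  # mmol ATP·gDCW⁻¹·h⁻¹ available for non-growth maintenance
    gam: float  # mmol ATP·gDCW⁻¹ per unit mu (assumption)
    mu: float
    negative: bool = False  # flagged, never clamped


def cofactor_balance(model: MetabolicModel, fd: FluxDistribution) -> CofactorBalance:
    """Production and consumption rates of ATP/NADH/NADPH/FADH2 under *fd*.

    Production of a carrier by a reaction is max(coef·flux, 0) where coef is
    the carrier's stoichiometric coefficient; consumption is the analogous
    negative part.  The per-reaction breakdown stores signed net rates and
    sums to production − consumption.
    """
    if not fd.optimal:
        raise ValueError("cofactor balance requires an optimal flux distribution")
    flows: dict[str, CofactorFlows] = {}
    for cof in COFACTORS:
        carrier = model.cofactor_metabolite(cof)
        if carrier is None:
            raise ModelError(f"model {model.id!r} lacks a metabolite with role {cof!r}")
        production = 0.0
        consumption = 0.0
        breakdown: dict[str, float] = {}
        for r in model.reactions:
            coef = r.stoichiometry.get(carrier.id)
            if coef is None:
                continue
            rate = coef * fd.flux.get(r.id, 0.0)
            if rate == 0.0:
                continue
            breakdown[r.id] = rate
            if rate > 0:
                production += rate
            else:
                consumption += -rate
        flows[cof] = CofactorFlows(
            cofactor=cof,
            production=production,
            consumption=consumption,
            breakdown=breakdown,
        )
    return CofactorBalance(flows=flows)


def estimate_maintenance_atp(
    balance: CofactorBalance,
    mu: float,
    gam: float = DEFAULT_GAM,
    biomass_id: str | None = None,
    maintenance_id: str | None = None,
) -> MaintenanceEstimate:
    """NGAM from the ATP balance: production − metabolic consumption − gam·μ.

    *biomass_id* and *maintenance_id* name the reactions whose ATP consumption
    is excluded from the metabolic term (growth-associated demand is accounted
    by gam·μ; the dedicated hydrolysis flux is what is being estimated).  A
    negative estimate is reported as fitted and flagged.
    """
    if gam < 0:
        raise ValueError("gam must be >= 0")
    atp = balance["ATP"]
    consumption_metabolic = atp.consumption
    for excluded in (biomass_id, maintenance_id):
        if excluded is None:
            continue
        rate = atp.breakdown.get(excluded, 0.0)
        if rate < 0:
            consumption_metabolic -= -rate
    ngam = atp.production - consumption_metabolic - gam * mu
    return MaintenanceEstimate(ngam=ngam, gam=gam, mu=mu, negative=ngam < 0)


def estimate_maintenance_from_rates(
    model: MetabolicModel,
    constraints: CapacityConstraintSet,
    mu: float,
    gam: float = DEFAULT_GAM,
    maintenance_id: str = "ATPM",
    biomass_exchange_id: str | None = None,
) -> tuple[MaintenanceEstimate, FluxDistribution]:
    """Excess-ATP maintenance at measured rates.

    The classic batch-culture construction: with the measured exchange rates
    fixed as capacity constraints and growth pinned at the measured rate, the
    flux on the dedicated ATP-hydrolysis reaction is *maximized* — any ATP
    the network can still form at full oxidative-phosphorylation coupling,
    beyond biosynthesis and the growth-associated requirement, is maintenance
    energy.  (Maximizing resolves the degeneracy between phosphorylating and
    non-phosphorylating respiratory branches, which would otherwise leave the
    ATP surplus undetermined.)

    *biomass_exchange_id* names the exchange used to pin growth; when None
    the exchange carrying the biomass metabolite is located automatically.
    Returns the maintenance estimate together with the underlying flux
    distribution.
    """
    if biomass_exchange_id is None:
        biomass = model.reaction(model.biomass_id)
        produced = [m for m, c in biomass.stoichiometry.items() if c > 0]
        for ex in model.exchange_ids:
            if any(m in model.reaction(ex).stoichiometry for m in produced):
                biomass_exchange_id = ex
                break
        if biomass_exchange_id is None:
            raise ModelError("could not locate a biomass exchange reaction")
    cs = CapacityConstraintSet(entries=dict(constraints.entries))
    cs.add(biomass_exchange_id, mu)
    fd = solve_fba(model, cs, objective_id=maintenance_id)
    if not fd.optimal:
        raise ValueError(f"maintenance LP terminated with status {fd.status}")
    balance = cofactor_balance(model, fd)
    est = estimate_maintenance_atp(
        balance, mu=mu, gam=gam, biomass_id=model.biomass_id,
        maintenance_id=maintenance_id,
    )
    return est, fd
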