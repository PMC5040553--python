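"""Synthetic data generators emulating an n-heptanoic-acid stress study.

Every generator is the statistical inverse of the estimator that consumes its
output: at zero noise the estimators recover the configured ground truth
exactly, and all randomness flows from :attr:`ScenarioConfig.seed`, so equal
configurations produce identical data.

The emulated structure follows the study design the package analyses:

* exponential batch growth with the specific growth rate declining linearly
  in the acid concentration, μ(acid) = μ0 − slope·acid;
* extracellular glucose/acetate/lactate/ethanol time courses following the
  exponential-biomass closed form for a ground-truth specific-rate vector;
* feasible steady-state flux vectors of the bundled network sampled by LP
  with a randomized objective, whose exchange fluxes become the measured
  capacity constraints;
* one-color microarray intensities with multiplicative log-normal noise and
  planted log2 effects between control and stressed conditions;
* GABase assay absorbances by Beer–Lambert inversion of chosen activities,
  Poisson colony counts around a true survival frequency, and GC/MS peak
  areas proportional to true concentrations with a palmitic-acid internal
  standard.

Noise models: multiplicative log-normal for OD, intensities and peak areas
(instrument-typical), Poisson for plate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .assays import (
    BiotransformationTimeCourse,
    GadAssayRecord,
    NADPH_EPSILON_M_CM,
    PeakTable,
    SurvivalMeasurement,
)
from .expression import IntensityMatrix
from .fba import CapacityConstraintSet
from .model_core import MetabolicModel, stoichiometric_matrix
from .rates import GrowthTimeCourse

import pandas as pd

__all__ = [
    "ScenarioConfig",
    "PhenotypeData",
    "generate_growth_timecourse",
    "generate_flux_scenario",
    "generate_intensity_matrix",
    "generate_phenotype_data",
    "default_scenarios",
    "EXCHANGE_MAP",
]

#: species name → exchange reaction id of the bundled model
EXCHANGE_MAP = {
    "glucose": "EX_glc",
    "acetate": "EX_ac",
    "lactate": "EX_lac",
    "ethanol": "EX_etoh",
}

# distinct RNG stream tags so the generators are independent of call order
_STREAM_GROWTH, _STREAM_FLUX, _STREAM_EXPR, _STREAM_ASSAY = 11, 13, 17, 19


@dataclass
class ScenarioConfig:
    """Ground truth and noise levels for one simulated culture condition.

    Defaults describe an unstressed BL21(DE3)-like culture in glucose
    mineral medium; :func:`default_scenarios` builds the full design matrix
    (two strains × acid levels) with growth inhibition calibrated so the
    stressed conditions sit at roughly half-maximal growth, as in the study
    design this emulates.
    """

    seed: int = 0
    strain: str = "BL21(DE3)"
    acid_mM: float = 0.0
    mu0: float = 0.65  # h⁻¹, unstressed specific growth rate
    inhibition_slope: float = 0.117  # h⁻¹ per mM acid (linear decline)
    od0: float = 0.1
    duration_h: float = 7.0  # full exponential phase: ~46 mM glucose consumed
    n_points: int = 29  # 15-min sampling
    dcw_per_od: float = 0.4
    q_truth: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": -8.0,
            "acetate": 0.8,
            "lactate": 0.2,
            "ethanol": 0.1,
        }
    )
    c0: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": 55.5,  # 10 g/L
            "acetate": 0.0,
            "lactate": 0.0,
            "ethanol": 0.0,
        }
    )
    # noise coefficients of variation per channel
    noise_od_cv: float = 0.0
    noise_conc_cv: float = 0.0
    noise_intensity_cv: float = 0.0
    noise_peak_cv: float = 0.0
    noise_absorbance_cv: float = 0.0
    # microarray
    n_genes: int = 200
    replicates: int = 3
    de_truth: dict[str, float] = field(default_factory=dict)  # gene -> log2 effect
    flag_absent_frac: float = 0.0
    background_level: float = 20.0
    background_above_frac: float = 0.0
    # assays
    gad_truth_activity: float = 2.0  # nmol GABA·min⁻¹·mg⁻¹
    gad_replicates: int = 3
    survival_truth_pct: float = 5.0
    survival_plates: int = 3
    survival_expected_counts: float = 200.0
    poisson_counts: bool = True  # False: plate counts at their expectations
    # biotransformation (one product molecule of each species per substrate)
    substrate0_mM: float = 15.0
    yield_frac: float = 0.68
    plateau_h: float = 4.0
    biotrans_duration_h: float = 8.0
    biotrans_points: int = 17
    is_conc_mM: float = 5.0
    is_area: float = 1.0e5

    def __post_init__(self) -> None:
        if self.mu_at(self.acid_mM) < 0:
            raise ValueError(
                f"mu(acid={self.acid_mM}) < 0; scenario outside the linear range"
            )

    def mu_at(self, acid_mM: float) -> float:
        return self.mu0 - self.inhibition_slope * acid_mM

    @property
    def mu(self) -> float:
        return self.mu_at(self.acid_mM)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit median and given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_growth_timecourse(cfg: ScenarioConfig) -> GrowthTimeCourse:
    """OD600 and extracellular concentrations for one scenario.

    OD is exponential at μ(acid) with multiplicative noise; each species
    follows C(t) = C0 + (q·X0/μ)(e^{μt} − 1) for the ground-truth q.
    Concentrations are clipped at zero only if noise drives them negative.
    """
    rng = cfg.rng(_STREAM_GROWTH)
    t = np.linspace(0.0, cfg.duration_h, cfg.n_points)
    mu = cfg.mu
    od = cfg.od0 * np.exp(mu * t) * _lognoise(rng, cfg.noise_od_cv, t.shape)
    x0 = cfg.dcw_per_od * cfg.od0
    conc: dict[str, np.ndarray] = {}
    for sp, q in cfg.q_truth.items():
        c0 = cfg.c0.get(sp, 0.0)
        if mu > 0:
            series = c0 + q * x0 / mu * (np.exp(mu * t) - 1.0)
        else:
            series = c0 + q * x0 * t
        series = series * _lognoise(rng, cfg.noise_conc_cv, t.shape)
        conc[sp] = np.clip(series, 0.0, None)
    return GrowthTimeCourse(
        times=t, od600=od, concentrations=conc, dcw_per_od=cfg.dcw_per_od
    )


def generate_flux_scenario(
    model: MetabolicModel,
    cfg: ScenarioConfig,
    tolerance: float = 0.0,
    exchange_ids: list[str] | None = None,
) -> tuple[dict[str, float], CapacityConstraintSet]:
    """Sample a feasible steady-state flux vector and emit its exchange rates.

    The vector is the optimum of a random linear objective over
    {S·v = 0, lb ≤ v ≤ ub} with the glucose exchange pinned to the
    scenario's ground-truth uptake rate, so the sampled physiology matches
    the scenario.  The returned constraint set carries the sample's fluxes
    on *exchange_ids* (default: the exchanges of the measured species —
    glucose, acetate, lactate, ethanol — as in a batch-culture experiment);
    feeding it to :func:`heptflux.fba.solve_fba` must give an objective at
    least as large as the sample's biomass flux.
    """
    S = stoichiometric_matrix(model)
    rxn_ids = list(S.columns)
    rng = cfg.rng(_STREAM_FLUX)
    c = rng.normal(size=len(rxn_ids))
    bounds = []
    glc_rate = cfg.q_truth.get("glucose")
    for r in model.reactions:
        if r.id == EXCHANGE_MAP["glucose"] and glc_rate is not None:
            bounds.append((glc_rate, glc_rate))
        else:
            bounds.append((r.lb, r.ub))
    res = linprog(
        -c, A_eq=S.values, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
    )
    if res.status != 0:
        raise RuntimeError(f"flux sampling LP failed with status {res.status}")
    truth = {rid: float(v) for rid, v in zip(rxn_ids, res.x)}
    if exchange_ids is None:
        exchange_ids = [
            rid for rid in EXCHANGE_MAP.values() if rid in set(model.exchange_ids)
        ]
    constraints = CapacityConstraintSet()
    for rid in exchange_ids:
        constraints.add(rid, truth[rid], tolerance)
    return truth, constraints


_ACID_GENES = [
    "gadA", "gadB", "gadC", "gadE", "gadW", "gadX", "rpoS", "glsA", "gabT",
    "gabD", "hdeA", "hdeB", "hdeD", "slp", "hchA", "ibpA", "dnaK", "groEL",
    "cfa", "ompF", "ompC", "nuoF", "sdhB", "cyoA", "atpA", "icd", "sucA",
    "gltA", "frdA", "cydA",
]


def gene_universe(n_genes: int) -> list[str]:
    """Acid-resistance marker genes padded with null filler genes."""
    fillers = [f"y{idx:04d}" for idx in range(max(0, n_genes - len(_ACID_GENES)))]
    return _ACID_GENES[:n_genes] + fillers


def generate_intensity_matrix(cfg: ScenarioConfig) -> IntensityMatrix:
    """One-color intensities with planted log2 effects between conditions.

    Genes absent from ``de_truth`` are null.  Baseline intensities are
    log-normally spread around a few hundred a.u.; noise is multiplicative
    log-normal at ``noise_intensity_cv``; a configured fraction of cells is
    flagged A/M or given background above signal.
    """
    genes = gene_universe(cfg.n_genes)
    unknown = set(cfg.de_truth) - set(genes)
    if unknown:
        raise ValueError(f"de_truth genes outside the universe: {sorted(unknown)}")
    for frac in (cfg.flag_absent_frac, cfg.background_above_frac):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = cfg.rng(_STREAM_EXPR)
    baseline = 200.0 * rng.lognormal(0.0, 1.0, size=len(genes))
    effect = np.array([2.0 ** cfg.de_truth.get(g, 0.0) for g in genes])
    # genes with planted effects get bright baselines so that scaling them
    # never moves the chip median: the per-chip normalization then cancels
    # exactly and a zero-noise run recovers each planted log2 effect exactly
    de_idx = np.array([g in cfg.de_truth for g in genes])
    if de_idx.any():
        baseline[de_idx] = 3000.0 * rng.lognormal(0.0, 0.3, size=int(de_idx.sum()))
    samples = [f"control_{i+1}" for i in range(cfg.replicates)] + [
        f"stressed_{i+1}" for i in range(cfg.replicates)
    ]
    conditions = {
        s: ("control" if s.startswith("control") else "stressed") for s in samples
    }
    intensity = {}
    for s in samples:
        mean = baseline * (effect if conditions[s] == "stressed" else 1.0)
        intensity[s] = mean * _lognoise(rng, cfg.noise_intensity_cv, mean.shape)
    probe_ids = [f"probe_{g}" for g in genes]
    intensity_df = pd.DataFrame(intensity, index=probe_ids)
    background = pd.DataFrame(
        cfg.background_level, index=probe_ids, columns=samples, dtype=float
    )
    if cfg.background_above_frac > 0:
        lift = rng.random(background.shape) < cfg.background_above_frac
        background = background.where(~lift, intensity_df * 1.5)
    flags = pd.DataFrame("P", index=probe_ids, columns=samples)
    if cfg.flag_absent_frac > 0:
        drop = rng.random(flags.shape) < cfg.flag_absent_frac
        which = rng.choice(["A", "M"], size=flags.shape)
        flags = flags.where(~drop, which)
    probes = pd.Series(genes, index=probe_ids, name="gene")
    return IntensityMatrix(
        probes=probes,
        intensity=intensity_df,
        background=background,
        flags=flags,
        conditions=conditions,
    )


@dataclass
class PhenotypeData:
    """Assay inputs generated from known truths (kept alongside for tests)."""

    gad_records: list[GadAssayRecord]
    gad_truth_activity: float
    survival: list[SurvivalMeasurement]
    survival_truth_pct: float
    biotransformation: BiotransformationTimeCourse
    peak_tables: list[PeakTable]  # one per time point, same order as times


def generate_phenotype_data(cfg: ScenarioConfig) -> PhenotypeData:
    """GABase assay records, CFU survival measurements and GC/MS peak tables.

    * Assay absorbances invert Beer–Lambert from the configured true
      activity (0.2 mL reaction, 0.5 mg protein, 60 min incubation).
    * CFU counts are Poisson around plate expectations consistent with the
      true survival percentage; reported CFU·mL⁻¹ are dilution-corrected
      plate means.
    * The biotransformation course rises linearly to its plateau
      (yield_frac × substrate loading) at ``plateau_h`` and stays flat; both
      cleavage products share the course (1:1 stoichiometry).  Peak areas
      are proportional to concentration against the internal standard.
    """
    rng = cfg.rng(_STREAM_ASSAY)
    volume_ml, protein_mg = 0.2, 0.5
    records = []
    for _ in range(cfg.gad_replicates):
        gaba_nmol = cfg.gad_truth_activity * 60.0 * protein_mg
        nadph_um = gaba_nmol / volume_ml
        delta_a = nadph_um * 1e-6 * NADPH_EPSILON_M_CM
        delta_a *= float(_lognoise(rng, cfg.noise_absorbance_cv, ()))
        records.append(
            GadAssayRecord(
                a340_initial=0.05,
                a340_final=0.05 + delta_a,
                reaction_volume_ml=volume_ml,
                lysate_protein_mg=protein_mg,
                gad_incubation_min=60.0,
            )
        )

    survival = []
    lam_pre = cfg.survival_expected_counts
    lam_post = lam_pre * cfg.survival_truth_pct / 100.0
    # pre-stress plated at a 10x deeper dilution than post so both stay countable
    dil_pre, dil_post = 1e6, 1e5
    for _ in range(cfg.survival_plates):
        if cfg.poisson_counts:
            n_pre = rng.poisson(lam_pre)
            n_post = rng.poisson(lam_post * 10.0)  # shallower dilution, 10x counts
        else:
            n_pre, n_post = lam_pre, lam_post * 10.0
        survival.append(
            SurvivalMeasurement(cfu_pre=n_pre * dil_pre, cfu_post=n_post * dil_post)
        )

    t = np.linspace(0.0, cfg.biotrans_duration_h, cfg.biotrans_points)
    plateau = cfg.yield_frac * cfg.substrate0_mM
    product = plateau * np.minimum(t, cfg.plateau_h) / cfg.plateau_h
    substrate = cfg.substrate0_mM - product
    course = BiotransformationTimeCourse(
        times=t,
        concentrations={
            "ricinoleic_acid": substrate,
            "heptanoic_acid": product.copy(),
            "hydroxyundecenoic_acid": product.copy(),
        },
    )
    peak_tables = []
    for k in range(len(t)):
        areas = {}
        for analyte, series in course.concentrations.items():
            true_area = cfg.is_area * series[k] / cfg.is_conc_mM
            areas[analyte] = true_area * float(_lognoise(rng, cfg.noise_peak_cv, ()))
        peak_tables.append(
            PeakTable(areas=areas, is_area=cfg.is_area, is_conc_mm=cfg.is_conc_mM)
        )
    return PhenotypeData(
        gad_records=records,
        gad_truth_activity=cfg.gad_truth_activity,
        survival=survival,
        survival_truth_pct=cfg.survival_truth_pct,
        biotransformation=course,
        peak_tables=peak_tables,
    )


def default_scenarios(seed: int = 0) -> list[ScenarioConfig]:
    """The emulated design matrix: two strains across acid concentrations.

    BL21(DE3)-like cultures lose growth fast (about half-maximal at 3 mM);
    MG1655-like cultures are more tolerant (half-maximal near 10 mM) and
    carry the glutamate-decarboxylase expression response in ``de_truth``.
    """
    scenarios = []
    strains = {
        # strain: (mu0, slope, acid levels, stressed q_truth scale, de response)
        "BL21(DE3)": (0.65, 0.117, [0.0, 3.0, 5.0], True, False),
        "MG1655": (0.70, 0.042, [0.0, 5.0, 10.0], False, True),
    }
    for i, (strain, (mu0, slope, acids, scale_q, gdar)) in enumerate(strains.items()):
        for j, acid in enumerate(acids):
            q = {"glucose": -8.0, "acetate": 0.8, "lactate": 0.2, "ethanol": 0.1}
            if scale_q and acid >= 5.0:
                # stressed BL21(DE3): glucose uptake doubles, acetate x18
                q["glucose"] *= 2.0
                q["acetate"] *= 18.0
            de = {}
            if acid > 0:
                de = {"dnaK": 2.5, "groEL": 2.3, "nuoF": 2.1, "sdhB": 2.0}
                if gdar:
                    de.update(
                        {"gadA": 2.27, "gadB": 2.28, "gadC": 2.04, "gadE": 1.97,
                         "glsA": 2.90, "hchA": 1.78, "ibpA": 1.36}
                    )
            scenarios.append(
                ScenarioConfig(
                    seed=seed + 100 * i + j,
                    strain=strain,
                    acid_mM=acid,
                    mu0=mu0,
                    inhibition_slope=slope,
                    q_truth=q,
                    de_truth=de,
                    noise_od_cv=0.05,
                    noise_conc_cv=0.05,
                    noise_intensity_cv=0.2,
                    noise_peak_cv=0.05,
                    noise_absorbance_cv=0.05,
                    gad_truth_activity=2.0 if gdar else 0.2,
                    survival_truth_pct=50.0 if gdar else 5.0,
                )
            )
    return scenarios
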