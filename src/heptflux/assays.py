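"""Phenotype assay quantification.

Four small calculators used around acid-stress physiology experiments:

* **GadA/B (glutamate decarboxylase) activity** from the GABase-coupled
  readout: GABA formed during the decarboxylase incubation is oxidised with
  1:1 stoichiometry to NADPH, read as A340 via Beer–Lambert
  (ε = 6220 M⁻¹cm⁻¹ for NADPH).
* **Survival frequency** after an acid challenge,
  100 · CFU(post stress)/CFU(prior stress).
* **Internal-standard GC/MS quantification**: analyte concentration from the
  analyte-to-standard peak-area ratio, the known standard concentration
  (palmitic acid here) and a response factor.
* **Biotransformation conversion yield and product-formation rate** on a
  molar basis against the substrate loading.

All calculators are pure functions of their records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GadAssayRecord",
    "GadActivity",
    "SurvivalMeasurement",
    "PeakTable",
    "BiotransformationTimeCourse",
    "nadph_from_absorbance",
    "gad_specific_activity",
    "survival_frequency",
    "quantify_by_internal_standard",
    "conversion_yield",
    "product_formation_rate",
    "bradford_protein",
    "NADPH_EPSILON_M_CM",
]

#: molar extinction coefficient of NADPH at 340 nm, M⁻¹·cm⁻¹
NADPH_EPSILON_M_CM = 6220.0


@dataclass
class GadAssayRecord:
    """One GABase-coupled decarboxylase assay reading."""

    a340_initial: float
    a340_final: float
    reaction_volume_ml: float
    lysate_protein_mg: float  # protein in the decarboxylase reaction (Bradford)
    path_cm: float = 1.0
    gad_incubation_min: float = 60.0
    dilution_factor: float = 1.0  # fold-dilution of the GABA sample before GABase

    def __post_init__(self) -> None:
        if self.a340_initial < 0 or self.a340_final < 0:
            raise ValueError("absorbances must be non-negative")
        if self.lysate_protein_mg <= 0:
            raise ValueError("protein mass must be positive")
        if self.reaction_volume_ml <= 0:
            raise ValueError("reaction volume must be positive")


@dataclass
class GadActivity:
    """Specific GadA/B activity, nmol GABA·min⁻¹·mg protein⁻¹."""

    specific_activity: float
    negative: bool = False  # blank exceeded signal; reported, not clamped


@dataclass
class SurvivalMeasurement:
    cfu_pre: float  # CFU·mL⁻¹, dilution-corrected
    cfu_post: float

    @property
    def survival_pct(self) -> float:
        return survival_frequency(self.cfu_pre, self.cfu_post)


@dataclass
class PeakTable:
    """GC/MS peak areas with a palmitic-acid internal standard."""

    areas: dict[str, float]  # analyte -> peak area, a.u.
    is_area: float  # internal standard peak area
    is_conc_mm: float  # internal standard concentration, mM
    response_factors: dict[str, float] = field(default_factory=dict)  # default 1.0

    def __post_init__(self) -> None:
        if self.is_area <= 0:
            raise ValueError("internal standard peak area must be positive")
        if any(a < 0 for a in self.areas.values()):
            raise ValueError("peak areas must be non-negative")


@dataclass
class BiotransformationTimeCourse:
    times: np.ndarray  # h
    concentrations: dict[str, np.ndarray]  # analyte -> mM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for k, v in self.concentrations.items():
            v = np.asarray(v, dtype=float)
            if len(v) != len(self.times):
                raise ValueError(f"series {k!r} length mismatch")
            self.concentrations[k] = v


def nadph_from_absorbance(
    delta_a340: float, path_cm: float = 1.0, epsilon: float = NADPH_EPSILON_M_CM
) -> float:
    """NADPH concentration (μM) from an A340 difference via Beer–Lambert."""
    if path_cm <= 0 or epsilon <= 0:
        raise ValueError("path length and extinction coefficient must be positive")
    return delta_a340 / (epsilon * path_cm) * 1e6


def gad_specific_activity(rec: GadAssayRecord) -> GadActivity:
    """Specific activity from one assay record.

    GABA (nmol) = NADPH (μM) × reaction volume (mL) × dilution factor, using
    the 1:1 GABA:NADPH stoichiometry of the GABase reaction; activity divides
    by the decarboxylase incubation time and the protein mass.  A negative
    ΔA340 (blank above signal) propagates to a negative activity, flagged.
    """
    delta = rec.a340_final - rec.a340_initial
    nadph_um = nadph_from_absorbance(abs(delta), rec.path_cm) * np.sign(delta)
    gaba_nmol = nadph_um * rec.reaction_volume_ml * rec.dilution_factor
    activity = gaba_nmol / rec.gad_incubation_min / rec.lysate_protein_mg
    return GadActivity(specific_activity=float(activity), negative=activity < 0)


def survival_frequency(cfu_pre: float, cfu_post: float) -> float:
    """survival (%) = CFU(post stress) / CFU(prior stress) × 100."""
    if cfu_pre <= 0:
        raise ValueError("cfu_pre must be positive")
    return 100.0 * cfu_post / cfu_pre


def quantify_by_internal_standard(pt: PeakTable, analyte: str) -> float:
    """Analyte concentration (mM): (area/IS area) · IS conc / response factor."""
    if analyte not in pt.areas:
        raise KeyError(f"no peak area recorded for analyte {analyte!r}")
    rf = pt.response_factors.get(analyte, 1.0)
    if rf <= 0:
        raise ValueError(f"response factor for {analyte!r} must be positive")
    return (pt.areas[analyte] / pt.is_area) * pt.is_conc_mm / rf


def conversion_yield(product_mm: float, substrate0_mm: float) -> float:
    """Molar conversion yield (%) of a product against the substrate loading.

    The emulated pathway cleaves one substrate molecule into one molecule of
    each product species, so the yield of either product is product/substrate.
    """
    if substrate0_mm <= 0:
        raise ValueError("substrate loading must be positive")
    return 100.0 * product_mm / substrate0_mm


def product_formation_rate(
    tc: BiotransformationTimeCourse, analyte: str, interval: tuple[float, float]
) -> float:
    """Least-squares slope (mM·h⁻¹) of *analyte* over *interval*."""
    t0, t1 = interval
    if t0 < tc.times[0] - 1e-12 or t1 > tc.times[-1] + 1e-12:
        raise ValueError("interval outside the time course")
    mask = (tc.times >= t0 - 1e-12) & (tc.times <= t1 + 1e-12)
    if mask.sum() < 2:
        raise ValueError("interval must contain at least 2 points")
    slope, _ = np.polyfit(tc.times[mask], tc.concentrations[analyte][mask], 1)
    return float(slope)


def bradford_protein(
    standards_mg_ml: np.ndarray, standards_a595: np.ndarray, sample_a595: float
) -> float:
    """Protein concentration (mg/mL) from a linear Bradford standard curve."""
    slope, intercept = np.polyfit(
        np.asarray(standards_mg_ml, float), np.asarray(standards_a595, float), 1
    )
    if slope <= 0:
        raise ValueError("standard curve has non-positive slope")
    return (sample_a595 - intercept) / slope
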