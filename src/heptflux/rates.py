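"""Specific growth- and exchange-rate estimation from batch-culture time courses.

During unlimited exponential growth, biomass follows X(t) = X0·e^{μt} and an
extracellular species consumed or produced at a constant biomass-specific rate
q (mmol·gDCW⁻¹·h⁻¹) follows the closed form

    C(t) = C0 + (q·X0/μ)·(e^{μt} − 1),

with q < 0 for consumption (uptake) and q > 0 for production, matching the
exchange-flux sign convention of :mod:`heptflux.model_core`.  μ is estimated
as the least-squares slope of ln(OD600) against time over a user-declared
exponential window; q by linear least squares on the closed form (which is
linear in C0 and q once μ is known).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthTimeCourse",
    "SpecificRates",
    "fit_specific_growth_rate",
    "fit_specific_rate",
    "estimate_rates",
    "read_timecourse_tsv",
    "write_timecourse_tsv",
]

#: default dry-cell-weight conversion, g DCW per litre per OD600 unit
DEFAULT_DCW_PER_OD = 0.4


@dataclass
class GrowthTimeCourse:
    """A batch-culture time course: OD600 plus extracellular concentrations (mM)."""

    times: np.ndarray  # h, strictly increasing
    od600: np.ndarray  # dimensionless, >= 0
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    dcw_per_od: float = DEFAULT_DCW_PER_OD  # g·L⁻¹ per OD600 unit

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.od600):
            raise ValueError("times and od600 must be 1-D series of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError("od600 must be non-negative")
        for sp, series in self.concentrations.items():
            series = np.asarray(series, dtype=float)
            if len(series) != len(self.times):
                raise ValueError(f"concentration series {sp!r} length mismatch")
            if np.any(series < -1e-12):
                raise ValueError(f"concentration series {sp!r} has negative values")
            self.concentrations[sp] = series

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window must satisfy t_start < t_end")
        return (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)


@dataclass
class SpecificRates:
    """Growth rate μ (h⁻¹) and specific exchange rates q (mmol·gDCW⁻¹·h⁻¹)."""

    mu: float
    q: dict[str, float]
    window: tuple[float, float]
    declining: bool = False  # set when the fitted mu is negative

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "q": dict(self.q),
            "window": list(self.window),
            "declining": self.declining,
        }


def fit_specific_growth_rate(
    tc: GrowthTimeCourse, window: tuple[float, float]
) -> float:
    """Least-squares slope of ln(OD600) vs time over *window* (μ, h⁻¹)."""
    mask = tc.window_mask(window)
    if mask.sum() < 3:
        raise ValueError(f"window {window} contains {int(mask.sum())} points; need >= 3")
    od = tc.od600[mask]
    if np.any(od <= 0):
        raise ValueError("all OD600 values in the window must be positive")
    slope, _ = np.polyfit(tc.times[mask], np.log(od), 1)
    return float(slope)


def _x0(tc: GrowthTimeCourse, window: tuple[float, float], mu: float) -> float:
    """Biomass (gDCW/L) at the window start, from the log-linear OD fit."""
    mask = tc.window_mask(window)
    t = tc.times[mask]
    slope, intercept = np.polyfit(t, np.log(tc.od600[mask]), 1)
    return tc.dcw_per_od * float(np.exp(intercept + slope * t[0]))


def fit_specific_rate(
    tc: GrowthTimeCourse,
    species: str,
    mu: float,
    window: tuple[float, float],
) -> float:
    """Specific consumption/production rate of *species* over *window*.

    Fits C(t) = C0 + (q·X0/μ)(e^{μ(t−t0)} − 1) by linear least squares; the
    returned q is negative for consumed species (uptake) and positive for
    produced ones.
    """
    if mu <= 0:
        raise ValueError("fit_specific_rate requires mu > 0 from the same window")
    if species not in tc.concentrations:
        raise KeyError(f"no concentration series for species {species!r}")
    mask = tc.window_mask(window)
    if mask.sum() < 2:
        raise ValueError(f"window {window} contains {int(mask.sum())} points; need >= 2")
    t = tc.times[mask]
    conc = tc.concentrations[species][mask]
    x0 = _x0(tc, window, mu)
    growth_factor = (np.exp(mu * (t - t[0])) - 1.0) * x0 / mu
    design = np.column_stack([np.ones_like(t), growth_factor])
    (c0, q), *_ = np.linalg.lstsq(design, conc, rcond=None)
    return float(q)


def estimate_rates(
    tc: GrowthTimeCourse,
    window: tuple[float, float],
    species: list[str] | None = None,
) -> SpecificRates:
    """Fit μ and every requested specific rate over one exponential window.

    A declining culture (fitted μ ≤ 0) is reported as fitted, flagged via
    ``declining``, and its q values are left empty (the closed form does not
    apply).
    """
    mu = fit_specific_growth_rate(tc, window)
    if species is None:
        species = sorted(tc.concentrations)
    if mu <= 0:
        return SpecificRates(mu=mu, q={}, window=window, declining=True)
    q = {sp: fit_specific_rate(tc, sp, mu, window) for sp in species}
    return SpecificRates(mu=mu, q=q, window=window)


# ---------------------------------------------------------------------------
# IO: time-course TSV with columns time_h, od600, then one column per species


def read_timecourse_tsv(path, dcw_per_od: float = DEFAULT_DCW_PER_OD) -> GrowthTimeCourse:
    df = pd.read_csv(path, sep="\t")
    if "time_h" not in df.columns or "od600" not in df.columns:
        raise ValueError(f"{path}: expected columns time_h and od600")
    species = [c for c in df.columns if c not in ("time_h", "od600")]
    return GrowthTimeCourse(
        times=df["time_h"].to_numpy(),
        od600=df["od600"].to_numpy(),
        concentrations={sp: df[sp].to_numpy() for sp in species},
        dcw_per_od=dcw_per_od,
    )


def write_timecourse_tsv(tc: GrowthTimeCourse, path) -> None:
    df = pd.DataFrame({"time_h": tc.times, "od600": tc.od600})
    for sp, series in tc.concentrations.items():
        df[sp] = series
    df.to_csv(path, sep="\t", index=False)
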