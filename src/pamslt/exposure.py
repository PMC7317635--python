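"""Physical-activity exposure distributions, relative risks, and population impact fractions.

Exposure is measured in MVPA MET-minutes per week (moderate-to-vigorous
physical activity, metabolic-equivalent weighted). The population
distribution is categorical: ordered bins with midpoints and proportions,
as produced by survey instruments that ask about weekly activity. An
intervention shifts part of the population's exposure upward; combining
the shifted ("counterfactual") distribution with a protective relative
risk curve yields a population impact fraction (PIF), the proportional
reduction in disease incidence. Disease responses to exposure change are
lagged: the effective PIF in a given year is the unweighted mean of the
annual PIFs over a disease-specific window of past years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExposureDistribution",
    "RelativeRiskFunction",
    "LagSpec",
    "steps_to_met_minutes",
    "met_minutes_to_activity_hours",
    "shift_distribution",
    "compute_pif",
    "lag_pif_series",
    "effective_pif_series",
]

#: standard steps-per-day to MET-minute conversion (steps per MVPA-MET-minute)
STEPS_PER_MET_MINUTE = 34.5

#: conventional MET values for activity intensities
MET_BRISK_WALKING = 3.0
MET_MODERATE = 4.5
MET_VIGOROUS = 6.5


class ExposureError(ValueError):
    """Invalid exposure distribution or incompatible bin structures."""


@dataclass(frozen=True)
class ExposureDistribution:
    """Categorical distribution of weekly MVPA MET-minutes.

    Bins are ordered, non-overlapping intervals ``[lower, upper)``; the top
    bin may be unbounded (``upper = inf``). ``proportion`` is the population
    mass per bin (non-negative, summing to one).
    """

    lower: np.ndarray
    upper: np.ndarray
    midpoint: np.ndarray
    proportion: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lower", "upper", "midpoint", "proportion"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.lower.size
        if not (self.upper.size == self.midpoint.size == self.proportion.size == n) or n == 0:
            raise ExposureError("bin arrays must be non-empty and of equal length")
        if np.any(self.upper <= self.lower):
            raise ExposureError("each bin must satisfy lower < upper")
        if np.any(self.lower[1:] < self.upper[:-1] - 1e-12):
            raise ExposureError("bins must be ordered and non-overlapping")
        if np.any(self.proportion < -1e-15):
            raise ExposureError("bin proportions must be non-negative")
        total = float(self.proportion.sum())
        if abs(total - 1.0) > 1e-6:
            raise ExposureError(f"bin proportions must sum to 1 (got {total!r})")

    @property
    def n_bins(self) -> int:
        return int(self.lower.size)

    def mean(self) -> float:
        """Mean exposure, evaluating each bin at its midpoint."""
        return float(np.dot(self.midpoint, self.proportion))

    def same_bins(self, other: "ExposureDistribution") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.allclose(self.lower, other.lower)
            and np.allclose(self.upper, other.upper, equal_nan=True)
        )

    def fraction_below(self, threshold: float) -> float:
        """Population fraction with exposure below ``threshold``.

        Bins entirely below the threshold count fully; a straddling bin
        contributes proportionally to the covered width (uniform-within-bin).
        For an unbounded top bin the effective width is taken symmetric
        around its midpoint.
        """
        frac = 0.0
        for lo, hi, mid, p in zip(self.lower, self.upper, self.midpoint, self.proportion):
            eff_hi = 2.0 * mid - lo if np.isinf(hi) else hi
            if eff_hi <= threshold:
                frac += p
            elif lo < threshold:
                frac += p * (threshold - lo) / (eff_hi - lo)
        return float(frac)

    def replace_proportions(self, proportion: np.ndarray) -> "ExposureDistribution":
        return ExposureDistribution(self.lower, self.upper, self.midpoint, proportion)


@dataclass(frozen=True)
class RelativeRiskFunction:
    """Log-linear protective dose-response for one disease.

    ``RR(e) = max(floor, exp(-log_slope * (e - anchor)))`` — anchored at
    RR = 1 for the reference exposure (default: the zero-activity bin),
    non-increasing in exposure, bounded below by ``floor``.
    """

    disease: str
    log_slope: float  # per MET-min/week, >= 0 for a protective exposure
    floor: float = 0.5
    anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.log_slope < 0:
            raise ExposureError("log_slope must be >= 0 (protective exposure)")
        if not (0.0 < self.floor <= 1.0):
            raise ExposureError("floor must be in (0, 1]")

    def __call__(self, exposure) -> np.ndarray:
        e = np.asarray(exposure, dtype=float)
        rr = np.exp(-self.log_slope * (e - self.anchor))
        return np.maximum(rr, self.floor)


@dataclass(frozen=True)
class LagSpec:
    """Lag window for a disease's response to exposure change.

    Offsets are inclusive integer years: the effective PIF at year ``t``
    averages annual PIFs at years ``t - max_years .. t - min_years``.
    Cardio-metabolic diseases respond over the past 0-5 years; cancers
    over the previous 10-30 years.
    """

    disease: str
    min_years: int
    max_years: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_years < self.max_years):
            raise ExposureError("lag window requires 0 <= min_years < max_years")

    @property
    def n_terms(self) -> int:
        return self.max_years - self.min_years + 1


def steps_to_met_minutes(steps_per_day: float, steps_per_met_min: float = STEPS_PER_MET_MINUTE) -> float:
    """Convert daily step counts to weekly MVPA MET-minutes."""
    if steps_per_met_min <= 0:
        raise ValueError("steps_per_met_min must be positive")
    if steps_per_day < 0:
        raise ValueError("steps_per_day must be non-negative")
    return steps_per_day * 7.0 / steps_per_met_min


def met_minutes_to_activity_hours(met_min_per_week: float, met_value: float = MET_BRISK_WALKING) -> float:
    """Express weekly MET-minutes as hours per week of an activity with the given MET value."""
    if met_value <= 0:
        raise ValueError("met_value must be positive")
    return met_min_per_week / met_value / 60.0


def shift_distribution(
    dist: ExposureDistribution, delta: float, affected_fraction: float
) -> ExposureDistribution:
    """Shift a fraction of every bin's mass upward by ``delta`` MET-min/week.

    The affected mass of each bin is reassigned to the bin containing
    (midpoint + delta); the top bin absorbs any overflow. Unaffected mass
    is unchanged and total mass is conserved exactly.
    """
    if delta < 0:
        raise ValueError("negative exposure shifts are not supported")
    if not (0.0 <= affected_fraction <= 1.0):
        raise ValueError("affected_fraction must be in [0, 1]")
    if affected_fraction == 0.0 or delta == 0.0:
        return dist
    new_prop = dist.proportion * (1.0 - affected_fraction)
    targets = np.searchsorted(dist.lower, dist.midpoint + delta, side="right") - 1
    targets = np.clip(targets, 0, dist.n_bins - 1)
    np.add.at(new_prop, targets, dist.proportion * affected_fraction)
    return dist.replace_proportions(new_prop)


def compute_pif(
    bau: ExposureDistribution, cf: ExposureDistribution, rr: RelativeRiskFunction
) -> float:
    """Population impact fraction of moving from ``bau`` to ``cf`` exposure.

    ``PIF = (sum p_i RR_i - sum p'_i RR_i) / sum p_i RR_i`` with the
    relative risk evaluated at bin midpoints. Positive when the
    counterfactual shifts mass toward lower-risk (higher-exposure) bins.
    """
    if not bau.same_bins(cf):
        raise ExposureError("BAU and counterfactual distributions must share bin structure")
    rr_vals = rr(bau.midpoint)
    if np.all(rr_vals == rr_vals[0]):
        return 0.0  # constant RR: exactly no impact, independent of the shift
    mean_rr_bau = float(np.dot(bau.proportion, rr_vals))
    if mean_rr_bau <= 0:
        raise ExposureError("mean relative risk under BAU must be positive")
    mean_rr_cf = float(np.dot(cf.proportion, rr_vals))
    return (mean_rr_bau - mean_rr_cf) / mean_rr_bau


def lag_pif_series(annual_pifs, lag: LagSpec, year: int) -> float:
    """Effective PIF at ``year``: mean annual PIF over the lag window.

    ``annual_pifs`` is indexed from the intervention start (year 0); years
    outside the defined series contribute PIF 0 (zero-padding), so the
    window always averages ``lag.n_terms`` values.
    """
    if year < 0:
        raise ValueError("year must be non-negative")
    pifs = np.asarray(annual_pifs, dtype=float)
    total = 0.0
    for k in range(lag.min_years, lag.max_years + 1):
        idx = year - k
        if 0 <= idx < pifs.size:
            total += pifs[idx]
    return total / lag.n_terms


def effective_pif_series(annual_pifs, lag: LagSpec, horizon: int) -> np.ndarray:
    """Vector of effective (lag-averaged) PIFs for years ``0..horizon-1``."""
    return np.array([lag_pif_series(annual_pifs, lag, t) for t in range(horizon)])
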