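"""Mass-media campaign intervention pathway.

A one-off national mass-media campaign promotes high-quality physical
activity smartphone apps to adults (default ages 15-79). The pathway from
campaign to exposure change is a product of four proportions: awareness
of the campaign, app download, app use (>= 7 days), and adherence
(weighted annual average). Those reached gain a fixed increment of weekly
MVPA MET-minutes, waning within the year: the effect lasts
``effect_duration`` years (1 for the base case; 5 for the maintenance
scenario) and the campaign cost falls entirely in year 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Mapping, Tuple

import numpy as np

from .exposure import ExposureDistribution, shift_distribution

__all__ = [
    "InterventionSpec",
    "effective_reach",
    "affected_fraction_and_delta",
    "build_counterfactual_exposures",
    "intervention_cost_stream",
]


class InterventionError(ValueError):
    """Invalid intervention specification."""


@dataclass(frozen=True)
class InterventionSpec:
    """Central pathway parameters for the app-promotion campaign.

    Defaults are the base-case central values: 77.9% awareness, 31%
    download, 16% use, 15% adherence, +285 MET-min/week for adherers,
    NZ$2,883,000 total cost, eligibility 15-79 years, one-year effect.
    ``adherence_mode`` chooses whether adherence scales the affected
    population fraction (default) or the effect size.
    """

    awareness: float = 0.779
    download: float = 0.31
    use: float = 0.16
    adherence: float = 0.15
    effect_met_min: float = 285.0
    cost_total: float = 2_883_000.0
    eligible_ages: Tuple[int, int] = (15, 79)
    effect_duration: int = 1
    adherence_mode: str = "fraction"

    def __post_init__(self) -> None:
        for name in ("awareness", "download", "use", "adherence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InterventionError(f"{name} must be a proportion in [0, 1]")
        if self.effect_met_min < 0:
            raise InterventionError("effect_met_min must be non-negative")
        if self.cost_total < 0:
            raise InterventionError("cost_total must be non-negative")
        if self.effect_duration < 1:
            raise InterventionError("effect_duration must be at least 1 year")
        if self.eligible_ages[0] >= self.eligible_ages[1]:
            raise InterventionError("eligible_ages must be an increasing (lo, hi) pair")
        if self.adherence_mode not in ("fraction", "effect"):
            raise InterventionError("adherence_mode must be 'fraction' or 'effect'")


def effective_reach(spec: InterventionSpec) -> float:
    """Proportion of eligible adults receiving the physical-activity effect.

    The product of the four pathway steps: awareness x download x use x
    adherence. Any broken step (zero) breaks the whole pathway.
    """
    return spec.awareness * spec.download * spec.use * spec.adherence


def affected_fraction_and_delta(spec: InterventionSpec) -> Tuple[float, float]:
    """Resolve the adherence convention into (affected fraction, MET-min shift)."""
    if spec.adherence_mode == "fraction":
        return effective_reach(spec), spec.effect_met_min
    return (
        spec.awareness * spec.download * spec.use,
        spec.effect_met_min * spec.adherence,
    )


def _band_eligible(band: Tuple[int, int], eligible: Tuple[int, int]) -> bool:
    lo, hi = band
    return lo >= eligible[0] and (hi - 1) <= eligible[1]


def build_counterfactual_exposures(
    exposure_bau: Mapping[Tuple[str, str, Tuple[int, int]], ExposureDistribution],
    spec: InterventionSpec,
    horizon: int,
) -> Dict[Tuple[str, str, Tuple[int, int]], Dict[int, ExposureDistribution]]:
    """Year-indexed counterfactual exposure distributions per stratum band.

    Eligible-age bands are shifted for years ``0..effect_duration-1``;
    every later year and every ineligible band stays at BAU (and is simply
    omitted from the returned mapping).
    """
    eligible_bands = [k for k in exposure_bau if _band_eligible(k[2], spec.eligible_ages)]
    if not eligible_bands:
        raise InterventionError(
            f"eligible age range {spec.eligible_ages} matches no exposure band"
        )
    frac, delta = affected_fraction_and_delta(spec)
    out: Dict[Tuple[str, str, Tuple[int, int]], Dict[int, ExposureDistribution]] = {}
    for key in eligible_bands:
        shifted = shift_distribution(exposure_bau[key], delta, frac)
        out[key] = {y: shifted for y in range(min(spec.effect_duration, horizon))}
    return out


def intervention_cost_stream(spec: InterventionSpec, horizon: int) -> np.ndarray:
    """Campaign cost by year: the full cost in year 0, zero thereafter."""
    stream = np.zeros(horizon)
    stream[0] = spec.cost_total
    return stream
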