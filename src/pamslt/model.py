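"""Prepared model bundle: synthetic inputs + cached BAU, run per intervention spec.

The business-as-usual scenario is independent of intervention parameters,
so a bundle computes it once and reuses it across scenario analyses and
Monte Carlo draws; only the intervention scenario and the costing are
recomputed per parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

from .cea import CeaResult, equity_adjust, run_cea
from .intervention import InterventionSpec, build_counterfactual_exposures
from .lifetable import RunOutput, run_mslt
from .synth import SyntheticInputs, default_lag_specs

__all__ = ["ModelBundle", "prepare_bundle"]


@dataclass
class ModelBundle:
    """Everything needed to evaluate one intervention parameter set."""

    inputs: SyntheticInputs
    discount_rate: float = 0.03
    half_cycle: bool = False
    equity: bool = False
    _population: dict = field(default_factory=dict, repr=False)
    _disease_rates: dict = field(default_factory=dict, repr=False)
    _bau_cache: dict = field(default_factory=dict, repr=False)
    _init_prev_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        demog = self.inputs.demography
        if self.equity:
            demog = equity_adjust(demog)
        from .lifetable import population_from_frame

        self._population = population_from_frame(demog)
        self._disease_rates = self.inputs.disease_rates()

    def run_model(self, spec: InterventionSpec) -> RunOutput:
        horizon = next(iter(self._population.values())).n_ages
        exposure_cf = build_counterfactual_exposures(self.inputs.exposure, spec, horizon)
        return run_mslt(
            self._population,
            self._disease_rates,
            self.inputs.exposure,
            exposure_cf,
            self.inputs.rr_funcs,
            default_lag_specs(),
            self.inputs.spec.age_band_edges,
            half_cycle=self.half_cycle,
            bau_cache=self._bau_cache,
            init_prev_cache=self._init_prev_cache,
        )

    def run(self, spec: InterventionSpec, discount_rate: Optional[float] = None) -> CeaResult:
        output = self.run_model(spec)
        return run_cea(
            output,
            self.inputs.costs,
            self.inputs.unrelated,
            spec,
            discount_rate=self.discount_rate if discount_rate is None else discount_rate,
        )


def prepare_bundle(
    inputs: SyntheticInputs,
    discount_rate: float = 0.03,
    half_cycle: bool = False,
    equity: bool = False,
) -> ModelBundle:
    return ModelBundle(inputs, discount_rate=discount_rate, half_cycle=half_cycle, equity=equity)
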