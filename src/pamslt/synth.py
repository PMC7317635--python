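"""Synthetic input generator for the multistate life table model.

Generates an internally consistent stand-in for the national input data
the model needs: a closed adult-plus-children population stratified by
sex and ethnicity (an "indigenous" group with elevated background
mortality and a reference "other" group) with all-cause mortality and
morbidity (pYLD) by single year of age; incidence, case fatality and
(cancers only) remission rates for five physical-activity-related
diseases; phase-specific disease treatment costs and per-capita
"unrelated" annual health-system costs; a weekly MVPA MET-minute
exposure distribution calibrated so ~42% of adults fall below the
150-minute (450 MET-min at MET 3.0) activity guideline; and protective
log-linear relative-risk curves per disease.

Everything is deterministic given the scenario seed: the same
(spec, scenario) pair yields byte-identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .exposure import ExposureDistribution, LagSpec, RelativeRiskFunction
from .lifetable import (
    DiseaseRates,
    disease_rates_from_frame,
    population_from_frame,
    run_disease_lifetable,
)

__all__ = [
    "StrataSpec",
    "SyntheticScenario",
    "SyntheticInputs",
    "DiseaseDefinition",
    "DISEASES",
    "ConfigurationError",
    "CalibrationError",
    "GenerationError",
    "generate_demography",
    "generate_disease_epi",
    "generate_pa_distribution",
    "generate_costs_and_rr",
    "generate_inputs",
    "default_lag_specs",
    "audit_disease_mortality",
]

SCHEMA_VERSION = "pamslt-synth/1"

#: fixed exposure bin edges in MET-min/week (top bin unbounded)
EXPOSURE_BIN_EDGES = (0.0, 1.0, 150.0, 300.0, 600.0, 1200.0, 2400.0, 4800.0, math.inf)
EXPOSURE_BIN_MIDPOINTS = (0.0, 75.0, 225.0, 450.0, 900.0, 1800.0, 3600.0, 6000.0)


class ConfigurationError(ValueError):
    """Invalid strata or scenario configuration."""


class CalibrationError(RuntimeError):
    """Exposure calibration failed for a stratum."""


class GenerationError(RuntimeError):
    """Generated rates remained inconsistent after damped retries."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class StrataSpec:
    """Population stratification: 5-year age bands covering [0, 110), two sexes, two ethnicities."""

    age_band_edges: Tuple[int, ...] = tuple(range(0, 115, 5))
    sexes: Tuple[str, ...] = ("male", "female")
    ethnicities: Tuple[str, ...] = ("indigenous", "other")
    adult_age: int = 15

    def __post_init__(self) -> None:
        edges = self.age_band_edges
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError("age band edges must be strictly increasing")
        if edges[0] != 0 or edges[-1] != 110:
            raise ConfigurationError("age bands must cover [0, 110)")
        if not self.sexes or not self.ethnicities:
            raise ConfigurationError("at least one sex and one ethnicity required")

    @property
    def terminal_age(self) -> int:
        return self.age_band_edges[-1]

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.terminal_age)

    def bands(self) -> List[Tuple[int, int]]:
        e = self.age_band_edges
        return list(zip(e[:-1], e[1:]))

    def adult_bands(self) -> List[Tuple[int, int]]:
        return [b for b in self.bands() if b[0] >= self.adult_age]

    def band_of(self, age: int) -> Tuple[int, int]:
        for lo, hi in self.bands():
            if lo <= age < hi:
                return (lo, hi)
        raise ConfigurationError(f"age {age} outside the band structure")

    def strata(self) -> List[Tuple[str, str]]:
        return [(s, e) for s in self.sexes for e in self.ethnicities]


@dataclass(frozen=True)
class MortalityParams:
    """Gompertz-Makeham hazard with stratum multipliers: mu(a) = a0 + b*exp(theta*a)."""

    makeham_a: float = 5e-4
    gompertz_b: float = 3e-5
    gompertz_theta: float = 0.095
    indigenous_multiplier: float = 1.5
    male_multiplier: float = 1.2


@dataclass(frozen=True)
class MorbidityParams:
    """Quadratic pYLD curve: pyld(a) = base + slope * (a/110)^2, times ethnicity multiplier."""

    base: float = 0.03
    slope: float = 0.22
    indigenous_multiplier: float = 1.2


@dataclass(frozen=True)
class PaParams:
    """Mixture model for exposure: point mass at zero + lognormal, calibrated per stratum."""

    p_zero: float = 0.10
    sigma: float = 1.0
    target_inactive: float = 0.42
    inactive_threshold: float = 450.0  # 150 min/week at MET 3.0
    stratum_jitter: float = 0.015
    max_iter: int = 100


@dataclass(frozen=True)
class RrParams:
    """Global relative-risk shape controls; scale=0 turns all RRs to 1 (null effect)."""

    scale: float = 1.0
    floor: float = 0.5


@dataclass(frozen=True)
class CostParams:
    scale: float = 1.0
    unrelated_base: float = 1400.0  # NZ$ per capita per year at age 0
    unrelated_growth: float = 0.022  # exponential growth per year of age


@dataclass(frozen=True)
class SyntheticScenario:
    """All knobs of the synthetic world, including the master seed."""

    seed: int = 0
    population_size: float = 4_400_000.0
    indigenous_share: float = 0.15
    mortality: MortalityParams = field(default_factory=MortalityParams)
    morbidity: MorbidityParams = field(default_factory=MorbidityParams)
    pa: PaParams = field(default_factory=PaParams)
    rr: RrParams = field(default_factory=RrParams)
    costs: CostParams = field(default_factory=CostParams)

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ConfigurationError("population_size must be positive")
        if not (0.0 < self.indigenous_share < 1.0):
            raise ConfigurationError("indigenous_share must be in (0, 1)")


def _rng(scenario: SyntheticScenario, table_id: int) -> np.random.Generator:
    """Independent, order-insensitive stream per output table."""
    return np.random.default_rng(np.random.SeedSequence([int(scenario.seed), table_id]))


# ---------------------------------------------------------------------------
# disease registry


@dataclass(frozen=True)
class DiseaseDefinition:
    """Shape parameters for one disease's synthetic epidemiology and costs."""

    name: str
    female_only: bool
    is_cancer: bool
    incidence_scale: float  # annual rate at onset age
    incidence_slope: float  # exponential growth per year of age
    onset_age: int
    fatality_base: float
    fatality_age_slope: float  # relative increase per year above age 40
    remission: float  # annual, cancers only
    disability_weight: float
    rr_log_slope: float  # protective log-RR per MET-min/week
    cost_first_year: float
    cost_subsequent: float
    cost_last_6m: float
    male_multiplier: float = 1.0
    indigenous_multiplier: float = 1.0


DISEASES: Dict[str, DiseaseDefinition] = {
    d.name: d
    for d in (
        DiseaseDefinition(
            "chd", False, False, 8e-5, 0.055, 20, 0.030, 0.010, 0.0, 0.15, 2.8e-4,
            12_000, 3_500, 18_000, male_multiplier=1.3, indigenous_multiplier=1.3,
        ),
        DiseaseDefinition(
            "stroke", False, False, 5e-5, 0.060, 20, 0.040, 0.012, 0.0, 0.18, 2.2e-4,
            15_000, 5_000, 20_000, male_multiplier=1.2, indigenous_multiplier=1.3,
        ),
        DiseaseDefinition(
            "t2dm", False, False, 2e-4, 0.040, 15, 0.005, 0.010, 0.0, 0.07, 3.0e-4,
            4_000, 2_500, 9_000, male_multiplier=1.1, indigenous_multiplier=1.5,
        ),
        DiseaseDefinition(
            "colorectal_cancer", False, True, 2e-5, 0.055, 25, 0.060, 0.008, 0.08, 0.12,
            1.2e-4, 30_000, 6_000, 35_000, male_multiplier=1.1,
        ),
        DiseaseDefinition(
            "breast_cancer", True, True, 6e-5, 0.040, 25, 0.040, 0.006, 0.10, 0.10,
            1.0e-4, 25_000, 5_500, 30_000,
        ),
    )
}

#: lag windows: cardio-metabolic diseases respond over the past 0-5 years,
#: cancers over the previous 10-30 years
LAG_CARDIOMETABOLIC = (0, 5)
LAG_CANCER = (10, 30)


def default_lag_specs() -> Dict[str, LagSpec]:
    return {
        name: LagSpec(name, *(LAG_CANCER if d.is_cancer else LAG_CARDIOMETABOLIC))
        for name, d in DISEASES.items()
    }


# ---------------------------------------------------------------------------
# demography


def generate_demography(spec: StrataSpec, scenario: SyntheticScenario) -> pd.DataFrame:
    """Population counts, all-cause mortality and pYLD per stratum and single year of age."""
    rng = _rng(scenario, 1)
    ages = spec.ages
    mp, wp = scenario.mortality, scenario.morbidity

    # age pyramid: broadly flat through midlife, declining at old ages;
    # indigenous group skews younger
    base_weight = np.clip(1.0 - (ages / 100.0) ** 3, 0.0, None) + 1e-4
    rows = []
    weights = {}
    for sex, eth in spec.strata():
        w = base_weight * (np.exp(-ages / 60.0) if eth == "indigenous" else 1.0)
        w = w * rng.uniform(0.97, 1.03, size=ages.size)
        weights[(sex, eth)] = w
    eth_share = {"indigenous": scenario.indigenous_share}
    for (sex, eth), w in weights.items():
        share = eth_share.get(eth, 1.0 - scenario.indigenous_share) / len(spec.sexes)
        counts = scenario.population_size * share * w / w.sum()
        mult = (mp.indigenous_multiplier if eth == "indigenous" else 1.0) * (
            mp.male_multiplier if sex == "male" else 1.0
        )
        hazard = mp.makeham_a + mp.gompertz_b * np.exp(mp.gompertz_theta * ages)
        mortality = np.clip(-np.expm1(-hazard * mult), 0.0, 0.995)
        pyld_mult = wp.indigenous_multiplier if eth == "indigenous" else 1.0
        pyld = np.clip((wp.base + wp.slope * (ages / spec.terminal_age) ** 2) * pyld_mult, 0.0, 0.95)
        for a in ages:
            rows.append(
                {
                    "sex": sex,
                    "ethnicity": eth,
                    "age": int(a),
                    "count": counts[a],
                    "mortality": mortality[a],
                    "pyld": pyld[a],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disease epidemiology


def _epi_arrays(
    d: DiseaseDefinition, sex: str, eth: str, ages: np.ndarray, jitter: float, damp: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if d.female_only and sex != "female":
        z = np.zeros(ages.size)
        return z, z.copy(), z.copy()
    mult = (d.male_multiplier if sex == "male" else 1.0) * (
        d.indigenous_multiplier if eth == "indigenous" else 1.0
    )
    inc = np.where(
        ages >= d.onset_age,
        d.incidence_scale * mult * jitter * damp * np.exp(d.incidence_slope * (ages - d.onset_age)),
        0.0,
    )
    inc = np.clip(inc, 0.0, 0.3)
    fat = np.clip(d.fatality_base * (1.0 + d.fatality_age_slope * np.clip(ages - 40, 0, None)), 0.0, 0.6)
    rem = np.full(ages.size, d.remission if d.is_cancer else 0.0)
    return inc, fat, rem


def audit_disease_mortality(demography: pd.DataFrame, epi: pd.DataFrame) -> pd.DataFrame:
    """Cell-by-cell audit: implied disease mortality vs all-cause mortality.

    Implied per-disease mortality at each age is the period-cohort
    prevalence times case fatality. Returns a frame with the summed
    implied disease mortality, the all-cause rate, and the excess (positive
    excess marks an inconsistency) per stratum-age cell.
    """
    rates = disease_rates_from_frame(epi)
    rows = []
    for (sex, eth), grp in demography.groupby(["sex", "ethnicity"], sort=True):
        grp = grp.sort_values("age")
        q = grp["mortality"].to_numpy()
        implied = np.zeros(q.size)
        for dr in rates[(sex, eth)]:
            table = run_disease_lifetable(dr)
            implied += table.mortality[: q.size]
        for a in range(q.size):
            rows.append(
                {
                    "sex": sex,
                    "ethnicity": eth,
                    "age": a,
                    "implied_disease_mortality": implied[a],
                    "all_cause_mortality": q[a],
                    "excess": implied[a] - q[a],
                }
            )
    return pd.DataFrame(rows)


def generate_disease_epi(
    spec: StrataSpec,
    scenario: SyntheticScenario,
    demography: pd.DataFrame,
    max_retries: int = 5,
) -> pd.DataFrame:
    """Incidence, case fatality and remission per disease, stratum and age.

    Cancers carry non-zero remission; breast cancer exists only in female
    strata. Consistency is enforced by audit: if the implied disease
    mortality exceeds all-cause mortality anywhere, incidence is damped
    (x0.7) and regenerated, erroring out after ``max_retries``.
    """
    rng = _rng(scenario, 2)
    ages = spec.ages
    jitters = {
        (name, sex, eth): rng.uniform(0.9, 1.1)
        for name in sorted(DISEASES)
        for sex, eth in spec.strata()
    }
    damp = 1.0
    for _ in range(max_retries):
        rows = []
        for name in sorted(DISEASES):
            d = DISEASES[name]
            for sex, eth in spec.strata():
                inc, fat, rem = _epi_arrays(d, sex, eth, ages, jitters[(name, sex, eth)], damp)
                for a in ages:
                    rows.append(
                        {
                            "disease": name,
                            "sex": sex,
                            "ethnicity": eth,
                            "age": int(a),
                            "incidence": inc[a],
                            "case_fatality": fat[a],
                            "remission": rem[a],
                            "disability_weight": d.disability_weight,
                        }
                    )
        epi = pd.DataFrame(rows)
        audit = audit_disease_mortality(demography, epi)
        if (audit["excess"] <= 0).all():
            return epi
        damp *= 0.7
    raise GenerationError(
        "implied disease mortality exceeds all-cause mortality after damped retries"
    )


# ---------------------------------------------------------------------------
# physical-activity exposure


def _mixture_bins(mu: float, sigma: float, p_zero: float) -> np.ndarray:
    """Bin proportions for the zero-inflated lognormal exposure mixture."""
    edges = np.array(EXPOSURE_BIN_EDGES)
    with np.errstate(divide="ignore"):
        z = np.where(edges[:-1] > 0, np.log(np.maximum(edges[:-1], 1e-300)), -np.inf)
        z_hi = np.where(np.isinf(edges[1:]), np.inf, np.log(np.maximum(edges[1:], 1e-300)))
    cdf_lo = norm.cdf((z - mu) / sigma)
    cdf_hi = np.where(np.isinf(z_hi), 1.0, norm.cdf((z_hi - mu) / sigma))
    props = (1.0 - p_zero) * (cdf_hi - cdf_lo)
    props[0] += p_zero
    return props / props.sum()


def _build_distribution(mu: float, sigma: float, p_zero: float) -> ExposureDistribution:
    edges = np.array(EXPOSURE_BIN_EDGES)
    return ExposureDistribution(
        lower=edges[:-1],
        upper=edges[1:],
        midpoint=np.array(EXPOSURE_BIN_MIDPOINTS),
        proportion=_mixture_bins(mu, sigma, p_zero),
    )


def generate_pa_distribution(
    spec: StrataSpec, scenario: SyntheticScenario
) -> Dict[Tuple[str, str, Tuple[int, int]], ExposureDistribution]:
    """Per (sex, ethnicity, adult 5-year band) exposure distribution.

    Each stratum's lognormal location is solved (bounded root-finding) so
    the fraction below the inactivity threshold matches the stratum target
    (42% plus a small seeded jitter); the population-weighted adult mean
    therefore sits at ~42% insufficiently active.
    """
    rng = _rng(scenario, 3)
    pa = scenario.pa
    out: Dict[Tuple[str, str, Tuple[int, int]], ExposureDistribution] = {}
    for sex, eth in spec.strata():
        for band in spec.adult_bands():
            target = float(
                np.clip(
                    pa.target_inactive + rng.uniform(-pa.stratum_jitter, pa.stratum_jitter),
                    pa.p_zero + 0.02,
                    0.90,
                )
            )

            def gap(mu: float) -> float:
                dist = _build_distribution(mu, pa.sigma, pa.p_zero)
                return dist.fraction_below(pa.inactive_threshold) - target

            try:
                mu = brentq(gap, math.log(5.0), math.log(50_000.0), maxiter=pa.max_iter)
            except (ValueError, RuntimeError) as err:
                raise CalibrationError(
                    f"exposure calibration failed for stratum {sex}/{eth} band {band}: {err}"
                ) from err
            out[(sex, eth, band)] = _build_distribution(mu, pa.sigma, pa.p_zero)
    return out


def exposure_to_frame(
    exposure: Mapping[Tuple[str, str, Tuple[int, int]], ExposureDistribution]
) -> pd.DataFrame:
    rows = []
    for (sex, eth, (lo, hi)), dist in sorted(exposure.items()):
        for b in range(dist.n_bins):
            rows.append(
                {
                    "sex": sex,
                    "ethnicity": eth,
                    "age_lo": lo,
                    "age_hi": hi,
                    "bin_lo": dist.lower[b],
                    "bin_hi": dist.upper[b],
                    "midpoint": dist.midpoint[b],
                    "proportion": dist.proportion[b],
                }
            )
    return pd.DataFrame(rows)


def exposure_from_frame(df: pd.DataFrame) -> Dict[Tuple[str, str, Tuple[int, int]], ExposureDistribution]:
    out: Dict[Tuple[str, str, Tuple[int, int]], ExposureDistribution] = {}
    for (sex, eth, lo, hi), grp in df.groupby(["sex", "ethnicity", "age_lo", "age_hi"], sort=True):
        grp = grp.sort_values("bin_lo")
        out[(sex, eth, (int(lo), int(hi)))] = ExposureDistribution(
            lower=grp["bin_lo"].to_numpy(),
            upper=grp["bin_hi"].to_numpy(),
            midpoint=grp["midpoint"].to_numpy(),
            proportion=grp["proportion"].to_numpy(),
        )
    return out


def adult_inactive_fraction(
    demography: pd.DataFrame,
    exposure: Mapping[Tuple[str, str, Tuple[int, int]], ExposureDistribution],
    spec: StrataSpec,
    threshold: float = 450.0,
) -> float:
    """Population-weighted adult fraction below the activity threshold."""
    counts_by_band: Dict[Tuple[str, str, Tuple[int, int]], float] = {}
    for _, row in demography.iterrows():
        age = int(row["age"])
        if age < spec.adult_age:
            continue
        band = spec.band_of(age)
        key = (row["sex"], row["ethnicity"], band)
        counts_by_band[key] = counts_by_band.get(key, 0.0) + float(row["count"])
    total = sum(counts_by_band.values())
    frac = sum(
        counts_by_band[k] * exposure[k].fraction_below(threshold)
        for k in counts_by_band
        if k in exposure
    )
    return frac / total


# ---------------------------------------------------------------------------
# costs and relative risks


def generate_costs_and_rr(
    spec: StrataSpec, scenario: SyntheticScenario
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, RelativeRiskFunction]]:
    """Phase costs per disease/stratum, unrelated annual cost by age, and RR curves.

    Phase costs cover the first year after diagnosis, each subsequent
    prevalent year, and the last six months of life (attached to
    disease-cause deaths); the last-6-months cost is always at least the
    subsequent-year cost. RR curves are log-linear in MET-min/week,
    anchored at RR = 1 for zero activity, floored at ``rr.floor``;
    ``rr.scale = 0`` yields RR = 1 everywhere.
    """
    rng = _rng(scenario, 4)
    cp, rp = scenario.costs, scenario.rr
    cost_rows = []
    for name in sorted(DISEASES):
        d = DISEASES[name]
        for sex, eth in spec.strata():
            jf, js, jl = rng.uniform(0.9, 1.1, size=3)
            c_first = d.cost_first_year * cp.scale * jf
            c_subs = d.cost_subsequent * cp.scale * js
            c_last = max(d.cost_last_6m * cp.scale * jl, c_subs)
            cost_rows.append(
                {
                    "disease": name,
                    "sex": sex,
                    "ethnicity": eth,
                    "cost_first_year": c_first,
                    "cost_subsequent_year": c_subs,
                    "cost_last_6m": c_last,
                }
            )
    costs = pd.DataFrame(cost_rows)

    ages = spec.ages
    unrelated = pd.DataFrame(
        {
            "age": ages,
            "cost": cp.unrelated_base * cp.scale * np.exp(cp.unrelated_growth * ages),
        }
    )

    rr_funcs = {
        name: RelativeRiskFunction(name, DISEASES[name].rr_log_slope * rp.scale, rp.floor)
        for name in sorted(DISEASES)
    }
    return costs, unrelated, rr_funcs


def rr_to_frame(rr_funcs: Mapping[str, RelativeRiskFunction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"disease": f.disease, "log_slope": f.log_slope, "floor": f.floor, "anchor": f.anchor}
            for f in rr_funcs.values()
        ]
    )


def rr_from_frame(df: pd.DataFrame) -> Dict[str, RelativeRiskFunction]:
    return {
        row["disease"]: RelativeRiskFunction(
            row["disease"], float(row["log_slope"]), float(row["floor"]), float(row["anchor"])
        )
        for _, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SyntheticInputs:
    """Everything the downstream model consumes, plus CSV round-tripping."""

    spec: StrataSpec
    scenario: Optional[SyntheticScenario]
    demography: pd.DataFrame
    disease_epi: pd.DataFrame
    exposure: Dict[Tuple[str, str, Tuple[int, int]], ExposureDistribution]
    costs: pd.DataFrame
    unrelated: pd.DataFrame
    rr_funcs: Dict[str, RelativeRiskFunction]

    TABLES = ("population", "disease_epi", "exposure", "costs", "unrelated_costs", "rr")

    def population_strata(self):
        return population_from_frame(self.demography)

    def disease_rates(self):
        return disease_rates_from_frame(self.disease_epi)

    def write_csvs(self, out_dir) -> Dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frames = {
            "population": self.demography,
            "disease_epi": self.disease_epi,
            "exposure": exposure_to_frame(self.exposure),
            "costs": self.costs,
            "unrelated_costs": self.unrelated,
            "rr": rr_to_frame(self.rr_funcs),
        }
        paths = {}
        for name, frame in frames.items():
            path = out_dir / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(f"# schema={SCHEMA_VERSION} table={name}\n")
                frame.to_csv(fh, index=False)
            paths[name] = path
        return paths

    @classmethod
    def read_csvs(cls, in_dir, spec: Optional[StrataSpec] = None) -> "SyntheticInputs":
        in_dir = Path(in_dir)
        read = lambda name: pd.read_csv(in_dir / f"{name}.csv", comment="#")
        exposure = exposure_from_frame(read("exposure"))
        return cls(
            spec=spec or StrataSpec(),
            scenario=None,
            demography=read("population"),
            disease_epi=read("disease_epi"),
            exposure=exposure,
            costs=read("costs"),
            unrelated=read("unrelated_costs"),
            rr_funcs=rr_from_frame(read("rr")),
        )


def generate_inputs(
    spec: Optional[StrataSpec] = None, scenario: Optional[SyntheticScenario] = None
) -> SyntheticInputs:
    """Generate the full synthetic input bundle for one scenario."""
    spec = spec or StrataSpec()
    scenario = scenario or SyntheticScenario()
    demography = generate_demography(spec, scenario)
    epi = generate_disease_epi(spec, scenario, demography)
    exposure = generate_pa_distribution(spec, scenario)
    costs, unrelated, rr_funcs = generate_costs_and_rr(spec, scenario)
    return SyntheticInputs(spec, scenario, demography, epi, exposure, costs, unrelated, rr_funcs)
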