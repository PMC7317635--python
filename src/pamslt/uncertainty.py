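"""Probabilistic sensitivity analysis (PSA).

Intervention parameters carry uncertainty distributions (beta for the
pathway proportions, normal truncated at zero for the effect size, gamma
for the campaign cost). A Monte Carlo analysis samples them
independently, reruns the model per draw, and summarises outputs as the
50th percentile with a 2.5th-97.5th percentile uncertainty interval. The
cost-effectiveness acceptability curve (CEAC) reports, per
willingness-to-pay threshold, the fraction of runs with non-negative net
monetary benefit; one-way (tornado) analysis moves one parameter at a
time to its 2.5th/97.5th percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .intervention import InterventionSpec
from .model import ModelBundle

__all__ = [
    "ParameterDistribution",
    "PsaSummary",
    "UncertaintyError",
    "fit_beta_from_interval",
    "default_parameter_distributions",
    "sample_parameters",
    "run_psa",
    "ceac",
    "tornado",
    "spec_from_params",
]


class UncertaintyError(ValueError):
    """Invalid distribution specification or empty PSA results."""


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter: family, hyperparameters, and central value.

    Families: ``beta`` (params a, b), ``normal`` (loc, scale; draws
    truncated at zero by resampling), ``gamma`` (shape, scale), ``point``
    (degenerate at the central value).
    """

    name: str
    family: str
    params: Dict[str, float]
    central: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "normal", "gamma", "point"):
            raise UncertaintyError(f"unknown distribution family {self.family!r}")

    def _frozen(self):
        if self.family == "beta":
            return stats.beta(self.params["a"], self.params["b"])
        if self.family == "normal":
            return stats.norm(self.params["loc"], self.params["scale"])
        if self.family == "gamma":
            return stats.gamma(self.params["shape"], scale=self.params["scale"])
        return None

    def ppf(self, q: float) -> float:
        frozen = self._frozen()
        if frozen is None:
            return self.central
        if self.family == "normal":
            # quantile of the zero-truncated normal
            p0 = frozen.cdf(0.0)
            return float(frozen.ppf(p0 + q * (1.0 - p0)))
        return float(frozen.ppf(q))

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.central)
        if self.family == "beta":
            return rng.beta(self.params["a"], self.params["b"], size=size)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=size)
        draws = rng.normal(self.params["loc"], self.params["scale"], size=size)
        # truncate at zero by resampling (effect sizes cannot be negative)
        for _ in range(1000):
            neg = draws < 0
            if not neg.any():
                break
            draws[neg] = rng.normal(self.params["loc"], self.params["scale"], size=int(neg.sum()))
        return np.clip(draws, 0.0, None)

    def as_point(self) -> "ParameterDistribution":
        return ParameterDistribution(self.name, "point", {}, self.central)


def fit_beta_from_interval(central: float, lo: float, hi: float) -> ParameterDistribution:
    """Fit a beta distribution to a (central value, 95% interval) triple.

    The mean is pinned to the central value; the concentration is solved
    numerically so the 2.5%/97.5% quantiles match ``(lo, hi)`` in least
    squares. The achieved quantiles are stored in ``params`` for
    diagnostics.
    """
    if not (0.0 < lo < central < hi < 1.0):
        raise UncertaintyError(
            f"infeasible beta triple: need 0 < lo < central < hi < 1, got "
            f"({central}, {lo}, {hi})"
        )

    def loss(log_kappa: float) -> float:
        kappa = math.exp(log_kappa)
        dist = stats.beta(central * kappa, (1.0 - central) * kappa)
        q_lo, q_hi = dist.ppf([0.025, 0.975])
        return (q_lo - lo) ** 2 + (q_hi - hi) ** 2

    res = optimize.minimize_scalar(loss, bounds=(math.log(2.0), math.log(1e6)), method="bounded")
    if not res.success:
        raise UncertaintyError(f"beta fit failed for ({central}, {lo}, {hi}): {res.message}")
    kappa = math.exp(res.x)
    a, b = central * kappa, (1.0 - central) * kappa
    q_lo, q_hi = stats.beta(a, b).ppf([0.025, 0.975])
    return ParameterDistribution(
        name="",
        family="beta",
        params={"a": a, "b": b, "achieved_lo": float(q_lo), "achieved_hi": float(q_hi)},
        central=central,
    )


def _named(dist: ParameterDistribution, name: str) -> ParameterDistribution:
    return ParameterDistribution(name, dist.family, dist.params, dist.central)


def default_parameter_distributions(
    cost_mean: float = 2_883_000.0, cost_sd_fraction: float = 0.20
) -> Dict[str, ParameterDistribution]:
    """The base-case intervention uncertainty set.

    Beta distributions for the four pathway proportions fitted to their
    central values and 95% intervals, a zero-truncated normal for the
    MET-minute effect size (mean 285, SD 43), and a gamma for the campaign
    cost (mean NZ$2,883,000, SD 20% of the mean).
    """
    shape = 1.0 / cost_sd_fraction**2
    return {
        "awareness": _named(fit_beta_from_interval(0.779, 0.70, 0.83), "awareness"),
        "download": _named(fit_beta_from_interval(0.31, 0.21, 0.41), "download"),
        "use": _named(fit_beta_from_interval(0.16, 0.10, 0.36), "use"),
        "adherence": _named(fit_beta_from_interval(0.15, 0.10, 0.21), "adherence"),
        "effect_met_min": ParameterDistribution(
            "effect_met_min", "normal", {"loc": 285.0, "scale": 43.0}, 285.0
        ),
        "cost_total": ParameterDistribution(
            "cost_total", "gamma", {"shape": shape, "scale": cost_mean / shape}, cost_mean
        ),
    }


def sample_parameters(
    distributions: Mapping[str, ParameterDistribution], n_runs: int, seed: int
) -> pd.DataFrame:
    """Independent draws per run; one RNG substream per run.

    Per-run substreams are spawned from the master seed, so each run's
    parameter set is reproducible and independent of execution order.
    """
    if n_runs < 1:
        raise UncertaintyError("n_runs must be at least 1")
    names = sorted(distributions)
    children = np.random.SeedSequence(seed).spawn(n_runs)
    rows = np.empty((n_runs, len(names)))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for j, name in enumerate(names):
            rows[i, j] = distributions[name].sample(rng, size=1)[0]
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "run", np.arange(n_runs))
    return df


def spec_from_params(base: InterventionSpec, params: Mapping[str, float]) -> InterventionSpec:
    """Intervention spec with sampled parameters substituted into a base spec."""
    from dataclasses import replace

    known = {k: float(v) for k, v in params.items() if k in (
        "awareness", "download", "use", "adherence", "effect_met_min", "cost_total"
    )}
    return replace(base, **known)


@dataclass
class PsaSummary:
    """Percentile summaries and run bookkeeping for a Monte Carlo analysis."""

    n_runs: int
    n_failures: int
    percentiles: pd.DataFrame  # rows: output, cols: p2.5, p50, p97.5

    def interval(self, output: str):
        row = self.percentiles.loc[output]
        return float(row["p2.5"]), float(row["p50"]), float(row["p97.5"])


def run_psa(
    bundle: ModelBundle,
    draws: pd.DataFrame,
    base_spec: Optional[InterventionSpec] = None,
) -> tuple[pd.DataFrame, PsaSummary]:
    """Evaluate the model for every parameter draw.

    Returns the per-run results (QALY gain, net cost, ICER, flag) and a
    percentile summary. A failing run is recorded, excluded, and counted.
    """
    base = base_spec or InterventionSpec()
    records: List[dict] = []
    n_failures = 0
    for _, row in draws.iterrows():
        spec = spec_from_params(base, row)
        try:
            res = bundle.run(spec)
        except Exception:  # noqa: BLE001 - per-run failures are reported, not fatal
            n_failures += 1
            continue
        records.append(
            {
                "run": int(row["run"]) if "run" in row else len(records),
                "qaly_gain": res.qaly_gain,
                "net_cost": res.net_cost,
                "icer": res.icer,
                "flag": res.flag,
            }
        )
    if not records:
        raise UncertaintyError("all PSA runs failed")
    results = pd.DataFrame(records)
    pct = {}
    for output in ("qaly_gain", "net_cost", "icer"):
        vals = results[output].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        pct[output] = dict(
            zip(["p2.5", "p50", "p97.5"], np.percentile(vals, [2.5, 50.0, 97.5]))
        )
    summary = PsaSummary(
        n_runs=len(results), n_failures=n_failures, percentiles=pd.DataFrame(pct).T
    )
    return results, summary


def ceac(results: pd.DataFrame, thresholds: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    A run is cost-effective at threshold λ iff its net monetary benefit
    ``λ·ΔQALY - Δcost`` is non-negative — this handles cost-saving and
    dominated runs coherently where a raw "ICER below λ" rule breaks down
    for negative ICERs. The curve is non-decreasing in λ whenever no run
    loses health (always the case here: protective relative risks and
    non-negative exposure shifts).
    """
    if results.empty:
        raise UncertaintyError("no PSA results to summarise")
    q = results["qaly_gain"].to_numpy(dtype=float)
    c = results["net_cost"].to_numpy(dtype=float)
    rows = [
        {"threshold": lam, "probability_cost_effective": float(np.mean(lam * q - c >= 0.0))}
        for lam in thresholds
    ]
    return pd.DataFrame(rows)


def tornado(
    bundle: ModelBundle,
    distributions: Mapping[str, ParameterDistribution],
    base_spec: Optional[InterventionSpec] = None,
) -> pd.DataFrame:
    """One-way sensitivity analysis.

    Each parameter in turn is set to its 2.5th then 97.5th percentile with
    all others at their central values; QALY gain, net cost, and ICER are
    recorded at both ends. Rows are sorted by the width of the ICER range
    (widest bar first).
    """
    base = base_spec or InterventionSpec()
    central = {name: d.central for name, d in distributions.items()}
    rows = []
    for name in sorted(distributions):
        d = distributions[name]
        results = {}
        for end, q in (("low", 0.025), ("high", 0.975)):
            params = dict(central)
            params[name] = d.ppf(q)
            results[end] = bundle.run(spec_from_params(base, params))
        rows.append(
            {
                "parameter": name,
                "value_low": d.ppf(0.025),
                "value_high": d.ppf(0.975),
                "qaly_low": results["low"].qaly_gain,
                "qaly_high": results["high"].qaly_gain,
                "net_cost_low": results["low"].net_cost,
                "net_cost_high": results["high"].net_cost,
                "icer_low": results["low"].icer,
                "icer_high": results["high"].icer,
            }
        )
    df = pd.DataFrame(rows)
    for output in ("qaly", "net_cost", "icer"):
        df[f"{output}_range"] = (df[f"{output}_high"] - df[f"{output}_low"]).abs()
    return df.sort_values("icer_range", ascending=False).reset_index(drop=True)
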