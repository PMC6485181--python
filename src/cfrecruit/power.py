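"""Bootstrap power estimation and sample-size search for biomarker endpoints.

The study-design question: how many patients are needed so that a biomarker
measured at enrollment shows a significant association with an outcome --
either a time-to-event endpoint (time to first pulmonary exacerbation,
transplant-free survival) under a proportional-hazards model, or a
continuous endpoint (acute FEV1% drop) under linear regression?

Rather than trusting asymptotic formulas alone, power is estimated by
resampling a pilot dataset: draw n patients with replacement, refit the
model, and record whether the biomarker coefficient is significant at the
chosen two-sided alpha.  The fraction of significant replicates estimates
the power at sample size n, with Monte-Carlo standard error
sqrt(p(1-p)/B).  A grid search returns the smallest n whose estimated
power reaches the target.

Closed forms are provided as independent oracles: the Schoenfeld required
event count for a proportional-hazards covariate,

    events = ceil( (z_{1-alpha/2} + z_power)^2 / (beta^2 sigma_x^2) ),

and the analogous requirement for a linear-regression slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "PowerEstimate",
    "PowerResult",
    "bootstrap_power",
    "sample_size_search",
    "closed_form_cox_events",
    "closed_form_linear_n",
]

MODELS = ("prop_hazards_tte", "linear_regression")


@dataclass(frozen=True)
class PowerSpec:
    """Design of one bootstrapped power calculation."""

    model: str
    alpha: float = 0.05
    target_power: float = 0.80
    n_grid: tuple[int, ...] = (20, 40, 60, 80, 100)
    n_replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not (0.0 < self.alpha < self.target_power < 1.0):
            raise ValueError(
                f"need 0 < alpha < target_power < 1, got alpha={self.alpha}, "
                f"target_power={self.target_power}"
            )
        if len(self.n_grid) == 0:
            raise ValueError("n_grid must be non-empty")
        if list(self.n_grid) != sorted(set(self.n_grid)) or self.n_grid[0] <= 0:
            raise ValueError("n_grid must be increasing positive integers")
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100 for reporting")


@dataclass
class PowerEstimate:
    """Estimated power at one sample size."""

    n: int
    power: float
    mc_se: float
    n_replicates: int
    n_redraws: int = 0


@dataclass
class PowerResult:
    """Outcome of a sample-size grid search."""

    spec: PowerSpec
    estimates: list[PowerEstimate] = field(default_factory=list)
    minimal_n: int | None = None
    grid_exhausted: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: model, target power (%), alpha, estimates per n."""
        rows = [
            {
                "model": self.spec.model,
                "percent_power_target": 100.0 * self.spec.target_power,
                "alpha": self.spec.alpha,
                "n": e.n,
                "estimated_power": e.power,
                "mc_se": e.mc_se,
                "replicates": e.n_replicates,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows)


def _fit_cox_pvalue(df: pd.DataFrame) -> float | None:
    """Two-sided Wald p-value for the biomarker in a proportional-hazards fit.

    Returns None for degenerate resamples (no events, constant biomarker,
    or a non-converged fit) so the caller can redraw.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if df["event"].sum() < 2 or df["biomarker"].nunique() < 2:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = CoxPHFitter().fit(
                df[["biomarker", "time", "event"]],
                duration_col="time",
                event_col="event",
            )
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None
    beta = float(f.params_.iloc[0])
    se = float(f.standard_errors_.iloc[0])
    if not (np.isfinite(beta) and np.isfinite(se)) or se <= 0 or se > 50:
        return None
    z = beta / se
    return 2.0 * stats.norm.sf(abs(z))


def _fit_linear_pvalue(df: pd.DataFrame) -> float | None:
    """Two-sided p-value for the biomarker slope in ordinary least squares."""
    x = df["biomarker"].to_numpy(dtype=float)
    y = df["response"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        return None
    res = stats.linregress(x, y)
    if not np.isfinite(res.pvalue):
        return None
    return float(res.pvalue)


_REQUIRED_COLUMNS = {
    "prop_hazards_tte": ("biomarker", "time", "event"),
    "linear_regression": ("biomarker", "response"),
}


def bootstrap_power(pilot: pd.DataFrame, spec: PowerSpec, n: int) -> PowerEstimate:
    """Estimate power at sample size *n* by patient-level resampling.

    Each of B replicates draws n rows with replacement from the pilot, fits
    the model, and tests the biomarker coefficient at the two-sided alpha.
    Degenerate or non-converged replicates are redrawn (counted in
    ``n_redraws``); more than 10*B total attempts raises.
    """
    need = _REQUIRED_COLUMNS[spec.model]
    missing = [c for c in need if c not in pilot.columns]
    if missing:
        raise ValueError(f"pilot lacks column(s) {missing} required by {spec.model}")
    if len(pilot) < 2:
        raise ValueError("pilot must have at least 2 subjects")
    fit = _fit_cox_pvalue if spec.model == "prop_hazards_tte" else _fit_linear_pvalue
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, n]))
    rows = pilot.reset_index(drop=True)
    significant = 0
    done = 0
    redraws = 0
    attempts = 0
    cap = 10 * spec.n_replicates
    while done < spec.n_replicates:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"exceeded {cap} resampling attempts at n={n}; pilot too degenerate"
            )
        idx = rng.integers(0, len(rows), size=n)
        p = fit(rows.iloc[idx])
        if p is None:
            redraws += 1
            continue
        if p < spec.alpha:
            significant += 1
        done += 1
    power = significant / spec.n_replicates
    mc_se = math.sqrt(power * (1.0 - power) / spec.n_replicates)
    return PowerEstimate(n=n, power=power, mc_se=mc_se,
                         n_replicates=spec.n_replicates, n_redraws=redraws)


def sample_size_search(pilot: pd.DataFrame, spec: PowerSpec) -> PowerResult:
    """Smallest grid n whose bootstrap power reaches the target.

    Walks the grid in order, stopping early once the target is met and
    confirmed at the following grid point (or at the last point).  When no
    grid point reaches the target the result is marked ``grid_exhausted``
    rather than raising.
    """
    result = PowerResult(spec=spec)
    met_at: int | None = None
    for i, n in enumerate(spec.n_grid):
        est = bootstrap_power(pilot, spec, n)
        result.estimates.append(est)
        if est.power >= spec.target_power:
            if met_at is None:
                met_at = n
                if i == len(spec.n_grid) - 1:
                    break
            else:
                break  # confirmed at the next grid point
        else:
            met_at = None
    result.minimal_n = met_at
    result.grid_exhausted = met_at is None
    return result


def closed_form_cox_events(
    beta: float, sigma_x: float = 1.0, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Schoenfeld required event count for a proportional-hazards covariate.

    events = ceil((z_{1-alpha/2} + z_power)^2 / (beta^2 sigma_x^2)), at
    least 1.  With no censoring the required patient count equals the
    required event count.
    """
    if beta == 0:
        raise ValueError("beta=0 implies an infinite event requirement")
    if sigma_x <= 0:
        raise ValueError("sigma_x must be positive")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    events = (z_a + z_b) ** 2 / (beta**2 * sigma_x**2)
    return max(int(math.ceil(events - 1e-12)), 1)


def closed_form_linear_n(
    slope: float,
    sigma_x: float = 1.0,
    sigma_resid: float = 1.0,
    alpha: float = 0.05,
    power: float = 0.80,
) -> int:
    """Required n for detecting a linear-regression slope (normal approximation).

    n = ceil((z_{1-alpha/2} + z_power)^2 sigma_resid^2 / (slope^2 sigma_x^2)) + 2;
    the +2 accounts for the intercept and slope degrees of freedom, giving
    n = 3 in the noiseless limit.
    """
    if slope == 0:
        raise ValueError("slope=0 implies an infinite sample-size requirement")
    if sigma_x <= 0 or sigma_resid < 0:
        raise ValueError("sigma_x must be positive and sigma_resid non-negative")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    n = (z_a + z_b) ** 2 * sigma_resid**2 / (slope**2 * sigma_x**2)
    return max(int(math.ceil(n - 1e-12)), 1) + 2
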