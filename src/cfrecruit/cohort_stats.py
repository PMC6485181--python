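"""Cohort representativeness, seasonal-bias, and shipping-effect statistics.

Three analyses that check whether an enrolled cohort can stand in for the
reference population it was drawn from:

* **Representativeness**: characteristic-by-characteristic comparison of
  the cohort against a reference registry population -- chi-square tests
  for binary characteristics (infection status, treatments, morbidities),
  Welch t-tests for continuous ones (age, lung function, weight), and
  quasi-Poisson regression for counts (prior-year exacerbations).
* **Seasonal effects**: regression of each characteristic on enrollment
  season (meteorological seasons, Summer as reference), with Bonferroni
  correction across the characteristics tested.
* **Shipping controls**: paired immediate-vs-shipped biomarker
  measurements, summarized by ordinary least squares of shipped on
  immediate and by per-pair elevation factors (shipped/immediate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "ComparisonReport",
    "SeasonalEffect",
    "SeasonalReport",
    "ShippingAnalysis",
    "season_of",
    "compare_binary",
    "compare_continuous",
    "compare_count",
    "compare_cohorts",
    "seasonal_effects",
    "paired_shipping_analysis",
]

SEASONS = ("Winter", "Spring", "Summer", "Fall")
REFERENCE_SEASON = "Summer"


def season_of(d: date | pd.Timestamp) -> str:
    """Meteorological season: Dec-Feb Winter, Mar-May Spring, Jun-Aug Summer, Sep-Nov Fall."""
    m = d.month
    if m in (12, 1, 2):
        return "Winter"
    if m in (3, 4, 5):
        return "Spring"
    if m in (6, 7, 8):
        return "Summer"
    return "Fall"


@dataclass(frozen=True)
class TestResult:
    name: str
    kind: str  # binary | continuous | count
    statistic: float
    p_value: float
    cohort_summary: str
    reference_summary: str
    test: str
    adjusted: bool = False


@dataclass
class ComparisonReport:
    rows: list[TestResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "characteristic": r.name,
                    "type": r.kind,
                    "cohort": r.cohort_summary,
                    "reference": r.reference_summary,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p": r.p_value,
                    "adjusted": r.adjusted,
                }
                for r in self.rows
            ]
        )


def compare_binary(
    cohort_successes: int, cohort_n: int, ref_successes: int, ref_n: int
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table, df=1, no continuity correction."""
    for name, (s, n) in {
        "cohort": (cohort_successes, cohort_n),
        "reference": (ref_successes, ref_n),
    }.items():
        if s < 0 or n < 0 or s > n:
            raise ValueError(f"invalid {name} counts: {s}/{n}")
    table = np.array(
        [
            [cohort_successes, cohort_n - cohort_successes],
            [ref_successes, ref_n - ref_successes],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: a margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_continuous(cohort: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test, two-sided.

    Both groups constant with equal means returns (0, 1) by convention.
    """
    cohort = np.asarray(cohort, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if cohort.size < 2 or reference.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(cohort).all() and np.isfinite(reference).all()):
        raise ValueError("non-finite values in input")
    if cohort.std(ddof=1) == 0 and reference.std(ddof=1) == 0:
        if cohort.mean() == reference.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(cohort.mean() - reference.mean()), 0.0
    t, p = stats.ttest_ind(cohort, reference, equal_var=False)
    return float(t), float(p)


def compare_count(cohort: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Quasi-Poisson comparison of count characteristics.

    Poisson regression of the count on a cohort indicator with the
    dispersion estimated from the Pearson chi-square (quasi-likelihood);
    returns the Wald statistic and two-sided p for the indicator.
    """
    cohort = np.asarray(cohort, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if cohort.size < 2 or reference.size < 2:
        raise ValueError("each group needs n >= 2")
    y = np.concatenate([cohort, reference])
    g = np.concatenate([np.ones(cohort.size), np.zeros(reference.size)])
    X = sm.add_constant(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
    z = float(fit.params[1] / fit.bse[1])
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


#: characteristic name -> kind, for the standard cohort table.
DEFAULT_CHARACTERISTICS: dict[str, str] = {
    "age_at_baseline": "continuous",
    "fev1pp": "continuous",
    "weight_kg": "continuous",
    "home_elevation_m": "continuous",
    "male": "binary",
    "prior_year_exacerbations": "count",
}


def _binary_col(df: pd.DataFrame, name: str) -> np.ndarray:
    if name == "male":
        return (df["sex"] == "male").to_numpy()
    return df[name].astype(bool).to_numpy()


def compare_cohorts(
    cohort: pd.DataFrame,
    reference: pd.DataFrame,
    characteristics: dict[str, str] | None = None,
    adjusted: bool = False,
) -> ComparisonReport:
    """Characteristic-by-characteristic cohort vs reference comparison.

    ``characteristics`` maps column names to "binary" | "continuous" |
    "count"; the default covers the standard demographic/clinical table
    plus every ``inf_*`` infection column present.  With ``adjusted=True``
    each characteristic is instead modeled on the pooled data as
    characteristic ~ cohort_indicator + age + sex, with the model family
    matched to the characteristic type, and the p-value is the Wald test
    of the cohort indicator.
    """
    if characteristics is None:
        characteristics = dict(DEFAULT_CHARACTERISTICS)
        for col in cohort.columns:
            if col.startswith("inf_") and col in reference.columns:
                characteristics[col] = "binary"
    report = ComparisonReport()
    for name, kind in characteristics.items():
        if kind == "binary":
            cvals = _binary_col(cohort, name)
            rvals = _binary_col(reference, name)
            if adjusted:
                stat, p = _adjusted_test(cohort, reference, name, kind)
            else:
                stat, p = compare_binary(int(cvals.sum()), cvals.size, int(rvals.sum()), rvals.size)
            csum = f"{int(cvals.sum())} ({cvals.mean():.2f})"
            rsum = f"{int(rvals.sum())} ({rvals.mean():.2f})"
            test = "chi-square" if not adjusted else "logistic (adjusted)"
        elif kind == "continuous":
            cvals = cohort[name].to_numpy(dtype=float)
            rvals = reference[name].to_numpy(dtype=float)
            if adjusted:
                stat, p = _adjusted_test(cohort, reference, name, kind)
            else:
                stat, p = compare_continuous(cvals, rvals)
            csum = f"{cvals.mean():.1f} ({cvals.std(ddof=1):.1f})"
            rsum = f"{rvals.mean():.1f} ({rvals.std(ddof=1):.1f})"
            test = "Welch t" if not adjusted else "linear (adjusted)"
        elif kind == "count":
            cvals = cohort[name].to_numpy(dtype=float)
            rvals = reference[name].to_numpy(dtype=float)
            if adjusted:
                stat, p = _adjusted_test(cohort, reference, name, kind)
            else:
                stat, p = compare_count(cvals, rvals)
            csum = f"{cvals.mean():.1f} ({cvals.std(ddof=1):.1f})"
            rsum = f"{rvals.mean():.1f} ({rvals.std(ddof=1):.1f})"
            test = "quasi-Poisson" if not adjusted else "quasi-Poisson (adjusted)"
        else:
            raise ValueError(f"unknown characteristic kind {kind!r} for {name!r}")
        report.rows.append(
            TestResult(name, kind, stat, p, csum, rsum, test, adjusted=adjusted)
        )
    return report


def _adjusted_test(
    cohort: pd.DataFrame, reference: pd.DataFrame, name: str, kind: str
) -> tuple[float, float]:
    """Wald test of the cohort indicator, adjusted for age and sex."""
    pooled = pd.concat(
        [cohort.assign(_cohort=1.0), reference.assign(_cohort=0.0)], ignore_index=True
    )
    if kind == "binary":
        y = _binary_col(pooled, name).astype(float)
    else:
        y = pooled[name].to_numpy(dtype=float)
    X = sm.add_constant(
        pd.DataFrame(
            {
                "cohort": pooled["_cohort"],
                "age": pooled["age_at_baseline"],
                "male": (pooled["sex"] == "male").astype(float),
            }
        )
    )
    family = {
        "binary": sm.families.Binomial(),
        "continuous": sm.families.Gaussian(),
        "count": sm.families.Poisson(),
    }[kind]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scale = "X2" if kind == "count" else None
        fit = sm.GLM(y, X, family=family).fit(scale=scale)
    z = float(fit.params["cohort"] / fit.bse["cohort"])
    return z, 2.0 * float(stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class SeasonalEffect:
    characteristic: str
    season: str
    coefficient: float
    p_value: float
    model: str
    significant_bonferroni: bool


@dataclass
class SeasonalReport:
    effects: list[SeasonalEffect] = field(default_factory=list)
    family_alpha: float = 0.05
    n_characteristics: int = 0

    @property
    def any_significant_after_bonferroni(self) -> bool:
        return any(e.significant_bonferroni for e in self.effects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "characteristic": e.characteristic,
                    "season": e.season,
                    "coefficient": e.coefficient,
                    "p": e.p_value,
                    "model": e.model,
                    "significant_bonferroni": e.significant_bonferroni,
                }
                for e in self.effects
            ]
        )


def seasonal_effects(
    cohort: pd.DataFrame,
    characteristics: dict[str, str],
    family_alpha: float = 0.05,
    date_column: str = "enrollment_date",
) -> SeasonalReport:
    """Per-characteristic seasonal-enrollment regressions, Summer reference.

    One model per characteristic (linear for continuous, logistic for
    binary, quasi-Poisson for counts) with season dummies for Winter,
    Spring, and Fall relative to Summer.  Bonferroni correction divides the
    family alpha by the number of characteristics tested; an effect is
    flagged significant only when its raw p-value is at most alpha/m.
    """
    seasons = cohort[date_column].map(season_of)
    present = seasons.unique()
    if len(present) < 2:
        raise ValueError("seasonal analysis needs at least two seasons represented")
    m = len(characteristics)
    threshold = family_alpha / m
    report = SeasonalReport(family_alpha=family_alpha, n_characteristics=m)
    dummies = pd.DataFrame(
        {s: (seasons == s).astype(float) for s in SEASONS if s != REFERENCE_SEASON}
    )
    X = sm.add_constant(dummies)
    for name, kind in characteristics.items():
        if kind == "binary":
            y = _binary_col(cohort, name).astype(float)
            family, model_name = sm.families.Binomial(), "logistic"
        elif kind == "count":
            y = cohort[name].to_numpy(dtype=float)
            family, model_name = sm.families.Poisson(), "quasi-Poisson"
        else:
            y = cohort[name].to_numpy(dtype=float)
            family, model_name = sm.families.Gaussian(), "linear"
        if np.ptp(y) == 0.0:
            # constant characteristic: every seasonal contrast is exactly zero
            for s in dummies.columns:
                if seasons.eq(s).sum() > 0:
                    report.effects.append(SeasonalEffect(name, s, 0.0, 1.0, model_name, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scale = "X2" if kind == "count" else None
            fit = sm.GLM(y, X, family=family).fit(scale=scale)
        for s in dummies.columns:
            if seasons.eq(s).sum() == 0:
                continue
            coef = float(fit.params[s])
            se = float(fit.bse[s])
            if se > 0 and np.isfinite(se):
                p = 2.0 * float(stats.norm.sf(abs(coef / se)))
            else:
                p = 1.0 if coef == 0 else 0.0
            report.effects.append(
                SeasonalEffect(name, s, coef, p, model_name, p <= threshold)
            )
    return report


@dataclass
class ShippingAnalysis:
    """Paired immediate-vs-shipped summary for one biomarker."""

    n_pairs: int
    n_excluded: int
    slope: float
    intercept: float
    p_value: float
    factors: np.ndarray
    mean_factor: float
    ci_low: float
    ci_high: float
    max_factor: float
    warnings: list[str] = field(default_factory=list)


def paired_shipping_analysis(pairs: pd.DataFrame) -> ShippingAnalysis:
    """OLS of shipped on immediate plus per-pair elevation factors.

    The elevation factor shipped/immediate is undefined for non-positive
    immediate values; such pairs are excluded with a warning.  The mean
    factor carries a normal-approximation 95% CI clipped below at zero.
    Requires at least 3 usable pairs.
    """
    notes: list[str] = []
    ok = pairs["immediate"] > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        notes.append(f"excluded {n_excluded} pair(s) with non-positive immediate value")
    use = pairs.loc[ok]
    if len(use) < 3:
        raise ValueError("paired shipping analysis needs >= 3 pairs with positive immediate values")
    x = use["immediate"].to_numpy(dtype=float)
    y = use["shipped"].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    factors = y / x
    mean_f = float(factors.mean())
    if factors.size > 1 and factors.std(ddof=1) > 0:
        half = 1.959963984540054 * factors.std(ddof=1)
        ci_low, ci_high = max(mean_f - half, 0.0), mean_f + half
    else:
        ci_low = ci_high = mean_f
    return ShippingAnalysis(
        n_pairs=int(len(use)),
        n_excluded=n_excluded,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        factors=factors,
        mean_factor=mean_f,
        ci_low=ci_low,
        ci_high=ci_high,
        max_factor=float(factors.max()),
        warnings=notes,
    )
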