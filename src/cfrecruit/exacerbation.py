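"""Rule-based pulmonary-exacerbation definition, stability, and sample windows.

A pulmonary exacerbation is declared when at least one symptom from a fixed
symptom list co-occurs with at least one objective sign, when respiratory
failure requires mechanical ventilation (regardless of other criteria), or
when the site principal investigator overrides a borderline call.  A
"mild exacerbation" denotes clinical instability short of the full
definition: symptoms without any objective sign, or signs without any
symptom.  Clinical stability -- the enrollment requirement -- is the
absence of a pulmonary exacerbation.

Sign criteria and their boundary conventions:

* relative drop in FEV1 or FVC percent predicted >= 10% of baseline
  (configurable to absolute percentage points),
* temperature strictly > 38.4 degC,
* witnessed hemoptysis strictly > 100 ml per episode,
* SaO2 < 90% or PaO2 < 60 mmHg despite usual oxygen,
* for adolescents (12 <= age < 18), a drop in SaO2 of >= 5 percentage
  points from baseline,
* increased supplemental oxygen requirement,
* unplanned weight loss >= 5% of baseline over <= 3 months (93 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from enum import Enum

__all__ = [
    "SYMPTOMS",
    "SIGNS",
    "Verdict",
    "Override",
    "ClinicalAssessment",
    "ExacerbationCall",
    "StabilityCall",
    "CollectionWindow",
    "evaluate_signs",
    "classify",
    "classify_from_criteria",
    "is_clinically_stable",
    "prior_exacerbation_history",
    "collection_windows",
]

SYMPTOMS = (
    "increased_sputum",
    "cough",
    "dyspnea",
    "chest_pain_or_tightness",
    "hemoptysis",
    "fever",
    "chills",
    "arthralgias",
    "fatigue",
)

SIGNS = (
    "lung_function_drop",
    "temperature",
    "major_hemoptysis",
    "hypoxemia",
    "adolescent_desaturation",
    "increased_o2_requirement",
    "weight_loss",
)

MAX_WEIGHT_LOSS_WINDOW_DAYS = 93  # "over 3 months"


class Verdict(str, Enum):
    STABLE = "stable"
    MILD = "mild"
    EXACERBATION = "exacerbation"


class Override(str, Enum):
    FORCE_EXACERBATION = "force_exacerbation"
    FORCE_NOT = "force_not"


@dataclass
class ClinicalAssessment:
    """One clinical encounter: reported symptoms, measurements, baselines.

    Measurement fields left as ``None`` are missing; a sign criterion whose
    inputs are missing is skipped and reported as unevaluated rather than
    treated as absent-by-assertion.
    """

    patient_id: str = ""
    date: date | None = None
    symptoms: frozenset[str] = frozenset()
    fev1_pp_current: float | None = None
    fvc_pp_current: float | None = None
    temperature_C: float | None = None
    witnessed_hemoptysis_ml: float | None = None
    sao2_percent: float | None = None
    pao2_mmHg: float | None = None
    on_usual_oxygen: bool = True
    increased_o2_requirement: bool = False
    weight_kg_current: float | None = None
    mechanical_ventilation: bool = False
    age_years: float | None = None
    baseline_fev1_pp: float | None = None
    baseline_fvc_pp: float | None = None
    baseline_sao2_percent: float | None = None
    baseline_weight_kg: float | None = None
    baseline_weight_date: date | None = None
    pi_override: Override | None = None

    def __post_init__(self) -> None:
        unknown = set(self.symptoms) - set(SYMPTOMS)
        if unknown:
            raise ValueError(f"unknown symptom(s): {sorted(unknown)}")
        self.symptoms = frozenset(self.symptoms)
        for name in ("fev1_pp_current", "fvc_pp_current", "witnessed_hemoptysis_ml",
                     "sao2_percent", "pao2_mmHg", "weight_kg_current",
                     "baseline_fev1_pp", "baseline_fvc_pp", "baseline_sao2_percent",
                     "baseline_weight_kg"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if self.temperature_C is not None and not (30.0 <= self.temperature_C <= 45.0):
            raise ValueError(f"temperature_C outside plausible range: {self.temperature_C!r}")


@dataclass
class SignEvaluation:
    met: list[str]
    unevaluated: list[str]


@dataclass
class ExacerbationCall:
    verdict: Verdict
    symptoms_met: list[str]
    signs_met: list[str]
    signs_unevaluated: list[str] = field(default_factory=list)
    override_applied: bool = False


@dataclass
class StabilityCall:
    """Stability for enrollment; a mild call is unstable pending adjudication."""

    stable: bool
    needs_adjudication: bool = False
    verdict: Verdict = Verdict.STABLE

    def __bool__(self) -> bool:
        return self.stable


def _relative_drop(current: float, baseline: float) -> float:
    if baseline <= 0:
        return 0.0
    return (baseline - current) / baseline


def evaluate_signs(
    a: ClinicalAssessment,
    relative_lung_drop: bool = True,
) -> SignEvaluation:
    """Evaluate each objective sign criterion on an assessment.

    Returns the criteria met and the criteria that could not be evaluated
    for lack of inputs.  ``relative_lung_drop`` selects whether the 10%
    lung-function drop is relative to baseline (default) or an absolute
    drop of 10 percentage points of predicted.
    """
    met: list[str] = []
    unevaluated: list[str] = []

    # 10% drop in FEV1 or FVC (>=, relative to baseline by default)
    evaluable = False
    hit = False
    for cur, base in ((a.fev1_pp_current, a.baseline_fev1_pp),
                      (a.fvc_pp_current, a.baseline_fvc_pp)):
        if cur is None or base is None:
            continue
        evaluable = True
        if relative_lung_drop:
            if _relative_drop(cur, base) >= 0.10:
                hit = True
        elif (base - cur) >= 10.0:
            hit = True
    if evaluable:
        if hit:
            met.append("lung_function_drop")
    else:
        unevaluated.append("lung_function_drop")

    if a.temperature_C is None:
        unevaluated.append("temperature")
    elif a.temperature_C > 38.4:
        met.append("temperature")

    if a.witnessed_hemoptysis_ml is None:
        unevaluated.append("major_hemoptysis")
    elif a.witnessed_hemoptysis_ml > 100.0:
        met.append("major_hemoptysis")

    if a.sao2_percent is None and a.pao2_mmHg is None:
        unevaluated.append("hypoxemia")
    else:
        low_sat = a.sao2_percent is not None and a.sao2_percent < 90.0
        low_pao2 = a.pao2_mmHg is not None and a.pao2_mmHg < 60.0
        if (low_sat or low_pao2) and a.on_usual_oxygen:
            met.append("hypoxemia")

    if a.age_years is None or a.sao2_percent is None or a.baseline_sao2_percent is None:
        unevaluated.append("adolescent_desaturation")
    elif 12.0 <= a.age_years < 18.0 and (a.baseline_sao2_percent - a.sao2_percent) >= 5.0:
        met.append("adolescent_desaturation")

    if a.increased_o2_requirement:
        met.append("increased_o2_requirement")

    if (a.weight_kg_current is None or a.baseline_weight_kg is None
            or a.baseline_weight_kg <= 0):
        unevaluated.append("weight_loss")
    else:
        within_window = True
        if a.date is not None and a.baseline_weight_date is not None:
            within_window = (a.date - a.baseline_weight_date).days <= MAX_WEIGHT_LOSS_WINDOW_DAYS
        loss = (a.baseline_weight_kg - a.weight_kg_current) / a.baseline_weight_kg
        if within_window and loss >= 0.05:
            met.append("weight_loss")

    return SignEvaluation(met=met, unevaluated=unevaluated)


def classify_from_criteria(
    symptoms_met: frozenset[str] | set[str],
    signs_met: frozenset[str] | set[str],
    mechanical_ventilation: bool = False,
    pi_override: Override | None = None,
) -> Verdict:
    """Core verdict rule at the presence/absence level.

    Exacerbation iff (>=1 symptom and >=1 sign) or mechanical ventilation
    or an explicit PI override; a PI ``force_not`` override is final and
    downgrades to mild when any criterion is present (stable otherwise).
    """
    has_sym = len(symptoms_met) > 0
    has_sign = len(signs_met) > 0
    if pi_override is Override.FORCE_NOT:
        return Verdict.MILD if (has_sym or has_sign or mechanical_ventilation) else Verdict.STABLE
    if pi_override is Override.FORCE_EXACERBATION:
        return Verdict.EXACERBATION
    if mechanical_ventilation or (has_sym and has_sign):
        return Verdict.EXACERBATION
    if has_sym or has_sign:
        return Verdict.MILD
    return Verdict.STABLE


def classify(a: ClinicalAssessment, relative_lung_drop: bool = True) -> ExacerbationCall:
    """Classify an encounter as stable, mild, or pulmonary exacerbation."""
    signs = evaluate_signs(a, relative_lung_drop=relative_lung_drop)
    symptoms = sorted(a.symptoms, key=SYMPTOMS.index)
    verdict = classify_from_criteria(
        a.symptoms, set(signs.met), a.mechanical_ventilation, a.pi_override
    )
    return ExacerbationCall(
        verdict=verdict,
        symptoms_met=symptoms,
        signs_met=signs.met,
        signs_unevaluated=signs.unevaluated,
        override_applied=a.pi_override is not None,
    )


def is_clinically_stable(
    a: ClinicalAssessment,
    mild_blocks_enrollment: bool = True,
) -> StabilityCall:
    """Stability = absence of a pulmonary exacerbation.

    By default a mild call also blocks enrollment but is flagged for PI
    adjudication; set ``mild_blocks_enrollment=False`` to count mild
    presentations as stable.
    """
    call = classify(a)
    if call.verdict is Verdict.EXACERBATION:
        return StabilityCall(stable=False, verdict=call.verdict)
    if call.verdict is Verdict.MILD:
        return StabilityCall(
            stable=not mild_blocks_enrollment,
            needs_adjudication=True,
            verdict=call.verdict,
        )
    return StabilityCall(stable=True, verdict=call.verdict)


def prior_exacerbation_history(
    event_dates: list[date], enrollment_date: date, max_events: int = 5
) -> list[date]:
    """Up to the five most recent exacerbation dates strictly before enrollment.

    Sorted most-recent first; events on or after the enrollment date are
    excluded.  These dates adjust analyses for duration of clinical
    stability before sample collection.
    """
    prior = sorted((d for d in event_dates if d < enrollment_date), reverse=True)
    return prior[:max_events]


@dataclass(frozen=True)
class CollectionWindow:
    """A protocol sputum-collection window; ``due_end`` is exclusive."""

    kind: str  # enrollment | exacerbation | convalescent | additional | end_of_study
    due_start: datetime
    due_end: datetime
    onset: date | None = None


def _dt(d: date) -> datetime:
    return datetime(d.year, d.month, d.day)


def collection_windows(
    enrollment_date: date,
    exacerbation_onsets: list[date],
    study_end_date: date,
) -> list[CollectionWindow]:
    """Protocol sample schedule for one participant.

    Enrollment sample on day 0; for the first exacerbation, a sample within
    48 hours of onset and a convalescent sample 4-12 weeks (28-84 days)
    after onset; additional windows for any later exacerbations; a final
    sample at the end of the study.
    """
    onsets = sorted(exacerbation_onsets)
    if onsets and onsets[0] < enrollment_date:
        raise ValueError("exacerbation onset precedes enrollment")
    windows = [
        CollectionWindow("enrollment", _dt(enrollment_date), _dt(enrollment_date) + timedelta(days=1))
    ]
    for i, onset in enumerate(onsets):
        kind = "exacerbation" if i == 0 else "additional"
        windows.append(
            CollectionWindow(kind, _dt(onset), _dt(onset) + timedelta(hours=48), onset=onset)
        )
        if i == 0:
            windows.append(
                CollectionWindow(
                    "convalescent",
                    _dt(onset) + timedelta(days=28),
                    _dt(onset) + timedelta(days=84) + timedelta(days=1),
                    onset=onset,
                )
            )
    windows.append(
        CollectionWindow("end_of_study", _dt(study_end_date), _dt(study_end_date) + timedelta(days=1))
    )
    return windows
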