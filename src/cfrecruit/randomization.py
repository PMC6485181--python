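"""Concealment-preserving random-letter recruitment with adaptive speed control.

Each potentially eligible patient is pre-assigned a uniformly random letter
of the alphabet within their recruitment block (one adult and one pediatric
block per center).  A patient may be approached at clinic only if their
letter is strictly earlier in the alphabet than the block's threshold
letter; since letters are assigned before any clinic contact and inclusion
depends on nothing else, clinic staff cannot select patients by their
characteristics.

The threshold is expressed throughout as ``k``, the number of flagged
letters (k = 0: nobody flagged, k = 26: everybody).  A patient with letter
index ``ell`` (0 = 'A') is flagged iff ``ell < k``; the threshold letter
itself, index k, is never flagged.  The planning arithmetic is

    expected enrollment = (k / 26) * pool * consent_rate * show_rate

and the initial threshold is the smallest k meeting the enrollment target.
At scheduled reviews (end of study month 1, then quarterly from month 3)
the threshold is recomputed from the remaining pool and target with
consent/show rates re-estimated from the observed trace, moving earlier in
the alphabet when enrollment runs ahead of the pro-rata target and later
when it lags.  Moving the threshold never revokes a past decision, so the
scheme stays a randomization.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdState",
    "ThresholdDecision",
    "IntegrityReport",
    "assign_letters",
    "required_threshold",
    "is_flagged",
    "letter_name",
    "adjust_threshold",
    "opportunity_fraction",
    "default_review_dates",
    "simulate_enrollment",
    "permutation_balance_test",
    "check_randomization_integrity",
]

N_LETTERS = 26
#: Pseudo-observation weight shrinking rate re-estimates toward planning values.
RATE_SHRINKAGE_WEIGHT = 10.0
#: Relative band around the pro-rata target inside which the threshold is held.
ON_TARGET_BAND = 0.05


def letter_name(index: int) -> str:
    """'A' for 0 ... 'Z' for 25; 'none' for k=0 sentinel contexts."""
    if not 0 <= index <= 25:
        raise ValueError(f"letter index must be in [0, 25], got {index!r}")
    return string.ascii_uppercase[index]


@dataclass
class ThresholdState:
    """Threshold in force for one recruitment block, with its provenance."""

    block_key: str
    k: int
    effective_from: date
    rationale: str = "planned"  # "planned" | "speed_adjustment"
    consent_rate_estimate: float = 0.53
    show_rate_estimate: float = 0.90
    pool_size: int = 0
    target_total: int = 0
    target_remaining: int = 0
    study_start: date | None = None
    study_end: date | None = None
    insufficient_pool: bool = False
    # observation snapshot of the review that produced this state
    observed_enrolled: int | None = None
    prorata_target: float | None = None
    history: list["ThresholdState"] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.k <= N_LETTERS:
            raise ValueError(f"threshold index must be in [0, 26], got {self.k!r}")
        for name, r in (
            ("consent_rate_estimate", self.consent_rate_estimate),
            ("show_rate_estimate", self.show_rate_estimate),
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r!r}")


@dataclass(frozen=True)
class ThresholdDecision:
    """Result of the smallest-k planning computation."""

    k: int
    expected_enrollment: float
    insufficient_pool: bool

    @property
    def threshold_letter(self) -> str:
        """The first letter NOT flagged ('all' when every letter is flagged)."""
        return "all" if self.k == N_LETTERS else letter_name(self.k)


def assign_letters(patients: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Assign one i.i.d. uniform random letter (index 0-25) per patient.

    Letters are drawn with replacement, independently across patients and
    blocks, and independently of every covariate.  Returns columns
    patient_id, block_key, letter.
    """
    pids = patients["patient_id"]
    if pids.duplicated().any():
        dups = pids[pids.duplicated()].tolist()
        raise ValueError(f"duplicate patient_id(s): {dups[:5]}")
    rng = np.random.default_rng(seed)
    letters = rng.integers(0, N_LETTERS, size=len(patients))
    block_key = patients["center_id"].astype(str) + ":" + patients["block"].astype(str)
    return pd.DataFrame(
        {"patient_id": pids.to_numpy(), "block_key": block_key.to_numpy(), "letter": letters}
    )


def required_threshold(
    pool_size: int,
    target_enrollment: float,
    consent_rate: float,
    show_rate: float,
) -> ThresholdDecision:
    """Smallest k in 0..26 with (k/26) * pool * consent * show >= target.

    Returns k=26 with ``insufficient_pool=True`` when even flagging every
    letter cannot be expected to meet the target.
    """
    if pool_size < 0:
        raise ValueError(f"pool_size must be non-negative, got {pool_size!r}")
    if target_enrollment < 0:
        raise ValueError(f"target_enrollment must be non-negative, got {target_enrollment!r}")
    for name, r in (("consent_rate", consent_rate), ("show_rate", show_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r!r}")
    if target_enrollment > 0 and (consent_rate == 0.0 or show_rate == 0.0):
        raise ValueError("infeasible: zero consent or show rate with a positive target")
    per_letter = pool_size * consent_rate * show_rate / N_LETTERS
    for k in range(N_LETTERS + 1):
        if k * per_letter >= target_enrollment - 1e-9:
            return ThresholdDecision(k, k * per_letter, False)
    return ThresholdDecision(N_LETTERS, N_LETTERS * per_letter, True)


def is_flagged(letter: int, threshold_index: int) -> bool:
    """True iff the patient's letter is strictly earlier than the threshold."""
    if not 0 <= letter <= 25:
        raise ValueError(f"letter index must be in [0, 25], got {letter!r}")
    if not 0 <= threshold_index <= 26:
        raise ValueError(f"threshold index must be in [0, 26], got {threshold_index!r}")
    return letter < threshold_index


def default_review_dates(study_start: date, study_end: date) -> list[date]:
    """Review schedule: end of study month 1, then months 3, 6, 9, ...

    Study months are 30-day blocks from the start date; the review at the
    end of month m falls 30*m days after the start.
    """
    reviews = []
    m = 1
    while True:
        d = study_start + pd.Timedelta(days=30 * m).to_pytimedelta()
        if d >= study_end:
            break
        reviews.append(d)
        m = 3 if m == 1 else m + 3
    return reviews


@dataclass(frozen=True)
class PeriodSummary:
    """Observed counts needed by a threshold review.

    ``elapsed_fraction`` is the fraction of expected recruitment
    opportunities already elapsed, not raw calendar time: with periodic
    clinic visits, most patients are first seen within one visit interval,
    so the expected enrollment trajectory is concave in calendar time and
    a calendar pro-rata benchmark would misread the natural early surge
    as excessive speed.
    """

    scheduled: int           # visits scheduled so far (all patients in block)
    shown: int               # of those, attended
    approached: int          # flagged + shown + not previously decided
    consented: int           # of approached, consented (== enrolled)
    enrolled_cumulative: int
    elapsed_fraction: float  # of expected recruitment opportunities


def opportunity_fraction(
    t_days: float,
    horizon_days: float,
    visit_interval_days: float,
    show_rate: float,
    n_grid: int = 200,
) -> float:
    """Expected fraction of recruitment opportunities elapsed by day t.

    A patient with visit-schedule offset u (uniform on one interval) has
    had ``floor((t - u)/interval) + 1`` scheduled visits by day t and has
    been seen at least once with probability ``1 - (1-s)^visits``.  The
    returned value is the offset-averaged probability at t relative to the
    study horizon.
    """
    if t_days <= 0:
        return 0.0
    s = min(max(show_rate, 1e-6), 1.0)
    offsets = (np.arange(n_grid) + 0.5) * visit_interval_days / n_grid

    def seen(t: float) -> float:
        visits = np.floor((t - offsets) / visit_interval_days) + 1.0
        visits = np.clip(visits, 0.0, None)
        return float(np.mean(1.0 - (1.0 - s) ** visits))

    denom = seen(horizon_days)
    if denom <= 0:
        return 0.0
    return min(seen(t_days) / denom, 1.0)


def _shrunk_rate(successes: int, trials: int, prior: float) -> float:
    """Empirical rate shrunk toward the planning value by pseudo-visits."""
    w = RATE_SHRINKAGE_WEIGHT
    return (successes + w * prior) / (trials + w)


def adjust_threshold(
    state: ThresholdState,
    observed: PeriodSummary,
    review_date: date,
    visits_remaining_per_patient: float = 1.0,
) -> ThresholdState:
    """Recompute the threshold at a scheduled review.

    The remaining pool is the block pool minus patients already approached
    (an approach is a final decision: enrolled or refused).  Consent and
    show rates are re-estimated from the trace with shrinkage toward the
    planning values.  A patient still in the pool gets
    ``visits_remaining_per_patient`` more chances to attend, so the
    effective show rate is ``1 - (1 - s)^v``.

    Direction rule: when cumulative enrollment exceeds the pro-rata
    (opportunity-weighted) target beyond a +/-5% band, the new k is
    strictly smaller (earlier threshold letter, slower enrollment); when
    it lags, strictly larger; inside the band the threshold is held.
    Braking is one letter at a time because enrollment already granted
    cannot be undone, while catch-up jumps straight to the recomputed k.
    Past flag decisions are never altered -- the returned state only
    governs future visits.
    """
    if observed.elapsed_fraction <= 0:
        raise ValueError("review before any observation period")
    if review_date < state.effective_from:
        raise ValueError("review_date precedes the state in force")
    prorata = observed.elapsed_fraction * state.target_total
    c_hat = _shrunk_rate(observed.consented, observed.approached, state.consent_rate_estimate)
    s_hat = _shrunk_rate(observed.shown, observed.scheduled, state.show_rate_estimate)
    v = max(visits_remaining_per_patient, 0.0)
    s_eff = 1.0 - (1.0 - s_hat) ** v if v > 0 else 0.0
    remaining_pool = max(state.pool_size - observed.approached, 0)
    remaining_target = max(state.target_total - observed.enrolled_cumulative, 0)

    if s_eff <= 0.0 and remaining_target > 0:
        k_req, insufficient = state.k, True
    else:
        dec = required_threshold(remaining_pool, remaining_target, c_hat, max(s_eff, 1e-12))
        k_req, insufficient = dec.k, dec.insufficient_pool

    band = ON_TARGET_BAND * max(prorata, 1.0)
    if observed.enrolled_cumulative > prorata + band:
        k_new = state.k - 1                      # too rapid -> earlier letter
    elif observed.enrolled_cumulative < prorata - band:
        # too slow -> later letter; at most two letters per review, since a
        # jump opens a backlog of newly flagged patients all at once and
        # enrollment already granted cannot be braked away.
        k_new = min(max(k_req, state.k + 1), state.k + 2)
    else:
        k_new = state.k                          # on target -> hold
    k_new = int(min(max(k_new, 0), N_LETTERS))

    new = ThresholdState(
        block_key=state.block_key,
        k=k_new,
        effective_from=review_date,
        rationale="speed_adjustment" if k_new != state.k else "planned",
        consent_rate_estimate=c_hat,
        show_rate_estimate=s_hat,
        pool_size=state.pool_size,
        target_total=state.target_total,
        target_remaining=remaining_target,
        study_start=state.study_start,
        study_end=state.study_end,
        insufficient_pool=insufficient,
        observed_enrolled=observed.enrolled_cumulative,
        prorata_target=prorata,
        history=state.history + [state],
    )
    return new


def simulate_enrollment(
    patients: pd.DataFrame,
    letters: pd.DataFrame,
    visits: pd.DataFrame,
    initial_states: dict[str, ThresholdState],
    review_dates: list[date] | None = None,
    consent_rate_true: float = 0.53,
    seed: int = 0,
    visit_interval_days: int = 91,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replay the recruitment process over a visit stream.

    Visits are processed in (date, patient_id) order.  A patient who shows,
    is eligible, is flagged under the threshold in force on the visit date,
    and has not already been decided is approached; consent is a Bernoulli
    draw with the true (simulated) consent rate.  Thresholds are reviewed
    and possibly adjusted at the given review dates (default schedule:
    month 1 then quarterly).

    Returns ``(trace, threshold_history)``.  The trace has one row per
    visit with columns patient_id, block_key, visit_date, letter, showed,
    flagged, approached, consented, enrolled, k_in_force.  The threshold
    history has one row per (block, state) with effective_from, k,
    rationale and rate estimates.
    """
    lt = letters.set_index("patient_id")
    unknown = set(visits["patient_id"]) - set(lt.index)
    if unknown:
        raise ValueError(f"visit references unknown patient(s): {sorted(unknown)[:5]}")
    elig = patients.set_index("patient_id")["eligible"]
    rng = np.random.default_rng(seed)

    states = {bk: st for bk, st in initial_states.items()}
    if review_dates is None:
        any_state = next(iter(states.values()))
        if any_state.study_start is None or any_state.study_end is None:
            raise ValueError("review_dates omitted and state lacks study_start/study_end")
        review_dates = default_review_dates(any_state.study_start, any_state.study_end)
    pending_reviews = sorted(review_dates)

    # Per-block running counts feeding the reviews.
    counts = {
        bk: {"scheduled": 0, "shown": 0, "approached": 0, "consented": 0}
        for bk in states
    }
    decided: set[str] = set()   # approached at least once (final)
    enrolled: set[str] = set()

    ordered = visits.sort_values(["visit_date", "patient_id"], kind="stable")
    trace_rows = []
    for row in ordered.itertuples(index=False):
        vdate = row.visit_date
        while pending_reviews and vdate >= pending_reviews[0]:
            rdate = pending_reviews.pop(0)
            for bk, st in states.items():
                span = (st.study_end - st.study_start).days or 1
                elapsed = opportunity_fraction(
                    (rdate - st.study_start).days, span,
                    visit_interval_days, st.show_rate_estimate,
                )
                elapsed = min(max(elapsed, 1e-9), 1.0)
                remaining_days = max((st.study_end - rdate).days, 0)
                v_remaining = remaining_days / visit_interval_days
                summary = PeriodSummary(
                    scheduled=counts[bk]["scheduled"],
                    shown=counts[bk]["shown"],
                    approached=counts[bk]["approached"],
                    consented=counts[bk]["consented"],
                    enrolled_cumulative=counts[bk]["consented"],
                    elapsed_fraction=elapsed,
                )
                states[bk] = adjust_threshold(st, summary, rdate, v_remaining)
        pid = row.patient_id
        letter = int(lt.at[pid, "letter"])
        bk = lt.at[pid, "block_key"]
        st = states[bk]
        counts[bk]["scheduled"] += 1
        showed = bool(row.showed)
        if showed:
            counts[bk]["shown"] += 1
        flagged = is_flagged(letter, st.k)
        approached = False
        consented = False
        if showed and flagged and pid not in decided and bool(elig.get(pid, False)):
            approached = True
            decided.add(pid)
            counts[bk]["approached"] += 1
            consented = bool(rng.random() < consent_rate_true)
            if consented:
                counts[bk]["consented"] += 1
                enrolled.add(pid)
        trace_rows.append(
            {
                "patient_id": pid,
                "block_key": bk,
                "visit_date": vdate,
                "letter": letter,
                "showed": showed,
                "flagged": flagged,
                "approached": approached,
                "consented": consented,
                "enrolled": consented,
                "k_in_force": st.k,
            }
        )

    hist_rows = []
    for bk, st in states.items():
        for s in st.history + [st]:
            hist_rows.append(
                {
                    "block_key": bk,
                    "effective_from": s.effective_from,
                    "k": s.k,
                    "rationale": s.rationale,
                    "consent_rate_estimate": s.consent_rate_estimate,
                    "show_rate_estimate": s.show_rate_estimate,
                    "observed_enrolled": s.observed_enrolled,
                    "prorata_target": s.prorata_target,
                }
            )
    trace = pd.DataFrame(trace_rows)
    history = pd.DataFrame(hist_rows).sort_values(["block_key", "effective_from"]).reset_index(drop=True)
    return trace, history


def permutation_balance_test(
    values: np.ndarray,
    flags: np.ndarray,
    n_permutations: int = 499,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for a covariate mean difference between groups.

    Statistic: |mean(values[flags]) - mean(values[~flags])|.  The p-value
    (1 + #{permuted >= observed}) / (n_permutations + 1) is uniform on a
    fine grid under exchangeability, i.e. when flags carry no information
    about the covariate.  Returns 1.0 when either group is empty.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    n1 = int(flags.sum())
    n = flags.size
    if n1 == 0 or n1 == n:
        return 1.0
    total = values.sum()
    obs = abs(values[flags].mean() - values[~flags].mean())
    # One shuffled flag vector per permutation, vectorized via argsort.
    order = np.argsort(rng.random((n_permutations, n)), axis=1)[:, :n1]
    sums1 = values[order].sum(axis=1)
    perm = np.abs(sums1 / n1 - (total - sums1) / (n - n1))
    return (1.0 + np.count_nonzero(perm >= obs - 1e-12)) / (n_permutations + 1.0)


@dataclass
class IntegrityReport:
    """Replay and covariate-balance diagnostics for a recruitment trace."""

    n_decisions: int
    n_mismatches: int
    mismatches: list[dict]
    balance_p_values: dict[str, float]
    replay_ok: bool
    balance_ok: bool

    @property
    def passed(self) -> bool:
        return self.replay_ok and self.balance_ok


def _k_in_force(history: pd.DataFrame, block_key: str, on_date: date) -> int:
    h = history[history["block_key"] == block_key]
    h = h[h["effective_from"] <= on_date]
    if h.empty:
        raise ValueError(f"no threshold in force for {block_key} on {on_date}")
    return int(h.sort_values("effective_from").iloc[-1]["k"])


def check_randomization_integrity(
    trace: pd.DataFrame,
    letters: pd.DataFrame,
    threshold_history: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    covariates: tuple[str, ...] = ("age_at_baseline", "fev1pp", "prior_year_exacerbations"),
    balance_alpha: float = 0.001,
    n_permutations: int = 499,
    seed: int = 0,
) -> IntegrityReport:
    """Verify that inclusion depended only on letters and the threshold schedule.

    (a) Replay: every ``flagged`` decision in the trace is recomputed as
    ``is_flagged(letter, k in force on the visit date)``; mismatches are
    listed.  (b) Exchangeability: a permutation test per covariate that the
    flagged and unflagged patients differ no more than chance; under a
    correct randomization the p-values are uniform, and the check fails
    only below ``balance_alpha``.
    """
    lt = letters.set_index("patient_id")["letter"]
    missing = set(trace["patient_id"]) - set(lt.index)
    if missing:
        raise ValueError(f"letters missing for traced patient(s): {sorted(missing)[:5]}")
    mismatches = []
    for row in trace.itertuples(index=False):
        k = _k_in_force(threshold_history, row.block_key, row.visit_date)
        expect = is_flagged(int(lt.at[row.patient_id]), k)
        if bool(row.flagged) != expect:
            mismatches.append(
                {"patient_id": row.patient_id, "visit_date": row.visit_date,
                 "recorded": bool(row.flagged), "expected": expect, "k": k}
            )
    balance: dict[str, float] = {}
    if patients is not None:
        rng = np.random.default_rng(seed)
        first = trace.sort_values(["visit_date", "patient_id"]).drop_duplicates("patient_id")
        merged = first.merge(patients, on="patient_id", how="inner")
        for cov in covariates:
            if cov not in merged.columns:
                continue
            balance[cov] = permutation_balance_test(
                merged[cov].to_numpy(dtype=float),
                merged["flagged"].to_numpy(dtype=bool),
                n_permutations=n_permutations,
                rng=rng,
            )
    replay_ok = not mismatches
    balance_ok = all(p >= balance_alpha for p in balance.values())
    return IntegrityReport(
        n_decisions=len(trace),
        n_mismatches=len(mismatches),
        mismatches=mismatches,
        balance_p_values=balance,
        replay_ok=replay_ok,
        balance_ok=balance_ok,
    )
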