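"""Median-score stratification and Kaplan-Meier diabetes-free survival.

The timescale is age in years: an individual's "survival time" is their age
at diabetes diagnosis (event) or their age at study entry (censored), with
administrative censoring at a fixed age (default 60) — events recorded later
count as censored non-events at that age. Self-reported integer diagnosis
ages produce tied event times, handled by the standard product-limit formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grs import ScoreVector
from .io_config import CohortTable, ValidationError


@dataclass
class StratifiedCohort:
    """Cohort joined to scores, split into high/low halves at the median.

    ``data`` adds ``score`` and ``group`` ({"high", "low"}) columns to the
    cohort table.
    """

    data: pd.DataFrame
    median_cutoff: float

    @property
    def n_high(self) -> int:
        return int((self.data["group"] == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.data["group"] == "low").sum())

    def group_frame(self, group: str) -> pd.DataFrame:
        return self.data[self.data["group"] == group]


@dataclass
class KMCurve:
    """Product-limit estimate: one row per distinct event/censor time."""

    table: pd.DataFrame  # columns: time, n_at_risk, n_events, n_censored, survival
    group: str = ""

    def survival_at(self, times: np.ndarray) -> np.ndarray:
        """Step-function evaluation of S(t) (right-continuous)."""
        t = self.table["time"].to_numpy()
        s = self.table["survival"].to_numpy()
        idx = np.searchsorted(t, np.asarray(times, dtype=float), side="right") - 1
        out = np.where(idx >= 0, s[np.clip(idx, 0, len(s) - 1)], 1.0)
        return out


def split_by_median(scores: ScoreVector, cohort: CohortTable) -> StratifiedCohort:
    """Rank individuals by score and split them at the median.

    Scores strictly above the median go to the high group, strictly below to
    the low group. Individuals tied exactly at the median are alternated
    deterministically in sample-id sort order, each assigned to whichever
    group is currently smaller (ties broken toward "low"), so the two halves
    balance to within one individual.
    """
    merged = cohort.data.merge(
        scores.frame[["sample_id", "score"]], left_on="id", right_on="sample_id", how="inner"
    ).drop(columns="sample_id")
    if len(merged) < 2:
        raise ValidationError("need at least two scored individuals to stratify")
    s = merged["score"].to_numpy()
    median = float(np.median(s))
    if np.ptp(s) == 0:
        raise ValidationError("all scores identical: median stratification undefined")

    group = np.where(s > median, "high", "low").astype(object)
    tied = np.flatnonzero(s == median)
    if tied.size:
        n_high = int((s > median).sum())
        n_low = int((s < median).sum())
        order = tied[np.argsort(merged["id"].to_numpy()[tied], kind="stable")]
        for i in order:
            if n_low <= n_high:
                group[i] = "low"
                n_low += 1
            else:
                group[i] = "high"
                n_high += 1
    merged["group"] = group
    return StratifiedCohort(merged, median)


def _event_inputs(
    cohort_frame: pd.DataFrame, censor_age: float
) -> tuple[np.ndarray, np.ndarray]:
    """(duration, event) pairs under the censoring rules: non-diabetic
    individuals censor at enrolment; everyone censors administratively at
    ``censor_age``; diagnoses after that age are censored non-events."""
    enrol = cohort_frame["enrolment_age"].to_numpy(dtype=float)
    diag = cohort_frame["age_at_diagnosis"].to_numpy(dtype=float)
    has = cohort_frame["has_diabetes"].to_numpy(dtype=bool)

    event = has & (diag <= censor_age)
    duration = np.where(event, diag, np.minimum(enrol, censor_age))
    return duration, event


def km_estimate(
    durations: np.ndarray,
    events: np.ndarray,
    censor_age: float | None = None,
    group: str = "",
) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over distinct event times t_i <= t of (1 - d_i / n_i),
    with d_i events among n_i at risk. If ``censor_age`` is given, events
    after it are converted to censorings at that age.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValidationError("empty survival input")
    if np.any(durations < 0):
        raise ValidationError("negative ages in survival input")
    if censor_age is not None:
        late = durations > censor_age
        events = events & ~late
        durations = np.minimum(durations, censor_age)

    order = np.argsort(durations, kind="stable")
    d = durations[order]
    e = events[order]
    times, start = np.unique(d, return_index=True)
    n_total = d.size
    # counts per distinct time
    counts = np.diff(np.append(start, n_total))
    ev = np.add.reduceat(e.astype(int), start)
    n_at_risk = n_total - start
    cens = counts - ev

    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - ev / n_at_risk
    survival = np.cumprod(factors)
    table = pd.DataFrame(
        {
            "time": times,
            "n_at_risk": n_at_risk,
            "n_events": ev,
            "n_censored": cens,
            "survival": survival,
        }
    )
    return KMCurve(table, group)


def km_by_group(stratified: StratifiedCohort, censor_age: float = 60.0) -> dict[str, KMCurve]:
    """Per-stratum diabetes-free survival under the cohort censoring rules."""
    curves = {}
    for grp in ("high", "low"):
        frame = stratified.group_frame(grp)
        dur, ev = _event_inputs(frame, censor_age)
        curves[grp] = km_estimate(dur, ev, group=grp)
    return curves


def km_hazard_ratio(
    durations_high: np.ndarray,
    events_high: np.ndarray,
    durations_low: np.ndarray,
    events_low: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Hazard ratio (high vs low) in the observed/expected log-rank form.

    HR = (O_h / E_h) / (O_l / E_l) with E the log-rank expected event counts,
    CI on the log scale with SE = sqrt(1/E_h + 1/E_l). Also returns the
    log-rank chi-square p-value. With zero events in either group the HR is
    undefined and reported as NaN.
    """
    dh = np.asarray(durations_high, dtype=float)
    eh = np.asarray(events_high, dtype=bool)
    dl = np.asarray(durations_low, dtype=float)
    el = np.asarray(events_low, dtype=bool)
    if dh.size == 0 or dl.size == 0:
        raise ValidationError("both groups must be non-empty")

    all_times = np.unique(np.concatenate([dh[eh], dl[el]]))
    O_h = float(eh.sum())
    O_l = float(el.sum())
    E_h = 0.0
    E_l = 0.0
    V = 0.0
    for t in all_times:
        n_h = float((dh >= t).sum())
        n_l = float((dl >= t).sum())
        d_h = float((dh[eh] == t).sum())
        d_l = float((dl[el] == t).sum())
        n = n_h + n_l
        d = d_h + d_l
        if n == 0:
            continue
        E_h += d * n_h / n
        E_l += d * n_l / n
        if n > 1:
            V += d * (n_h / n) * (n_l / n) * (n - d) / (n - 1)

    if O_h == 0 or O_l == 0 or E_h == 0 or E_l == 0:
        return {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_logrank": np.nan}

    log_hr = np.log((O_h / E_h) / (O_l / E_l))
    se = np.sqrt(1.0 / E_h + 1.0 / E_l)
    z = stats.norm.ppf(1 - alpha / 2)
    chi2 = (O_h - E_h) ** 2 / V if V > 0 else np.nan
    return {
        "hr": float(np.exp(log_hr)),
        "ci_low": float(np.exp(log_hr - z * se)),
        "ci_high": float(np.exp(log_hr + z * se)),
        "p_logrank": float(stats.chi2.sf(chi2, df=1)) if np.isfinite(chi2) else np.nan,
    }


def group_hazard_ratio(stratified: StratifiedCohort, censor_age: float = 60.0, alpha: float = 0.05) -> dict:
    """Hazard ratio high vs low for a stratified cohort."""
    hi = stratified.group_frame("high")
    lo = stratified.group_frame("low")
    dh, eh = _event_inputs(hi, censor_age)
    dl, el = _event_inputs(lo, censor_age)
    return km_hazard_ratio(dh, eh, dl, el, alpha=alpha)


def lifetable_frame(curves: dict[str, KMCurve]) -> pd.DataFrame:
    """Stacked per-group life table for CSV output."""
    frames = []
    for grp, curve in curves.items():
        tab = curve.table.copy()
        tab.insert(0, "group", grp)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
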