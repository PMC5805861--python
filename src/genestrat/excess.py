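"""The subtraction estimator for the genetically defined latent subgroup.

Because the low-scoring half of the population carries essentially no type 1
risk, and type 2 diabetes is equally frequent in both halves, the number of
type 1 cases is estimated as the excess of diabetes cases in the high half
over the low half — overall, per right-closed age band, cumulatively by age
of diagnosis, and per decade. Negative excesses (sampling noise) are reported
as-is and flagged, never clamped, so that band decompositions always sum to
the overall value exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import ValidationError
from .survival import StratifiedCohort

logger = logging.getLogger(__name__)


@dataclass
class ExcessEstimate:
    n_high_cases: int
    n_low_cases: int
    total_cases: int
    proportion_pct: float  # excess / total cases, as a percentage
    ci_low_pct: float
    ci_high_pct: float
    ci_method: str
    by_band: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def excess(self) -> int:
        return self.n_high_cases - self.n_low_cases


def excess_count(n_high_cases: int, n_low_cases: int) -> int:
    """Excess cases in the high-susceptibility half: high minus low.

    May be negative under sampling noise; flagged but never truncated.
    """
    if n_high_cases < 0 or n_low_cases < 0:
        raise ValidationError("case counts must be non-negative")
    excess = int(n_high_cases) - int(n_low_cases)
    if excess < 0:
        logger.warning(
            "negative excess (%d): low group has more cases than high; sampling noise dominates",
            excess,
        )
    return excess


def proportion_t1d(excess: int, total_cases: int) -> float:
    """Point estimate of the latent-subgroup share of all cases, in percent."""
    if total_cases <= 0:
        raise ValidationError("total case count must be positive")
    return 100.0 * excess / total_cases


def bootstrap_proportion_ci(
    n_high_cases: int,
    n_low_cases: int,
    n_total: int,
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI (percent scale) for excess / total cases.

    Resampling individuals with replacement and recounting the three
    categories (high-group case, low-group case, non-case) is equivalent to a
    multinomial redraw of the category counts, which is what is done here.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_cases = n_high_cases + n_low_cases
    if n_total < n_cases:
        raise ValidationError("total cohort size smaller than case count")
    probs = np.array([n_high_cases, n_low_cases, n_total - n_cases], dtype=float) / n_total
    draws = rng.multinomial(n_total, probs, size=n_boot).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        props = 100.0 * (draws[:, 0] - draws[:, 1]) / (draws[:, 0] + draws[:, 1])
    props = props[np.isfinite(props)]
    lo, hi = np.percentile(props, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def wald_proportion_ci(
    n_high_cases: int, n_low_cases: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Normal-approximation CI treating the two case counts as independent
    Poisson, so var(excess) = n_high + n_low; delta method on excess/total."""
    h, l = float(n_high_cases), float(n_low_cases)
    total = h + l
    if total <= 0:
        raise ValidationError("no cases: proportion undefined")
    p = (h - l) / total
    # gradient of (h-l)/(h+l): d/dh = 2l/total^2, d/dl = -2h/total^2
    var = (2 * l / total**2) ** 2 * h + (2 * h / total**2) ** 2 * l
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(100 * (p - half)), float(100 * (p + half))


def _case_frame(stratified: StratifiedCohort, censor_age: float) -> pd.DataFrame:
    """Diabetes cases counted by the estimator: diagnosed at or before the
    administrative censoring age."""
    df = stratified.data
    mask = df["has_diabetes"] & (df["age_at_diagnosis"] <= censor_age)
    return df[mask]


def _band_label(lo: float, hi: float, first: bool) -> str:
    return f"{int(lo)}-{int(hi)}" if first else f"{int(lo) + 1}-{int(hi)}"


def band_masks(ages: np.ndarray, edges: tuple[float, ...]) -> list[tuple[str, np.ndarray]]:
    """Right-closed integer-age band membership: with edges [0, 30, 60] the
    bands are 0-30 (age <= 30, including age 0) and 31-60 (31 <= age <= 60)."""
    edges = tuple(edges)
    if not all(b > a for a, b in zip(edges, edges[1:])):
        raise ValidationError("band edges must be strictly increasing (bands must not overlap)")
    out = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        first = i == 0
        mask = (ages <= hi) if first else (ages > lo) & (ages <= hi)
        out.append((_band_label(lo, hi, first), mask))
    return out


def excess_estimate(
    stratified: StratifiedCohort,
    censor_age: float = 60.0,
    band_edges: tuple[float, ...] = (0, 30, 60),
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ExcessEstimate:
    """Overall and per-band excess with a CI on the overall share.

    Per band: high/low/excess/total counts, the band's share of the total
    excess, and the excess's share of all cases in the band. Band excesses sum
    to the overall excess exactly (bands partition (0, censor_age] with the
    first band closed at 0).
    """
    cases = _case_frame(stratified, censor_age)
    n_high = int((cases["group"] == "high").sum())
    n_low = int((cases["group"] == "low").sum())
    total = n_high + n_low
    if total == 0:
        raise ValidationError("no diabetes cases before the censoring age")
    exc = excess_count(n_high, n_low)
    point = proportion_t1d(exc, total)
    if ci_method == "bootstrap":
        lo, hi = bootstrap_proportion_ci(
            n_high, n_low, len(stratified.data), n_boot=n_boot, alpha=alpha, rng=rng
        )
    elif ci_method == "wald":
        lo, hi = wald_proportion_ci(n_high, n_low, alpha=alpha)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    ages = cases["age_at_diagnosis"].to_numpy(dtype=float)
    groups = cases["group"].to_numpy()
    rows = []
    for label, mask in band_masks(ages, band_edges):
        bh = int(((groups == "high") & mask).sum())
        bl = int(((groups == "low") & mask).sum())
        b_exc = bh - bl
        b_tot = bh + bl
        rows.append(
            {
                "band": label,
                "n_high": bh,
                "n_low": bl,
                "excess": b_exc,
                "total": b_tot,
                "share_of_excess_pct": 100.0 * b_exc / exc if exc != 0 else np.nan,
                "share_of_band_total_pct": 100.0 * b_exc / b_tot if b_tot else np.nan,
            }
        )
    by_band = pd.DataFrame(rows)
    if len(by_band) and by_band["excess"].sum() != exc:
        raise AssertionError("band excesses failed to sum to the overall excess")
    return ExcessEstimate(n_high, n_low, total, point, lo, hi, ci_method, by_band)


def cumulative_excess(stratified: StratifiedCohort, censor_age: float = 60.0) -> pd.DataFrame:
    """Cumulative excess of cases by age of diagnosis, one row per year of
    age 1..censor_age; the final value equals the overall excess."""
    cases = _case_frame(stratified, censor_age)
    ages = cases["age_at_diagnosis"].to_numpy(dtype=float)
    groups = cases["group"].to_numpy()
    grid = np.arange(1, int(censor_age) + 1, dtype=float)
    cum_high = np.searchsorted(np.sort(ages[groups == "high"]), grid, side="right")
    cum_low = np.searchsorted(np.sort(ages[groups == "low"]), grid, side="right")
    return pd.DataFrame(
        {
            "age": grid.astype(int),
            "cumulative_high": cum_high,
            "cumulative_low": cum_low,
            "cumulative_excess": cum_high - cum_low,
        }
    )


def incidence_by_decade(
    stratified: StratifiedCohort,
    censor_age: float = 60.0,
    decade_edges: tuple[float, ...] = (0, 10, 20, 30, 40, 50, 60),
) -> pd.DataFrame:
    """Per-decade counts of genetically defined type 1 (the excess) and
    type 2 (total minus excess, so the two series sum to observed totals)."""
    cases = _case_frame(stratified, censor_age)
    ages = cases["age_at_diagnosis"].to_numpy(dtype=float)
    groups = cases["group"].to_numpy()
    rows = []
    for label, mask in band_masks(ages, decade_edges):
        bh = int(((groups == "high") & mask).sum())
        bl = int(((groups == "low") & mask).sum())
        exc = bh - bl
        tot = bh + bl
        rows.append({"decade": label, "type1_excess": exc, "type2": tot - exc, "total": tot})
    return pd.DataFrame(rows)
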