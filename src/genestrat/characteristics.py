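"""Clinical characteristics of the latent excess group, by subtraction.

The high-scoring half's cases are a mixture of the latent type 1 group and a
type 2 component distributed exactly as the low half's cases. Summary
statistics of the latent group therefore follow by moment subtraction:

    mean_T1D = (n_H * mean_H - n_L * mean_L) / n_T1D,   n_T1D = n_H - n_L

and, reconstructing second moments as E[X^2] = var + mean^2 (population
convention), the latent SD the same way. For a characteristic whose pooled
distribution is bimodal (BMI), the subtracted second moment is unstable and
the type 2 group's SD is borrowed instead. Categorical characteristics are
subtracted per category as count excesses.

Group comparisons use chi-square tests (no continuity correction) for
categorical characteristics and Welch t tests from summary statistics for
continuous ones, Bonferroni-adjusted over the number of characteristics
tested (default 7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import PipelineConfig, ValidationError
from .survival import StratifiedCohort

logger = logging.getLogger(__name__)

#: (name, cohort column, derived-SD mode)
CONTINUOUS_CHARACTERISTICS = [
    ("age_at_entry", "enrolment_age", "moment_subtraction"),
    ("age_at_diagnosis", "age_at_diagnosis", "moment_subtraction"),
    ("bmi", "bmi", "borrow_t2d_sd"),
]

#: (name, cohort column); sex is encoded as the male indicator
CATEGORICAL_CHARACTERISTICS = [
    ("male", "sex"),
    ("insulin_1yr", "insulin_within_1yr"),
    ("insulin_entry", "insulin_at_entry"),
    ("dka", "dka_admission"),
]

#: characteristics counted toward the Bonferroni multiplier (sex once)
TESTED_CHARACTERISTICS = [
    "age_at_entry", "age_at_diagnosis", "male", "bmi",
    "insulin_1yr", "insulin_entry", "dka",
]


# ---------------------------------------------------------------------------
# Subtraction algebra (pure functions)


def derived_mean(n_high: int, mean_high: float, n_low: int, mean_low: float, n_t1d: int) -> float:
    """Latent-group mean by subtraction of group totals."""
    if n_t1d <= 0:
        raise ValidationError(
            "derived mean undefined for non-positive latent group size "
            f"(n_t1d={n_t1d}); sampling noise dominates the excess"
        )
    if n_high - n_low != n_t1d:
        raise ValidationError("n_t1d must equal n_high - n_low")
    return (n_high * mean_high - n_low * mean_low) / n_t1d


def derived_sd(
    n_high: int,
    mean_high: float,
    sd_high: float,
    n_low: int,
    mean_low: float,
    sd_low: float,
    n_t1d: int,
    mode: str = "moment_subtraction",
    ddof: int = 0,
) -> float:
    """Latent-group SD, by second-moment subtraction or borrowed from the
    comparison group.

    ``ddof`` declares the convention of the input SDs and of the returned SD
    (0 = population, 1 = sample). Internally moments use the population
    convention, under which the subtraction identity is exact for any true
    decomposition of the high group into the low group plus a latent group.
    """
    if sd_high < 0 or sd_low < 0:
        raise ValidationError("SDs must be non-negative")
    if mode == "borrow_t2d_sd":
        return float(sd_low)
    if mode != "moment_subtraction":
        raise ValidationError(f"unknown derived-SD mode {mode!r}")
    if n_t1d <= 0:
        raise ValidationError("derived SD undefined for non-positive latent group size")

    def to_pop_var(sd: float, n: int) -> float:
        v = sd * sd
        return v * (n - ddof) / n if ddof else v

    m_t = derived_mean(n_high, mean_high, n_low, mean_low, n_t1d)
    ex2_h = to_pop_var(sd_high, n_high) + mean_high**2
    ex2_l = to_pop_var(sd_low, n_low) + mean_low**2
    ex2_t = (n_high * ex2_h - n_low * ex2_l) / n_t1d
    var_t = ex2_t - m_t**2
    if var_t < 0:
        if var_t > -1e-9 * max(ex2_t, 1.0):  # numerical jitter around zero
            var_t = 0.0
        else:
            raise ValidationError(
                f"negative reconstructed variance ({var_t:.4g}): "
                "inconsistent summary inputs or sampling noise"
            )
    if ddof:
        if n_t1d - ddof <= 0:
            raise ValidationError("latent group too small for the requested ddof")
        var_t = var_t * n_t1d / (n_t1d - ddof)
    return float(np.sqrt(var_t))


def derived_categorical(count_high: int, count_low: int) -> int:
    """Latent-group count for one category: high minus low."""
    if count_high < 0 or count_low < 0:
        raise ValidationError("category counts must be non-negative")
    excess = int(count_high) - int(count_low)
    if excess < 0:
        logger.warning("negative derived category count (%d); sampling noise", excess)
    return excess


# ---------------------------------------------------------------------------
# Group summaries


@dataclass
class GroupSummary:
    """Per-group clinical summary.

    ``continuous`` maps characteristic -> (n_obs, mean, sd) with population
    (ddof=0) SDs; ``categorical`` maps characteristic -> (n_obs, count).
    """

    label: str
    n: int
    continuous: dict[str, tuple[int, float, float]] = field(default_factory=dict)
    categorical: dict[str, tuple[int, int]] = field(default_factory=dict)


def summarize_group(frame: pd.DataFrame, label: str) -> GroupSummary:
    """Summaries of the seven clinical characteristics for a case subset."""
    out = GroupSummary(label, len(frame))
    for name, col, _mode in CONTINUOUS_CHARACTERISTICS:
        vals = pd.to_numeric(frame[col], errors="coerce").dropna().to_numpy(dtype=float)
        if vals.size:
            out.continuous[name] = (vals.size, float(vals.mean()), float(vals.std(ddof=0)))
        else:
            out.continuous[name] = (0, np.nan, np.nan)
    for name, col in CATEGORICAL_CHARACTERISTICS:
        series = frame[col]
        if col == "sex":
            obs = series.dropna()
            out.categorical[name] = (len(obs), int((obs == "male").sum()))
        else:
            obs = series.dropna().astype(bool)
            out.categorical[name] = (len(obs), int(obs.sum()))
    return out


# ---------------------------------------------------------------------------
# Comparisons


def welch_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float, ddof: int = 0
) -> float:
    """Two-sided Welch t-test p-value from summary statistics.

    ``ddof`` declares the convention of the input SDs; sample variances are
    reconstructed before applying the Welch-Satterthwaite formula.
    """
    if min(n1, n2) < 2:
        raise ValidationError("Welch test needs at least two observations per group")

    def sample_var(sd: float, n: int) -> float:
        v = sd * sd
        return v if ddof == 1 else v * n / (n - 1)

    v1, v2 = sample_var(sd1, n1), sample_var(sd2, n2)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return 1.0 if mean1 == mean2 else 0.0
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(2 * stats.t.sf(abs(t), df))


def chi_square_2x2(
    yes1: int, n1: int, yes2: int, n2: int, correction: bool = False
) -> float:
    """Chi-square p-value for a 2x2 table of (yes, no) counts per group.

    No continuity correction by default; identical proportions give p = 1.
    Returns NaN (with a warning) when any expected cell count is zero or a
    count is negative (possible for noisy derived counts).
    """
    table = np.array([[yes1, n1 - yes1], [yes2, n2 - yes2]], dtype=float)
    if (table < 0).any():
        logger.warning("chi-square invalid: negative cell in %s", table.tolist())
        return np.nan
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        logger.warning("chi-square invalid: zero marginal in %s", table.tolist())
        return np.nan
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(p)


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if np.isnan(p):
        return np.nan
    return float(min(1.0, p * n_tests))


def compare_groups(
    a: GroupSummary, b: GroupSummary, characteristic: str, n_tested: int = 7
) -> tuple[float, float]:
    """(raw, Bonferroni-adjusted) p-value for one characteristic between two
    group summaries: Welch t for continuous, 2x2 chi-square for categorical."""
    if characteristic in a.continuous:
        n1, m1, s1 = a.continuous[characteristic]
        n2, m2, s2 = b.continuous[characteristic]
        p = welch_t_from_summary(n1, m1, s1, n2, m2, s2)
    elif characteristic in a.categorical:
        n1, c1 = a.categorical[characteristic]
        n2, c2 = b.categorical[characteristic]
        p = chi_square_2x2(c1, n1, c2, n2)
    else:
        raise ValidationError(f"unknown characteristic {characteristic!r}")
    return p, bonferroni(p, n_tested)


# ---------------------------------------------------------------------------
# Derived (latent-group) summaries with bootstrap CIs


@dataclass
class DerivedGroup:
    """Latent-group summary derived from a (high, low) pair of case subsets."""

    label: str
    n_t1d: int
    summary: GroupSummary  # derived summary in GroupSummary form
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def derive_group(
    high: pd.DataFrame,
    low: pd.DataFrame,
    label: str,
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> DerivedGroup:
    """Subtraction summary of the latent group within one age band, with
    percentile-bootstrap CIs over individuals (means) and category counts
    (proportions)."""
    if rng is None:
        rng = np.random.default_rng(0)
    n_h, n_l = len(high), len(low)
    n_t1d = n_h - n_l
    if n_t1d <= 0:
        raise ValidationError(
            f"band {label!r}: latent group size {n_t1d} is not positive; derivation undefined"
        )
    sh = summarize_group(high, "high")
    sl = summarize_group(low, "low")
    derived = GroupSummary(label, n_t1d)
    ci: dict[str, tuple[float, float]] = {}

    for name, col, mode in CONTINUOUS_CHARACTERISTICS:
        nh, mh, sdh = sh.continuous[name]
        nl, ml, sdl = sl.continuous[name]
        if nl == 0:  # empty comparison group: the latent group IS the high group
            ml, sdl = 0.0, 0.0
        nt = nh - nl
        if nt <= 0 or nh == 0:
            derived.continuous[name] = (max(nt, 0), np.nan, np.nan)
            ci[name] = (np.nan, np.nan)
            logger.warning("band %s, %s: non-positive latent n (%d); reported missing", label, name, nt)
            continue
        mean_t = derived_mean(nh, mh, nl, ml, nt)
        sd_t = derived_sd(nh, mh, sdh, nl, ml, sdl, nt, mode=mode)
        derived.continuous[name] = (nt, mean_t, sd_t)
        vh = pd.to_numeric(high[col], errors="coerce").dropna().to_numpy(dtype=float)
        vl = pd.to_numeric(low[col], errors="coerce").dropna().to_numpy(dtype=float)
        # bootstrap means via multinomial resampling weights (equivalent to
        # resampling individuals with replacement), vectorised over replicates
        w_h = rng.multinomial(nh, np.full(nh, 1.0 / nh), size=n_boot)
        boot_low = (
            rng.multinomial(nl, np.full(nl, 1.0 / nl), size=n_boot) @ vl
            if nl
            else np.zeros(n_boot)
        )
        boot = ((w_h @ vh) - boot_low) / nt
        ci[name] = tuple(np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)]))

    for name, col in CATEGORICAL_CHARACTERISTICS:
        nh, ch = sh.categorical[name]
        nl, cl = sl.categorical[name]
        nt = nh - nl
        if nt <= 0:
            derived.categorical[name] = (max(nt, 0), 0)
            ci[name] = (np.nan, np.nan)
            continue
        count_t = derived_categorical(ch, cl)
        derived.categorical[name] = (nt, count_t)
        ph = ch / nh
        pl = cl / nl if nl else 0.0
        boot_c = rng.binomial(nh, ph, n_boot) - rng.binomial(nl, pl, n_boot)
        boot_p = 100.0 * boot_c / nt
        ci[name] = tuple(np.percentile(boot_p, [100 * alpha / 2, 100 * (1 - alpha / 2)]))

    return DerivedGroup(label, n_t1d, derived, ci)


def type2_summary(low: pd.DataFrame, label: str = "T2D") -> GroupSummary:
    """Type 2 comparison summary: the low half's cases represent the type 2
    distribution, weighted to the full type 2 count (total minus excess,
    which equals twice the low count)."""
    s = summarize_group(low, label)
    doubled = GroupSummary(label, 2 * s.n)
    doubled.continuous = {k: (2 * n, m, sd) for k, (n, m, sd) in s.continuous.items()}
    doubled.categorical = {k: (2 * n, 2 * c) for k, (n, c) in s.categorical.items()}
    return doubled


# ---------------------------------------------------------------------------
# Report tables


def _rows_for_group(
    label: str,
    summary: GroupSummary,
    ci: dict[str, tuple[float, float]] | None,
    p_raw: dict[str, float],
    n_tested: int,
) -> list[dict]:
    rows = []
    for name, (n_obs, mean, sd) in summary.continuous.items():
        lo, hi = (ci or {}).get(name, (np.nan, np.nan))
        p = p_raw.get(name, np.nan)
        rows.append(
            {
                "group": label, "characteristic": name, "n": n_obs,
                "estimate": mean, "sd": sd, "ci_low": lo, "ci_high": hi,
                "p_raw": p, "p_bonferroni": bonferroni(p, n_tested),
            }
        )
    for name, (n_obs, count) in summary.categorical.items():
        pct = 100.0 * count / n_obs if n_obs else np.nan
        lo, hi = (ci or {}).get(name, (np.nan, np.nan))
        p = p_raw.get(name, np.nan)
        rows.append(
            {
                "group": label, "characteristic": name, "n": count,
                "estimate": pct, "sd": np.nan, "ci_low": lo, "ci_high": hi,
                "p_raw": p, "p_bonferroni": bonferroni(p, n_tested),
            }
        )
    return rows


def build_tables(
    stratified: StratifiedCohort,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two clinical-characteristics report tables.

    Table 1: derived type 1 vs type 2 within the older age band (31–60 by
    default). Table 2: derived type 1 in the younger band vs the older band.
    Cells are mean (95% CI) or n (%, 95% CI); p-values raw and Bonferroni-
    adjusted over the tested characteristics.
    """
    if config is None:
        config = PipelineConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    from .excess import band_masks, _case_frame

    cases = _case_frame(stratified, config.censor_age)
    ages = cases["age_at_diagnosis"].to_numpy(dtype=float)
    bands = band_masks(ages, config.age_band_edges)
    if len(bands) < 2:
        raise ValidationError("need at least two age bands for the report tables")
    young_label, young_mask = bands[0]
    old_label, old_mask = bands[-1]

    def derived_for(mask: np.ndarray, label: str) -> DerivedGroup:
        sub = cases[mask]
        return derive_group(
            sub[sub["group"] == "high"],
            sub[sub["group"] == "low"],
            label,
            n_boot=config.n_bootstrap,
            alpha=config.alpha,
            rng=rng,
        )

    n_tested = config.n_tested_characteristics

    # Table 1: latent type 1 vs type 2, older band
    old_cases = cases[old_mask]
    t2 = type2_summary(old_cases[old_cases["group"] == "low"], f"T2D_{old_label}")
    try:
        t1_old = derived_for(old_mask, f"T1D_{old_label}")
        p1 = {
            name: compare_groups(t1_old.summary, t2, name, n_tested)[0]
            for name in TESTED_CHARACTERISTICS
        }
        table1 = pd.DataFrame(
            _rows_for_group(t1_old.summary.label, t1_old.summary, t1_old.ci, p1, n_tested)
            + _rows_for_group(t2.label, t2, None, p1, n_tested)
        )
    except ValidationError as err:
        logger.warning("table 1 unavailable: %s", err)
        table1 = pd.DataFrame(
            [{"group": f"T1D_{old_label}", "characteristic": "ALL", "n": 0,
              "estimate": np.nan, "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan,
              "p_raw": np.nan, "p_bonferroni": np.nan}]
        )
        t1_old = None

    # Table 2: latent type 1, young band vs older band
    try:
        t1_young = derived_for(young_mask, f"T1D_{young_label}")
        if t1_old is None:
            raise ValidationError("older-band latent group unavailable")
        p2 = {
            name: compare_groups(t1_young.summary, t1_old.summary, name, n_tested)[0]
            for name in TESTED_CHARACTERISTICS
        }
        table2 = pd.DataFrame(
            _rows_for_group(t1_young.summary.label, t1_young.summary, t1_young.ci, p2, n_tested)
            + _rows_for_group(t1_old.summary.label, t1_old.summary, t1_old.ci, p2, n_tested)
        )
    except ValidationError as err:
        logger.warning("table 2 unavailable: %s", err)
        table2 = pd.DataFrame(
            [{"group": f"T1D_{young_label}", "characteristic": "ALL", "n": 0,
              "estimate": np.nan, "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan,
              "p_raw": np.nan, "p_bonferroni": np.nan}]
        )
    return table1, table2
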