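"""Seeded synthetic biobank cohorts with the structure the analysis assumes.

The generator emulates a middle-aged population cohort (enrolment ages
40–69) carrying three latent classes: type 1 diabetes (autoimmune,
insulin-dependent, onset spread across ages 0–60 and strongly concentrated in
the upper half of the genetic-risk-score distribution), type 2 diabetes
(onset incidence rising steeply with age, genetic risk score distributed
exactly as the non-diabetic population), and no diabetes. Genotypes are drawn
independently per variant under Hardy-Weinberg equilibrium; the only coupling
between genotype and phenotype is the rejection-resampling step that places a
configurable small fraction of type 1 cases below the population-median score.

Class-conditional clinical characteristics (BMI, insulin use within a year of
diagnosis and at study entry, ketoacidosis admission, sex) are drawn from
per-class distributions so that the subtraction estimator has known recovery
targets. Truth labels exist only here — the analysis itself never sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_config import CohortTable, GenotypeMatrix, ValidationError, VariantWeightSet

# ---------------------------------------------------------------------------
# Placeholder weight set
#
# The additive variant ids and weights below are synthetic placeholders with
# plausible ln-OR magnitudes for non-HLA type 1 diabetes loci; they are NOT
# published values. The diplotype table obeys the documented ordering
# high(DR3/DR4 heterozygote) > single-haplotype carriers > neither, with the
# (1,1) cell — one copy of each tagged haplotype — largest.

_PLACEHOLDER_ADDITIVE_WEIGHTS = [
    0.59, 0.45, 0.39, 0.34, 0.31, 0.29, 0.27, 0.25, 0.24, 0.22,
    0.21, 0.20, 0.19, 0.18, 0.17, 0.16, 0.15, 0.14, 0.13, 0.13,
    0.12, 0.11, 0.11, 0.10, 0.09, 0.09, 0.08, 0.07, 0.06,
]

_PLACEHOLDER_ALLELE_FREQS = [
    0.30, 0.62, 0.41, 0.28, 0.55, 0.33, 0.47, 0.21, 0.38, 0.66,
    0.25, 0.52, 0.36, 0.44, 0.58, 0.31, 0.49, 0.23, 0.61, 0.35,
    0.42, 0.27, 0.56, 0.39, 0.48, 0.22, 0.53, 0.34, 0.45,
]

_PLACEHOLDER_DIPLOTYPE = {
    (0, 0): 0.0, (0, 1): 2.2, (0, 2): 2.6,
    (1, 0): 1.9, (1, 1): 3.4, (1, 2): 3.2,
    (2, 0): 2.3, (2, 1): 3.0, (2, 2): 2.9,
}

#: effect-allele frequencies for the two HLA tag SNPs (DR3 tag, DR4-DQ8 tag)
TAG_ALLELE_FREQS = (0.11, 0.105)


def placeholder_weights(n_additive: int = 29) -> VariantWeightSet:
    """A synthetic, clearly non-canonical variant weight set for simulation.

    Additive variants are named ``var01..varNN``; the HLA tag ids keep their
    conventional names (rs2187668, rs7454108) since those index the diplotype
    table, but every weight value is a placeholder.
    """
    if not 0 <= n_additive <= len(_PLACEHOLDER_ADDITIVE_WEIGHTS):
        raise ValidationError(f"n_additive must be in [0, {len(_PLACEHOLDER_ADDITIVE_WEIGHTS)}]")
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    rows = []
    for i in range(n_additive):
        eff, oth = alleles[i % 4]
        rows.append(
            {
                "variant_id": f"var{i + 1:02d}",
                "effect_allele": eff,
                "other_allele": oth,
                "weight": _PLACEHOLDER_ADDITIVE_WEIGHTS[i],
            }
        )
    additive = pd.DataFrame(rows, columns=["variant_id", "effect_allele", "other_allele", "weight"])
    return VariantWeightSet(additive, ("rs2187668", "rs7454108"), dict(_PLACEHOLDER_DIPLOTYPE))


def placeholder_allele_freqs(n_additive: int = 29) -> dict[str, float]:
    freqs = {f"var{i + 1:02d}": _PLACEHOLDER_ALLELE_FREQS[i] for i in range(n_additive)}
    freqs["rs2187668"], freqs["rs7454108"] = TAG_ALLELE_FREQS
    return freqs


# ---------------------------------------------------------------------------
# Simulation configuration


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Prevalences are of diagnosed diabetes by study entry within the cohort;
    ``frac_t1d_below_median`` is the fraction of type 1 cases whose score
    falls below the population median (the score overlap that the subtraction
    estimator cannot see). Onset-age defaults: type 1 onset is a 60/40 mixture
    of uniform ages 0–30 and 31–60; type 2 onset rises exponentially with age
    on (20, 60], calibrated so ~95% of cases onset after age 30. Clinical
    defaults are per latent class, with insulin use within a year of diagnosis
    split by onset age (young = 30 or younger) for type 1.
    """

    n_individuals: int = 380_000
    t1d_prevalence: float = 0.0034
    t2d_prevalence: float = 0.031
    frac_t1d_below_median: float = 0.04
    t1d_young_onset_weight: float = 0.6  # share of T1D onsets in ages 0-30
    t2d_frac_onset_by_30: float = 0.05
    enrolment_age_range: tuple[int, int] = (40, 69)
    bmi_mean_sd: dict = field(
        default_factory=lambda: {"T1D": (27.4, 4.5), "T2D": (32.4, 6.0), "none": (27.0, 4.5)}
    )
    insulin_1yr_prob: dict = field(
        default_factory=lambda: {"T1D_young": 0.97, "T1D_old": 0.89, "T2D": 0.055}
    )
    insulin_entry_prob: dict = field(
        default_factory=lambda: {"T1D_young": 0.99, "T1D_old": 1.0, "T2D": 0.16}
    )
    dka_prob: dict = field(default_factory=lambda: {"T1D": 0.10, "T2D": 0.003, "none": 0.0})
    male_prob: dict = field(default_factory=lambda: {"T1D": 0.59, "T2D": 0.66, "none": 0.5})
    missingness: float = 0.0  # uniform missingness rate for bmi / insulin fields
    rng_seed: int = 0
    max_resample_rounds: int = 200

    def __post_init__(self) -> None:
        if self.t1d_prevalence < 0 or self.t2d_prevalence < 0:
            raise ValidationError("prevalences must be non-negative")
        if self.t1d_prevalence + self.t2d_prevalence >= 1:
            raise ValidationError("t1d + t2d prevalence must be below 1")
        if not 0 <= self.frac_t1d_below_median <= 1:
            raise ValidationError("frac_t1d_below_median must lie in [0, 1]")
        if not 0 <= self.missingness < 1:
            raise ValidationError("missingness must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    cohort: CohortTable
    truth: pd.DataFrame  # columns: id, latent_class
    weights: VariantWeightSet
    population_median_score: float


# ---------------------------------------------------------------------------
# Generation


def _t2d_onset_rate(frac_by_30: float) -> float:
    """Rate of the exponential onset density on (20, 60] such that the stated
    fraction of cases onsets by age 30."""

    def mass_by_30(lam: float) -> float:
        return (np.exp(30 * lam) - np.exp(20 * lam)) / (np.exp(60 * lam) - np.exp(20 * lam))

    return brentq(lambda lam: mass_by_30(lam) - frac_by_30, 1e-6, 1.0)


def _draw_t2d_onset(rng: np.random.Generator, n: int, lam: float) -> np.ndarray:
    u = rng.random(n)
    lo, hi = np.exp(20 * lam), np.exp(60 * lam)
    ages = np.log(lo + u * (hi - lo)) / lam
    return np.clip(np.ceil(ages), 21, 60).astype(int)


def _draw_t1d_onset(rng: np.random.Generator, n: int, young_weight: float) -> np.ndarray:
    young = rng.random(n) < young_weight
    ages = np.where(young, rng.integers(0, 31, n), rng.integers(31, 61, n))
    return ages.astype(int)


def _draw_genotypes(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    return rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)


def simulate_cohort(
    config: SimulationConfig,
    weights: VariantWeightSet | None = None,
    allele_freqs: dict[str, float] | None = None,
) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort.

    Genotypes are drawn per variant under HWE; the population-median score is
    computed from this initial draw, after which each type 1 individual's
    genotype vector is rejection-resampled until its score lands on the
    intended side of that median (below with probability
    ``frac_t1d_below_median``). Type 2 and unaffected individuals keep their
    initial genotypes, making their score distribution identical by
    construction. Diagnosis ages are redrawn until no later than enrolment.
    """
    from .grs import compute_grs  # local import to avoid a cycle

    if weights is None:
        weights = placeholder_weights()
    if allele_freqs is None:
        allele_freqs = placeholder_allele_freqs(weights.n_additive)
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_individuals

    variant_ids = weights.variant_ids  # tags first, then additive
    freqs = np.array([allele_freqs[v] for v in variant_ids], dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValidationError("allele frequencies must lie strictly in (0, 1)")

    ids = np.array([f"s{i:07d}" for i in range(n)], dtype=object)
    classes = rng.choice(
        np.array(["T1D", "T2D", "none"], dtype=object),
        size=n,
        p=[config.t1d_prevalence, config.t2d_prevalence, 1 - config.t1d_prevalence - config.t2d_prevalence],
    )

    values = _draw_genotypes(rng, n, freqs)
    gm = GenotypeMatrix(ids, np.asarray(variant_ids, dtype=object), values)
    scores = compute_grs(gm, weights).scores
    median = float(np.median(scores))
    if np.ptp(scores) == 0:
        raise ValidationError("degenerate score distribution: all scores identical")

    # place T1D scores on the intended side of the population median
    t1d_idx = np.flatnonzero(classes == "T1D")
    if t1d_idx.size:
        target_below = rng.random(t1d_idx.size) < config.frac_t1d_below_median
        pending = np.ones(t1d_idx.size, dtype=bool)
        current = scores[t1d_idx]
        satisfied = np.where(target_below, current < median, current > median)
        pending &= ~satisfied
        rounds = 0
        while pending.any():
            rounds += 1
            if rounds > config.max_resample_rounds:
                raise RuntimeError(
                    "could not place type 1 scores on the intended side of the median "
                    f"after {config.max_resample_rounds} resampling rounds"
                )
            redo = t1d_idx[pending]
            fresh = _draw_genotypes(rng, redo.size, freqs)
            values[redo] = fresh
            gm_sub = GenotypeMatrix(ids[redo], np.asarray(variant_ids, dtype=object), fresh)
            new_scores = compute_grs(gm_sub, weights).scores
            ok = np.where(target_below[pending], new_scores < median, new_scores > median)
            done = np.flatnonzero(pending)[ok]
            pending[done] = False
    gm = GenotypeMatrix(ids, np.asarray(variant_ids, dtype=object), values)

    # ages
    lo, hi = config.enrolment_age_range
    enrolment = rng.integers(lo, hi + 1, n)
    onset = np.full(n, np.nan)
    lam = _t2d_onset_rate(config.t2d_frac_onset_by_30)
    for cls, draw in (
        ("T1D", lambda k: _draw_t1d_onset(rng, k, config.t1d_young_onset_weight)),
        ("T2D", lambda k: _draw_t2d_onset(rng, k, lam)),
    ):
        idx = np.flatnonzero(classes == cls)
        if not idx.size:
            continue
        ages = draw(idx.size).astype(float)
        bad = ages > enrolment[idx]
        rounds = 0
        while bad.any():
            rounds += 1
            if rounds > config.max_resample_rounds:
                raise RuntimeError("could not draw diagnosis ages no later than enrolment")
            ages[bad] = draw(int(bad.sum()))
            bad = ages > enrolment[idx]
        onset[idx] = ages

    has_diabetes = classes != "none"
    young_onset = has_diabetes & (onset <= 30)

    # clinical characteristics
    bmi = np.empty(n)
    male = np.empty(n, dtype=bool)
    dka = np.zeros(n, dtype=bool)
    for cls in ("T1D", "T2D", "none"):
        idx = classes == cls
        k = int(idx.sum())
        mean, sd = config.bmi_mean_sd[cls]
        bmi[idx] = rng.normal(mean, sd, k)
        male[idx] = rng.random(k) < config.male_prob[cls]
        dka[idx] = rng.random(k) < config.dka_prob[cls]
    bmi = np.clip(bmi, 14, 70)

    insulin_1yr = np.full(n, pd.NA, dtype=object)
    insulin_entry = np.full(n, pd.NA, dtype=object)
    for cls, key_young, key_old in (("T1D", "T1D_young", "T1D_old"), ("T2D", "T2D", "T2D")):
        for young, key in ((True, key_young), (False, key_old)):
            idx = np.flatnonzero((classes == cls) & (young_onset == young))
            if not idx.size:
                continue
            insulin_1yr[idx] = rng.random(idx.size) < config.insulin_1yr_prob[key]
            insulin_entry[idx] = rng.random(idx.size) < config.insulin_entry_prob[key]

    data = pd.DataFrame(
        {
            "id": ids,
            "sex": np.where(male, "male", "female"),
            "enrolment_age": enrolment.astype(float),
            "has_diabetes": has_diabetes,
            "age_at_diagnosis": onset,
            "insulin_within_1yr": pd.array(insulin_1yr, dtype="boolean"),
            "insulin_at_entry": pd.array(insulin_entry, dtype="boolean"),
            "bmi": bmi,
            "dka_admission": dka,
        }
    )
    if config.missingness > 0:
        for col in ("bmi", "insulin_within_1yr", "insulin_at_entry", "sex"):
            hole = rng.random(n) < config.missingness
            data.loc[hole, col] = np.nan if col == "bmi" else pd.NA

    truth = pd.DataFrame({"id": ids, "latent_class": classes})
    return SyntheticCohort(gm, CohortTable(data), truth, weights, median)


def truth_report(synth: SyntheticCohort, band_edges: tuple[float, ...] = (0, 30, 60)) -> pd.DataFrame:
    """Ground-truth summary: class counts, onset-band counts, and class-
    conditional phenotype means — the recovery targets for the estimator."""
    df = synth.cohort.data.merge(synth.truth, on="id")
    rows: list[dict] = []
    for cls, grp in df.groupby("latent_class"):
        rows.append({"section": "class_count", "key": cls, "value": float(len(grp))})
    edges = list(band_edges)
    for cls in ("T1D", "T2D"):
        sub = df[df["latent_class"] == cls]
        for lo, hi in zip(edges[:-1], edges[1:]):
            label = f"{int(lo)}-{int(hi)}" if lo == 0 else f"{int(lo) + 1}-{int(hi)}"
            n_band = int(((sub["age_at_diagnosis"] > lo) & (sub["age_at_diagnosis"] <= hi)).sum())
            if lo == 0:
                n_band = int((sub["age_at_diagnosis"] <= hi).sum())
            rows.append({"section": f"{cls}_band_count", "key": label, "value": float(n_band)})
    for cls in ("T1D", "T2D", "none"):
        sub = df[df["latent_class"] == cls]
        if not len(sub):
            continue
        rows.append({"section": "mean_bmi", "key": cls, "value": float(sub["bmi"].mean())})
        rows.append({"section": "dka_rate", "key": cls, "value": float(sub["dka_admission"].mean())})
        if cls != "none":
            rows.append(
                {
                    "section": "insulin_1yr_rate",
                    "key": cls,
                    "value": float(sub["insulin_within_1yr"].astype(float).mean()),
                }
            )
    return pd.DataFrame(rows, columns=["section", "key", "value"])
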