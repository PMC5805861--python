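"""Type 1 diabetes genetic risk score and Hardy-Weinberg QC.

The score for an individual is the HLA diplotype weight — looked up from the
hard-call genotypes at the two HLA tag SNPs — plus the sum over the remaining
additive variants of (effect-allele dosage x ln-OR weight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import GenotypeMatrix, ValidationError, VariantWeightSet

logger = logging.getLogger(__name__)

#: dosages farther than this from an integer are flagged when hard-calling
HARD_CALL_TOLERANCE = 0.1


@dataclass
class ScoreVector:
    """Per-sample risk scores with the HLA and additive components retained.

    ``frame`` columns: sample_id, score, hla_part, additive_part.
    ``excluded`` lists samples dropped for missing genotypes.
    """

    frame: pd.DataFrame
    excluded: list[str]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame["sample_id"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy()


@dataclass(frozen=True)
class HweResult:
    variant_id: str
    counts: tuple[int, int, int]  # (hom other, het, hom effect)
    chi_square: float
    p_value: float


def hard_call(dosages: np.ndarray, variant_id: str = "?") -> np.ndarray:
    """Round dosages to hard-call genotypes (nearest integer, ties to even).

    Dosages farther than ``HARD_CALL_TOLERANCE`` from an integer are logged:
    diplotype lookup needs discrete genotypes and a fuzzy dosage means poor
    imputation at a tag SNP.
    """
    dosages = np.asarray(dosages, dtype=float)
    calls = np.rint(dosages)
    fuzzy = np.isfinite(dosages) & (np.abs(dosages - calls) > HARD_CALL_TOLERANCE)
    if fuzzy.any():
        logger.warning(
            "%d dosage(s) at %s are > %.2f from an integer; hard calls may be unreliable",
            int(fuzzy.sum()), variant_id, HARD_CALL_TOLERANCE,
        )
    return calls


def compute_grs(
    genotypes: GenotypeMatrix,
    weights: VariantWeightSet,
    allow_impute: bool = False,
    allele_freqs: dict[str, float] | None = None,
) -> ScoreVector:
    """Compute the genetic risk score per sample.

    score = diplotype_weight[(g_tag1, g_tag2)] + sum_v dosage_v * weight_v

    Samples missing any score variant are excluded and reported, unless
    ``allow_impute`` is set, in which case missing additive dosages are
    replaced by 2 x effect-allele frequency (``allele_freqs``, or the sample
    mean dosage / 2 when absent). Missing HLA tag genotypes always exclude the
    sample: the diplotype lookup has no meaningful mean fill-in.
    """
    tag1, tag2 = weights.hla_tag_ids
    additive_ids = list(weights.additive["variant_id"])
    gm = genotypes.subset([tag1, tag2] + additive_ids)

    g1 = hard_call(gm.values[:, 0], tag1)
    g2 = hard_call(gm.values[:, 1], tag2)
    dosages = gm.values[:, 2:].copy()
    w = weights.additive["weight"].to_numpy(dtype=float)

    missing_add = ~np.isfinite(dosages)
    if allow_impute and missing_add.any():
        for j, vid in enumerate(additive_ids):
            col = dosages[:, j]
            hole = ~np.isfinite(col)
            if not hole.any():
                continue
            if allele_freqs is not None and vid in allele_freqs:
                fill = 2.0 * allele_freqs[vid]
            else:
                fill = float(np.nanmean(col))
            dosages[hole, j] = fill
        missing_add = np.zeros_like(missing_add)

    ok = np.isfinite(g1) & np.isfinite(g2) & ~missing_add.any(axis=1)
    excluded = [str(s) for s in gm.sample_ids[~ok]]
    if excluded:
        logger.warning("excluded %d sample(s) with missing score genotypes", len(excluded))

    diplo = np.array([[weights.hla_diplotype_weights[(i, j)] for j in range(3)] for i in range(3)])
    g1i = np.clip(g1[ok].astype(int), 0, 2)
    g2i = np.clip(g2[ok].astype(int), 0, 2)
    hla_part = diplo[g1i, g2i]
    additive_part = dosages[ok] @ w

    frame = pd.DataFrame(
        {
            "sample_id": gm.sample_ids[ok],
            "score": hla_part + additive_part,
            "hla_part": hla_part,
            "additive_part": additive_part,
        }
    )
    return ScoreVector(frame, excluded)


def hwe_test(counts: tuple[int, int, int], variant_id: str = "?") -> HweResult:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg equilibrium.

    ``counts`` are the genotype counts (n_hom_ref, n_het, n_hom_alt). Expected
    counts come from the observed allele frequency; a monomorphic variant
    carries no information about departure and returns chi-square 0, p 1.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValidationError("total genotype count must be positive")
    p_hat = (2 * n2 + n1) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HweResult(variant_id, (n0, n1, n2), 0.0, 1.0)
    q_hat = 1.0 - p_hat
    expected = np.array([n * q_hat**2, 2 * n * p_hat * q_hat, n * p_hat**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return HweResult(variant_id, (n0, n1, n2), chi2, p)


def hwe_exact_midp(counts: tuple[int, int, int]) -> float:
    """Exact conditional HWE test (mid-p), as a slow cross-check.

    Enumerates heterozygote counts conditional on the observed minor-allele
    count; probability from the Levene–Haldane distribution.
    """
    n0, n1, n2 = (int(c) for c in counts)
    n = n0 + n1 + n2
    n_minor = min(2 * n0 + n1, 2 * n2 + n1)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log-probabilities of each possible het count given (n, n_minor)
    from scipy.special import gammaln

    def logprob(h):
        rare_hom = (n_minor - h) // 2
        common_hom = n - h - rare_hom
        return (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1)
            - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(2 * n - n_minor + 1))
        )

    logp = np.array([logprob(h) for h in hets], dtype=float)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n1][0]
    return float(probs[probs < p_obs].sum() + 0.5 * probs[probs == p_obs].sum())


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Hard-call genotype counts (0, 1, 2 effect alleles) from dosages."""
    calls = hard_call(dosages)
    calls = calls[np.isfinite(calls)].astype(int)
    return (int((calls == 0).sum()), int((calls == 1).sum()), int((calls == 2).sum()))


def hwe_scan(genotypes: GenotypeMatrix, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """HWE test for every (or the named) variant column of a genotype matrix."""
    ids = list(genotypes.variant_ids) if variant_ids is None else list(variant_ids)
    rows = []
    for vid in ids:
        res = hwe_test(genotype_counts(genotypes.column(vid)), vid)
        rows.append(
            {
                "variant_id": vid,
                "n_hom_other": res.counts[0],
                "n_het": res.counts[1],
                "n_hom_effect": res.counts[2],
                "chi_square": res.chi_square,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def apply_hwe_exclusions(
    weights: VariantWeightSet,
    genotypes: GenotypeMatrix,
    threshold: float,
) -> tuple[VariantWeightSet, pd.DataFrame]:
    """Drop additive score variants out of Hardy-Weinberg equilibrium.

    Returns the pruned weight set plus the full per-variant HWE report with an
    ``excluded`` flag. The threshold is a p-value in (0, 1]; a threshold of 1
    excludes everything with p < 1 and warns, which is almost certainly not
    what the caller wants.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("HWE exclusion threshold must lie in (0, 1]")
    if threshold == 1:
        logger.warning("HWE threshold of 1 excludes every variant with p < 1")
    report = hwe_scan(genotypes, list(weights.additive["variant_id"]))
    report["excluded"] = report["p_value"] < threshold
    dropped = report.loc[report["excluded"], "variant_id"].tolist()
    if dropped:
        logger.info("HWE exclusion (p < %g): %s", threshold, ", ".join(dropped))
    return weights.drop_additive(dropped), report
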