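"""Input/output and validation for the three pipeline artifacts.

The pipeline consumes (1) a variant-weight set — additive per-allele ln-OR
weights plus an HLA diplotype weight table keyed on the joint genotype at two
tag SNPs, (2) a genotype matrix (hard calls or dosages in [0, 2]) from a plain
samples-by-variants table or a VCF, and (3) a cohort phenotype table with the
censoring information needed for diabetes-free survival analysis.

All tabular outputs are CSV with floats at 6 significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: questionnaire markers mapped to missing
MISSING_MARKERS = frozenset(
    {"don't know", "dont know", "do not know", "prefer not to answer", "na", "nan", ""}
)

FLOAT_FORMAT = "%.6g"

COHORT_COLUMNS = [
    "id",
    "sex",
    "enrolment_age",
    "has_diabetes",
    "age_at_diagnosis",
    "insulin_within_1yr",
    "insulin_at_entry",
    "bmi",
    "dka_admission",
]


class ValidationError(ValueError):
    """Raised when an input artifact violates its contract."""


# ---------------------------------------------------------------------------
# Variant weights


@dataclass(frozen=True)
class VariantWeightSet:
    """Additive variant weights plus the HLA diplotype weight table.

    Parameters
    ----------
    additive
        DataFrame with columns ``variant_id``, ``effect_allele``,
        ``other_allele``, ``weight`` (natural-log odds-ratio units). Row order
        is preserved from the source file.
    hla_tag_ids
        The two tag SNPs whose joint hard-call genotype indexes the diplotype
        table (defaults elsewhere: rs2187668 tagging DR3, rs7454108 tagging
        DR4-DQ8).
    hla_diplotype_weights
        Mapping ``(g_tag1, g_tag2) -> weight`` covering all 9 genotype pairs,
        with g in {0, 1, 2} counting effect alleles.
    """

    additive: pd.DataFrame
    hla_tag_ids: tuple[str, str]
    hla_diplotype_weights: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        required = {"variant_id", "effect_allele", "other_allele", "weight"}
        missing = required - set(self.additive.columns)
        if missing:
            raise ValidationError(f"additive weight table missing columns: {sorted(missing)}")
        ids = self.additive["variant_id"]
        dup = ids[ids.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate additive variant id(s): {', '.join(dup)}")
        clash = set(self.hla_tag_ids) & set(ids)
        if clash:
            raise ValidationError(f"HLA tag variant(s) also listed as additive: {sorted(clash)}")
        for col in ("effect_allele", "other_allele"):
            bad = set(self.additive[col]) - VALID_ALLELES
            if bad:
                raise ValidationError(f"invalid {col} value(s): {sorted(bad)}")
        expected = {(i, j) for i in range(3) for j in range(3)}
        holes = expected - set(self.hla_diplotype_weights)
        if holes:
            raise ValidationError(f"diplotype weight table missing genotype pair(s): {sorted(holes)}")

    @property
    def variant_ids(self) -> list[str]:
        """All variant ids entering the score: the two tags then additive."""
        return list(self.hla_tag_ids) + list(self.additive["variant_id"])

    @property
    def n_additive(self) -> int:
        return len(self.additive)

    def drop_additive(self, variant_ids: Iterable[str]) -> "VariantWeightSet":
        drop = set(variant_ids)
        kept = self.additive[~self.additive["variant_id"].isin(drop)].reset_index(drop=True)
        return VariantWeightSet(kept, self.hla_tag_ids, dict(self.hla_diplotype_weights))


def read_weights(path: str | Path, diplotype_path: str | Path | None = None) -> VariantWeightSet:
    """Read a tab-separated additive-weight table plus the HLA diplotype table.

    The diplotype table is a YAML file (``diplotype_path``, or ``<path
    stem>.hla.yaml`` next to the weights file) of the form::

        hla_tag_ids: [rs2187668, rs7454108]
        weights:
          "0,0": 0.0
          "0,1": 2.2
          ...   # all 9 genotype pairs

    Raises
    ------
    ValidationError
        On duplicate additive ids, a missing diplotype cell, or missing
        columns; the offending id / genotype pair is named.
    """
    path = Path(path)
    additive = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    if diplotype_path is None:
        diplotype_path = path.with_suffix(".hla.yaml")
    with open(diplotype_path) as fh:
        spec = yaml.safe_load(fh)
    tags = tuple(spec["hla_tag_ids"])
    if len(tags) != 2:
        raise ValidationError("hla_tag_ids must name exactly two tag variants")
    weights: dict[tuple[int, int], float] = {}
    for key, value in spec["weights"].items():
        g1, g2 = (int(part) for part in str(key).split(","))
        weights[(g1, g2)] = float(value)
    return VariantWeightSet(additive, tags, weights)


def write_weights(ws: VariantWeightSet, path: str | Path, diplotype_path: str | Path | None = None) -> None:
    path = Path(path)
    ws.additive.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    if diplotype_path is None:
        diplotype_path = path.with_suffix(".hla.yaml")
    payload = {
        "hla_tag_ids": list(ws.hla_tag_ids),
        "weights": {f"{g1},{g2}": float(w) for (g1, g2), w in sorted(ws.hla_diplotype_weights.items())},
    }
    with open(diplotype_path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class GenotypeMatrix:
    """Samples-by-variants dosage matrix; entries in [0, 2], NaN = missing."""

    sample_ids: np.ndarray
    variant_ids: np.ndarray
    values: np.ndarray  # float, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValidationError("genotype value matrix shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in genotype matrix")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValidationError("duplicate variant ids in genotype matrix")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("genotype dosages must lie in [0, 2]")

    def subset(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise ValidationError(f"variant(s) absent from genotype matrix: {', '.join(missing)}")
        cols = [index[v] for v in variant_ids]
        return GenotypeMatrix(self.sample_ids, np.asarray(variant_ids, dtype=object), self.values[:, cols])

    def column(self, variant_id: str) -> np.ndarray:
        idx = int(np.flatnonzero(self.variant_ids == variant_id)[0])
        return self.values[:, idx]


def flip_dosage(values: np.ndarray) -> np.ndarray:
    """Re-orient dosages to the opposite allele: d -> 2 - d (an involution)."""
    return 2.0 - np.asarray(values, dtype=float)


def _is_strand_ambiguous(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def read_genotypes(
    path: str | Path,
    wanted: Sequence[str],
    weights: VariantWeightSet | None = None,
) -> GenotypeMatrix:
    """Read genotype dosages for ``wanted`` variants from TSV or VCF.

    A plain table (anything not ending ``.vcf``/``.vcf.gz``) is read as
    samples x variants with a leading ``sample_id`` column; dosages are assumed
    already oriented to the weight set's effect alleles.

    For VCF input a ``weights`` set is required: the effect-allele dosage is
    the ALT dosage when (ref, alt) == (other, effect), and is flipped
    (d -> 2 - d) when the orientation is swapped. Strand-ambiguous A/T and C/G
    weight rows cannot be oriented and are rejected.
    """
    path = Path(path)
    wanted = list(wanted)
    if path.suffix == ".vcf" or str(path).endswith(".vcf.gz"):
        if weights is None:
            raise ValidationError("VCF input requires the variant weight set for allele orientation")
        return _read_vcf(path, wanted, weights)
    table = pd.read_csv(path, sep="\t", index_col=0)
    gm = GenotypeMatrix(
        table.index.to_numpy(dtype=object),
        table.columns.to_numpy(dtype=object),
        table.to_numpy(dtype=float),
    )
    return gm.subset(wanted)


def _read_vcf(path: Path, wanted: Sequence[str], weights: VariantWeightSet) -> GenotypeMatrix:
    from cyvcf2 import VCF

    alleles: dict[str, tuple[str, str]] = {}
    for _, row in weights.additive.iterrows():
        alleles[row["variant_id"]] = (row["effect_allele"], row["other_allele"])

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    columns: dict[str, np.ndarray] = {}
    for record in vcf:
        vid = record.ID
        if vid not in wanted or vid in columns:
            continue
        gts = record.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan
        dosage = gts.sum(axis=1)
        if vid in alleles:
            effect, other = alleles[vid]
            if _is_strand_ambiguous(effect, other):
                raise ValidationError(
                    f"variant {vid}: effect/other alleles {effect}/{other} are strand-ambiguous"
                )
            ref, alt = record.REF, record.ALT[0]
            if (ref, alt) == (other, effect):
                pass  # ALT dosage counts the effect allele directly
            elif (ref, alt) == (effect, other):
                dosage = flip_dosage(dosage)
            else:
                raise ValidationError(
                    f"variant {vid}: VCF alleles {ref}/{alt} do not match weight alleles {effect}/{other}"
                )
        columns[vid] = dosage
    missing = [v for v in wanted if v not in columns]
    if missing:
        raise ValidationError(f"variant(s) absent from VCF: {', '.join(missing)}")
    values = np.column_stack([columns[v] for v in wanted])
    return GenotypeMatrix(samples, np.asarray(wanted, dtype=object), values)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(gm.values, index=pd.Index(gm.sample_ids, name="sample_id"), columns=gm.variant_ids)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Cohort phenotypes


@dataclass
class CohortTable:
    """Per-individual phenotype table with exclusion accounting.

    ``data`` columns: id, sex ({male, female} or NA), enrolment_age (years),
    has_diabetes (bool), age_at_diagnosis (years, NA unless diabetic),
    insulin_within_1yr / insulin_at_entry (boolean, NA allowed),
    bmi (kg/m^2, NA allowed), dka_admission (bool).
    ``exclusions`` counts rows removed per validation rule.
    """

    data: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(COHORT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"cohort table missing column(s): {sorted(missing)}")
        self.data = self.data[COHORT_COLUMNS].reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_excluded(self) -> int:
        return int(sum(self.exclusions.values()))


def _to_missing(series: pd.Series) -> pd.Series:
    def clean(x):
        if isinstance(x, str) and x.strip().lower() in MISSING_MARKERS:
            return np.nan
        return x

    return series.map(clean)


def _to_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }

    def conv(x):
        if pd.isna(x):
            return pd.NA
        if isinstance(x, (bool, np.bool_)):
            return bool(x)
        if isinstance(x, (int, np.integer, float, np.floating)):
            return bool(int(x))
        key = str(x).strip().lower()
        if key in mapping:
            return mapping[key]
        raise ValidationError(f"cannot interpret boolean value {x!r}")

    return series.map(conv).astype("boolean")


def read_cohort(path: str | Path) -> CohortTable:
    """Read a delimited phenotype table, mapping questionnaire non-answers
    ("don't know" / "prefer not to answer") to missing and removing (with
    per-rule counts) rows that violate the table invariants:

    * diabetic rows must carry an age at diagnosis no later than enrolment;
    * non-diabetic rows must not carry diagnosis-dependent fields;
    * enrolment age must be positive.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = set(COHORT_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise ValidationError(f"cohort file missing column(s): {sorted(missing_cols)}")

    df = raw.apply(_to_missing)
    out = pd.DataFrame()
    out["id"] = df["id"].astype(str)
    out["sex"] = df["sex"].str.strip().str.lower().where(df["sex"].notna())
    out.loc[~out["sex"].isin(["male", "female"]), "sex"] = pd.NA
    out["enrolment_age"] = pd.to_numeric(df["enrolment_age"], errors="coerce")
    out["has_diabetes"] = _to_bool(df["has_diabetes"]).fillna(False)
    out["age_at_diagnosis"] = pd.to_numeric(df["age_at_diagnosis"], errors="coerce")
    out["insulin_within_1yr"] = _to_bool(df["insulin_within_1yr"])
    out["insulin_at_entry"] = _to_bool(df["insulin_at_entry"])
    out["bmi"] = pd.to_numeric(df["bmi"], errors="coerce")
    out["dka_admission"] = _to_bool(df["dka_admission"]).fillna(False)
    return _apply_cohort_rules(out)


def _apply_cohort_rules(df: pd.DataFrame) -> CohortTable:
    exclusions: dict[str, int] = {}

    def drop(mask: pd.Series, rule: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            exclusions[rule] = exclusions.get(rule, 0) + n
            logger.info("cohort QC: removed %d row(s): %s", n, rule)
        return df[~mask]

    df = drop(df["enrolment_age"].isna() | (df["enrolment_age"] <= 0), "nonpositive or missing enrolment age")
    df = drop(df["has_diabetes"] & df["age_at_diagnosis"].isna(), "diabetes without age at diagnosis")
    df = drop(
        df["has_diabetes"] & (df["age_at_diagnosis"] > df["enrolment_age"]),
        "age at diagnosis after enrolment",
    )
    # diagnosis-dependent fields on non-diabetic rows: blank rather than drop
    nondiab = ~df["has_diabetes"]
    df = df.copy()
    df.loc[nondiab, ["age_at_diagnosis"]] = np.nan
    df.loc[nondiab, ["insulin_within_1yr", "insulin_at_entry"]] = pd.NA
    df = drop(df["id"].duplicated(keep=False), "duplicate individual id")
    return CohortTable(df.reset_index(drop=True), exclusions)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Analysis settings shared across stages.

    censor_age
        Administrative censoring age in years; events recorded later are
        treated as censored at this age (default 60, where the subtraction
        estimator stops being interpretable against the type 2 background).
    age_band_edges
        Right-closed integer age bands for the headline split
        (default [0, 30, 60]: "30 or younger" and "31–60").
    n_tested_characteristics
        Bonferroni multiplier for the clinical-characteristic comparisons
        (default 7).
    hwe_exclusion_p
        Variants with a Hardy-Weinberg chi-square p below this are dropped
        from the additive score (default 1e-6).
    """

    censor_age: float = 60.0
    age_band_edges: tuple[float, ...] = (0.0, 30.0, 60.0)
    decade_edges: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    n_tested_characteristics: int = 7
    alpha: float = 0.05
    rng_seed: int = 0
    hwe_exclusion_p: float = 1e-6
    n_bootstrap: int = 2000
    ci_method: str = "bootstrap"  # or "wald"

    def __post_init__(self) -> None:
        edges = np.asarray(self.age_band_edges, dtype=float)
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("age_band_edges must be strictly increasing")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.hwe_exclusion_p <= 1:
            raise ValidationError("hwe_exclusion_p must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("age_band_edges", "decade_edges"):
            if key in raw:
                raw[key] = tuple(float(x) for x in raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "censor_age": self.censor_age,
            "age_band_edges": list(self.age_band_edges),
            "decade_edges": list(self.decade_edges),
            "n_tested_characteristics": self.n_tested_characteristics,
            "alpha": self.alpha,
            "rng_seed": self.rng_seed,
            "hwe_exclusion_p": self.hwe_exclusion_p,
            "n_bootstrap": self.n_bootstrap,
            "ci_method": self.ci_method,
        }


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an output table as CSV with 6-significant-digit floats."""
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
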