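"""Polygenic score engine: weight tables, genotype dosages, scoring, standardization.

A polygenic risk score (PRS) is the weighted sum of risk-allele dosages over
a set of variants, score_i = sum_j w_j * d_ij, followed by standardization
against a reference distribution so downstream effect sizes are "per SD".

Allele matching is exact-string on A/C/G/T alleles with an explicit flip
rule: when a weight's effect allele is the matrix's non-coded (reference)
allele the dosage is replaced by ``2 - d``. Strand-ambiguous variants (A/T,
C/G) are matched literally; strand QC belongs upstream. Missing dosages are
imputed to the variant's mean observed dosage, which preserves the cohort
mean score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeightTable",
    "GenotypeMatrix",
    "StandardizationReference",
    "ScoreResult",
    "read_weight_table",
    "write_weight_table",
    "read_vcf",
    "read_dosage_tsv",
    "score_individuals",
    "standardize_scores",
]

WEIGHT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele", "weight"]

_ACGT = set("ACGT")


def _valid_allele(a: str) -> bool:
    return isinstance(a, str) and len(a) >= 1 and set(a) <= _ACGT


@dataclass(frozen=True)
class WeightTable:
    """Per-variant effect weights keyed by (chrom, pos, effect_allele)."""

    frame: pd.DataFrame  # columns WEIGHT_COLUMNS

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(WEIGHT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"weight table missing columns {sorted(missing)}")
        if not np.all(np.isfinite(df["weight"].to_numpy(dtype=float))):
            raise ValueError("weight table contains non-finite weights")
        for col in ("effect_allele", "other_allele"):
            bad = [a for a in df[col] if not _valid_allele(a)]
            if bad:
                raise ValueError(f"non-ACGT allele in column {col}: {bad[0]!r}")
        if (df["effect_allele"] == df["other_allele"]).any():
            raise ValueError("effect_allele equals other_allele for some variant")
        dup = df.duplicated(subset=["chrom", "pos", "effect_allele"])
        if dup.any():
            raise ValueError(
                "duplicate variant key (chrom, pos, effect_allele) at row "
                f"{int(np.flatnonzero(dup.to_numpy())[0]) + 1}"
            )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x variants dosage matrix; dosage counts the coded allele.

    ``dosages`` is float with NaN for missing, values in [0, 2]. ``variants``
    carries columns id, chrom, pos, ref, alt; the coded allele is ``alt``.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame  # columns id, chrom, pos, ref, alt

    def __post_init__(self) -> None:
        d = self.dosages
        if d.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if d.shape[0] != len(self.samples) or d.shape[1] != len(self.variants):
            raise ValueError("dosage shape inconsistent with samples/variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(d, initial=0.0) < -1e-6 or np.nanmax(d, initial=0.0) > 2 + 1e-6:
                raise ValueError("dosages outside [0, 2]")
        keys = list(zip(self.variants["chrom"], self.variants["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant (chrom, pos) columns")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class StandardizationReference:
    mean: float
    sd: float
    n_reference: int

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("standardization reference sd must be > 0")


@dataclass(frozen=True)
class ScoreResult:
    scores: np.ndarray  # per-individual raw score
    matched_counts: np.ndarray  # per-individual count of observed matched dosages
    n_matched_variants: int
    n_dropped_variants: int  # matched position but incompatible alleles
    n_imputed: int  # missing dosages imputed to variant mean


def read_weight_table(path) -> WeightTable:
    """Parse a tab-delimited weight file, reporting offending line numbers.

    Expected header: ``id chrom pos effect_allele other_allele weight``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: header missing columns {sorted(missing)}")

    def _line(i: int) -> int:  # +2: header line + 1-based
        return i + 2

    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = np.flatnonzero(pos.isna().to_numpy() | (pos.to_numpy(dtype=float) % 1 != 0))
    if bad.size:
        raise ValueError(f"{path}: line {_line(bad[0])}: unparseable position")
    weight = pd.to_numeric(df["weight"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(weight.to_numpy(dtype=float)))
    if bad.size:
        raise ValueError(f"{path}: line {_line(bad[0])}: unparseable weight")
    for col in ("effect_allele", "other_allele"):
        bad = np.flatnonzero([not _valid_allele(a) for a in df[col]])
        if bad.size:
            raise ValueError(f"{path}: line {_line(bad[0])}: non-ACGT allele in {col}")
    bad = np.flatnonzero((df["effect_allele"] == df["other_allele"]).to_numpy())
    if bad.size:
        raise ValueError(f"{path}: line {_line(bad[0])}: effect allele equals other allele")
    dup = df.duplicated(subset=["chrom", "pos", "effect_allele"]).to_numpy()
    if dup.any():
        raise ValueError(
            f"{path}: line {_line(int(np.flatnonzero(dup)[0]))}: "
            "duplicate (chrom, pos, effect_allele)"
        )
    out = df.assign(pos=pos.astype(int), weight=weight.astype(float))
    return WeightTable(out[WEIGHT_COLUMNS].reset_index(drop=True))


def write_weight_table(table: WeightTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> GenotypeMatrix:
    """Read dosages from a VCF (v4.2). Prefers the DS FORMAT field, falls
    back to summing GT hard calls. Multi-allelic records use the first ALT.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    meta: list[tuple] = []
    for v in vcf:
        ds = None
        try:
            arr = v.format("DS")
        except KeyError:
            arr = None
        if arr is not None:
            ds = np.asarray(arr, dtype=float).reshape(len(samples), -1)[:, 0]
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gt = np.asarray(v.gt_types, dtype=float)
            ds = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        ds = np.where((ds < -0.5) | (ds > 2.5), np.nan, ds)
        cols.append(np.clip(ds, 0.0, 2.0))
        alt = v.ALT[0] if v.ALT else "."
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), int(v.POS), v.REF, alt))
    if not meta:
        raise ValueError(f"{path}: no variant records")
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(np.column_stack(cols), samples, variants)


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a plain dosage matrix: first column ``sample_id``, remaining
    columns named ``chrom:pos:ref:alt``; empty/NA cells are missing.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    samples = df["sample_id"].astype(str).tolist()
    meta = []
    for col in df.columns[1:]:
        parts = col.split(":")
        if len(parts) != 4:
            raise ValueError(f"{path}: column {col!r} not 'chrom:pos:ref:alt'")
        chrom, pos, ref, alt = parts
        meta.append((col, chrom, int(pos), ref, alt))
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(dosages, samples, variants)


def score_individuals(geno: GenotypeMatrix, weights: WeightTable) -> ScoreResult:
    """Raw PRS per individual: sum over matched variants of weight x dosage.

    Variants are joined on (chrom, pos). If the weight's effect allele is the
    matrix's coded (alt) allele the dosage is used as-is; if it is the
    non-coded (ref) allele and the other allele is the alt, ``2 - d`` is
    used; anything else is dropped and counted. Raises if no variant matches.
    """
    wdf = weights.frame
    vindex = {
        (c, p): j
        for j, (c, p) in enumerate(zip(geno.variants["chrom"], geno.variants["pos"]))
    }
    cols: list[int] = []
    w_eff: list[float] = []
    flip: list[bool] = []
    n_dropped = 0
    for _, row in wdf.iterrows():
        j = vindex.get((row["chrom"], row["pos"]))
        if j is None:
            continue
        ref = geno.variants["ref"].iat[j]
        alt = geno.variants["alt"].iat[j]
        if row["effect_allele"] == alt and row["other_allele"] == ref:
            cols.append(j), w_eff.append(row["weight"]), flip.append(False)
        elif row["effect_allele"] == ref and row["other_allele"] == alt:
            cols.append(j), w_eff.append(row["weight"]), flip.append(True)
        else:
            n_dropped += 1
    if not cols:
        raise ValueError("zero matched variants between weights and genotypes")

    d = geno.dosages[:, cols].copy()
    observed = ~np.isnan(d)
    col_mean = np.nanmean(np.where(observed, d, np.nan), axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)  # all-missing column
    n_imputed = int((~observed).sum())
    d = np.where(observed, d, col_mean)
    flip_arr = np.asarray(flip)
    d[:, flip_arr] = 2.0 - d[:, flip_arr]
    scores = d @ np.asarray(w_eff, dtype=float)
    return ScoreResult(
        scores=scores,
        matched_counts=observed.sum(axis=1),
        n_matched_variants=len(cols),
        n_dropped_variants=n_dropped,
        n_imputed=n_imputed,
    )


def standardize_scores(
    raw: np.ndarray, ref: StandardizationReference | None = None
) -> tuple[np.ndarray, StandardizationReference]:
    """z = (raw - mean) / sd against ``ref``, or self-standardize if ``ref``
    is None (mean/sd estimated from ``raw`` itself, sample SD with ddof=1).
    """
    raw = np.asarray(raw, dtype=float)
    if ref is None:
        sd = float(np.std(raw, ddof=1)) if raw.size > 1 else 0.0
        if not sd > 0:
            raise ValueError("zero-variance scores cannot be self-standardized")
        ref = StandardizationReference(float(np.mean(raw)), sd, int(raw.size))
    return (raw - ref.mean) / ref.sd, ref
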