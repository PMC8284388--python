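"""Synthetic biobank-like cohorts with known ground-truth parameters.

Every downstream stage of the pipeline (scoring, clinical risk, integration,
evaluation, impact) is testable against cohorts generated here, where the
generating hazard ratio per SD of PRS, the clinical signal strength, and the
10-year event rate are all known exactly.

Generative model
----------------
* PRS ~ N(0, 1), independent of all clinical covariates by construction.
* Clinical covariates: age uniform on the configured range, sex Bernoulli(1/2),
  SBP ~ N(140, 20) mm Hg, smoking Bernoulli(0.10), diabetes Bernoulli(0.05),
  antihypertensive treatment Bernoulli(0.15), lipids log-normal (mmol/L).
* The clinical log-hazard component is the bundled pooled-cohort-equations
  linear predictor (LP - LPbar), z-scored across the cohort and scaled to
  ``clinical_effect_sd`` — so the clinical risk equation is the correctly
  specified clinical model for the simulated events.
* Incident events: exponential proportional hazards,
  ``log h = log(lambda0) + log(hr_per_sd_prs) * prs_z + clinical component``,
  with uniform administrative censoring on ``censor_window_years``. The
  baseline hazard is auto-calibrated by root finding so the marginal 10-year
  event probability matches ``target_10y_event_rate``.
* Prevalent disease: an independent logistic model in PRS and age; prevalent
  cases are flagged so incident analyses can exclude them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .clinical import (
    MMOL_TO_MGDL_CHOL,
    centered_linear_predictor_frame,
    load_default_pce,
)
from .prs import GenotypeMatrix, WeightTable

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "generate_genotypes",
    "simulate_survival",
    "write_cohort",
    "read_cohort",
    "write_vcf",
]

COHORT_COLUMNS = [
    "id",
    "age_at_baseline",
    "sex",
    "sbp",
    "total_chol",
    "hdl",
    "ldl",
    "smoker",
    "diabetic",
    "treated_bp",
    "prs_raw",
    "prs_z",
    "clinical_lp",
    "time_to_event_or_censor",
    "incident_event",
    "prevalent_case",
    "stratum",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for a synthetic cohort.

    ``hr_per_sd_prs`` is the generating hazard ratio per 1 SD of PRS;
    ``clinical_effect_sd`` the SD of the clinical linear predictor on the
    log-hazard scale (0 disables the clinical signal). ``baseline_hazard``
    (per year) is calibrated automatically when None.
    """

    n_individuals: int = 50_000
    seed: int = 0
    hr_per_sd_prs: float = 1.62
    clinical_effect_sd: float = 1.15
    baseline_hazard: float | None = None
    censor_window_years: tuple[float, float] = (8.0, 12.0)
    age_range: tuple[float, float] = (40.0, 70.0)
    target_10y_event_rate: float = 0.04
    prevalence_intercept: float = -3.2
    prevalence_beta_prs: float = field(default=math.log(1.90))
    prevalence_beta_age: float = 0.05

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not self.hr_per_sd_prs > 0:
            raise ValueError("hr_per_sd_prs must be > 0")
        if self.clinical_effect_sd < 0:
            raise ValueError("clinical_effect_sd must be >= 0")
        low, high = self.censor_window_years
        if low > high or low <= 0:
            raise ValueError("censor window must satisfy 0 < low <= high")
        if not 0.0 < self.target_10y_event_rate < 1.0:
            raise ValueError("target_10y_event_rate must be in (0, 1)")
        if self.baseline_hazard is not None and not self.baseline_hazard > 0:
            raise ValueError("baseline_hazard must be > 0")


def simulate_survival(
    linear_predictor: np.ndarray,
    baseline_hazard: float,
    censor_window: tuple[float, float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times under proportional hazards plus uniform
    administrative censoring.

    ``T_event = -log(U) / (lambda0 * exp(LP))``; observed time is
    ``min(T_event, T_censor)`` and the flag marks ``T_event <= T_censor``.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    if not baseline_hazard > 0:
        raise ValueError("baseline_hazard must be > 0")
    low, high = censor_window
    if low > high:
        raise ValueError("censor window low > high")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=lp.shape)
    t_event = -np.log(u) / (baseline_hazard * np.exp(lp))
    t_censor = rng.uniform(low, high, size=lp.shape)
    event = t_event <= t_censor
    return np.minimum(t_event, t_censor), event


def _calibrate_baseline_hazard(lp: np.ndarray, target: float, horizon: float = 10.0) -> float:
    """Solve for lambda0 so mean(1 - exp(-lambda0 * e^LP * horizon)) = target."""

    def excess(log_lam: float) -> float:
        lam = math.exp(log_lam)
        return float(np.mean(-np.expm1(-lam * np.exp(lp) * horizon))) - target

    return math.exp(brentq(excess, math.log(1e-10), math.log(10.0), xtol=1e-12))


def _stratum_labels(age: np.ndarray, male: np.ndarray) -> np.ndarray:
    older = age >= 55
    return np.where(
        male,
        np.where(older, "M55-69", "M40-54"),
        np.where(older, "F55-69", "F40-54"),
    )


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort table; deterministic given the config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    age = rng.uniform(*config.age_range, size=n)
    male = rng.random(n) < 0.5
    sbp = np.clip(rng.normal(140.0, 20.0, size=n), 80.0, 220.0)
    total_chol = np.exp(rng.normal(math.log(5.5), 0.18, size=n))
    hdl = np.exp(rng.normal(math.log(1.4), 0.22, size=n))
    ldl = np.exp(rng.normal(math.log(3.4), 0.25, size=n))
    smoker = rng.random(n) < 0.10
    diabetic = rng.random(n) < 0.05
    treated_bp = rng.random(n) < 0.15
    prs_z = rng.standard_normal(n)

    if config.clinical_effect_sd > 0:
        pce_inputs = pd.DataFrame(
            {
                "age": age,
                "sex": np.where(male, "male", "female"),
                "sbp": sbp,
                "total_chol": total_chol * MMOL_TO_MGDL_CHOL,
                "hdl": hdl * MMOL_TO_MGDL_CHOL,
                "smoker": smoker.astype(float),
                "diabetic": diabetic.astype(float),
                "treated_bp": treated_bp.astype(float),
                "untreated_bp": (~treated_bp).astype(float),
            }
        )
        lp_pce = centered_linear_predictor_frame(pce_inputs, load_default_pce())
        clinical_lp = config.clinical_effect_sd * (
            (lp_pce - lp_pce.mean()) / lp_pce.std(ddof=0)
        )
    else:
        clinical_lp = np.zeros(n)

    lp = math.log(config.hr_per_sd_prs) * prs_z + clinical_lp
    lam0 = (
        config.baseline_hazard
        if config.baseline_hazard is not None
        else _calibrate_baseline_hazard(lp, config.target_10y_event_rate)
    )
    times, events = simulate_survival(
        lp, lam0, config.censor_window_years, seed=int(rng.integers(2**31))
    )

    logit_prev = (
        config.prevalence_intercept
        + config.prevalence_beta_prs * prs_z
        + config.prevalence_beta_age * (age - 55.0)
    )
    prevalent = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_prev))

    df = pd.DataFrame(
        {
            "id": [f"S{i:07d}" for i in range(n)],
            "age_at_baseline": age,
            "sex": np.where(male, "male", "female"),
            "sbp": sbp,
            "total_chol": total_chol,
            "hdl": hdl,
            "ldl": ldl,
            "smoker": smoker,
            "diabetic": diabetic,
            "treated_bp": treated_bp,
            "prs_raw": prs_z,
            "prs_z": prs_z,
            "clinical_lp": clinical_lp,
            "time_to_event_or_censor": times,
            "incident_event": events,
            "prevalent_case": prevalent,
            "stratum": _stratum_labels(age, male),
        }
    )
    df.attrs["baseline_hazard"] = lam0
    df.attrs["config"] = config
    return df


def generate_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int = 0,
) -> tuple[GenotypeMatrix, WeightTable]:
    """Hardy-Weinberg dosages plus a weight table rescaled to a unit-variance
    score, for end-to-end tests of the scoring engine."""
    if n_individuals <= 0 or n_variants <= 0:
        raise ValueError("counts must be positive")
    low, high = maf_range
    if not (0.0 < low <= high <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(low, high, size=n_variants)
    dosages = rng.binomial(2, mafs, size=(n_individuals, n_variants)).astype(float)
    weights = rng.normal(0.0, 1.0, size=n_variants)
    score = dosages @ weights
    sd = float(np.std(score, ddof=0))
    if not sd > 0:
        raise ValueError("zero-variance score; cannot rescale weights")
    weights = weights / sd

    alleles = np.array(list("ACGT"))
    eff_idx = rng.integers(0, 4, size=n_variants)
    oth_idx = (eff_idx + rng.integers(1, 4, size=n_variants)) % 4
    chrom = [str(1 + i % 22) for i in range(n_variants)]
    pos = [1000 + 10 * (i // 22) for i in range(n_variants)]
    wtab = WeightTable(
        pd.DataFrame(
            {
                "id": [f"rs{i + 1}" for i in range(n_variants)],
                "chrom": chrom,
                "pos": pos,
                "effect_allele": alleles[eff_idx],
                "other_allele": alleles[oth_idx],
                "weight": weights,
            }
        )
    )
    variants = pd.DataFrame(
        {
            "id": wtab.frame["id"],
            "chrom": chrom,
            "pos": pos,
            "ref": alleles[oth_idx],
            "alt": alleles[eff_idx],  # coded allele = effect allele
        }
    )
    geno = GenotypeMatrix(
        dosages, [f"S{i:07d}" for i in range(n_individuals)], variants
    )
    return geno, wtab


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF v4.2 with a DS FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        v = geno.variants
        for j in range(geno.n_variants):
            vals = [
                "." if np.isnan(d) else f"{d:.4g}" for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{v['chrom'].iat[j]}\t{v['pos'].iat[j]}\t{v['id'].iat[j]}\t"
                f"{v['ref'].iat[j]}\t{v['alt'].iat[j]}\t.\tPASS\t.\tDS\t"
                + "\t".join(vals)
                + "\n"
            )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (replicate helper)."""
    return replace(config, seed=seed)
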