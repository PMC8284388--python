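"""End-to-end orchestration: simulate -> score -> clinical risk -> integrate
-> evaluate -> impact, as a seeded, logged run with train/test discipline.

The integration model is fitted on the training split only; all reported
discrimination / reclassification metrics are computed on the held-out test
split. A manifest records versions, seeds, per-stage wall time, and a digest
of the run configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import MMOL_TO_MGDL_CHOL, load_default_pce, ten_year_risk_frame
from .impact import (
    ImpactParams,
    lives_saved_over_horizon,
    preventable_deaths_annual,
    scale_by_uptake,
)
from .integrate import IntegrationModel, apply_irt, fit_integration, save_model
from .metrics import (
    bonferroni,
    categorical_nri,
    cumulative_incidence,
    harrell_c,
    harrell_c_difference,
    pearson_correlation,
    percentile_rank,
    prs_percentile_band,
    reclassification_table,
    threshold_metrics,
)
from .simulate import SimulationConfig, generate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "SUBGROUPS"]

SUBGROUPS = ("M40-54", "M55-69", "F40-54", "F55-69")
#: overall test + the four age-by-sex subgroup tests
BONFERRONI_TESTS = 5


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    train_fraction: float = 0.5
    threshold: float = 0.075
    n_bootstrap: int = 500
    seed: int = 0
    outdir: str = "irtpipe_run"
    impact: ImpactParams | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (doc.get("simulation") or {}).items()
        })
        impact = None
        if doc.get("impact"):
            block = dict(doc["impact"])
            block.pop("ci_annual_deaths", None)
            impact = ImpactParams(**block)
        pipe = doc.get("pipeline") or {}
        return cls(simulation=sim, impact=impact, **pipe)

    def digest(self) -> str:
        payload = {
            "simulation": dataclasses.asdict(self.simulation),
            "train_fraction": self.train_fraction,
            "threshold": self.threshold,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "impact": dataclasses.asdict(self.impact) if self.impact else None,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _metric_row(metric, model, subgroup, est, seed=None, p_bonf=None) -> dict:
    return {
        "metric": metric,
        "model": model,
        "subgroup": subgroup,
        "value": est.value,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "method": est.method,
        "p_value": est.p_value,
        "p_bonferroni": p_bonf,
        "n": est.n,
        "seed": seed if seed is not None else est.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns paths and in-memory artifacts.

    Outputs under ``config.outdir``: report.tsv (one row per metric x model
    x subgroup), reclass.tsv, curves.tsv, model.json, manifest.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "irtpipe_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": [],
    }

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = _time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                manifest["stages"].append(
                    {"stage": name, "wall_s": round(_time.perf_counter() - self_inner.t0, 3)}
                )
                return False

        return _Stage()

    with stage("synthetic_cohort"):
        cohort = generate_cohort(config.simulation)
        incident = cohort.loc[~cohort["prevalent_case"]].reset_index(drop=True)
        if incident.empty:
            raise ValueError("no incident-analysis individuals after excluding prevalent cases")
        manifest["n_cohort"] = int(len(cohort))
        manifest["n_incident_analysis"] = int(len(incident))

    with stage("clinical_risk"):
        table = load_default_pce()
        pce_inputs = incident.assign(
            age=incident["age_at_baseline"],
            total_chol=incident["total_chol"] * MMOL_TO_MGDL_CHOL,
            hdl=incident["hdl"] * MMOL_TO_MGDL_CHOL,
            smoker=incident["smoker"].astype(float),
            diabetic=incident["diabetic"].astype(float),
            treated_bp=incident["treated_bp"].astype(float),
            untreated_bp=(~incident["treated_bp"]).astype(float),
        )
        table.check_units({"age": "years", "sbp": "mm Hg", "total_chol": "mg/dL", "hdl": "mg/dL"})
        incident["pce_risk"] = ten_year_risk_frame(pce_inputs, table)

    with stage("split"):
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(len(incident))
        n_train = int(round(config.train_fraction * len(incident)))
        train = incident.iloc[perm[:n_train]].reset_index(drop=True)
        test = incident.iloc[perm[n_train:]].reset_index(drop=True)
        manifest["n_train"], manifest["n_test"] = int(len(train)), int(len(test))

    def outcome10(df: pd.DataFrame) -> np.ndarray:
        return (df["incident_event"] & (df["time_to_event_or_censor"] <= 10.0)).to_numpy()

    with stage("irt"):
        model = fit_integration(
            train["pce_risk"].to_numpy(),
            train["prs_z"].to_numpy(),
            outcome10(train),
            threshold=config.threshold,
        )
        save_model(model, outdir / "model.json")

    with stage("evaluation"):
        report_rows, reclass_frame, curves = _evaluate(test, model, config)

    if config.impact is not None:
        with stage("population_impact"):
            deaths_raw, deaths = preventable_deaths_annual(config.impact)
            horizon = lives_saved_over_horizon(
                deaths_raw, config.impact.horizon_years
            )
            report_rows.append(
                {
                    "metric": "preventable_deaths_annual",
                    "model": "irt",
                    "subgroup": "overall",
                    "value": deaths,
                    "ci_low": None,
                    "ci_high": None,
                    "method": "arithmetic",
                    "p_value": None,
                    "p_bonferroni": None,
                    "n": None,
                    "seed": None,
                }
            )
            report_rows.append(
                {
                    "metric": f"lives_saved_{config.impact.horizon_years}y",
                    "model": "irt",
                    "subgroup": "overall",
                    "value": horizon,
                    "ci_low": None,
                    "ci_high": None,
                    "method": "arithmetic",
                    "p_value": None,
                    "p_bonferroni": None,
                    "n": None,
                    "seed": None,
                }
            )

    with stage("write"):
        report = pd.DataFrame(report_rows)
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        reclass_frame.to_csv(outdir / "reclass.tsv", sep="\t", index=False)
        curves.to_csv(outdir / "curves.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "outdir": outdir,
        "model": model,
        "report": report,
        "reclass": reclass_frame,
        "curves": curves,
        "manifest": manifest,
        "cohort": cohort,
        "test": test,
    }


def _evaluate(test: pd.DataFrame, model: IntegrationModel, config: RunConfig):
    time_v = test["time_to_event_or_censor"].to_numpy()
    event_v = test["incident_event"].to_numpy(dtype=bool)
    out10 = event_v & (time_v <= 10.0)
    pce = test["pce_risk"].to_numpy()
    prs = test["prs_z"].to_numpy()
    irt = apply_irt(pce, prs, model)
    thr = config.threshold
    rows: list[dict] = []

    # discrimination, overall and per subgroup, with Bonferroni on the
    # difference test (overall + 4 subgroup tests)
    masks = {"overall": np.ones(len(test), dtype=bool)}
    strata = test["stratum"].to_numpy()
    for g in SUBGROUPS:
        masks[g] = strata == g
    for g, m in masks.items():
        if m.sum() < 20 or event_v[m].sum() == 0:
            continue
        c_pce = harrell_c(pce[m], time_v[m], event_v[m])
        c_irt = harrell_c(irt[m], time_v[m], event_v[m])
        dc, z, p = harrell_c_difference(irt[m], pce[m], time_v[m], event_v[m])
        rows.append(_metric_row("harrell_c", "pce", g, c_pce))
        rows.append(_metric_row("harrell_c", "irt", g, c_irt))
        rows.append(
            {
                "metric": "delta_harrell_c",
                "model": "irt_vs_pce",
                "subgroup": g,
                "value": dc,
                "ci_low": None,
                "ci_high": None,
                "method": "jackknife",
                "p_value": p,
                "p_bonferroni": bonferroni(p, BONFERRONI_TESTS),
                "n": int(m.sum()),
                "seed": None,
            }
        )

    # reclassification + NRI
    old_high = pce >= thr
    new_high = irt >= thr
    reclass_rows = []
    for g, m in masks.items():
        if out10[m].sum() == 0 or (~out10[m]).sum() == 0:
            continue
        summ = reclassification_table(old_high[m], new_high[m], out10[m])
        nri = categorical_nri(summ, n_resamples=config.n_bootstrap, seed=config.seed)
        for key, est in nri.items():
            rows.append(_metric_row(key, "irt_vs_pce", g, est))
        tab = summ.to_frame()
        tab.insert(0, "subgroup", g)
        tab["fraction_up"] = summ.fraction_up
        tab["fraction_down"] = summ.fraction_down
        tab["fraction_reclassified"] = summ.fraction_reclassified
        reclass_rows.append(tab)

    # threshold metrics for both models
    for name, risk in (("pce", pce), ("irt", irt)):
        tm = threshold_metrics(risk, out10, thr)
        for metric, value in (
            ("sensitivity", tm.sensitivity),
            ("specificity", tm.specificity),
            ("ppv", tm.ppv),
        ):
            rows.append(
                {
                    "metric": metric,
                    "model": name,
                    "subgroup": "overall",
                    "value": value,
                    "ci_low": None,
                    "ci_high": None,
                    "method": "analytic",
                    "p_value": None,
                    "p_bonferroni": None,
                    "n": int(len(test)),
                    "seed": None,
                }
            )

    # PRS vs clinical-risk independence (log-odds scale)
    from scipy.special import logit as _logit

    r = pearson_correlation(prs, _logit(np.clip(pce, 1e-9, 1 - 1e-9)))
    rows.append(
        {
            "metric": "pearson_r_prs_vs_clinical",
            "model": "pce",
            "subgroup": "overall",
            "value": r,
            "ci_low": None,
            "ci_high": None,
            "method": "analytic",
            "p_value": None,
            "p_bonferroni": None,
            "n": int(len(test)),
            "seed": None,
        }
    )

    # cumulative incidence by PRS percentile band
    band = prs_percentile_band(percentile_rank(prs))
    in_band = band != ""
    curves = cumulative_incidence(time_v[in_band], event_v[in_band], band[in_band])

    reclass_frame = (
        pd.concat(reclass_rows, ignore_index=True) if reclass_rows else pd.DataFrame()
    )
    return rows, reclass_frame, curves
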