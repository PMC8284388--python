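"""Ten-year clinical cardiovascular risk from configurable Cox-form equations.

The risk equation is expressed as *data*, not code: a
:class:`RiskCoefficientTable` holds, per stratum (typically sex), a list of
coefficient terms plus the baseline 10-year survival ``S10`` and the mean
linear predictor ``LPbar`` of the derivation population. Ten-year risk is

    risk = 1 - S10 ** exp(LP - LPbar),    LP = sum_k  c_k * f_k(x) [* g_k(p)]

where each term applies a transform ``f`` (identity or natural log) to its
variable and optionally multiplies by a transformed interaction partner.
This single code path serves the bundled ACC/AHA pooled cohort equations
(PCE), QRISK-style variants supplied as config, and toy equations for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TermSpec",
    "StratumSpec",
    "RiskCoefficientTable",
    "read_coefficient_table",
    "write_coefficient_table",
    "load_default_pce",
    "compute_ten_year_risk",
    "ten_year_risk_frame",
    "MMOL_TO_MGDL_CHOL",
]

_TRANSFORMS = {"identity", "natural_log"}

#: mmol/L -> mg/dL conversion factor for cholesterol measures.
MMOL_TO_MGDL_CHOL = 38.67


@dataclass(frozen=True)
class TermSpec:
    """One additive term of a Cox-form linear predictor."""

    variable: str
    transform: str
    coefficient: float
    partner: str | None = None
    partner_transform: str = "identity"

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ValueError(
                f"term {self.variable!r}: unknown transform {self.transform!r}"
            )
        if self.partner_transform not in _TRANSFORMS:
            raise ValueError(
                f"term {self.variable!r}: unknown partner_transform "
                f"{self.partner_transform!r}"
            )
        if not math.isfinite(self.coefficient):
            raise ValueError(f"term {self.variable!r}: non-finite coefficient")


@dataclass(frozen=True)
class StratumSpec:
    label: str
    terms: tuple[TermSpec, ...]
    baseline_survival_10y: float
    mean_linear_predictor: float

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_survival_10y <= 1.0:
            raise ValueError(
                f"stratum {self.label!r}: baseline_survival_10y must be in (0, 1], "
                f"got {self.baseline_survival_10y}"
            )
        if not math.isfinite(self.mean_linear_predictor):
            raise ValueError(f"stratum {self.label!r}: non-finite mean_linear_predictor")

    def variables(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out.add(t.variable)
            if t.partner is not None:
                out.add(t.partner)
        return out


@dataclass(frozen=True)
class RiskCoefficientTable:
    """Stratified Cox-form 10-year risk equation plus declared input units."""

    name: str
    strata: Mapping[str, StratumSpec]
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("coefficient table has no strata")

    def check_units(self, declared: Mapping[str, str]) -> None:
        """Refuse inputs whose declared units differ from the table's.

        Only variables present in both mappings are compared; a mismatch
        raises ``ValueError`` naming the variable.
        """
        for var, unit in declared.items():
            want = self.units.get(var)
            if want is not None and want != unit:
                raise ValueError(
                    f"unit mismatch for {var!r}: table declares {want!r}, "
                    f"input declares {unit!r}"
                )


def _transform(values: np.ndarray, kind: str, variable: str) -> np.ndarray:
    if kind == "identity":
        return values
    if np.any(values <= 0):
        raise ValueError(
            f"natural_log transform of {variable!r} requires positive values"
        )
    return np.log(values)


def _linear_predictor(spec: StratumSpec, data: Mapping[str, np.ndarray]) -> np.ndarray:
    missing = spec.variables() - set(data)
    if missing:
        raise KeyError(
            f"stratum {spec.label!r}: missing variables {sorted(missing)}"
        )
    lp = None
    for t in spec.terms:
        x = _transform(np.asarray(data[t.variable], dtype=float), t.transform, t.variable)
        if t.partner is not None:
            x = x * _transform(
                np.asarray(data[t.partner], dtype=float), t.partner_transform, t.partner
            )
        contrib = t.coefficient * x
        lp = contrib if lp is None else lp + contrib
    return np.asarray(lp, dtype=float)


def compute_ten_year_risk(
    inputs: Mapping[str, float], table: RiskCoefficientTable, stratum: str
) -> float:
    """Ten-year risk for a single individual; ``risk = 1 - S10^exp(LP - LPbar)``.

    Raises ``KeyError`` for an unknown stratum or missing variable and
    ``ValueError`` for a non-positive value under a log transform. The result
    is clamped to [0, 1] rather than erroring on extreme linear predictors.
    """
    if stratum not in table.strata:
        raise KeyError(f"stratum {stratum!r} not in table {table.name!r}")
    spec = table.strata[stratum]
    data = {k: np.asarray([v], dtype=float) for k, v in inputs.items()}
    if not all(np.isfinite(next(iter(data.values())))):
        raise ValueError("non-finite input value")
    lp = _linear_predictor(spec, data)[0]
    risk = 1.0 - spec.baseline_survival_10y ** math.exp(lp - spec.mean_linear_predictor)
    return float(min(1.0, max(0.0, risk)))


def ten_year_risk_frame(
    df: pd.DataFrame, table: RiskCoefficientTable, stratum_col: str = "sex"
) -> np.ndarray:
    """Vectorized ten-year risk for a cohort frame.

    ``df`` must contain every variable the table references plus
    ``stratum_col`` whose values are stratum labels of the table.
    """
    risks = np.empty(len(df), dtype=float)
    strata = df[stratum_col].to_numpy()
    for label, spec in table.strata.items():
        mask = strata == label
        if not mask.any():
            continue
        sub = {v: df.loc[mask, v].to_numpy(dtype=float) for v in spec.variables()}
        lp = _linear_predictor(spec, sub)
        risks[mask] = 1.0 - spec.baseline_survival_10y ** np.exp(
            lp - spec.mean_linear_predictor
        )
    unknown = set(np.unique(strata)) - set(table.strata)
    if unknown:
        raise KeyError(f"strata {sorted(unknown)} not in table {table.name!r}")
    return np.clip(risks, 0.0, 1.0)


def centered_linear_predictor_frame(
    df: pd.DataFrame, table: RiskCoefficientTable, stratum_col: str = "sex"
) -> np.ndarray:
    """LP - LPbar per individual; the log-relative-hazard against the
    derivation population's mean. ``1 - S10^exp(.)`` of this is the risk."""
    out = np.empty(len(df), dtype=float)
    strata = df[stratum_col].to_numpy()
    for label, spec in table.strata.items():
        mask = strata == label
        if not mask.any():
            continue
        sub = {v: df.loc[mask, v].to_numpy(dtype=float) for v in spec.variables()}
        out[mask] = _linear_predictor(spec, sub) - spec.mean_linear_predictor
    unknown = set(np.unique(strata)) - set(table.strata)
    if unknown:
        raise KeyError(f"strata {sorted(unknown)} not in table {table.name!r}")
    return out


def _table_from_dict(doc: dict, source: str = "<dict>") -> RiskCoefficientTable:
    try:
        strata_doc = doc["strata"]
    except (KeyError, TypeError):
        raise ValueError(f"{source}: missing top-level 'strata' mapping") from None
    strata: dict[str, StratumSpec] = {}
    for label, block in strata_doc.items():
        try:
            terms = tuple(
                TermSpec(
                    variable=t["variable"],
                    transform=t.get("transform", "identity"),
                    coefficient=float(t["coefficient"]),
                    partner=t.get("partner"),
                    partner_transform=t.get("partner_transform", "identity"),
                )
                for t in block["terms"]
            )
            spec = StratumSpec(
                label=str(label),
                terms=terms,
                baseline_survival_10y=float(block["baseline_survival_10y"]),
                mean_linear_predictor=float(block["mean_linear_predictor"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{source}: strata.{label}: {exc}") from None
        # every interaction partner must itself be a defined input variable
        declared = {t.variable for t in spec.terms}
        for t in spec.terms:
            if t.partner is not None and t.partner not in declared | spec.variables():
                raise ValueError(
                    f"{source}: strata.{label}: undefined partner {t.partner!r}"
                )
        strata[str(label)] = spec
    return RiskCoefficientTable(
        name=str(doc.get("name", source)),
        strata=strata,
        units=dict(doc.get("units", {})),
    )


def read_coefficient_table(path) -> RiskCoefficientTable:
    """Load and validate a YAML coefficient table."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _table_from_dict(doc, source=str(path))


def write_coefficient_table(table: RiskCoefficientTable, path) -> None:
    doc = {
        "name": table.name,
        "units": dict(table.units),
        "strata": {
            label: {
                "baseline_survival_10y": spec.baseline_survival_10y,
                "mean_linear_predictor": spec.mean_linear_predictor,
                "terms": [
                    {
                        "variable": t.variable,
                        "transform": t.transform,
                        "coefficient": t.coefficient,
                        **(
                            {"partner": t.partner, "partner_transform": t.partner_transform}
                            if t.partner is not None
                            else {}
                        ),
                    }
                    for t in spec.terms
                ],
            }
            for label, spec in table.strata.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_default_pce() -> RiskCoefficientTable:
    """Bundled 2013 ACC/AHA pooled cohort equations (White/European sets)."""
    ref = resources.files("irtpipe.data").joinpath("pce_acc_aha_2013.yaml")
    with ref.open() as fh:
        doc = yaml.safe_load(fh)
    return _table_from_dict(doc, source="pce_acc_aha_2013.yaml")
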