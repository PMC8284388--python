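"""Integrated risk tool: clinical 10-year risk + PRS on the log-odds scale.

The combined risk is

    logit(irt) = logit(clinical) + beta_prs * prs_z + offset

justified by the near-zero correlation between PRS and clinical risk:
``beta_prs`` is the log-odds ratio per SD of PRS given the clinical risk,
estimated by logistic regression with logit(clinical risk) as a fixed
offset. The recalibration ``offset`` is then chosen so the positive
predictive value of {irt >= threshold} matches that of
{clinical >= threshold} on the training data — "PPV-preserving rescaling",
which trades a moderate specificity cost for improved sensitivity at the
action threshold (default 7.5% ten-year risk).

Also provides the alternative *risk-enhancer* rule: borderline individuals
(5% < clinical < 7.5%) are promoted to high risk when their PRS is in the
top 20% of the reference distribution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "IntegrationModel",
    "fit_integration",
    "apply_irt",
    "calibrate_offset",
    "risk_enhancer_rule",
    "save_model",
    "load_model",
]

_EPS = 1e-9
MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class IntegrationModel:
    """PRS log-odds coefficient plus recalibration offset defining the IRT."""

    beta_prs: float
    offset: float
    threshold: float = 0.075
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if not np.isfinite(self.beta_prs):
            raise ValueError("beta_prs must be finite")


def _safe_logit(risk: np.ndarray) -> np.ndarray:
    return logit(np.clip(np.asarray(risk, dtype=float), _EPS, 1.0 - _EPS))


def fit_integration(
    clinical_risk,
    prs_z,
    outcome,
    threshold: float = 0.075,
) -> IntegrationModel:
    """Fit the IRT on training data: logistic MLE for ``beta_prs`` with
    logit(clinical risk) as a fixed offset, then PPV-matching calibration of
    the recalibration offset at ``threshold``. Deterministic given the data.

    The MLE includes a free intercept so miscalibration of the clinical risk
    does not bias ``beta_prs``; that intercept is discarded — the deployed
    shift is the PPV-matching offset.

    Raises ``ValueError`` when the outcome has a single class or the MLE is
    non-finite (separation).
    """
    import statsmodels.api as sm

    clinical_risk = np.asarray(clinical_risk, dtype=float)
    prs_z = np.asarray(prs_z, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or not outcome.any():
        raise ValueError("outcome must contain both classes")
    if np.any((clinical_risk <= 0) | (clinical_risk >= 1)):
        clinical_risk = np.clip(clinical_risk, _EPS, 1.0 - _EPS)

    exog = sm.add_constant(prs_z)
    model = sm.GLM(
        outcome.astype(float),
        exog,
        family=sm.families.Binomial(),
        offset=_safe_logit(clinical_risk),
    )
    res = model.fit()
    beta = float(res.params[1])
    if not (np.isfinite(beta) and np.all(np.isfinite(res.bse))):
        raise ValueError("separation: logistic MLE is non-finite")

    offset = calibrate_offset(beta, clinical_risk, prs_z, outcome, threshold)
    irt = apply_irt(
        clinical_risk, prs_z, IntegrationModel(beta, offset, threshold)
    )
    high_clin = clinical_risk >= threshold
    high_irt = irt >= threshold
    summary = {
        "n": int(len(outcome)),
        "intercept_mle": float(res.params[0]),
        "beta_se": float(res.bse[1]),
        "ppv_clinical": _ppv(high_clin, outcome),
        "ppv_irt": _ppv(high_irt, outcome),
        "sensitivity_clinical": _sens(high_clin, outcome),
        "sensitivity_irt": _sens(high_irt, outcome),
    }
    return IntegrationModel(beta, offset, threshold, summary)


def apply_irt(clinical_risk, prs_z, model: IntegrationModel) -> np.ndarray:
    """Combined risk: ``expit(logit(clinical) + beta_prs * prs_z + offset)``.

    Clinical risks of exactly 0 or 1 are clamped to (1e-9, 1 - 1e-9).
    Strictly increasing in clinical risk, and in prs_z when beta_prs > 0.
    """
    prs_z = np.asarray(prs_z, dtype=float)
    return expit(_safe_logit(clinical_risk) + model.beta_prs * prs_z + model.offset)


def _ppv(pred_high: np.ndarray, outcome: np.ndarray) -> float:
    n_pos = int(pred_high.sum())
    return float(outcome[pred_high].sum() / n_pos) if n_pos else float("nan")


def _sens(pred_high: np.ndarray, outcome: np.ndarray) -> float:
    n_ev = int(outcome.sum())
    return float((pred_high & outcome).sum() / n_ev) if n_ev else float("nan")


def calibrate_offset(
    beta_prs: float,
    clinical_risk,
    prs_z,
    outcome,
    threshold: float = 0.075,
) -> float:
    """Offset such that PPV of {irt >= threshold} matches the clinical PPV.

    PPV is a step function of the offset: individual i enters the high-risk
    set once ``offset >= logit(threshold) - s_i`` with
    ``s_i = logit(clinical_i) + beta_prs * prs_i``. Every achievable
    classification is therefore a prefix of individuals sorted by s, and the
    candidate offsets are interval representatives (midpoints between
    consecutive entry points, the extremes, and 0). The offset whose PPV is
    closest to the clinical PPV is returned, ties broken toward smaller
    |offset|.

    Raises ``ValueError`` when nobody is above threshold under the clinical
    score (its PPV is undefined).
    """
    clinical_risk = np.asarray(clinical_risk, dtype=float)
    prs_z = np.asarray(prs_z, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    high_clin = clinical_risk >= threshold
    if not high_clin.any():
        raise ValueError("no individual above threshold under clinical risk")
    target_ppv = _ppv(high_clin, outcome)

    s = _safe_logit(clinical_risk) + beta_prs * prs_z
    entry = np.sort(logit(threshold) - s)  # offset at which each individual enters
    n = len(entry)

    # candidate = the minimal-|offset| point of each classification interval
    # [entry[k-1], entry[k]) (top-k individuals classified high)
    candidates: list[float] = []
    for k in range(1, n + 1):
        lo = float(entry[k - 1])
        hi = float(entry[k]) if k < n else np.inf
        if hi <= lo:  # tied scores: zero-width interval, classification unreachable
            continue
        if lo <= 0.0 < hi:
            candidates.append(0.0)
        elif lo > 0.0:
            candidates.append(lo)
        else:  # hi <= 0: approach the open upper end from below
            candidates.append(max(lo, hi - 1e-9))

    best_offset = None
    best_gap = np.inf
    for off in candidates:
        high = s >= logit(threshold) - off
        if not high.any():
            continue
        gap = abs(_ppv(high, outcome) - target_ppv)
        if gap < best_gap - 1e-15 or (
            abs(gap - best_gap) <= 1e-15
            and best_offset is not None
            and abs(off) < abs(best_offset)
        ):
            best_gap = gap
            best_offset = float(off)
    assert best_offset is not None
    return best_offset


def risk_enhancer_rule(clinical_risk, prs_percentile) -> np.ndarray:
    """Alternative classifier: high iff clinical >= 7.5%, or borderline
    (5% < clinical < 7.5%) with PRS in the top 20% (percentile >= 80).

    Returns a boolean array (True = high risk). Individuals below 5%
    clinical risk are never promoted.
    """
    c = np.asarray(clinical_risk, dtype=float)
    pct = np.asarray(prs_percentile, dtype=float)
    return (c >= 0.075) | ((c > 0.05) & (c < 0.075) & (pct >= 80.0))


def save_model(model: IntegrationModel, path) -> None:
    doc = {"format_version": MODEL_FORMAT_VERSION, **asdict(model)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def load_model(path) -> IntegrationModel:
    with open(path) as fh:
        doc = json.load(fh)
    doc.pop("format_version", None)
    return IntegrationModel(**doc)
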