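"""Discrimination, reclassification, and association metrics with resampling CIs.

Implements Harrell's concordance index under right censoring (with a
leave-one-out jackknife CI and a paired-jackknife z test for the difference
between two scores on the same individuals), Cox hazard ratios per SD
(via lifelines, Efron tie handling), categorical net reclassification
improvement with a seeded bootstrap, threshold-based diagnostic metrics,
Kaplan-Meier cumulative incidence curves, a PRS-by-age interaction test,
and Pearson correlation.

Harrell's C pair rule: a pair is usable iff the observed times differ and
the subject with the shorter time had an event; concordant pairs score 1,
score ties 1/2. Pairs with tied observed times are never used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad

__all__ = [
    "MetricEstimate",
    "ReclassificationSummary",
    "ThresholdMetrics",
    "harrell_c",
    "harrell_c_difference",
    "cox_hr_per_sd",
    "reclassification_table",
    "categorical_nri",
    "threshold_metrics",
    "cumulative_incidence",
    "prs_percentile_band",
    "percentile_rank",
    "prs_age_interaction",
    "pearson_correlation",
    "expected_concordance_exponential",
    "bonferroni",
]


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with a 95% CI and the method that produced it."""

    value: float
    ci_low: float
    ci_high: float
    method: str  # analytic | bootstrap | jackknife
    se: float | None = None
    p_value: float | None = None
    n: int | None = None
    n_resamples: int | None = None
    seed: int | None = None


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _as_bool(x) -> np.ndarray:
    return np.asarray(x, dtype=bool)


def _concordance_counts(
    score: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, int, np.ndarray, np.ndarray]:
    """Concordance numerator/denominator plus per-subject pair sums.

    Returns (num, den, num_i, den_i) where num counts concordant pairs plus
    half-credit score ties, den counts usable pairs, and num_i/den_i are each
    subject's share (every pair contributes to both members, so
    sum(num_i) == 2*num).
    """
    n = len(score)
    order = np.argsort(time, kind="stable")
    ts, sc, ev = time[order], score[order], event[order]
    num_i = np.zeros(n)
    den_i = np.zeros(n)
    num = 0.0
    den = 0
    for p in np.flatnonzero(ev):
        q0 = int(np.searchsorted(ts, ts[p], side="right"))
        if q0 >= n:
            continue
        later = sc[q0:]
        contrib = (sc[p] > later).astype(float)
        contrib += 0.5 * (sc[p] == later)
        m = n - q0
        s = float(contrib.sum())
        num += s
        den += m
        num_i[p] += s
        den_i[p] += m
        num_i[q0:] += contrib
        den_i[q0:] += 1.0
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return num, den, num_i[inv], den_i[inv]


def _jackknife_values(num: float, den: int, num_i: np.ndarray, den_i: np.ndarray) -> np.ndarray:
    c = num / den
    den_loo = den - den_i
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (num - num_i) / den_loo
    return np.where(den_loo > 0, loo, c)


def harrell_c(score, time, event) -> MetricEstimate:
    """Harrell's concordance index with a jackknife 95% CI.

    Raises ``ValueError`` when no usable pair exists (e.g. no events).
    """
    score, time, event = _as_float(score), _as_float(time), _as_bool(event)
    if not event.any():
        raise ValueError("concordance requires at least one event")
    num, den, num_i, den_i = _concordance_counts(score, time, event)
    if den == 0:
        raise ValueError("no usable pairs for concordance")
    c = num / den
    loo = _jackknife_values(num, den, num_i, den_i)
    n = len(score)
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return MetricEstimate(
        value=float(c),
        ci_low=float(c - 1.959964 * se),
        ci_high=float(c + 1.959964 * se),
        method="jackknife",
        se=se,
        n=n,
    )


def harrell_c_difference(score_a, score_b, time, event) -> tuple[float, float, float]:
    """Difference C(a) - C(b) on the same individuals with a paired-jackknife
    z test; returns (delta_c, z, two-sided p).

    Refuses fewer than 20 individuals (jackknife SE unstable).
    """
    score_a, score_b = _as_float(score_a), _as_float(score_b)
    time, event = _as_float(time), _as_bool(event)
    n = len(time)
    if n < 20:
        raise ValueError("harrell_c_difference requires at least 20 individuals")
    if len(score_a) != n or len(score_b) != n:
        raise ValueError("scores and survival data must have equal length")
    num_a, den_a, ni_a, di_a = _concordance_counts(score_a, time, event)
    num_b, den_b, ni_b, di_b = _concordance_counts(score_b, time, event)
    if den_a == 0 or den_b == 0:
        raise ValueError("no usable pairs for concordance")
    delta = num_a / den_a - num_b / den_b
    d_loo = _jackknife_values(num_a, den_a, ni_a, di_a) - _jackknife_values(
        num_b, den_b, ni_b, di_b
    )
    se = float(np.sqrt((n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2)))
    if se == 0.0:
        return float(delta), 0.0, 1.0 if delta == 0 else 0.0
    z = float(delta / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(delta), z, p


def cox_hr_per_sd(
    prs_z, time, event, covariates: pd.DataFrame | None = None
) -> MetricEstimate:
    """Hazard ratio per SD from a Cox proportional-hazards fit (Efron ties).

    If the predictor's sample SD deviates from 1 by more than 5% it is
    re-standardized internally so the estimate is genuinely per SD.
    """
    from lifelines import CoxPHFitter

    prs_z = _as_float(prs_z)
    time, event = _as_float(time), _as_bool(event)
    if not event.any():
        raise ValueError("Cox fit requires at least one event")
    sd = float(np.std(prs_z, ddof=1))
    if not sd > 0:
        raise ValueError("constant predictor")
    if abs(sd - 1.0) > 0.05:
        prs_z = (prs_z - prs_z.mean()) / sd
    df = pd.DataFrame({"prs_z": prs_z, "time": time, "event": event.astype(int)})
    if covariates is not None:
        df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # monotone likelihood / separation
        raise ValueError(f"Cox fit failed: {exc}") from exc
    row = cph.summary.loc["prs_z"]
    return MetricEstimate(
        value=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        method="analytic",
        se=float(row["se(coef)"]),
        p_value=float(row["p"]),
        n=len(df),
    )


@dataclass(frozen=True)
class ReclassificationSummary:
    """2 x 2 x {nonevent, event} counts at a risk threshold.

    ``counts[old, new, outcome]`` with index 1 meaning high risk / event.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2, 2) or (c < 0).any():
            raise ValueError("counts must be a non-negative (2, 2, 2) array")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def fraction_up(self) -> float:
        return float(self.counts[0, 1, :].sum() / self.n)

    @property
    def fraction_down(self) -> float:
        return float(self.counts[1, 0, :].sum() / self.n)

    @property
    def fraction_reclassified(self) -> float:
        return self.fraction_up + self.fraction_down

    @property
    def case_up(self) -> float:
        """P(up-classified | event)."""
        ev = self.counts[:, :, 1].sum()
        return float(self.counts[0, 1, 1] / ev) if ev else float("nan")

    @property
    def case_down(self) -> float:
        ev = self.counts[:, :, 1].sum()
        return float(self.counts[1, 0, 1] / ev) if ev else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = ("low", "high")
        for o in (0, 1):
            for nw in (0, 1):
                rows.append(
                    {
                        "old_class": labels[o],
                        "new_class": labels[nw],
                        "nonevents": int(self.counts[o, nw, 0]),
                        "events": int(self.counts[o, nw, 1]),
                    }
                )
        return pd.DataFrame(rows)


def reclassification_table(old_high, new_high, is_event) -> ReclassificationSummary:
    old_high, new_high, is_event = map(_as_bool, (old_high, new_high, is_event))
    if not (len(old_high) == len(new_high) == len(is_event)):
        raise ValueError("input vectors must have equal length")
    counts = np.zeros((2, 2, 2), dtype=np.int64)
    np.add.at(counts, (old_high.astype(int), new_high.astype(int), is_event.astype(int)), 1)
    return ReclassificationSummary(counts)


def _nri_from_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized over leading axes; counts[..., old, new, outcome]."""
    ev = counts[..., 1]
    ne = counts[..., 0]
    ev_tot = ev.sum(axis=(-2, -1))
    ne_tot = ne.sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        nri_ev = (ev[..., 0, 1] - ev[..., 1, 0]) / ev_tot
        nri_ne = (ne[..., 1, 0] - ne[..., 0, 1]) / ne_tot
    return nri_ev + nri_ne, nri_ev, nri_ne


def categorical_nri(
    summary: ReclassificationSummary, n_resamples: int = 1000, seed: int = 0
) -> dict[str, MetricEstimate]:
    """Categorical NRI and its event/nonevent components with percentile
    bootstrap CIs.

    ``nri_events = P(up|event) - P(down|event)``;
    ``nri_nonevents = P(down|nonevent) - P(up|nonevent)``; their sum is the
    overall NRI (an exact identity). The bootstrap resamples the 2x2x2 cell
    counts multinomially, which is equivalent to resampling individuals.
    """
    counts = np.asarray(summary.counts, dtype=float)
    if counts[:, :, 1].sum() == 0 or counts[:, :, 0].sum() == 0:
        raise ValueError("NRI requires at least one event and one nonevent")
    nri, nri_ev, nri_ne = _nri_from_counts(counts)

    rng = np.random.default_rng(seed)
    p = counts.ravel() / counts.sum()
    draws = rng.multinomial(summary.n, p, size=n_resamples).reshape(-1, 2, 2, 2)
    b_nri, b_ev, b_ne = _nri_from_counts(draws.astype(float))

    def est(value: float, boots: np.ndarray) -> MetricEstimate:
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        return MetricEstimate(
            value=float(value),
            ci_low=float(lo),
            ci_high=float(hi),
            method="bootstrap",
            n=summary.n,
            n_resamples=n_resamples,
            seed=seed,
        )

    return {
        "nri": est(nri, b_nri),
        "nri_events": est(nri_ev, b_ev),
        "nri_nonevents": est(nri_ne, b_ne),
    }


@dataclass(frozen=True)
class ThresholdMetrics:
    sensitivity: float
    specificity: float
    ppv: float  # NaN when no positives are predicted


def threshold_metrics(risk, is_event, threshold: float) -> ThresholdMetrics:
    """Sensitivity, specificity, PPV of the classifier {risk >= threshold}."""
    risk, is_event = _as_float(risk), _as_bool(is_event)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be within [0, 1]")
    pred = risk >= threshold
    tp = int(np.sum(pred & is_event))
    fp = int(np.sum(pred & ~is_event))
    fn = int(np.sum(~pred & is_event))
    tn = int(np.sum(~pred & ~is_event))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    return ThresholdMetrics(sens, spec, ppv)


def percentile_rank(values, reference=None) -> np.ndarray:
    """Percentile (0-100] of each value within a reference distribution
    (the values themselves when ``reference`` is None)."""
    values = _as_float(values)
    ref = values if reference is None else _as_float(reference)
    ref_sorted = np.sort(ref)
    return 100.0 * np.searchsorted(ref_sorted, values, side="right") / len(ref_sorted)


def prs_percentile_band(percentile) -> np.ndarray:
    """Assign the reporting bands bottom 5% / middle 40-60% / top 5%.

    Returns an object array with '' for individuals outside the bands.
    """
    pct = _as_float(percentile)
    out = np.full(pct.shape, "", dtype=object)
    out[pct < 5.0] = "bottom5"
    out[(pct >= 40.0) & (pct <= 60.0)] = "mid40-60"
    out[pct > 95.0] = "top5"
    return out


def cumulative_incidence(time, event, group) -> pd.DataFrame:
    """Per-group 1 - Kaplan-Meier step curves as a long-format frame with
    columns (group, time, cum_incidence); curves truncate at the last
    observed time per group, never extrapolating."""
    from lifelines import KaplanMeierFitter

    time, event = _as_float(time), _as_bool(event)
    group = np.asarray(group)
    rows = []
    for g in pd.unique(group):
        mask = group == g
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_
        for t, s in zip(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()):
            rows.append({"group": g, "time": float(t), "cum_incidence": float(1.0 - s)})
    return pd.DataFrame(rows, columns=["group", "time", "cum_incidence"])


def prs_age_interaction(
    prs_z, age, time, event, sex=None, age_center: float = 55.0
) -> dict[str, MetricEstimate]:
    """Cox model with prs, age, and prs x (age - 55); Wald test on the
    interaction coefficient, pooled and (when ``sex`` is given) per sex."""
    from lifelines import CoxPHFitter

    prs_z, age = _as_float(prs_z), _as_float(age)
    time, event = _as_float(time), _as_bool(event)
    if np.std(age) == 0:
        raise ValueError("age is constant; interaction model is collinear")

    def _fit(mask: np.ndarray) -> MetricEstimate:
        df = pd.DataFrame(
            {
                "prs_z": prs_z[mask],
                "age_c": age[mask] - age_center,
                "prs_x_age": prs_z[mask] * (age[mask] - age_center),
                "time": time[mask],
                "event": event[mask].astype(int),
            }
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        row = cph.summary.loc["prs_x_age"]
        return MetricEstimate(
            value=float(row["coef"]),
            ci_low=float(row["coef lower 95%"]),
            ci_high=float(row["coef upper 95%"]),
            method="analytic",
            se=float(row["se(coef)"]),
            p_value=float(row["p"]),
            n=int(mask.sum()),
        )

    out = {"pooled": _fit(np.ones(len(prs_z), dtype=bool))}
    if sex is not None:
        sex = np.asarray(sex)
        for label in pd.unique(sex):
            out[str(label)] = _fit(sex == label)
    return out


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; requires >= 3 pairs and nonzero variances."""
    x, y = _as_float(x), _as_float(y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_correlation requires >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y)[0])


def expected_concordance_exponential(hr_per_sd: float) -> float:
    """Closed-form concordance for an exponential proportional-hazards model
    with a single standard-normal predictor at hazard ratio ``hr_per_sd``.

    For two subjects the better-ranked one fails first with probability
    sigmoid(beta * dz); averaging the oriented pair gives
    C = E[sigmoid(|D|)] with D ~ N(0, 2 beta^2), computed by quadrature.
    """
    beta = np.log(hr_per_sd)
    sd = float(np.sqrt(2.0) * abs(beta))
    if sd == 0:
        return 0.5
    val, _ = quad(
        lambda x: (1.0 / (1.0 + np.exp(-x))) * 2.0 * stats.norm.pdf(x, scale=sd),
        0.0,
        np.inf,
    )
    return float(val)


def bonferroni(p: float, n_tests: int) -> float:
    return float(min(1.0, p * n_tests))
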