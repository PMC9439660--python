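"""Survival estimation and discrimination metrics for risk scores.

Kaplan–Meier curves, two-group log-rank tests and Cox regressions are
delegated to lifelines; Harrell's concordance uses lifelines' fast
implementation with the risk-score orientation fixed package-wide (higher
score = higher risk = shorter expected time); time-dependent cumulative/
dynamic ROC AUC with inverse-probability-of-censoring weights (IPCW) comes
from scikit-survival.  Calibration against the within-bin Kaplan–Meier and
the continuous (category-free) net reclassification improvement, IPCW-
weighted at the evaluation horizon, are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "SurvivalCurve",
    "CoxResult",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "harrell_c",
    "td_roc_auc",
    "calibration_curve",
    "nri",
]


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(time: np.ndarray, event: np.ndarray) -> SurvivalCurve:
    """Product-limit estimator with Greenwood confidence band."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if np.any(time < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
        events=table["observed"].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
    )


def logrank_test(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    a = group == levels[0]
    res = _ll_logrank(time[a], time[~a], event[a], event[~a])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Hazard ratios with Wald CIs, per covariate."""

    table: pd.DataFrame  # index covariate; columns HR, ci_lower, ci_upper, p
    log_likelihood: float
    n: int
    n_events: int


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame,
    mode: str = "multi",
) -> CoxResult:
    """Cox proportional-hazards regression (Efron ties, Newton solver).

    ``mode="multi"`` fits all covariates jointly; ``mode="uni"`` fits one
    model per covariate and collects the rows.
    """
    covariates = pd.DataFrame(covariates)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < covariates.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")
    if mode not in ("uni", "multi"):
        raise ValueError("mode must be 'uni' or 'multi'")

    def _fit(cols: List[str]) -> CoxPHFitter:
        df = covariates[cols].copy()
        df["time"], df["event"] = time, event
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # lifelines raises ConvergenceError/Warning
            raise RuntimeError(
                f"Cox fit failed for covariates {cols}: {exc}"
            ) from exc
        return cph

    if mode == "multi":
        cph = _fit(list(covariates.columns))
        s = cph.summary
        table = pd.DataFrame(
            {
                "HR": s["exp(coef)"],
                "ci_lower": s["exp(coef) lower 95%"],
                "ci_upper": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )
        ll = float(cph.log_likelihood_)
    else:
        rows = []
        ll = float("nan")
        for col in covariates.columns:
            s = _fit([col]).summary
            rows.append(
                {
                    "covariate": col,
                    "HR": float(s["exp(coef)"].iloc[0]),
                    "ci_lower": float(s["exp(coef) lower 95%"].iloc[0]),
                    "ci_upper": float(s["exp(coef) upper 95%"].iloc[0]),
                    "p": float(s["p"].iloc[0]),
                }
            )
        table = pd.DataFrame(rows).set_index("covariate")
    return CoxResult(table, ll, len(time), int(event.sum()))


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def harrell_c(
    time: np.ndarray,
    event: np.ndarray,
    score: np.ndarray,
    ci: bool = True,
    ci_method: str = "bootstrap",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> Tuple[float, Optional[Tuple[float, float]]]:
    """Harrell's C of a risk score (higher score = higher risk).

    Ties in the score count 0.5.  The 95% CI is by seeded bootstrap
    (default) or a Noether-style proportion approximation.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    score = np.asarray(score, dtype=float)
    try:
        c = float(_ll_concordance(time, -score, event))
    except ZeroDivisionError as exc:
        raise ValueError("no comparable pairs (need at least one event)") from exc
    if not ci:
        return c, None
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(time)
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            if event[idx].sum() == 0:
                continue
            reps.append(_ll_concordance(time[idx], -score[idx], event[idx]))
        lo, hi = np.percentile(reps, [2.5, 97.5])
        return c, (float(lo), float(hi))
    if ci_method == "noether":
        # comparable pairs: event-anchored, earlier time strictly smaller
        order = np.argsort(time)
        t_s, e_s = time[order], event[order]
        m = 0
        for i in range(len(t_s)):
            if e_s[i]:
                m += int(np.sum(t_s > t_s[i]))
        se = np.sqrt(max(c * (1 - c), 1e-12) / max(m, 1))
        return c, (c - 1.96 * se, c + 1.96 * se)
    raise ValueError("ci_method must be 'bootstrap' or 'noether'")


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

def td_roc_auc(
    time: np.ndarray,
    event: np.ndarray,
    score: np.ndarray,
    horizon: float,
    train_time: Optional[np.ndarray] = None,
    train_event: Optional[np.ndarray] = None,
) -> float:
    """Cumulative-cases / dynamic-controls AUC at a horizon, IPCW-weighted.

    The censoring distribution is estimated from the training sample
    (defaults to the evaluation sample itself).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    score = np.asarray(score, dtype=float)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if cases.sum() == 0:
        raise ValueError("no events before the horizon")
    if controls.sum() == 0:
        raise ValueError("no subjects at risk past the horizon")
    if train_time is None:
        train_time, train_event = time, event
    y_train = Surv.from_arrays(np.asarray(train_event).astype(bool), np.asarray(train_time, dtype=float))
    y_test = Surv.from_arrays(event.astype(bool), time)
    auc, _ = cumulative_dynamic_auc(y_train, y_test, score, [horizon])
    return float(auc[0])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration_curve(
    predicted_risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Mean predicted vs KM-observed event probability by risk quantile bin.

    ``predicted_risk`` is the predicted probability of an event by
    ``horizon`` (in [0, 1]).  Observed risk per bin is 1 − S(horizon) from
    the within-bin Kaplan–Meier.  Degenerate bins merge with a neighbor.
    """
    predicted_risk = np.asarray(predicted_risk, dtype=float)
    if np.any((predicted_risk < 0) | (predicted_risk > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    edges = np.unique(np.quantile(predicted_risk, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        edges = np.array([predicted_risk.min() - 1e-9, predicted_risk.max() + 1e-9])
        warnings.warn("constant predictions: single calibration bin")
    bins = np.clip(np.searchsorted(edges, predicted_risk, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = bins == b
        if sel.sum() == 0:
            warnings.warn(f"empty calibration bin {b}: merged with neighbor")
            continue
        km = km_curve(time[sel], event[sel])
        rows.append(
            {
                "bin": b,
                "n": int(sel.sum()),
                "mean_predicted": float(predicted_risk[sel].mean()),
                "observed": 1.0 - km.survival_at(horizon),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Net reclassification improvement
# ---------------------------------------------------------------------------

def _censor_km(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    return kmf


def nri(
    score_new: np.ndarray,
    score_old: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
    ci: bool = True,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> Tuple[float, Optional[Tuple[float, float]]]:
    """Continuous (category-free) NRI of a new score over an old one.

    NRI = [P(up|event) − P(down|event)] + [P(down|non-event) − P(up|non-event)]
    with event status taken at the horizon and censoring handled by IPCW:
    events before the horizon weigh 1/G(T−), survivors past it 1/G(h),
    subjects censored before the horizon are dropped.
    """
    score_new = np.asarray(score_new, dtype=float)
    score_old = np.asarray(score_old, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if len(score_new) != len(score_old) or len(score_new) != len(time):
        raise ValueError("scores and outcomes must cover the same subjects")
    if horizon >= time.max():
        raise ValueError("horizon lies beyond the observed follow-up")

    def _nri_once(idx: np.ndarray) -> float:
        t, e = time[idx], event[idx]
        sn, so = score_new[idx], score_old[idx]
        kmf = _censor_km(t, e)
        up = sn > so
        down = sn < so
        is_event = (t <= horizon) & (e == 1)
        is_nonevent = t > horizon
        g_at_t = np.maximum(
            kmf.survival_function_at_times(np.clip(t - 1e-9, 0, None)).to_numpy(), 1e-8
        )
        g_at_h = max(float(kmf.survival_function_at_times([horizon]).iloc[0]), 1e-8)
        w_event = np.where(is_event, 1.0 / g_at_t, 0.0)
        w_non = np.where(is_nonevent, 1.0 / g_at_h, 0.0)
        if w_event.sum() == 0 or w_non.sum() == 0:
            return np.nan
        p_up_e = (w_event * up).sum() / w_event.sum()
        p_dn_e = (w_event * down).sum() / w_event.sum()
        p_up_n = (w_non * up).sum() / w_non.sum()
        p_dn_n = (w_non * down).sum() / w_non.sum()
        return (p_up_e - p_dn_e) + (p_dn_n - p_up_n)

    value = float(_nri_once(np.arange(len(time))))
    if not ci:
        return value, None
    rng = np.random.default_rng(seed)
    reps = []
    n = len(time)
    for _ in range(n_bootstrap):
        r = _nri_once(rng.integers(0, n, n))
        if np.isfinite(r):
            reps.append(r)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return value, (float(lo), float(hi))
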