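"""Survival statistics layer: Kaplan-Meier curves and 5-year rates,
k-group log-rank tests, Cox proportional-hazards fits (via lifelines,
Efron ties), Harrell's concordance index, and IPCW cumulative/dynamic
AUC integrated over 0-5 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit estimate: right-continuous step function over the
    distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass
class SurvivalFit:
    """Cox model output: per-covariate-level effects plus model-level
    discrimination (Harrell's C and iAUC over 0-5 years)."""

    effects: pd.DataFrame  # covariate, level, hazard_ratio, ci95_low, ci95_high, p_value
    c_index: float
    iauc_0_5y: float
    n: int
    n_events: int


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be equal-length 1-D arrays")
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0 (censored) or 1 (death)")
    return times, events


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    times, events = _check_times_events(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    n = times.size
    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = np.sum(t_sorted >= t)
        d[i] = np.sum((t_sorted == t) & (e_sorted == 1))
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(event_times=event_times, survival=surv, at_risk=at_risk, n_events=d)


def survival_at(curve: KMCurve, t: float, left: bool = False) -> float:
    """Evaluate S(t) (right-continuous); ``left=True`` gives S(t-)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    side = "left" if left else "right"
    i = np.searchsorted(curve.event_times, t, side=side)
    return 1.0 if i == 0 else float(curve.survival[i - 1])


def logrank(times, events, group_labels) -> tuple[float, float]:
    """k-group log-rank test; returns (chi2, p) with k-1 degrees of freedom."""
    times, events = _check_times_events(times, events)
    groups = np.asarray(group_labels)
    if groups.shape != times.shape:
        raise ValueError("group_labels must match times in length")
    levels, gidx = np.unique(groups, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dying = at_risk & (times == t) & (events == 1)
        d = dying.sum()
        d_g = np.bincount(gidx[dying], minlength=k).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            V += (d * (n - d) / (n - 1)) * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    cov = V[:-1, :-1]
    chi2 = float(diff @ np.linalg.pinv(cov) @ diff)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


def _dummy_code(
    data: pd.DataFrame,
    covariates: list[str],
    reference_levels: dict[str, object] | None,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Dummy-code categorical covariates against stated reference levels.

    Returns the design frame and (column, covariate, level) bookkeeping.
    """
    reference_levels = reference_levels or {}
    X = pd.DataFrame(index=data.index)
    mapping: list[tuple[str, str, str]] = []
    for cov in covariates:
        col = data[cov]
        if col.nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant")
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            X[cov] = col.astype(float)
            mapping.append((cov, cov, ""))
            continue
        levels = sorted(col.unique(), key=str)
        ref = reference_levels.get(cov, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in covariate {cov!r}")
        for lev in levels:
            if lev == ref:
                continue
            name = f"{cov}[{lev}]"
            X[name] = (col == lev).astype(float)
            mapping.append((name, cov, str(lev)))
    return X, mapping


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "os_years",
    event_col: str = "os_event",
    reference_levels: dict[str, object] | None = None,
    horizon: float = 5.0,
) -> SurvivalFit:
    """Proportional-hazards fit (partial likelihood, Efron ties).

    Categorical covariates are dummy-coded against ``reference_levels``
    (default: first level in sorted order).  HR = exp(coef) with Wald 95%
    CIs on the log scale.  Model-level discrimination is Harrell's C and
    the 0-``horizon`` iAUC of the linear predictor.
    """
    X, mapping = _dummy_code(data, covariates, reference_levels)
    for name in X.columns:
        if X[name].nunique() <= 1:
            raise ValueError(f"covariate column {name!r} is constant")
    n_events = int(data[event_col].sum())
    if n_events < X.shape[1]:
        raise ValueError(
            f"{n_events} events for {X.shape[1]} parameters; model not identifiable"
        )
    df = X.copy()
    df[duration_col] = data[duration_col].astype(float)
    df[event_col] = data[event_col].astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    rows = []
    for name, cov, level in mapping:
        s = summary.loc[name]
        rows.append(
            {
                "covariate": cov,
                "level": level,
                "hazard_ratio": float(s["exp(coef)"]),
                "ci95_low": float(s["exp(coef) lower 95%"]),
                "ci95_high": float(s["exp(coef) upper 95%"]),
                "p_value": float(s["p"]),
            }
        )
    effects = pd.DataFrame(rows)
    risk = cph.predict_log_partial_hazard(df).to_numpy()
    times = df[duration_col].to_numpy()
    events = df[event_col].to_numpy()
    c = c_index(risk, times, events)
    try:
        ia = iauc(risk, times, events, horizon=horizon)
    except ValueError:
        ia = float("nan")
    return SurvivalFit(
        effects=effects, c_index=c, iauc_0_5y=ia, n=len(df), n_events=n_events
    )


def univariate_selection(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "os_years",
    event_col: str = "os_event",
    reference_levels: dict[str, object] | None = None,
    alpha: float = 0.05,
) -> tuple[dict[str, SurvivalFit], list[str]]:
    """Fit each covariate alone; return all fits plus those with any level
    p < alpha (the multivariate entry rule)."""
    fits: dict[str, SurvivalFit] = {}
    selected: list[str] = []
    for cov in covariates:
        fit = cox_fit(
            data, [cov], duration_col, event_col, reference_levels
        )
        fits[cov] = fit
        if (fit.effects["p_value"] < alpha).any():
            selected.append(cov)
    return fits, selected


def c_index(marker_or_risk, times, events) -> float:
    """Harrell's concordance over comparable pairs; tied risks count 0.5.

    A pair is comparable when the earlier time is an event, or when the
    times tie with exactly one event (the event is the earlier subject).
    Tied event times are not comparable.
    """
    times, events = _check_times_events(times, events)
    risk = np.asarray(marker_or_risk, dtype=float)
    if risk.shape != times.shape:
        raise ValueError("risk scores must match times in length")
    concordant = 0.0
    n_pairs = 0
    for i in np.flatnonzero(events == 1):
        later = (times > times[i]) | ((times == times[i]) & (events == 0))
        later[i] = False
        m = int(later.sum())
        if m:
            concordant += np.sum(risk[i] > risk[later]) + 0.5 * np.sum(
                risk[i] == risk[later]
            )
            n_pairs += m
    if n_pairs == 0:
        raise ValueError("no comparable pairs for concordance")
    return concordant / n_pairs


def _ipcw_weights(times, events, eval_times) -> np.ndarray:
    """G(t-) from the KM estimate of the censoring distribution."""
    cens_curve = km_curve(times, 1 - events)
    return np.array([survival_at(cens_curve, t, left=True) for t in eval_times])


def cumulative_dynamic_auc(
    risk_scores, times, events, eval_times
) -> np.ndarray:
    """IPCW cumulative/dynamic AUC(t): cases are subjects with an event at
    or before t (weighted 1/G(T-)), controls those still at risk after t."""
    times, events = _check_times_events(times, events)
    risk = np.asarray(risk_scores, dtype=float)
    w_all = np.zeros_like(times)
    is_event = events == 1
    w_all[is_event] = 1.0 / _ipcw_weights(times, events, times[is_event])
    aucs = np.full(len(eval_times), np.nan)
    for j, t in enumerate(eval_times):
        cases = is_event & (times <= t)
        controls = times > t
        if not cases.any() or not controls.any():
            continue
        w = w_all[cases]
        r_case = risk[cases][:, None]
        r_ctrl = risk[controls][None, :]
        wins = (r_case > r_ctrl) + 0.5 * (r_case == r_ctrl)
        aucs[j] = float((w[:, None] * wins).sum() / (w.sum() * controls.sum()))
    return aucs


def iauc(
    risk_scores,
    times,
    events,
    horizon: float = 5.0,
    max_grid: int = 100,
) -> float:
    """Time-averaged cumulative/dynamic AUC over (0, horizon].

    AUC(t) is evaluated on the distinct event times before the horizon
    (thinned to at most ``max_grid`` quantile points) and integrated by the
    trapezoid rule, normalized by the grid span.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    times, events = _check_times_events(times, events)
    grid = np.unique(times[(events == 1) & (times <= horizon)])
    if grid.size == 0:
        raise ValueError("no events before horizon; iAUC undefined")
    if grid.size > max_grid:
        grid = np.unique(np.quantile(grid, np.linspace(0, 1, max_grid)))
    aucs = cumulative_dynamic_auc(risk_scores, times, events, grid)
    ok = ~np.isnan(aucs)
    grid, aucs = grid[ok], aucs[ok]
    if grid.size == 0:
        raise ValueError("no evaluable grid times for iAUC")
    if grid.size == 1:
        return float(aucs[0])
    return float(np.trapezoid(aucs, grid) / (grid[-1] - grid[0]))


def stratified_km(
    data: pd.DataFrame,
    stratum_col: str,
    stratum_value,
    group_col: str,
    duration_col: str = "os_years",
    event_col: str = "os_event",
) -> tuple[dict[object, KMCurve], float | None]:
    """KM curves per group within one stratum plus the stratum's log-rank p.

    Returns ({group: KMCurve}, p) — p is None (with a warning) when the
    stratum is empty or has a single group.
    """
    sub = data[data[stratum_col] == stratum_value]
    if sub.empty:
        log.warning("stratum %s=%r is empty; skipped", stratum_col, stratum_value)
        return {}, None
    curves = {
        g: km_curve(d[duration_col], d[event_col])
        for g, d in sub.groupby(group_col, observed=True)
    }
    if len(curves) < 2:
        log.warning(
            "stratum %s=%r has a single group; log-rank skipped",
            stratum_col, stratum_value,
        )
        return curves, None
    _, p = logrank(sub[duration_col], sub[event_col], sub[group_col])
    return curves, p
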