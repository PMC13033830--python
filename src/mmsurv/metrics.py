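"""Survival-metric suite and risk stratification.

Discrimination: Harrell's C-index (headline number) and cumulative/dynamic
time-dependent AUC with inverse-probability-of-censoring weights.
Calibration: Breslow-baseline risk-to-probability conversion, IPCW Brier
score and quantile-binned calibration tables.  Group comparison:
Kaplan-Meier curves, two-sided log-rank test (chi-square, 1 df), univariate
proportional-hazards hazard ratio (Newton iteration on the Breslow partial
likelihood, Wald CI).  Uncertainty: patient-level bootstrap percentile CIs.
Clinical utility: survival-adapted decision-curve analysis.

Cutoffs for risk stratification are always computed on training risks only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance
from sksurv.linear_model.coxph import BreslowEstimator
from sksurv.metrics import brier_score as _sks_brier
from sksurv.metrics import cumulative_dynamic_auc as _sks_cd_auc
from sksurv.util import Surv


def _arrays(risks, times, events):
    r = np.asarray(risks, dtype=np.float64).ravel()
    t = np.asarray(times, dtype=np.float64).ravel()
    e = np.asarray(events, dtype=int).ravel()
    if not (len(r) == len(t) == len(e)):
        raise ValueError("risks, times, events must have equal length")
    return r, t, e


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------


def concordance_index(risks, times, events) -> float:
    """Harrell's C: fraction of comparable pairs (earlier observed event vs
    longer survivor) ranked correctly by risk; risk ties count 1/2."""
    r, t, e = _arrays(risks, times, events)
    try:
        return float(_ll_concordance(t, -r, e))
    except ZeroDivisionError as err:
        raise ValueError("no comparable pairs") from err


def time_dependent_auc(
    risks, times, events, horizon: float, train_times=None, train_events=None
) -> float:
    """Cumulative/dynamic AUC at ``horizon``: cases are events by the horizon,
    controls are patients still at risk beyond it; censoring is corrected by
    IPCW from the Kaplan-Meier censoring distribution (estimated on the
    training outcomes when given, else on the evaluated outcomes)."""
    r, t, e = _arrays(risks, times, events)
    if horizon >= t.max():
        raise ValueError(f"horizon {horizon} beyond observed follow-up {t.max():.1f}")
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("need at least one case and one control at the horizon")
    if train_times is None:
        train_times, train_events = t, e
    surv_train = Surv.from_arrays(
        np.asarray(train_events, bool), np.asarray(train_times, float)
    )
    surv_test = Surv.from_arrays(e.astype(bool), t)
    auc, _ = _sks_cd_auc(surv_train, surv_test, r, [horizon])
    return float(auc[0])


# ---------------------------------------------------------------------------
# probability conversion, Brier, calibration
# ---------------------------------------------------------------------------


def breslow_survival_probability(
    train_risks, train_times, train_events, risks, horizons
) -> np.ndarray:
    """S_i(t) = S0(t)^exp(r_i) with the Breslow baseline fitted on training
    data only (no test leakage).  Returns len(risks) x len(horizons)."""
    tr_r, tr_t, tr_e = _arrays(train_risks, train_times, train_events)
    est = BreslowEstimator().fit(tr_r, tr_e.astype(bool), tr_t)
    s0 = np.atleast_1d(
        np.asarray([est.baseline_survival_(h) for h in np.asarray(horizons, float).ravel()])
    ).astype(float)
    r = np.asarray(risks, dtype=np.float64).ravel()
    return s0[None, :] ** np.exp(r)[:, None]


def ipcw_brier(pred_event_prob, times, events, horizon, train_times=None, train_events=None) -> float:
    """IPCW Brier score at one horizon for predicted event probabilities."""
    p = np.asarray(pred_event_prob, dtype=np.float64).ravel()
    _, t, e = _arrays(p, times, events)
    if horizon >= t.max():
        raise ValueError(f"horizon {horizon} beyond observed follow-up")
    if train_times is None:
        train_times, train_events = t, e
    surv_train = Surv.from_arrays(
        np.asarray(train_events, bool), np.asarray(train_times, float)
    )
    surv_test = Surv.from_arrays(e.astype(bool), t)
    _, score = _sks_brier(surv_train, surv_test, 1.0 - p, horizon)
    return float(score[0])


def brier_and_calibration(
    train_risks,
    train_times,
    train_events,
    test_risks,
    test_times,
    test_events,
    horizons,
    n_bins: int = 4,
) -> tuple[dict[float, float], pd.DataFrame]:
    """Per-horizon IPCW Brier scores and quantile-binned calibration table
    (mean predicted event probability vs Kaplan-Meier observed)."""
    horizons = list(horizons)
    surv = breslow_survival_probability(
        train_risks, train_times, train_events, test_risks, horizons
    )
    r, t, e = _arrays(test_risks, test_times, test_events)
    briers: dict[float, float] = {}
    rows = []
    for j, h in enumerate(horizons):
        p_event = 1.0 - surv[:, j]
        briers[h] = ipcw_brier(p_event, t, e, h, train_times, train_events)
        qs = np.quantile(p_event, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.searchsorted(qs, p_event, side="right")
        for b in range(n_bins):
            sel = bins == b
            if sel.sum() == 0:
                continue
            km = kaplan_meier(t[sel], e[sel])
            rows.append(
                {
                    "horizon": h,
                    "bin": b,
                    "n": int(sel.sum()),
                    "mean_predicted": float(p_event[sel].mean()),
                    "observed": float(1.0 - km.survival_at(h)),
                }
            )
    return briers, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / hazard ratio
# ---------------------------------------------------------------------------


class KMEstimate:
    """Product-limit survival curve (right-continuous step function)."""

    def __init__(self, times, events):
        _, t, e = _arrays(np.zeros(len(times)), times, events)
        self._kmf = KaplanMeierFitter().fit(t, e)
        self._max_t = t.max()

    @property
    def table(self) -> pd.DataFrame:
        df = self._kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        return df

    def survival_at(self, t: float) -> float:
        return float(self._kmf.predict(min(t, self._max_t)))

    def __call__(self, t):
        return np.array([self.survival_at(x) for x in np.atleast_1d(t)])


def kaplan_meier(times, events) -> KMEstimate:
    if len(np.atleast_1d(times)) == 0:
        raise ValueError("empty outcome list")
    return KMEstimate(times, events)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sided log-rank test; returns (chi-square statistic, p-value)."""
    _, ta, ea = _arrays(np.zeros(len(times_a)), times_a, events_a)
    _, tb, eb = _arrays(np.zeros(len(times_b)), times_b, events_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi2, p = float(res.test_statistic), float(res.p_value)
    if not np.isfinite(chi2):
        raise ValueError("zero-variance log-rank statistic")
    return chi2, p


@dataclass
class HazardRatioResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    log_hr: float
    se: float
    monotone: bool = False  # monotone likelihood (e.g. no events in a group)


def cox_hazard_ratio(group_labels, times, events, max_iter: int = 50) -> HazardRatioResult:
    """Univariate proportional-hazards HR for a binary group label, fitted by
    Newton iteration on the Breslow partial likelihood; Wald 95% CI."""
    x = np.asarray(group_labels)
    if x.dtype.kind in "UOS":
        levels = sorted(set(x.tolist()))
        if len(levels) != 2:
            raise ValueError("group_labels must be binary")
        x = (x == levels[1]).astype(float)
    x = x.astype(float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("group_labels must be binary (0/1)")
    _, t, e = _arrays(x, times, events)
    if e.sum() == 0:
        raise ValueError("no events")
    monotone = e[x == 1].sum() == 0 or e[x == 0].sum() == 0

    order = np.argsort(-t, kind="stable")  # descending time
    xs, ts, es = x[order], t[order], e[order]

    def score_info(beta: float) -> tuple[float, float, float]:
        w = np.exp(beta * xs)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xs)
        # risk set of an event at time ti = all with t >= ti; with descending
        # sort that is the prefix up to the *last* index sharing time ti
        last_tie = np.searchsorted(-ts, -ts, side="right") - 1
        ev = np.flatnonzero(es == 1)
        S0 = s0[last_tie[ev]]
        S1 = s1[last_tie[ev]]
        mu = S1 / S0
        u = float(np.sum(xs[ev] - mu))
        info = float(np.sum(mu * (1 - mu)))  # x binary: S2 == S1
        ll = float(np.sum(beta * xs[ev] - np.log(S0)))
        return u, info, ll

    beta = 0.0
    for _ in range(max_iter):
        u, info, _ = score_info(beta)
        if info < 1e-12 or abs(beta) > 20:
            monotone = True
            break
        step = u / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < 1e-12:
            break
    u, info, _ = score_info(beta)
    if monotone or info < 1e-12:
        return HazardRatioResult(np.exp(beta), 0.0, np.inf, beta, np.inf, True)
    se = 1.0 / np.sqrt(info)
    z = 1.959963984540054
    return HazardRatioResult(
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
        float(beta),
        float(se),
        False,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    metric_fn,
    risks,
    times,
    events,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraw_factor: int = 10,
) -> tuple[float, float, float]:
    """Patient-level bootstrap: percentile (alpha/2, 1-alpha/2) CI and the
    coefficient of variation of the bootstrap distribution.  Resamples on
    which the metric fails (e.g. no comparable pairs) are redrawn."""
    r, t, e = _arrays(risks, times, events)
    rng = np.random.default_rng(seed)
    n = len(r)
    values = []
    attempts = 0
    while len(values) < n_boot:
        if attempts >= max_redraw_factor * n_boot:
            raise ValueError("metric failed on (nearly) all bootstrap resamples")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(metric_fn(r[idx], t[idx], e[idx])))
        except (ValueError, ZeroDivisionError):
            continue
    values = np.array(values)
    if np.all(values == values[0]):  # constant metric: degenerate distribution
        return float(values[0]), float(values[0]), 0.0
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    mean = values.mean()
    sd = values.std(ddof=1)
    cv = 0.0 if sd == 0 else float(sd / abs(mean))
    return float(lo), float(hi), cv


# ---------------------------------------------------------------------------
# decision curves
# ---------------------------------------------------------------------------


def decision_curve(
    pred_event_probs, times, events, horizon: float, thresholds
) -> pd.DataFrame:
    """Survival-adapted net benefit at a horizon.

    Among patients called positive at threshold p (predicted event
    probability >= p), the event probability by the horizon is estimated by
    Kaplan-Meier:

        NB(p) = P(pos) * [ (1 - S_pos(t)) - S_pos(t) * p / (1 - p) ]

    With no censoring this reduces to TP/n - FP/n * p/(1-p).  Also emits the
    treat-all and treat-none reference curves.
    """
    p_hat = np.asarray(pred_event_probs, dtype=np.float64).ravel()
    _, t, e = _arrays(p_hat, times, events)
    thresholds = np.asarray(thresholds, dtype=np.float64).ravel()
    if np.any(thresholds >= 1) or np.any(thresholds <= 0):
        raise ValueError("thresholds must be in (0, 1)")
    km_all = kaplan_meier(t, e)
    s_all = km_all.survival_at(horizon)
    rows = []
    for p in thresholds:
        odds = p / (1 - p)
        pos = p_hat >= p
        if pos.sum() == 0:
            nb = 0.0
        else:
            s_pos = kaplan_meier(t[pos], e[pos]).survival_at(horizon)
            nb = (pos.mean()) * ((1 - s_pos) - s_pos * odds)
        rows.append(
            {
                "threshold": p,
                "net_benefit": nb,
                "treat_all": (1 - s_all) - s_all * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@dataclass
class RiskStratification:
    cutoffs: np.ndarray  # computed on training risks only
    group_labels: list[str]  # per test patient, ordered low -> high
    quantiles: tuple[float, ...]


_NAMED_QUANTILES = {
    "median": (0.5,),
    "tertiles": (1 / 3, 2 / 3),
    "quartiles": (0.25, 0.5, 0.75),
}


def stratify_by_quantile(train_risks, test_risks, quantile_spec="median") -> RiskStratification:
    """Assign test patients to ordered risk groups by training-set quantile
    cutoffs (median by default; any percentile, tertiles, quartiles)."""
    tr = np.asarray(train_risks, dtype=np.float64).ravel()
    te = np.asarray(test_risks, dtype=np.float64).ravel()
    if tr.size == 0:
        raise ValueError("training risks are empty")
    if np.ptp(tr) == 0:
        raise ValueError("degenerate training risks (all equal): no cutoff exists")
    if isinstance(quantile_spec, str):
        qs = _NAMED_QUANTILES.get(quantile_spec)
        if qs is None:
            raise ValueError(f"unknown quantile spec: {quantile_spec}")
    elif np.isscalar(quantile_spec):
        qs = (float(quantile_spec),)
    else:
        qs = tuple(float(q) for q in quantile_spec)
    if not all(0 < q < 1 for q in qs):
        raise ValueError("quantiles must be in (0, 1)")
    cutoffs = np.quantile(tr, qs)
    idx = np.searchsorted(cutoffs, te, side="right")
    if len(qs) == 1:
        names = ["low", "high"]
    else:
        names = [f"q{i + 1}" for i in range(len(qs) + 1)]
    return RiskStratification(
        cutoffs=cutoffs, group_labels=[names[i] for i in idx], quantiles=qs
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    c_index: float
    td_auc: dict[float, float]
    brier: dict[float, float]
    calibration: pd.DataFrame
    km_tables: dict[str, pd.DataFrame]
    logrank_p: float
    logrank_chi2: float
    hazard_ratio: HazardRatioResult
    bootstrap_c_index: tuple[float, float, float]  # lower, upper, cv
    dca: pd.DataFrame
    stratification: RiskStratification
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        hr = self.hazard_ratio
        return {
            "c_index": self.c_index,
            "td_auc": {str(k): v for k, v in self.td_auc.items()},
            "brier": {str(k): v for k, v in self.brier.items()},
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "hazard_ratio": hr.hazard_ratio,
            "hazard_ratio_ci": [hr.ci_lower, hr.ci_upper],
            "c_index_ci": list(self.bootstrap_c_index[:2]),
            "c_index_bootstrap_cv": self.bootstrap_c_index[2],
            "cutoffs": self.stratification.cutoffs.tolist(),
            **self.extras,
        }


def evaluate_risk_scores(
    train_risks,
    train_times,
    train_events,
    test_risks,
    test_times,
    test_events,
    horizons=(36.0, 60.0, 84.0),
    n_boot: int = 200,
    seed: int = 0,
    thresholds=None,
) -> EvaluationReport:
    """Full evaluation of trained risk scores on a held-out set.

    Default horizons are the 3/5/7-year grid in months.  Cutoff for the
    high/low split is the training-risk median.
    """
    te_r, te_t, te_e = _arrays(test_risks, test_times, test_events)
    horizons = [h for h in horizons if h < te_t.max()]
    if not horizons:
        raise ValueError("no requested horizon lies within the observed follow-up")
    c = concordance_index(te_r, te_t, te_e)
    td = {
        h: time_dependent_auc(te_r, te_t, te_e, h, train_times, train_events)
        for h in horizons
    }
    briers, calib = brier_and_calibration(
        train_risks, train_times, train_events, te_r, te_t, te_e, horizons
    )
    strat = stratify_by_quantile(train_risks, te_r, "median")
    labels = np.array(strat.group_labels)
    hi, lo = labels == "high", labels == "low"
    km_tables = {
        "high": kaplan_meier(te_t[hi], te_e[hi]).table if hi.any() else pd.DataFrame(),
        "low": kaplan_meier(te_t[lo], te_e[lo]).table if lo.any() else pd.DataFrame(),
    }
    if hi.any() and lo.any() and te_e.sum() > 0:
        chi2, p = logrank_test(te_t[hi], te_e[hi], te_t[lo], te_e[lo])
        hr = cox_hazard_ratio((labels == "high").astype(int), te_t, te_e)
    else:
        chi2, p = np.nan, np.nan
        hr = HazardRatioResult(np.nan, np.nan, np.nan, np.nan, np.nan, True)
    boot = bootstrap_ci(concordance_index, te_r, te_t, te_e, n_boot=n_boot, seed=seed)
    surv = breslow_survival_probability(
        train_risks, train_times, train_events, te_r, [horizons[-1]]
    )
    thr = np.linspace(0.05, 0.6, 12) if thresholds is None else thresholds
    dca = decision_curve(1.0 - surv[:, 0], te_t, te_e, horizons[-1], thr)
    return EvaluationReport(
        c_index=c,
        td_auc=td,
        brier=briers,
        calibration=calib,
        km_tables=km_tables,
        logrank_p=p,
        logrank_chi2=chi2,
        hazard_ratio=hr,
        bootstrap_c_index=boot,
        dca=dca,
        stratification=strat,
    )
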