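"""Survival machinery and cohort stratification.

Kaplan–Meier estimation, the two-group log-rank test and Cox
proportional-hazards fits are delegated to :mod:`lifelines`; this module adds
the stratification logic around them: the maximally selected log-rank cutoff
("optimal prognostic cutoff"), top-fraction and median splits, binary
relapse-within-horizon labelling, and the ROC/Youden cutoff.

A survival table is a :class:`pandas.DataFrame` indexed by sample id with at
least ``rfs_months`` (relapse-free-survival time, months, > 0) and ``event``
(1 = relapse) columns; any further columns are treated as clinical covariates
for multivariate adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "StratumLabels",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "RelapseLabel",
    "validate_survival",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "optimal_cox_cutoff",
    "top_fraction_split",
    "median_split",
    "relapse_labels",
    "youden_cutoff",
]

REQUIRED_COLUMNS = ("rfs_months", "event")

#: Clinical covariates of the discovery-cohort multivariate model.
DISCOVERY_COVARIATES = (
    "age",
    "sex",
    "pt_stage",
    "tumour_location",
    "differentiation_grade",
    "mucinous",
    "lymphovascular_invasion",
    "lymph_node_count",
)

#: Covariates of the validation-cohort multivariate model.
VALIDATION_COVARIATES = ("age", "sex", "tnm_stage", "tumour_location")


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in surv.columns:
            raise ValueError(f"survival table lacks mandatory column {col!r}")
    if surv.index.has_duplicates:
        raise ValueError("duplicate sample ids in survival table")
    t = surv["rfs_months"].to_numpy(dtype=float)
    if (t <= 0).any():
        bad = surv.index[t <= 0].tolist()
        raise ValueError(f"non-positive survival times for samples {bad}")
    ev = surv["event"].to_numpy()
    if not np.isin(ev, [0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return surv


@dataclass
class StratumLabels:
    """High/Low assignment of samples, plus the cutoff that produced it."""

    labels: pd.Series  # values in {"High", "Low"}
    cutoff: float
    method: str  # optimal_cox | top_fraction | median | youden
    score_name: str = ""
    statistic: float | None = None  # selection statistic where applicable

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"High", "Low"}
        if bad:
            raise ValueError(f"labels must be High/Low, found {bad}")

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "High"]

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "Low"]

    def counts(self) -> dict[str, int]:
        return {"High": int((self.labels == "High").sum()), "Low": int((self.labels == "Low").sum())}


@dataclass
class KMCurve:
    """Product-limit survival curve for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival, "at_risk": self.at_risk})

    def at(self, t: float) -> float:
        """S(t): step-function evaluation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class CoxFit:
    """Per-term hazard ratios with Wald CIs and model-level diagnostics."""

    summary: pd.DataFrame  # index: term; columns hr, ci_low, ci_high, p, coef, se
    lr_p: float
    n: int
    events: int
    ties: str
    ph_p: pd.Series | None = None  # per-term proportional-hazards diagnostic

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


@dataclass
class RelapseLabel:
    """Binary relapse-within-horizon contrast (events after horizon excluded)."""

    labels: pd.Series  # 1 = relapse within horizon, 0 = never relapsed
    horizon: float
    excluded: tuple[str, ...] = field(default_factory=tuple)
    low_followup: tuple[str, ...] = field(default_factory=tuple)

    @property
    def relapse(self) -> pd.Index:
        return self.labels.index[self.labels == 1]

    @property
    def non_relapse(self) -> pd.Index:
        return self.labels.index[self.labels == 0]


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


def km_estimate(surv: pd.DataFrame, labels: StratumLabels) -> dict[str, KMCurve]:
    """Per-group Kaplan–Meier curves."""
    validate_survival(surv)
    curves: dict[str, KMCurve] = {}
    for group in ("High", "Low"):
        idx = labels.labels.index[labels.labels == group]
        idx = idx.intersection(surv.index)
        if len(idx) == 0:
            raise ValueError(f"group {group!r} is empty")
        sub = surv.loc[idx]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["rfs_months"], sub["event"])
        table = kmf.event_table
        times = table.index.to_numpy(dtype=float)
        surv_prob = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        curves[group] = KMCurve(
            times=times,
            survival=surv_prob,
            at_risk=table["at_risk"].to_numpy(dtype=float),
            censor_times=sub.loc[sub["event"] == 0, "rfs_months"].to_numpy(dtype=float),
            group=group,
        )
    return curves


def logrank_test(surv: pd.DataFrame, labels: StratumLabels) -> LogRankResult:
    """Two-group log-rank test (observed-minus-expected chi-square)."""
    validate_survival(surv)
    hi = labels.high.intersection(surv.index)
    lo = labels.low.intersection(surv.index)
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both groups must be non-empty")
    if surv.loc[hi.union(lo), "event"].sum() < 1:
        raise ValueError("log-rank needs at least one event")
    res = _ll_logrank(
        surv.loc[hi, "rfs_months"],
        surv.loc[lo, "rfs_months"],
        event_observed_A=surv.loc[hi, "event"],
        event_observed_B=surv.loc[lo, "event"],
    )
    return LogRankResult(statistic=float(res.test_statistic), df=1, p=float(res.p_value))


def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_group: np.ndarray) -> float:
    """Fast two-group log-rank chi-square (numpy; used for cutoff scanning)."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], in_group[order].astype(float)
    n = len(t)
    # at each distinct event time: d = events, n_at_risk, per-group counts
    uniq, first = np.unique(t, return_index=True)
    # cumulative from the end: number at risk just before each unique time
    at_risk_total = n - first
    g_cum = np.concatenate([[0.0], np.cumsum(g)])
    at_risk_g = g.sum() - g_cum[first]
    ev_total = np.add.reduceat(e, first)
    ev_g = np.add.reduceat(e * g, first)
    mask = ev_total > 0
    d, n1, ntot = ev_total[mask], at_risk_g[mask], at_risk_total[mask].astype(float)
    exp_g = d * n1 / ntot
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / ntot) * (1 - n1 / ntot) * (ntot - d) / np.maximum(ntot - 1, 1)
    o_minus_e = float((ev_g[mask] - exp_g).sum())
    v = float(var.sum())
    return 0.0 if v == 0 else o_minus_e**2 / v


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _breslow_neg_loglik(beta: np.ndarray, t: np.ndarray, e: np.ndarray, X: np.ndarray) -> float:
    eta = X @ beta
    order = np.argsort(-t, kind="stable")  # descending time
    eta_o, t_o, e_o = eta[order], t[order], e[order]
    log_risk = np.logaddexp.accumulate(eta_o)  # log sum exp over risk set
    # group tied times: risk set at time t includes all with time >= t
    ll = 0.0
    uniq = np.unique(t_o[e_o == 1])
    for tt in uniq:
        in_risk = np.searchsorted(-t_o, -tt, side="right") - 1  # last idx with time >= tt
        deaths = (t_o == tt) & (e_o == 1)
        d = deaths.sum()
        ll += eta_o[deaths].sum() - d * log_risk[in_risk]
    return -ll


def cox_partial_loglik(
    times: np.ndarray, events: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> float:
    """Breslow log partial likelihood at ``beta`` (exposed for diagnostics)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    return -_breslow_neg_loglik(beta, np.asarray(times, float), np.asarray(events, int), X)


def _fit_breslow(t: np.ndarray, e: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    p = X.shape[1]
    res = optimize.minimize(
        _breslow_neg_loglik, np.zeros(p), args=(t, e, X), method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(f"Breslow Cox fit did not converge: {res.message}")
    # numeric Hessian of the negative log-likelihood for Wald SEs
    eps = 1e-5
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            bpp = res.x.copy(); bpp[i] += eps; bpp[j] += eps
            bpm = res.x.copy(); bpm[i] += eps; bpm[j] -= eps
            bmp = res.x.copy(); bmp[i] -= eps; bmp[j] += eps
            bmm = res.x.copy(); bmm[i] -= eps; bmm[j] -= eps
            H[i, j] = H[j, i] = (
                _breslow_neg_loglik(bpp, t, e, X)
                - _breslow_neg_loglik(bpm, t, e, X)
                - _breslow_neg_loglik(bmp, t, e, X)
                + _breslow_neg_loglik(bmm, t, e, X)
            ) / (4 * eps * eps)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    ll0 = -_breslow_neg_loglik(np.zeros(p), t, e, X)
    lr = 2 * (-res.fun - ll0)
    lr_p = float(stats.chi2.sf(max(lr, 0.0), p))
    return res.x, se, lr_p


def cox_fit(
    surv: pd.DataFrame,
    terms: pd.DataFrame | pd.Series,
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit of ``terms`` against RFS.

    ``terms`` must be sample-aligned numeric/binary columns.  Efron ties
    handling (the default of the R ``survival`` package) is delegated to
    lifelines; Breslow uses an in-house partial-likelihood maximiser.  The
    proportional-hazards diagnostic is the scaled-Schoenfeld-residual test
    against Kaplan–Meier-transformed time and always uses the Efron fit.
    """
    validate_survival(surv)
    if isinstance(terms, pd.Series):
        terms = terms.to_frame()
    terms = terms.reindex(surv.index)
    if terms.isna().any().any():
        raise ValueError("terms are not aligned with the survival table (missing values)")
    for col in terms.columns:
        if terms[col].nunique() < 2:
            raise ValueError(f"term {col!r} is constant across samples")
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")

    df = pd.concat([surv[["rfs_months", "event"]], terms.astype(float)], axis=1)
    n, events = len(df), int(df["event"].sum())

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="rfs_months", event_col="event")

    if ties == "efron":
        s = cph.summary
        summary = pd.DataFrame(
            {
                "coef": s["coef"],
                "se": s["se(coef)"],
                "hr": s["exp(coef)"],
                "ci_low": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
                "ci_high": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
                "p": s["p"],
            }
        )
        lr_p = float(cph.log_likelihood_ratio_test().p_value)
    else:
        t = df["rfs_months"].to_numpy(float)
        e = df["event"].to_numpy(int)
        X = terms.astype(float).to_numpy()
        beta, se, lr_p = _fit_breslow(t, e, X)
        z = beta / se
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - 1.959963984540054 * se),
                "ci_high": np.exp(beta + 1.959963984540054 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=terms.columns,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = proportional_hazard_test(cph, df, time_transform="km")
        ph_p = ph.summary["p"]
        ph_p.index = ph_p.index.get_level_values(0)
    except Exception:  # diagnostic only; never fail the fit for it
        ph_p = None

    return CoxFit(summary=summary, lr_p=lr_p, n=n, events=events, ties=ties, ph_p=ph_p)


# ---------------------------------------------------------------------------
# Stratification


def optimal_cox_cutoff(score, surv: pd.DataFrame, min_tail_frac: float = 0.10) -> StratumLabels:
    """Maximally selected log-rank cutoff on a prognostic score.

    Every observed score value that leaves at least ``min_tail_frac`` of the
    samples on each side is evaluated as a ``High = score >= cutoff`` split;
    the cutoff maximising the log-rank chi-square wins, ties broken toward
    the cutoff nearest the score median.  The selected statistic is reported
    unadjusted — it is selection-inflated and must not be read as a p-value.
    """
    s = score.scores if hasattr(score, "scores") else score
    name = getattr(score, "name", "") or (s.name or "score")
    validate_survival(surv)
    s = s.reindex(surv.index)
    if s.isna().any():
        raise ValueError("score not defined for all survival-table samples")
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events to select a cutoff")
    vals = s.to_numpy(dtype=float)
    n = len(vals)
    min_tail = max(int(np.ceil(min_tail_frac * n)), 1)
    candidates = [
        c for c in np.unique(vals)
        if min_tail <= int((vals >= c).sum()) <= n - min_tail
    ]
    if not candidates:
        raise ValueError("no admissible cutoffs (scores too concentrated)")
    times = surv["rfs_months"].to_numpy(float)
    events = surv["event"].to_numpy(int)
    chi2s = np.array([_logrank_chi2(times, events, vals >= c) for c in candidates])
    best = chi2s.max()
    med = float(np.median(vals))
    tied = [c for c, x in zip(candidates, chi2s) if x == best]
    cutoff = min(tied, key=lambda c: (abs(c - med), c))
    warnings.warn(
        "optimal_cox_cutoff statistic is selection-inflated; do not interpret as a nominal p-value",
        stacklevel=2,
    )
    labels = pd.Series(np.where(vals >= cutoff, "High", "Low"), index=s.index)
    return StratumLabels(labels=labels, cutoff=float(cutoff), method="optimal_cox",
                         score_name=name, statistic=float(best))


def top_fraction_split(score, fraction: float) -> StratumLabels:
    """Label the top ``ceil(fraction * n)`` scores High (exact count)."""
    s = score.scores if hasattr(score, "scores") else score
    name = getattr(score, "name", "") or (s.name or "score")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(s)
    k = int(np.ceil(fraction * n))
    order = sorted(s.index, key=lambda i: (-s[i], i))
    high = set(order[:k])
    boundary = s[order[k - 1]]
    if k < n and s[order[k]] == boundary:
        warnings.warn("ties at the top-fraction boundary resolved by sample-id order", stacklevel=2)
    labels = pd.Series(["High" if i in high else "Low" for i in s.index], index=s.index)
    return StratumLabels(labels=labels, cutoff=float(boundary), method="top_fraction", score_name=name)


def median_split(score) -> StratumLabels:
    """High = score >= median.  Errors on degenerate (one-sided) splits."""
    s = score.scores if hasattr(score, "scores") else score
    name = getattr(score, "name", "") or (s.name or "score")
    if len(s) < 4:
        raise ValueError("median split needs at least 4 samples")
    vals = s.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("zero score variance; cannot median-split")
    med = float(np.median(vals))
    high = vals >= med
    if high.all() or not high.any():
        raise ValueError("degenerate median split: ties put every sample on one side")
    labels = pd.Series(np.where(high, "High", "Low"), index=s.index)
    return StratumLabels(labels=labels, cutoff=med, method="median", score_name=name)


def relapse_labels(surv: pd.DataFrame, horizon_months: float = 60.0) -> RelapseLabel:
    """Binary relapse-within-horizon contrast.

    Relapse = event at or before the horizon.  Non-relapse = no event at any
    follow-up length ("never relapsed"); samples censored before the horizon
    are kept but flagged as low-follow-up.  Events after the horizon are
    excluded and listed.
    """
    validate_survival(surv)
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    t = surv["rfs_months"]
    e = surv["event"]
    relapse = (e == 1) & (t <= horizon_months)
    late_event = (e == 1) & (t > horizon_months)
    never = e == 0
    labels = pd.Series(
        np.where(relapse, 1, 0)[~late_event.to_numpy()],
        index=surv.index[~late_event],
    )
    low_fu = surv.index[never & (t < horizon_months)]
    return RelapseLabel(
        labels=labels,
        horizon=float(horizon_months),
        excluded=tuple(surv.index[late_event]),
        low_followup=tuple(low_fu),
    )


def youden_cutoff(score, rlabels: RelapseLabel) -> tuple[float, float]:
    """ROC-optimal (Youden J) cutoff and AUROC for a binary relapse contrast.

    Returns ``(cutoff, auroc)`` where the cutoff maximises sensitivity +
    specificity - 1 for the rule ``score >= cutoff`` predicting the positive
    class, placed midway between adjacent observed scores; ties in J resolved
    toward the cutoff nearest the score median.
    """
    from sklearn.metrics import roc_auc_score

    s = score.scores if hasattr(score, "scores") else score
    s = s.reindex(rlabels.labels.index)
    if s.isna().any():
        raise ValueError("score not defined for all labelled samples")
    y = rlabels.labels.to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    vals = s.to_numpy(dtype=float)
    auroc = float(roc_auc_score(y, vals))
    uniq = np.unique(vals)
    mids = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    js = np.array([
        (vals[y == 1] >= c).sum() / n_pos - (vals[y == 0] >= c).sum() / n_neg for c in mids
    ])
    if auroc < 0.5:  # protective score: the informative rule is score < cutoff
        js = -js
    best = js.max()
    med = float(np.median(vals))
    cutoff = min(mids[js == best], key=lambda c: (abs(c - med), c))
    return float(cutoff), auroc
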