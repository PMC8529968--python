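"""Prognostic modeling: LASSO-Cox selection, Cox fits, risk scores,
optimal cutpoint stratification, KM curves, log-rank, C-index, AUC and
rank-sum group comparisons.

The Cox proportional-hazards fit uses Efron tie handling (lifelines); the
L1 path comes from the coordinate-descent solver in scikit-survival, with
cross-validated partial-likelihood deviance (Verweij & van Houwelingen)
computed here to pick lambda_min.  The risk score is the linear predictor
sum(beta_i * x_i) of the refitted multivariate Cox model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "SurvivalData",
    "CoxFit",
    "RiskModel",
    "LassoCoxResult",
    "CutpointResult",
    "fit_cox",
    "lasso_cox",
    "build_risk_model",
    "risk_score",
    "optimal_cutpoint",
    "km_estimate",
    "log_rank",
    "concordance_index",
    "auc",
    "group_difference_test",
]


@dataclass
class SurvivalData:
    """Aligned survival outcomes and per-sample features."""

    time: pd.Series
    event: pd.Series
    features: pd.DataFrame  # samples x features

    @classmethod
    def from_frames(cls, survival: pd.DataFrame, features: pd.DataFrame) -> "SurvivalData":
        """Align a (sample, time, event) table with a samples x features matrix."""
        surv = survival.set_index("sample") if "sample" in survival.columns else survival
        shared = [s for s in surv.index if s in features.index]
        if not shared:
            raise ValueError("no shared samples between survival table and features")
        surv = surv.loc[shared]
        return cls(
            time=surv["time"].astype(float),
            event=surv["event"].astype(int),
            features=features.loc[shared].astype(float),
        )

    def validate(self) -> None:
        if (self.time.to_numpy() <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if self.features.isna().to_numpy().any():
            raise ValueError("features contain missing values")


@dataclass
class CoxFit:
    beta: pd.Series
    se: pd.Series
    hazard_ratio: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    log_likelihood: float
    concordance: float
    ties: str = "efron"


@dataclass
class RiskModel:
    features: list[str]
    beta: pd.Series
    metadata: dict = field(default_factory=dict)


@dataclass
class LassoCoxResult:
    alphas: np.ndarray
    path: pd.DataFrame            # features x alphas, original-scale coefficients
    cv_deviance: np.ndarray       # mean CV deviance per alpha
    alpha_min: float
    selected: list[str]
    coef_min: pd.Series


@dataclass
class CutpointResult:
    threshold: float
    statistic: float              # max standardized log-rank statistic
    n_low: int
    n_high: int


def _check_collinear(X: pd.DataFrame) -> None:
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    sd = Xc.std(axis=0)
    if (sd == 0).any():
        const = list(X.columns[sd == 0])
        raise ValueError(f"constant features: {const}")
    if X.shape[1] > 1:
        corr = np.corrcoef(Xc, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        bad = np.flatnonzero(np.abs(corr[iu]) > 1 - 1e-10)
        if bad.size:
            pairs = [(X.columns[iu[0][b]], X.columns[iu[1][b]]) for b in bad]
            raise ValueError(f"collinear features: {pairs}")


def fit_cox(data: SurvivalData) -> CoxFit:
    """Multivariate Cox proportional-hazards fit with Efron tie handling."""
    data.validate()
    if int(data.event.sum()) < 10:
        raise ValueError("fewer than 10 events: Cox fit is unreliable")
    _check_collinear(data.features)
    df = data.features.copy()
    df["time"] = data.time.to_numpy()
    df["event"] = data.event.to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-12})
    except ConvergenceError as err:
        raise ValueError(
            "Cox fit failed to converge (possible perfect separation); "
            "consider penalization"
        ) from err
    summ = cph.summary
    return CoxFit(
        beta=summ["coef"].rename(None),
        se=summ["se(coef)"].rename(None),
        hazard_ratio=summ["exp(coef)"].rename(None),
        ci_lower=summ["exp(coef) lower 95%"].rename(None),
        ci_upper=summ["exp(coef) upper 95%"].rename(None),
        p=summ["p"].rename(None),
        log_likelihood=float(cph.log_likelihood_),
        concordance=float(cph.concordance_index_),
    )


def _breslow_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood (used only for CV deviance)."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o = eta[order]
    log_risk = np.logaddexp.accumulate(eta_o)  # log sum exp over risk set
    ll = 0.0
    ev = event[order].astype(bool)
    ll = float(np.sum(eta_o[ev] - log_risk[ev]))
    return ll


def lasso_cox(
    data: SurvivalData,
    alphas: np.ndarray | list[float] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> LassoCoxResult:
    """L1-penalized Cox path with cross-validated deviance; selects lambda_min.

    Features are standardized internally for penalization; coefficients are
    reported on the original scale.  CV deviance per fold is the
    Verweij–van Houwelingen partial-likelihood difference
    ``-2 * (ll_full(beta_train) - ll_train(beta_train))``.  A grid value of
    exactly 0 is solved by the unpenalized Newton fit (the lambda -> 0 limit).
    """
    data.validate()
    _check_collinear(data.features)
    X = data.features.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    Xs = (X - mu) / sd
    y = Surv.from_arrays(event=data.event.to_numpy().astype(bool), time=data.time.to_numpy())
    time = data.time.to_numpy()
    event = data.event.to_numpy()
    names = list(data.features.columns)

    if alphas is None:
        probe = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=50, fit_baseline_model=False)
        probe.fit(Xs, y)
        grid = np.asarray(probe.alphas_, dtype=float)
    else:
        grid = np.asarray(sorted(alphas, reverse=True), dtype=float)

    def coefs_for(Xmat, t, e, grid):
        """Standardized-scale coefficient matrix (features x alphas)."""
        ymat = Surv.from_arrays(event=e.astype(bool), time=t)
        pos = grid[grid > 0]
        out = np.zeros((Xmat.shape[1], len(grid)))
        if len(pos):
            model = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=pos, fit_baseline_model=False, normalize=False
            )
            model.fit(Xmat, ymat)
            fitted = list(model.alphas_)
            for j, a in enumerate(grid):
                if a <= 0:
                    continue
                k = int(np.argmin(np.abs(np.asarray(fitted) - a)))
                out[:, j] = model.coef_[:, k]
        for j, a in enumerate(grid):
            if a == 0:
                sub = SurvivalData(
                    time=pd.Series(t), event=pd.Series(e),
                    features=pd.DataFrame(Xmat, columns=names),
                )
                out[:, j] = fit_cox(sub).beta.to_numpy()
        return out

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, len(grid)))
    for fi, (tr, _te) in enumerate(kf.split(Xs)):
        coefs = coefs_for(Xs[tr], time[tr], event[tr], grid)
        for j in range(len(grid)):
            b = coefs[:, j]
            ll_full = _breslow_loglik(b, Xs, time, event)
            ll_train = _breslow_loglik(b, Xs[tr], time[tr], event[tr])
            dev[fi, j] = -2.0 * (ll_full - ll_train)
    mean_dev = dev.mean(axis=0)
    j_min = int(np.argmin(mean_dev))
    alpha_min = float(grid[j_min])

    full_coefs = coefs_for(Xs, time, event, grid)
    path_orig = full_coefs / sd[:, None]
    coef_min = pd.Series(path_orig[:, j_min], index=names)
    selected = [n for n in names if coef_min[n] != 0.0]
    if not np.any(full_coefs != 0):
        raise ValueError("all-zero coefficient path: no signal or grid too coarse")
    return LassoCoxResult(
        alphas=grid,
        path=pd.DataFrame(path_orig, index=names, columns=[f"{a:.6g}" for a in grid]),
        cv_deviance=mean_dev,
        alpha_min=alpha_min,
        selected=selected,
        coef_min=coef_min,
    )


def build_risk_model(
    data: SurvivalData,
    alphas: np.ndarray | list[float] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[RiskModel, CoxFit]:
    """LASSO-Cox feature selection followed by a multivariate Cox refit.

    The risk model's coefficients are the refitted (unpenalized) Cox betas
    of the features selected at lambda_min.
    """
    lasso = lasso_cox(data, alphas=alphas, n_folds=n_folds, seed=seed)
    if not lasso.selected:
        raise ValueError("LASSO selected no features at lambda_min")
    sub = SurvivalData(time=data.time, event=data.event, features=data.features[lasso.selected])
    fit = fit_cox(sub)
    model = RiskModel(
        features=lasso.selected,
        beta=fit.beta,
        metadata={"lambda_min": lasso.alpha_min, "n_folds": n_folds, "seed": seed},
    )
    return model, fit


def risk_score(model: RiskModel, features: pd.DataFrame) -> pd.Series:
    """Linear predictor sum_i beta_i * x_i per sample (no intercept)."""
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise ValueError(f"features missing from input: {missing}")
    X = features[model.features].to_numpy(dtype=float)
    b = model.beta.loc[model.features].to_numpy(dtype=float)
    return pd.Series(X @ b, index=features.index, name="risk_score")


def _logrank_oe(time: np.ndarray, event: np.ndarray, in_group: np.ndarray):
    """(O - E, V) of group 1 in a two-group log-rank comparison."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], in_group[order].astype(float)
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    at_risk_total = n - start
    cum_g = np.concatenate([[0.0], np.cumsum(g)])
    at_risk_g = g.sum() - cum_g[start]
    d_total = np.add.reduceat(e, start)
    d_g = np.add.reduceat(e * g, start)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = d_total * at_risk_g / at_risk_total
        V = np.where(
            at_risk_total > 1,
            d_total
            * (at_risk_g / at_risk_total)
            * (1 - at_risk_g / at_risk_total)
            * (at_risk_total - d_total)
            / (at_risk_total - 1),
            0.0,
        )
    O = d_g
    return float((O - E).sum()), float(V.sum())


def optimal_cutpoint(
    scores: pd.Series | np.ndarray,
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    minprop: float = 0.1,
) -> CutpointResult:
    """Maximally selected standardized log-rank statistic over score splits.

    Candidate thresholds are midpoints between adjacent distinct scores that
    leave at least ``minprop`` of the samples on each side; the returned
    threshold maximizes |(O - E) / sqrt(V)| of the high-score group.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(np.unique(s)) < 2:
        raise ValueError("need at least 2 distinct scores")
    if e.sum() < 1:
        raise ValueError("need at least 1 event")
    n = len(s)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for thr in mids:
        high = s > thr
        n_high = int(high.sum())
        if min(n_high, n - n_high) < max(minprop * n, 1):
            continue
        oe, v = _logrank_oe(t, e, high)
        if v <= 0:
            continue
        z = oe / np.sqrt(v)
        if best is None or abs(z) > abs(best[1]):
            best = (thr, z, n - n_high, n_high)
    if best is None:
        raise ValueError("no admissible threshold under the minprop constraint")
    thr, z, n_low, n_high = best
    return CutpointResult(threshold=float(thr), statistic=float(z), n_low=n_low, n_high=n_high)


def km_estimate(
    time, event, groups
) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier product-limit curves per group.

    Returns, per group, a frame with event-time grid, survival probability
    and the number at risk.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tab = kmf.event_table
        out[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": tab["at_risk"].to_numpy(),
            }
        )
    return out


def log_rank(time, event, groups) -> tuple[float, int, float]:
    """k-group log-rank test: (chi-square, df, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    if event.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    k = len(pd.unique(groups))
    if k < 2:
        raise ValueError("need at least 2 groups")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), k - 1, float(res.p_value)


def concordance_index(scores, time, event) -> float:
    """Harrell's C: higher score predicting earlier event counts concordant."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no comparable pairs (no events)")
    return float(_lifelines_cindex(time, -scores, event))


def auc(labels, scores) -> float:
    """Rank-based (Mann–Whitney) AUC with tie correction."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def group_difference_test(values, groups) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum between the two groups in ``groups``.

    Returns a centered statistic (U - n1*n2/2, so swapping group labels flips
    its sign) and the p-value; the exact null distribution is used below a
    combined n of 20 when there are no ties.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labs = np.sort(pd.unique(groups))
    if len(labs) != 2:
        raise ValueError("group_difference_test needs exactly 2 groups")
    x = values[groups == labs[0]]
    y = values[groups == labs[1]]
    n1, n2 = len(x), len(y)
    no_ties = len(np.unique(values)) == n1 + n2
    method = "exact" if (n1 + n2 < 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic - n1 * n2 / 2.0), float(res.pvalue)
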