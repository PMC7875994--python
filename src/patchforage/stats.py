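"""Per-participant behavioural statistics and group-level inference.

The analysis follows a two-stage summary-statistics approach: every
regression is fitted per participant on z-scored predictors (plus a
constant), and the per-participant coefficients are then tested against
zero with two-tailed one-sample t tests, reported with the 95% CI of the
mean and Cohen's U3_1 (the fraction of the sample below zero).

Patch-leaving behaviour is summarized by the patch-leaving advantage
(PLA): at each leave trial, the previous trial's patch value difference
(alternative - current) minus the current travel cost.  Cost sensitivity
of the leave threshold is assessed by the per-cost-level median value
difference at leaving, compared across the four cost levels with a
one-way repeated-measures ANOVA and a per-participant linear trend test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats as sps

from patchforage.models import FitResult

__all__ = [
    "DecisionVariableSet",
    "GroupTestResult",
    "RMAnovaResult",
    "RobustFitResult",
    "compute_patch_leaving_advantage",
    "median_leave_vdiff_by_cost",
    "rm_anova_linear_trend",
    "design_columns",
    "build_design_matrix",
    "fit_participant_regression",
    "group_level_ttest",
    "compute_accuracy",
    "compute_decision_variables",
    "robust_regression",
]

COST_LEVELS = (5, 10, 15, 20)

PATCH_RT_PREDICTORS = [
    "prev_vdiff",
    "switch",
    "cost",
    "trial",
    "side_change",
    "prev_rewarded",
]
VALUE_CHOICE_PREDICTORS = [
    "ev_diff",
    "ev_sum",
    "cur_vdiff",
    "cost",
    "prev_value_choice",
    "patch_choice_right",
    "prev_rewarded",
    "no_brainer",
    "trial",
    "switch",
]
# the value-stage RT model replaces the signed EV difference by its
# absolute value (no side-conditional effect expected on speed)
VALUE_RT_PREDICTORS = ["abs_ev_diff"] + VALUE_CHOICE_PREDICTORS[1:]


@dataclass
class GroupTestResult:
    """Two-tailed one-sample t test of per-participant values against 0."""

    mean: float
    t: float
    p: float
    df: int
    ci95: tuple[float, float]
    u3_1: float
    n: int


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA with a linear trend follow-up."""

    f: float
    p: float
    df: tuple[int, int]
    eta_sq: float
    trend: GroupTestResult
    n: int


@dataclass
class RobustFitResult:
    slope: float
    t: float
    p: float
    ci95: tuple[float, float]


@dataclass
class DecisionVariableSet:
    """Per-participant scalars entering the E/I link analysis."""

    mean_pla: float = float("nan")
    cost_rt_beta: float = float("nan")
    pct_correct: float = float("nan")
    alpha: float = float("nan")
    gamma: float = float("nan")
    vdiff_rt_beta: float = float("nan")
    mean_logrt_value: float = float("nan")
    nb_share: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "mean_pla": self.mean_pla,
            "cost_rt_beta": self.cost_rt_beta,
            "pct_correct": self.pct_correct,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "vdiff_rt_beta": self.vdiff_rt_beta,
            "mean_logrt_value": self.mean_logrt_value,
            "nb_share": self.nb_share,
        }


def _prev_vdiff(trials: pd.DataFrame) -> pd.Series:
    return (trials["val_alt"] - trials["val_cur"]).shift(1)


def compute_patch_leaving_advantage(trials: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-leave-trial PLA and its mean over leave trials.

    PLA at leave trial t is the previous trial's (alternative - current)
    patch value difference minus the travel cost paid at t.  Leave trials
    without a preceding trial are skipped.
    """
    leave = trials["patch_choice"].astype(str) == "leave"
    pla = _prev_vdiff(trials) - trials["cost"]
    pla_leave = pla[leave].dropna()
    if pla_leave.empty:
        warnings.warn("no leave trials; mean PLA is undefined", stacklevel=2)
        return pla_leave, float("nan")
    return pla_leave, float(pla_leave.mean())


def median_leave_vdiff_by_cost(
    trials: pd.DataFrame, cost_levels: tuple = COST_LEVELS
) -> pd.Series:
    """Median previous-trial patch value difference at leaving, per cost
    level; cost levels without any leave trial yield NaN."""
    leave = trials["patch_choice"].astype(str) == "leave"
    vdiff = _prev_vdiff(trials)
    out = {}
    for c in cost_levels:
        sel = leave & (trials["cost"] == c) & vdiff.notna()
        out[c] = float(vdiff[sel].median()) if sel.any() else float("nan")
    return pd.Series(out, name="median_leave_vdiff")


def group_level_ttest(coefficients) -> GroupTestResult:
    """Two-tailed one-sample t test against zero with 95% CI of the mean
    and Cohen's U3_1 (share of values strictly below zero)."""
    x = np.asarray(coefficients, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for a group-level test")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coefficients in group-level test")
    if np.var(x) == 0:
        raise ValueError("zero variance across participants")
    n = x.size
    mean = float(x.mean())
    se = float(x.std(ddof=1) / math.sqrt(n))
    t = mean / se
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.975, df) * se
    return GroupTestResult(
        mean=mean,
        t=float(t),
        p=float(p),
        df=df,
        ci95=(mean - half, mean + half),
        u3_1=float(np.mean(x < 0)),
        n=n,
    )


def rm_anova_linear_trend(
    matrix, cost_levels: tuple = COST_LEVELS
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA over cost levels plus a linear
    trend test.

    Rows are participants, columns the per-cost-level medians; rows with
    any missing level are dropped listwise.  Effect size is eta^2 =
    SS_condition / SS_total (including between-subject variance).  The
    trend test regresses each complete row on the cost levels (with a
    constant) and t-tests the per-participant slopes against zero.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(cost_levels):
        raise ValueError(f"matrix must be participants x {len(cost_levels)} cost levels")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 3:
        raise ValueError("need at least 3 complete participants")
    grand = m.mean()
    ss_total = float(((m - grand) ** 2).sum())
    ss_cond = float(n * ((m.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(k * ((m.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    f = (ss_cond / df_cond) / ms_err if ms_err > 0 else 0.0
    p = float(sps.f.sf(f, df_cond, df_err)) if ms_err > 0 else 1.0
    eta_sq = ss_cond / ss_total if ss_total > 0 else 0.0

    levels = np.asarray(cost_levels, dtype=float)
    x = levels - levels.mean()
    slopes = m @ x / (x @ x)
    if np.var(slopes) == 0:
        # degenerate (e.g. identical columns): no testable trend spread
        mean = float(slopes.mean())
        trend = GroupTestResult(
            mean=mean,
            t=0.0 if mean == 0 else math.copysign(math.inf, mean),
            p=1.0 if mean == 0 else 0.0,
            df=n - 1,
            ci95=(mean, mean),
            u3_1=float(np.mean(slopes < 0)),
            n=n,
        )
    else:
        trend = group_level_ttest(slopes)
    return RMAnovaResult(
        f=float(f), p=p, df=(df_cond, df_err), eta_sq=float(eta_sq), trend=trend, n=n
    )


def design_columns(trials: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Raw (un-normalized) predictor columns for one regression stage.

    First-trial lags are NaN; :func:`build_design_matrix` drops those rows
    before z-scoring.
    """
    t = trials
    leave = (t["patch_choice"].astype(str) == "leave").astype(float)
    cols = pd.DataFrame(index=t.index)
    if stage == "patch_rt":
        cols["prev_vdiff"] = _prev_vdiff(t)
        cols["switch"] = leave
        cols["cost"] = t["cost"].astype(float)
        cols["trial"] = t["trial"].astype(float)
        side = t["side_cur"].astype(str)
        cols["side_change"] = (side != side.shift(1)).astype(float)
        cols.loc[t.index[0], "side_change"] = np.nan
        cols["prev_rewarded"] = (t["reward"] > 0).astype(float).shift(1)
        return cols[PATCH_RT_PREDICTORS]
    if stage in ("value_choice", "value_rt"):
        ev_left = t["m_left"] * t["p_left"]
        ev_right = t["m_right"] * t["p_right"]
        if stage == "value_choice":
            cols["ev_diff"] = ev_right - ev_left
        else:
            cols["abs_ev_diff"] = (ev_right - ev_left).abs()
        cols["ev_sum"] = ev_right + ev_left
        cols["cur_vdiff"] = t["val_alt"] - t["val_cur"]
        cols["cost"] = t["cost"].astype(float)
        cols["prev_value_choice"] = (
            (t["value_choice"].astype(str) == "right").astype(float).shift(1)
        )
        side = t["side_cur"].astype(str)
        chosen_right = np.where(leave.astype(bool), side == "left", side == "right")
        cols["patch_choice_right"] = chosen_right.astype(float)
        cols["prev_rewarded"] = (t["reward"] > 0).astype(float).shift(1)
        cols["no_brainer"] = t["no_brainer"].astype(str).isin(["left", "right"]).astype(float)
        cols["trial"] = t["trial"].astype(float)
        cols["switch"] = leave
        order = VALUE_CHOICE_PREDICTORS if stage == "value_choice" else VALUE_RT_PREDICTORS
        return cols[order]
    raise ValueError(f"unknown stage {stage!r}")


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def build_design_matrix(
    trials: pd.DataFrame, stage: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Z-scored design matrix (with constant) and dependent variable.

    ``stage``: ``'patch_rt'`` predicts z-scored log patch-stage RT;
    ``'value_choice'`` predicts the binary right-option choice;
    ``'value_rt'`` predicts z-scored log value-stage RT.  Rows with
    undefined lagged predictors (the first trial) are dropped; a predictor
    with zero variance raises a ValueError naming the column.
    """
    raw = design_columns(trials, stage)
    keep = raw.notna().all(axis=1)
    raw = raw.loc[keep]
    X = pd.DataFrame(index=raw.index)
    for name in raw.columns:
        col = raw[name].to_numpy(float)
        if np.std(col) == 0:
            raise ValueError(f"zero-variance predictor column: {name!r}")
        X[name] = _zscore(col)
    X["const"] = 1.0

    if stage == "value_choice":
        y = (trials.loc[keep, "value_choice"].astype(str) == "right").to_numpy(int)
    else:
        rt_col = "rt_patch" if stage == "patch_rt" else "rt_value"
        rt = trials.loc[keep, rt_col].to_numpy(float)
        if np.any(~np.isfinite(rt)) or np.any(rt <= 0):
            raise ValueError(f"non-positive or missing response times in {rt_col!r}")
        y = _zscore(np.log(rt))
    return X, y


def fit_participant_regression(y, X: pd.DataFrame, link: str = "linear") -> pd.Series:
    """One participant's regression coefficients.

    ``link='linear'`` is OLS; ``link='logistic'`` is maximum-likelihood
    logistic regression with a tiny ridge penalty on the slopes (escalated
    tenfold up to 1e-2 if the fit fails to converge, e.g. under complete
    separation).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X have different numbers of rows")
    Xv = X.to_numpy(float)
    if link == "linear":
        beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
        return pd.Series(beta, index=X.columns)
    if link != "logistic":
        raise ValueError(f"unknown link {link!r}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic regression requires a binary 0/1 outcome")
    slope_mask = np.array([c != "const" for c in X.columns], dtype=float)

    for ridge in (1e-6, 1e-5, 1e-4, 1e-3, 1e-2):
        def nll(b):
            eta = Xv @ b
            # log-likelihood via log1p(exp) in a stable form
            ll = y * eta - np.logaddexp(0.0, eta)
            return -ll.sum() + ridge * np.sum(slope_mask * b**2)

        def grad(b):
            mu = special.expit(Xv @ b)
            return -Xv.T @ (y - mu) + 2.0 * ridge * slope_mask * b

        res = optimize.minimize(nll, np.zeros(Xv.shape[1]), jac=grad, method="BFGS")
        if res.success and np.all(np.isfinite(res.x)):
            return pd.Series(res.x, index=X.columns)
    raise RuntimeError("logistic regression failed to converge even with ridge 1e-2")


def compute_accuracy(trials: pd.DataFrame) -> float:
    """Percentage of unequal-expected-value trials on which the higher-EV
    option was chosen; equal-EV trials are excluded from the denominator."""
    ev_left = trials["m_left"] * trials["p_left"]
    ev_right = trials["m_right"] * trials["p_right"]
    unequal = ev_left != ev_right
    if not unequal.any():
        warnings.warn("no unequal-EV trials; accuracy undefined", stacklevel=2)
        return float("nan")
    chose_right = trials["value_choice"].astype(str) == "right"
    correct = np.where(ev_right > ev_left, chose_right, ~chose_right)[unequal]
    return float(100.0 * np.mean(correct))


def robust_regression(y, x) -> RobustFitResult:
    """Simple robust regression of y on x by iteratively reweighted least
    squares with a Tukey bisquare weight function (tuning constant 4.685);
    inference on the slope uses a t distribution with n - 2 df."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise ValueError("y and x must have equal length")
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if np.var(x) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    fit = model.fit()
    if not np.all(np.isfinite(fit.params)):
        raise RuntimeError("robust regression did not converge")
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    df = y.size - 2
    t = slope / se
    p = 2.0 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.975, df) * se
    return RobustFitResult(slope=slope, t=float(t), p=float(p), ci95=(slope - half, slope + half))


def compute_decision_variables(
    trials: pd.DataFrame, fit: FitResult | None = None
) -> DecisionVariableSet:
    """Assemble one participant's decision variables.

    Components that cannot be computed (e.g. a session without leave
    trials, or a degenerate design matrix) are propagated as NaN rather
    than raising.
    """
    dv = DecisionVariableSet()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, dv.mean_pla = compute_patch_leaving_advantage(trials)
        dv.pct_correct = compute_accuracy(trials)
    try:
        X, y = build_design_matrix(trials, "patch_rt")
        dv.cost_rt_beta = float(fit_participant_regression(y, X, "linear")["cost"])
    except (ValueError, RuntimeError):
        pass
    try:
        X, y = build_design_matrix(trials, "value_rt")
        coeffs = fit_participant_regression(y, X, "linear")
        dv.vdiff_rt_beta = float(coeffs["abs_ev_diff"])
    except (ValueError, RuntimeError):
        pass
    rt_value = trials["rt_value"].to_numpy(float)
    if np.all(np.isfinite(rt_value)) and np.all(rt_value > 0):
        dv.mean_logrt_value = float(np.mean(np.log(rt_value)))
    nb = trials["no_brainer"].astype(str).isin(["left", "right"])
    dv.nb_share = float(100.0 * nb.mean())
    if fit is not None:
        dv.alpha = float(fit.params.alpha)
        dv.gamma = float(fit.params.gamma)
    return dv
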