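"""Metabolite normalization, E/I ratios, and the gated link analysis.

Spectroscopy quality control keeps a region's measurement only if the
Cramér–Rao lower bound of both metabolites is below 20%, the line width
(FWHM) below 25 Hz, and the signal-to-noise ratio above 8; a participant
failing quality control in any of the five regions is dropped listwise.

GABA and glutamate are referenced to grey matter (absolute concentration
divided by the voxel's relative GM), total creatine to GM+WM, and both
metabolites are then expressed relative to creatine.  E/I balance is the
ratio of normalized glutamate to normalized GABA.

The link analysis follows a fixed testing hierarchy per decision
variable: (1) only configured decision variables (optionally gated on a
significant behavioural group effect) enter; (2) a single GLM regresses
the decision variable on the z-scored E/I values of all five regions
simultaneously (plus a constant, and a no-brainer-share covariate for
value-phase variables); (3) only regions significant in that GLM receive
follow-ups — a partial correlation by residualizing both the decision
variable and the target region's E/I on the other four regions; (4)
transmitter-level partial correlations (GABA and glutamate separately,
residualized on the nine remaining metabolite columns) and a robust
refit of the residual relationship.  No multiple-comparison correction is
applied across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from patchforage.agents import REGIONS
from patchforage.stats import robust_regression

__all__ = [
    "QCThresholds",
    "LinkConfig",
    "qc_filter",
    "normalize_metabolites",
    "compute_ei",
    "ei_profiles",
    "ei_glm",
    "EIGlmResult",
    "partial_correlation_region",
    "partial_correlation_transmitter",
    "region_coefficient_contrast",
    "run_testing_hierarchy",
]

DEFAULT_DV_LIST = (
    "mean_pla",
    "cost_rt_beta",
    "pct_correct",
    "alpha",
    "gamma",
    "vdiff_rt_beta",
    "mean_logrt_value",
)
VALUE_PHASE_DVS = ("pct_correct", "alpha", "gamma", "vdiff_rt_beta", "mean_logrt_value")


@dataclass
class QCThresholds:
    crlb_max: float = 20.0  # %
    fwhm_max: float = 25.0  # Hz
    snr_min: float = 8.0


@dataclass
class LinkConfig:
    """Configuration of the testing hierarchy."""

    dv_list: tuple = DEFAULT_DV_LIST
    value_phase_dvs: tuple = VALUE_PHASE_DVS
    gate_alpha: float = 0.05
    behavioural_p: dict | None = None  # dv -> group-level p; gates step 1
    mediation_covariates: dict = field(default_factory=dict)  # dv -> list of dv names
    robust_refit: bool = True
    contrasts: bool = True


def qc_filter(
    measurements: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, list]:
    """Apply spectral quality criteria per measurement.

    Returns the table with ``included`` and ``reason`` columns added, and
    the list of participants excluded listwise (any failing or missing
    region).
    """
    th = thresholds or QCThresholds()
    required = {"participant", "region", "crlb_gaba", "crlb_glu", "fwhm", "snr"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"metabolite table missing quality columns: {sorted(missing)}")
    out = measurements.copy()
    reasons = []
    for _, row in out.iterrows():
        why = []
        if not (row["crlb_gaba"] < th.crlb_max and row["crlb_glu"] < th.crlb_max):
            why.append("CRLB")
        if not (row["fwhm"] < th.fwhm_max):
            why.append("FWHM")
        if not (row["snr"] > th.snr_min):
            why.append("SNR")
        reasons.append(",".join(why))
    out["reason"] = reasons
    out["included"] = out["reason"] == ""
    excluded = set(out.loc[~out["included"], "participant"])
    counts = out[out["included"]].groupby("participant")["region"].nunique()
    for p in out["participant"].unique():
        if counts.get(p, 0) < len(REGIONS):
            excluded.add(p)
    return out, sorted(excluded)


def normalize_metabolites(
    gaba_abs: float,
    glu_abs: float,
    cr_abs: float,
    gm_frac: float,
    wm_frac: float,
    n_voxels: int | None = None,
) -> tuple[float, float]:
    """Grey-matter and creatine normalization of GABA and glutamate.

    ``gm_frac``/``wm_frac`` may be given either as fractions in [0, 1] or
    as summed tissue probabilities over the voxel mask together with
    ``n_voxels`` (they are then divided by the voxel count first).
    Metabolites are divided by relative GM, creatine by relative GM+WM,
    and the outputs are the metabolite-to-creatine ratios.
    """
    if n_voxels is not None:
        if n_voxels <= 0:
            raise ValueError("n_voxels must be positive")
        gm_frac = gm_frac / n_voxels
        wm_frac = wm_frac / n_voxels
    if gm_frac <= 0:
        raise ValueError("grey-matter fraction must be positive")
    if gm_frac + wm_frac <= 0:
        raise ValueError("GM + WM fraction must be positive")
    if min(gaba_abs, glu_abs, cr_abs) <= 0:
        raise ValueError("concentrations must be positive")
    cr_norm = cr_abs / (gm_frac + wm_frac)
    return (gaba_abs / gm_frac) / cr_norm, (glu_abs / gm_frac) / cr_norm


def compute_ei(gaba_norm: float, glu_norm: float) -> float:
    """E/I balance: normalized glutamate over normalized GABA."""
    if gaba_norm <= 0 or glu_norm <= 0:
        raise ValueError("normalized concentrations must be positive")
    return glu_norm / gaba_norm


def ei_profiles(measurements: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-participant wide tables of E/I, normalized GABA, and normalized
    glutamate (columns = regions).  Participants must have all regions."""
    gaba_rows, glu_rows, ei_rows = {}, {}, {}
    for p, grp in measurements.groupby("participant"):
        if set(grp["region"]) != set(REGIONS):
            raise ValueError(f"participant {p} lacks measurements for all regions")
        g, gl, ei = {}, {}, {}
        for _, row in grp.iterrows():
            gn, un = normalize_metabolites(
                row["gaba_abs"], row["glu_abs"], row["cr_abs"],
                row["gm_frac"], row["wm_frac"],
            )
            g[row["region"]] = gn
            gl[row["region"]] = un
            ei[row["region"]] = compute_ei(gn, un)
        gaba_rows[p], glu_rows[p], ei_rows[p] = g, gl, ei
    cols = list(REGIONS)
    return (
        pd.DataFrame.from_dict(ei_rows, orient="index")[cols],
        pd.DataFrame.from_dict(gaba_rows, orient="index")[cols],
        pd.DataFrame.from_dict(glu_rows, orient="index")[cols],
    )


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance column in design")
    return (x - x.mean()) / sd


@dataclass
class EIGlmResult:
    per_region: dict  # region -> dict(beta, t, p, ci95)
    regions: tuple
    model: object  # statsmodels RegressionResults
    covariate_names: tuple = ()

    def significant_regions(self, alpha: float = 0.05) -> list:
        return [r for r in self.regions if self.per_region[r]["p"] < alpha]


def ei_glm(
    dv: pd.Series,
    ei: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> EIGlmResult:
    """Regress a decision variable on all five regional E/I values at once.

    All variables (dv, regions, covariates) are z-scored; a constant is
    appended.  Per-region two-tailed t statistics and 95% CIs come from
    the OLS coefficient covariance.
    """
    regions = tuple(ei.columns)
    n = len(dv)
    n_pred = len(regions) + (0 if covariates is None else covariates.shape[1])
    if n <= n_pred + 2:
        raise ValueError(f"too few participants (n={n}) for {n_pred} predictors")
    data = {r: _z(ei[r].to_numpy(float)) for r in regions}
    cov_names = ()
    if covariates is not None:
        cov_names = tuple(covariates.columns)
        for c in covariates.columns:
            data[c] = _z(covariates[c].to_numpy(float))
    X = pd.DataFrame(data)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design matrix (rank {rank} < {X.shape[1]})")
    X = sm.add_constant(X)
    y = _z(dv.to_numpy(float))
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    per_region = {}
    for r in regions:
        per_region[r] = {
            "beta": float(fit.params[r]),
            "t": float(fit.tvalues[r]),
            "p": float(fit.pvalues[r]),
            "ci95": (float(ci.loc[r, 0]), float(ci.loc[r, 1])),
        }
    return EIGlmResult(per_region=per_region, regions=regions, model=fit, covariate_names=cov_names)


def _residualize(y: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residuals of y after OLS on the nuisance columns plus a constant."""
    X = np.column_stack([nuisance, np.ones(len(y))])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _pearson_with_ci(a: np.ndarray, b: np.ndarray) -> dict:
    res = sps.pearsonr(a, b)
    try:
        ci = res.confidence_interval()
        ci95 = (float(ci.low), float(ci.high))
    except ValueError:
        ci95 = (float("nan"), float("nan"))
    return {"r": float(res.statistic), "p": float(res.pvalue), "ci95": ci95}


def partial_correlation_region(
    dv: pd.Series, ei: pd.DataFrame, target_region: str
) -> dict:
    """Partial correlation between a decision variable and the target
    region's E/I, both residualized on the other regions' E/I (plus a
    constant).  Returns r, p, CI, and the residual pairs."""
    if target_region not in ei.columns:
        raise ValueError(f"unknown region {target_region!r}")
    others = [c for c in ei.columns if c != target_region]
    nuisance = ei[others].to_numpy(float)
    r_dv = _residualize(dv.to_numpy(float), nuisance)
    r_tgt = _residualize(ei[target_region].to_numpy(float), nuisance)
    out = _pearson_with_ci(r_dv, r_tgt)
    out["residual_dv"] = r_dv
    out["residual_target"] = r_tgt
    return out


def partial_correlation_transmitter(
    dv: pd.Series,
    gaba: pd.DataFrame,
    glu: pd.DataFrame,
    target_region: str,
    transmitter: str,
) -> dict:
    """Partial correlation between a decision variable and one transmitter
    in the target region, residualizing both on the other transmitter in
    that region and both transmitters in all other regions (9 nuisance
    columns plus a constant)."""
    if transmitter not in ("gaba", "glu"):
        raise ValueError("transmitter must be 'gaba' or 'glu'")
    target = (gaba if transmitter == "gaba" else glu)[target_region].to_numpy(float)
    others = [c for c in gaba.columns if c != target_region]
    nuisance_cols = [(glu if transmitter == "gaba" else gaba)[target_region].to_numpy(float)]
    for c in others:
        nuisance_cols.append(gaba[c].to_numpy(float))
        nuisance_cols.append(glu[c].to_numpy(float))
    nuisance = np.column_stack(nuisance_cols)
    n = len(dv)
    if n <= nuisance.shape[1] + 2:
        raise ValueError(
            f"too few participants (n={n}) to residualize on {nuisance.shape[1]} columns"
        )
    r_dv = _residualize(dv.to_numpy(float), nuisance)
    r_tgt = _residualize(target, nuisance)
    return _pearson_with_ci(r_dv, r_tgt)


def region_coefficient_contrast(
    glm: EIGlmResult, region_a: str, region_b: str
) -> tuple[float, float]:
    """t test of the linear contrast beta_a - beta_b using the fitted
    GLM's coefficient covariance."""
    names = list(glm.model.params.index)
    vec = np.zeros(len(names))
    vec[names.index(region_a)] += 1.0
    vec[names.index(region_b)] -= 1.0
    if not vec.any():  # a region contrasted with itself
        return 0.0, 1.0
    res = glm.model.t_test(vec)
    return float(np.squeeze(res.tvalue)), float(np.squeeze(res.pvalue))


def run_testing_hierarchy(
    dvs: pd.DataFrame,
    ei: pd.DataFrame,
    gaba: pd.DataFrame | None = None,
    glu: pd.DataFrame | None = None,
    config: LinkConfig | None = None,
) -> dict:
    """Run the full gated hierarchy for every configured decision variable.

    ``dvs`` is participants x decision variables (may include an
    ``nb_share`` column used as covariate for value-phase variables);
    ``ei``/``gaba``/``glu`` are participants x regions.  Returns a nested
    JSON-serializable report with, per decision variable, the GLM
    coefficients and — only for regions significant at ``gate_alpha`` —
    the partial correlations, transmitter follow-ups, contrasts, and
    robust refit.  Regions or variables not tested carry an explicit
    reason.
    """
    cfg = config or LinkConfig()
    report: dict = {"gate_alpha": cfg.gate_alpha, "dvs": {}}
    for dv_name in cfg.dv_list:
        entry: dict = {}
        if dv_name not in dvs.columns:
            entry["tested"] = False
            entry["reason"] = "decision variable not available"
            report["dvs"][dv_name] = entry
            continue
        if cfg.behavioural_p is not None:
            p_beh = cfg.behavioural_p.get(dv_name)
            if p_beh is None or p_beh >= cfg.gate_alpha:
                entry["tested"] = False
                entry["reason"] = (
                    f"no significant behavioural effect (p={p_beh})"
                )
                report["dvs"][dv_name] = entry
                continue
        dv = dvs[dv_name]
        finite = np.isfinite(dv.to_numpy(float))
        if not finite.all():
            entry["tested"] = False
            entry["reason"] = "missing values in decision variable"
            report["dvs"][dv_name] = entry
            continue

        cov_frames = []
        if dv_name in cfg.value_phase_dvs and "nb_share" in dvs.columns:
            cov_frames.append(dvs[["nb_share"]])
        for extra in cfg.mediation_covariates.get(dv_name, []):
            cov_frames.append(dvs[[extra]])
        covariates = pd.concat(cov_frames, axis=1) if cov_frames else None

        glm = ei_glm(dv, ei, covariates)
        entry["tested"] = True
        entry["glm"] = {r: dict(glm.per_region[r]) for r in glm.regions}
        entry["covariates"] = list(glm.covariate_names)
        entry["followups"] = {}
        significant = glm.significant_regions(cfg.gate_alpha)
        entry["significant_regions"] = significant
        for region in significant:
            follow: dict = {}
            pc = partial_correlation_region(dv, ei, region)
            res_dv = pc.pop("residual_dv")
            res_tgt = pc.pop("residual_target")
            follow["partial_correlation"] = pc
            if gaba is not None and glu is not None:
                follow["transmitters"] = {}
                for tr in ("gaba", "glu"):
                    try:
                        follow["transmitters"][tr] = partial_correlation_transmitter(
                            dv, gaba, glu, region, tr
                        )
                    except ValueError as err:
                        follow["transmitters"][tr] = {"error": str(err)}
            if cfg.robust_refit:
                rob = robust_regression(res_dv, res_tgt)
                follow["robust"] = {
                    "slope": rob.slope, "t": rob.t, "p": rob.p, "ci95": rob.ci95,
                }
            if cfg.contrasts:
                follow["contrasts"] = {}
                for other in glm.regions:
                    if other == region:
                        continue
                    t, p = region_coefficient_contrast(glm, region, other)
                    follow["contrasts"][other] = {"t": t, "p": p}
            entry["followups"][region] = follow
        report["dvs"][dv_name] = entry
    return report
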