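"""Generative agents and a synthetic cohort with planted effects.

The task's original analyses fit no generative model of patch choices or
response times, so the agents here are deliberately minimal stand-ins
whose outputs carry the statistical structure the analysis layer assumes:

* patch stage — a stochastic threshold: P(leave) is a logistic function
  of the patch-leaving advantage (PLA), centred on a per-agent threshold
  ``theta_leave`` with noise scale ``sigma_leave``.  Larger thresholds
  produce leaving at larger advantages, making the mean PLA a meaningful
  per-agent quantity.
* value stage — softmax choice over subjective option values from the
  multiplicative model with the agent's own distortion parameters
  (alpha, gamma) and fixed value scale omega_mult.
* response times — log-normal: log RT is a linear function of the same
  (z-scored within session) design variables the analysis regressions
  use, plus Gaussian noise.

The cohort generator draws, per participant, a multivariate-normal latent
vector over five regional E/I ratios and a set of behavioural traits with
a configurable ("planted") correlation structure, maps traits to agent
parameters through monotone transforms, and converts each latent E/I
value into an absolute GABA/glutamate/creatine triplet with realistic
tissue fractions, so the metabolite-normalization arithmetic downstream is
exercised end to end rather than bypassed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from patchforage import models, stats
from patchforage.task import OptionPair, PatchDynamicsParams, simulate_session

__all__ = [
    "AgentParams",
    "SoftmaxAgent",
    "AlwaysStayAgent",
    "PlantedEffect",
    "CohortSpec",
    "generate_cohort",
    "attach_response_times",
    "simulate_participant",
    "REGIONS",
]

REGIONS = ("dACC", "vmPFC", "dlPFC", "lM1", "rM1")

# default log-RT coefficients (per z-unit of the design variable), loosely
# shaped on the group-level effects the analysis layer is meant to detect
DEFAULT_RT_PATCH_BETAS = {
    "cost": 0.03,
    "switch": 0.09,
    "side_change": 0.05,
    "prev_rewarded": 0.05,
    "trial": -0.25,
}
DEFAULT_RT_VALUE_BETAS = {
    "abs_ev_diff": -0.20,
    "cur_vdiff": -0.12,
    "no_brainer": -0.30,
    "trial": -0.20,
    "switch": 0.05,
    "patch_choice_right": 0.02,
}


@dataclass
class AgentParams:
    """Per-agent generative parameters."""

    theta_leave: float = 15.0
    sigma_leave: float = 5.0
    alpha: float = 0.8
    gamma: float = 0.8
    omega_mult: float = models.DEFAULT_OMEGA_MULT
    rt_patch_betas: dict = field(default_factory=lambda: dict(DEFAULT_RT_PATCH_BETAS))
    rt_value_betas: dict = field(default_factory=lambda: dict(DEFAULT_RT_VALUE_BETAS))
    rt_patch_intercept: float = math.log(0.7)
    rt_value_intercept: float = math.log(1.2)
    rt_noise_sd: float = 0.35

    def validate(self) -> None:
        if self.sigma_leave <= 0:
            raise ValueError("sigma_leave must be positive")
        if self.rt_noise_sd <= 0:
            raise ValueError("rt_noise_sd must be positive")
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be positive")


class SoftmaxAgent:
    """Logistic patch-leaving policy plus softmax value choice.

    Value-stage magnitudes are mapped onto the fitting scale [1, 10] with
    a fixed affine map over the task's theoretical magnitude range so the
    agent's value function is stationary across sessions.
    """

    _VALUE_SPEC = models.ValueModelSpec(family="multiplicative", distortion="SU")

    def __init__(self, params: AgentParams):
        params.validate()
        self.params = params

    def choose_patch(self, pla: float, rng: np.random.Generator) -> str:
        p_leave = float(
            expit((pla - self.params.theta_leave) / self.params.sigma_leave)
        )
        return "leave" if rng.random() < p_leave else "stay"

    def choose_value(self, options: OptionPair, rng: np.random.Generator) -> str:
        p = self.params
        mp = models.ValueModelParams(
            alpha=p.alpha, gamma=p.gamma, omega_m=0.0, omega_p=0.0, omega_mult=p.omega_mult
        )
        m_l = 1.0 + 9.0 * (options.m_left - 1.0) / 80.0
        m_r = 1.0 + 9.0 * (options.m_right - 1.0) / 80.0
        v_l = models.option_value(m_l, options.p_left, mp, self._VALUE_SPEC)
        v_r = models.option_value(m_r, options.p_right, mp, self._VALUE_SPEC)
        p_right = models.choice_probability(v_l, v_r)
        return "right" if rng.random() < float(p_right) else "left"


class AlwaysStayAgent:
    """Never leaves the patch; value choices are uniform coin flips.
    Useful for probing the patch dynamics in isolation."""

    def choose_patch(self, pla: float, rng: np.random.Generator) -> str:
        return "stay"

    def choose_value(self, options: OptionPair, rng: np.random.Generator) -> str:
        return "right" if rng.random() < 0.5 else "left"


def _stage_log_rt(
    trials: pd.DataFrame,
    stage: str,
    intercept: float,
    betas: dict,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    raw = stats.design_columns(trials, stage)
    log_rt = np.full(len(trials), intercept, dtype=float)
    for name, beta in betas.items():
        if beta == 0.0 or name not in raw.columns:
            continue
        col = raw[name].to_numpy(float)
        sd = np.nanstd(col)
        if not np.isfinite(sd) or sd == 0:
            continue
        z = (col - np.nanmean(col)) / sd
        log_rt += beta * np.nan_to_num(z)
    log_rt += rng.normal(0.0, noise_sd, size=len(trials))
    return np.exp(log_rt)


def attach_response_times(
    trials: pd.DataFrame, params: AgentParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill ``rt_patch`` and ``rt_value`` with log-normal response times.

    log RT = intercept + sum_k beta_k * z_k + Normal(0, rt_noise_sd^2),
    where z_k are the session-z-scored design variables of the matching
    analysis regression.  Run after the session is simulated because the
    z-scoring needs the whole session.
    """
    params.validate()
    out = trials.copy()
    out["rt_patch"] = _stage_log_rt(
        trials, "patch_rt", params.rt_patch_intercept, params.rt_patch_betas,
        params.rt_noise_sd, rng,
    )
    out["rt_value"] = _stage_log_rt(
        trials, "value_rt", params.rt_value_intercept, params.rt_value_betas,
        params.rt_noise_sd, rng,
    )
    return out


def simulate_participant(
    params: AgentParams,
    task_params: PatchDynamicsParams | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    replicate_side_bias_bug: bool = True,
) -> pd.DataFrame:
    """Simulate one participant's full session (choices and RTs)."""
    from patchforage.io import records_to_frame

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    agent = SoftmaxAgent(params)
    records = simulate_session(
        agent, task_params, rng, replicate_side_bias_bug=replicate_side_bias_bug
    )
    frame = records_to_frame(records)
    return attach_response_times(frame, params, rng)


@dataclass
class PlantedEffect:
    """A cross-subject correlation planted between a regional E/I value
    and a behavioural trait (or an arbitrary named latent)."""

    region: str
    trait: str
    r: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not -1.0 < self.r < 1.0:
            raise ValueError("|r| must be below 1")


# monotone maps from standard-normal latents to agent-parameter scales;
# log-normal for strictly positive quantities
_TRAIT_MAPS = {
    "theta_leave": lambda z: 15.0 + 6.0 * z,
    "sigma_leave": lambda z: 5.0 * np.exp(0.2 * z),
    "alpha": lambda z: 0.8 * np.exp(0.22 * z),
    "gamma": lambda z: 0.8 * np.exp(0.25 * z),
    "cost_rt_beta": lambda z: 0.03 + 0.02 * z,
}

_DEFAULT_EI_MEANS = {"dACC": 4.2, "vmPFC": 4.0, "dlPFC": 4.1, "lM1": 4.4, "rM1": 4.4}
_DEFAULT_EI_SDS = {r: 0.6 for r in REGIONS}
_GM_FRAC = {"dACC": 0.55, "vmPFC": 0.52, "dlPFC": 0.48, "lM1": 0.42, "rM1": 0.42}
_WM_FRAC = {"dACC": 0.30, "vmPFC": 0.32, "dlPFC": 0.38, "lM1": 0.45, "rM1": 0.45}


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort."""

    n_participants: int = 29
    ei_means: dict = field(default_factory=lambda: dict(_DEFAULT_EI_MEANS))
    ei_sds: dict = field(default_factory=lambda: dict(_DEFAULT_EI_SDS))
    planted_effects: list = field(
        default_factory=lambda: [
            PlantedEffect("dACC", "theta_leave", 0.5),
            PlantedEffect("vmPFC", "alpha", -0.46),
        ]
    )
    seed: int | None = None

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for eff in self.planted_effects:
            if isinstance(eff, (tuple, list)):
                raise TypeError("planted_effects entries must be PlantedEffect instances")
            eff.__post_init__()


def _latent_correlation(spec: CohortSpec, traits: list[str]) -> tuple[list[str], np.ndarray]:
    names = list(REGIONS) + traits
    idx = {n: i for i, n in enumerate(names)}
    C = np.eye(len(names))
    for eff in spec.planted_effects:
        i, j = idx[eff.region], idx[eff.trait]
        C[i, j] = C[j, i] = eff.r
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"planted correlation structure is not positive semi-definite "
            f"(smallest eigenvalue {eigmin:.3g})"
        )
    return names, C


def generate_cohort(
    spec: CohortSpec, rng: np.random.Generator | int | None = None
) -> tuple[list[AgentParams], pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort.

    Returns ``(agents, metabolites, latents)``: per-participant agent
    parameters, a long-format metabolite table (one row per participant
    and region, with absolute concentrations, quality metrics, and tissue
    fractions constructed to reproduce the latent E/I after the
    normalization chain), and the latent trait table (regional E/I plus
    all traits, one column each) for reference.
    """
    spec.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)

    base_traits = list(_TRAIT_MAPS)
    extra = [e.trait for e in spec.planted_effects if e.trait not in base_traits]
    traits = base_traits + sorted(set(extra))
    names, C = _latent_correlation(spec, traits)
    z = rng.multivariate_normal(np.zeros(len(names)), C, size=spec.n_participants)
    latents = pd.DataFrame(z, columns=names)

    agents: list[AgentParams] = []
    for i in range(spec.n_participants):
        mapped = {t: float(_TRAIT_MAPS[t](latents.at[i, t])) for t in base_traits}
        p = AgentParams(
            theta_leave=mapped["theta_leave"],
            sigma_leave=mapped["sigma_leave"],
            alpha=mapped["alpha"],
            gamma=mapped["gamma"],
        )
        p.rt_patch_betas = dict(DEFAULT_RT_PATCH_BETAS)
        p.rt_patch_betas["cost"] = mapped["cost_rt_beta"]
        agents.append(p)

    rows = []
    for i in range(spec.n_participants):
        for region in REGIONS:
            ei = max(spec.ei_means[region] + spec.ei_sds[region] * latents.at[i, region], 0.2)
            latents.at[i, f"ei_{region}"] = ei
            gm = _GM_FRAC[region]
            wm = _WM_FRAC[region]
            cr_abs = rng.normal(8.0, 0.3)
            glu_norm = rng.normal(1.1, 0.04)
            gaba_norm = glu_norm / ei
            # invert the normalization chain so that
            # (x_abs / gm) / (cr_abs / (gm + wm)) equals the intended value
            cr_ratio = cr_abs / (gm + wm)
            rows.append(
                {
                    "participant": i,
                    "region": region,
                    "gaba_abs": gaba_norm * cr_ratio * gm,
                    "glu_abs": glu_norm * cr_ratio * gm,
                    "cr_abs": cr_abs,
                    "crlb_gaba": float(rng.uniform(5, 15)),
                    "crlb_glu": float(rng.uniform(3, 10)),
                    "fwhm": float(rng.uniform(10, 20)),
                    "snr": float(rng.uniform(12, 40)),
                    "gm_frac": gm,
                    "wm_frac": wm,
                }
            )
    metabolites = pd.DataFrame(rows)
    return agents, metabolites, latents
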