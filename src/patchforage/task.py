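"""Two-stage patch-foraging task environment.

Each trial has two stages.  At the patch stage the participant sees a
travel cost and decides whether to stay in the currently occupied patch or
to leave for the alternative at that cost.  Patch reward follows a decaying
Gaussian random walk: the occupied patch depletes towards a low decay
centre while the alternative replenishes towards a high one,

    mu[t+1] = lambda * mu[t] + (1 - lambda) * kappa + eps,

with eps ~ Normal(0, mean_noise_sd**2) drawn independently per patch.  The
displayed patch values are Gaussian draws around these latent means,
clamped to a fixed interval and rounded to integer points.  At the value
stage the chosen patch's value is split between two options at a random
unequal ratio, each option receives an independent reward probability from
a discrete set, and the participant picks one; both options are then
resolved by independent Bernoulli draws.

The latent mean recursion itself is never clamped; only the sampled values
are, which keeps the recursion an exact AR(1) process with fixed point
kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol

import numpy as np

__all__ = [
    "PatchDynamicsParams",
    "OptionPair",
    "TrialRecord",
    "Agent",
    "update_patch_means",
    "iterate_mean",
    "sample_patch_values",
    "draw_cost",
    "generate_options",
    "detect_no_brainer",
    "apply_flip_rule",
    "simulate_session",
]

PROBABILITY_SET = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class PatchDynamicsParams:
    """Parameters of the patch reward dynamics and trial structure.

    Defaults are the task's original settings: decay rate 0.96, decay
    centres 1 (occupied) and 100 (alternative), mean noise SD 1.2 points,
    value variance 3.5 points^2, values clamped to [10, 90], initial means
    50, travel costs drawn from {5, 10, 15, 20}, 320 trials.
    """

    lambda_decay: float = 0.96
    kappa_chosen: float = 1.0
    kappa_unchosen: float = 100.0
    mean_noise_sd: float = 1.2
    value_variance: float = 3.5
    value_min: float = 10.0
    value_max: float = 90.0
    initial_mean: float = 50.0
    cost_set: tuple = (5, 10, 15, 20)
    n_trials: int = 320
    integer_values: bool = True

    def validate(self) -> None:
        if not 0.0 < self.lambda_decay < 1.0:
            raise ValueError("lambda_decay must lie in (0, 1)")
        if not self.value_min < self.value_max:
            raise ValueError("value_min must be below value_max")
        if any(c <= 0 for c in self.cost_set):
            raise ValueError("all travel costs must be positive")
        if self.mean_noise_sd < 0 or self.value_variance < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


@dataclass
class OptionPair:
    """A value-stage option pair: magnitudes summing to the patch value,
    probabilities from the discrete set {0.1, ..., 0.9}."""

    m_left: float
    m_right: float
    p_left: float
    p_right: float
    no_brainer: str | None = None  # 'left', 'right', or None
    flipped: bool = False


@dataclass
class TrialRecord:
    """One task trial: patch state, patch choice, option pair, value
    choice, outcomes, and response times."""

    trial_index: int
    mu_current: float
    mu_alternative: float
    value_current: float
    value_alternative: float
    cost: float
    side_current: str  # 'left' or 'right' screen placement of current patch
    patch_choice: str  # 'stay' or 'leave'
    switch_trial: bool
    pla: float  # (prev alt value - prev current value) - cost
    options: OptionPair
    value_choice: str  # 'left' or 'right'
    rewarded_left: bool
    rewarded_right: bool
    reward_obtained: float
    rt_patch: float = float("nan")
    rt_value: float = float("nan")


class Agent(Protocol):
    """Choice policies consumed by :func:`simulate_session`."""

    def choose_patch(self, pla: float, rng: np.random.Generator) -> str: ...

    def choose_value(self, options: OptionPair, rng: np.random.Generator) -> str: ...


def _check_finite(**named: float) -> None:
    for name, value in named.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


def update_patch_means(
    mu_current: float,
    mu_alternative: float,
    params: PatchDynamicsParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Advance both latent patch means one step of the decaying random walk.

    The occupied patch decays towards ``kappa_chosen``, the alternative
    towards ``kappa_unchosen``; noise is drawn independently per patch.
    The recursion is not clamped.
    """
    params.validate()
    _check_finite(mu_current=mu_current, mu_alternative=mu_alternative)
    lam = params.lambda_decay
    eps = rng.normal(0.0, params.mean_noise_sd, size=2)
    new_cur = lam * mu_current + (1.0 - lam) * params.kappa_chosen + eps[0]
    new_alt = lam * mu_alternative + (1.0 - lam) * params.kappa_unchosen + eps[1]
    return new_cur, new_alt


def iterate_mean(
    mu0: float,
    kappa: float,
    n_steps: int,
    params: PatchDynamicsParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Iterate the unclamped mean recursion for one patch, returning the
    full trajectory (length ``n_steps + 1``, starting at ``mu0``)."""
    params.validate()
    lam = params.lambda_decay
    drift = (1.0 - lam) * kappa
    eps = rng.normal(0.0, params.mean_noise_sd, size=n_steps)
    out = np.empty(n_steps + 1)
    out[0] = mu0
    mu = mu0
    for t in range(n_steps):
        mu = lam * mu + drift + eps[t]
        out[t + 1] = mu
    return out


def sample_patch_values(
    mu_current: float,
    mu_alternative: float,
    params: PatchDynamicsParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw the displayed patch values around the latent means.

    Values are Normal(mu, value_variance), clamped into
    [value_min, value_max], and rounded to integer points by default.
    """
    params.validate()
    _check_finite(mu_current=mu_current, mu_alternative=mu_alternative)
    sd = math.sqrt(params.value_variance)
    vals = rng.normal([mu_current, mu_alternative], sd)
    vals = np.clip(vals, params.value_min, params.value_max)
    if params.integer_values:
        vals = np.rint(vals)
    return float(vals[0]), float(vals[1])


def draw_cost(
    previous_cost: float | None,
    previous_was_leave: bool,
    params: PatchDynamicsParams,
    rng: np.random.Generator,
) -> float:
    """Travel cost for the upcoming trial.

    The cost persists across stay trials; a new cost is drawn uniformly
    from the cost set only after a leave (or at session start, signalled by
    ``previous_cost is None``).
    """
    params.validate()
    if previous_cost is None or previous_was_leave:
        return float(rng.choice(params.cost_set))
    if previous_cost not in params.cost_set:
        raise ValueError(f"previous_cost {previous_cost} not in cost set {params.cost_set}")
    return float(previous_cost)


def detect_no_brainer(options: OptionPair) -> str | None:
    """Return the side strictly dominating on both magnitude and
    probability, or None.  Ties on either attribute are not dominance."""
    if options.m_left > options.m_right and options.p_left > options.p_right:
        return "left"
    if options.m_right > options.m_left and options.p_right > options.p_left:
        return "right"
    return None


def generate_options(
    patch_value: float,
    rng: np.random.Generator,
    *,
    replicate_side_bias_bug: bool = True,
    apply_flip: bool = True,
) -> OptionPair:
    """Split the chosen patch's value into a value-stage option pair.

    The left magnitude is drawn uniformly from the integer shares giving
    each option at least 10% of the patch value, excluding an exact 50/50
    split; probabilities are drawn independently from {0.1, ..., 0.9}.
    The dominance flag is evaluated and, when ``apply_flip`` is set, the
    50% magnitude-flip rule is applied (see :func:`apply_flip_rule`).
    """
    v = int(round(patch_value))
    lo = math.ceil(0.1 * v)
    hi = math.floor(0.9 * v)
    shares = [s for s in range(lo, hi + 1) if 2 * s != v]
    if not shares:
        raise ValueError(
            f"patch value {patch_value} admits no split with both options >=10% "
            "of the total and no 50% split"
        )
    m_left = int(rng.choice(shares))
    m_right = v - m_left
    p_left, p_right = rng.choice(PROBABILITY_SET, size=2)
    options = OptionPair(
        m_left=float(m_left),
        m_right=float(m_right),
        p_left=float(p_left),
        p_right=float(p_right),
    )
    options.no_brainer = detect_no_brainer(options)
    if apply_flip:
        options = apply_flip_rule(
            options, rng, replicate_side_bias_bug=replicate_side_bias_bug
        )
    return options


def apply_flip_rule(
    options: OptionPair,
    rng: np.random.Generator,
    *,
    replicate_side_bias_bug: bool = True,
) -> OptionPair:
    """Flip the magnitudes of a dominance ("no-brainer") pair in 50% of cases.

    The original experiment intended to flip magnitudes on half the
    dominance trials to control difficulty, but a coding error restricted
    the flip to trials where the *left* option dominated, making
    right-dominant pairs over-represented.  With
    ``replicate_side_bias_bug=True`` (default) that asymmetry is
    reproduced; with the flag off both sides are eligible.  Flipping swaps
    the magnitudes, re-evaluates dominance, and sets ``flipped``.
    """
    if options.no_brainer is None:
        return options
    eligible = (
        options.no_brainer == "left" if replicate_side_bias_bug else True
    )
    if not eligible or rng.random() >= 0.5:
        return options
    flipped = replace(
        options,
        m_left=options.m_right,
        m_right=options.m_left,
        flipped=True,
    )
    flipped.no_brainer = detect_no_brainer(flipped)
    return flipped


def simulate_session(
    agent: Agent,
    params: PatchDynamicsParams | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    replicate_side_bias_bug: bool = True,
) -> list[TrialRecord]:
    """Simulate one full session of the two-stage task.

    Per-trial order: the travel cost is shown, the agent makes the patch
    choice based on the previous trial's patch values and the current cost
    (on a leave the patches swap roles and the cost is paid), both latent
    means advance one random-walk step, the new patch values are revealed,
    the chosen patch's value is split into an option pair, the agent makes
    the value choice, and both options are resolved by independent
    Bernoulli draws.  Screen sides of the patches are re-randomized every
    trial.  Response-time fields are left NaN; generative agents attach
    them afterwards (see :mod:`patchforage.agents`).
    """
    if params is None:
        params = PatchDynamicsParams()
    params.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    mu_cur = params.initial_mean
    mu_alt = params.initial_mean
    # values "seen" before the first trial: the initial means
    prev_val_cur = params.initial_mean
    prev_val_alt = params.initial_mean
    cost: float | None = None
    prev_was_leave = False
    records: list[TrialRecord] = []

    for t in range(params.n_trials):
        cost = draw_cost(cost, prev_was_leave, params, rng)
        side_cur = "left" if rng.random() < 0.5 else "right"

        pla = (prev_val_alt - prev_val_cur) - cost
        choice = agent.choose_patch(pla, rng)
        if choice not in ("stay", "leave"):
            raise ValueError(
                f"agent returned illegal patch action {choice!r} on trial {t}"
            )
        leave = choice == "leave"
        if leave:
            mu_cur, mu_alt = mu_alt, mu_cur
            prev_val_cur, prev_val_alt = prev_val_alt, prev_val_cur

        mu_cur, mu_alt = update_patch_means(mu_cur, mu_alt, params, rng)
        val_cur, val_alt = sample_patch_values(mu_cur, mu_alt, params, rng)

        options = generate_options(
            val_cur, rng, replicate_side_bias_bug=replicate_side_bias_bug
        )
        vchoice = agent.choose_value(options, rng)
        if vchoice not in ("left", "right"):
            raise ValueError(
                f"agent returned illegal value action {vchoice!r} on trial {t}"
            )
        rew_left = bool(rng.random() < options.p_left)
        rew_right = bool(rng.random() < options.p_right)
        if vchoice == "left":
            reward = options.m_left if rew_left else 0.0
        else:
            reward = options.m_right if rew_right else 0.0

        records.append(
            TrialRecord(
                trial_index=t,
                mu_current=mu_cur,
                mu_alternative=mu_alt,
                value_current=val_cur,
                value_alternative=val_alt,
                cost=cost,
                side_current=side_cur,
                patch_choice=choice,
                switch_trial=leave,
                pla=pla,
                options=options,
                value_choice=vchoice,
                rewarded_left=rew_left,
                rewarded_right=rew_right,
                reward_obtained=reward,
            )
        )
        prev_val_cur, prev_val_alt = val_cur, val_alt
        prev_was_leave = leave

    return records
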