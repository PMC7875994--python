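"""Subjective-value models of the probabilistic choice stage.

Each option carries a reward magnitude m and probability p.  Subjective
distortions are a one-parameter probability weighting

    w(p) = p**gamma / (p**gamma + (1 - p)**gamma) ** (1 / gamma)

and a power utility u(m) = m**alpha.  Families differ in how u and w are
combined into an option value V:

    additive        V = omega_m * u(m) + omega_p * w(p)
    multiplicative  V = omega_mult * u(m) * w(p)
    hybrid          a normalized mixture of the two, scaled by
                    omega_sum = omega_m + omega_p + omega_mult

Within each family the distortion variant fixes parameters: EV (alpha =
gamma = 1), EU (gamma = 1), EVPW (alpha = 1), SU (both free).  Choice
probabilities follow a unit-temperature softmax on the value difference;
the omega weights absorb the choice-stochasticity scale, and the
multiplicative weight is conventionally fixed at 6.62 when fitting,
because it trades off against the distortion parameters and does not
recover well as a free parameter.

Fitting is constrained multi-start maximum likelihood: uniform random
starting points within box bounds, a local constrained optimizer from each
start, and the lowest negative log-likelihood solution retained.  Models
are compared by BIC = k*ln(n) + 2*NLL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ValueModelParams",
    "ValueModelSpec",
    "FitResult",
    "rescale_magnitudes",
    "weight_probability",
    "utility",
    "option_value",
    "choice_probability",
    "prepare_choice_data",
    "negative_log_likelihood",
    "simulate_choices",
    "fit_model",
    "compare_models_bic",
    "recover_parameters",
]

DEFAULT_OMEGA_MULT = 6.62
LIKELIHOOD_FLOOR = 1e-12
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.05, 5.0),
    "gamma": (0.05, 5.0),
    "omega_m": (0.0, 50.0),
    "omega_p": (0.0, 50.0),
    "omega_mult": (0.0, 50.0),
}

_FAMILIES = ("additive", "multiplicative", "hybrid")
_DISTORTIONS = ("EV", "EU", "EVPW", "SU")


@dataclass
class ValueModelParams:
    """Parameter vector of the value-model family."""

    alpha: float = 1.0
    gamma: float = 1.0
    omega_m: float = 1.0
    omega_p: float = 1.0
    omega_mult: float = 1.0

    @property
    def omega_sum(self) -> float:
        return self.omega_m + self.omega_p + self.omega_mult


@dataclass
class ValueModelSpec:
    """A concrete model: family, distortion variant, fixed parameters,
    per-parameter bounds, and number of optimizer starts."""

    family: str = "multiplicative"
    distortion: str = "SU"
    fixed: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 1000

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.distortion not in _DISTORTIONS:
            raise ValueError(f"unknown distortion {self.distortion!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    @classmethod
    def su_multiplicative(
        cls, omega_mult: float = DEFAULT_OMEGA_MULT, n_starts: int = 1000
    ) -> "ValueModelSpec":
        """The winning configuration: multiplicative SU with the softmax
        scale fixed, leaving alpha and gamma free."""
        return cls(
            family="multiplicative",
            distortion="SU",
            fixed={"omega_mult": omega_mult},
            n_starts=n_starts,
        )

    @property
    def free_parameters(self) -> list[str]:
        names: list[str] = []
        if self.distortion in ("EU", "SU"):
            names.append("alpha")
        if self.distortion in ("EVPW", "SU"):
            names.append("gamma")
        if self.family in ("additive", "hybrid"):
            names += ["omega_m", "omega_p"]
        if self.family in ("multiplicative", "hybrid"):
            names.append("omega_mult")
        return [n for n in names if n not in self.fixed]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    def make_params(self, free_values: Sequence[float] = ()) -> ValueModelParams:
        """Assemble a full parameter set from free values in the order of
        :attr:`free_parameters`, applying variant and fixed constraints."""
        p = ValueModelParams()
        if self.family == "additive":
            p.omega_mult = 0.0
        if self.family == "multiplicative":
            p.omega_m = 0.0
            p.omega_p = 0.0
        for name, value in self.fixed.items():
            setattr(p, name, float(value))
        free = self.free_parameters
        if len(free_values) != len(free):
            raise ValueError(
                f"expected {len(free)} free values {free}, got {len(free_values)}"
            )
        for name, value in zip(free, free_values):
            setattr(p, name, float(value))
        return p


@dataclass
class FitResult:
    """Best multi-start solution with diagnostics."""

    spec: ValueModelSpec
    params: ValueModelParams
    nll: float
    bic: float
    n_trials: int
    start_nlls: np.ndarray
    converged: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        assert np.isclose(self.nll, float(np.nanmin(self.start_nlls)))


def rescale_magnitudes(magnitudes, lo: float = 1.0, hi: float = 10.0) -> np.ndarray:
    """Linearly map a magnitude vector so its min -> 1 and max -> 10."""
    m = np.asarray(magnitudes, dtype=float)
    if m.size == 0:
        raise ValueError("empty magnitude vector")
    mmin, mmax = float(np.min(m)), float(np.max(m))
    if mmax == mmin:
        raise ValueError("cannot rescale a constant magnitude vector")
    return lo + (hi - lo) * (m - mmin) / (mmax - mmin)


def weight_probability(p, gamma: float):
    """One-parameter probability weighting; identity at gamma = 1."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pg = p**gamma
    qg = (1.0 - p) ** gamma
    out = pg / (pg + qg) ** (1.0 / gamma)
    return out if out.ndim else float(out)


def utility(m, alpha: float):
    """Power utility of (rescaled) magnitudes."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("magnitudes must be non-negative")
    out = m**alpha
    return out if out.ndim else float(out)


def option_value(m, p, params: ValueModelParams, spec: ValueModelSpec):
    """Subjective value V of an option under the spec's family."""
    u = utility(m, params.alpha)
    w = weight_probability(p, params.gamma)
    if spec.family == "additive":
        return params.omega_m * u + params.omega_p * w
    if spec.family == "multiplicative":
        return params.omega_mult * u * w
    # hybrid: normalized mixture of additive and multiplicative parts
    w_add = params.omega_m + params.omega_p
    if w_add == 0:
        raise ValueError("hybrid model requires omega_m + omega_p > 0")
    w_sum = params.omega_sum
    mix = params.omega_mult / w_sum
    additive_part = (params.omega_m / w_add) * u + (params.omega_p / w_add) * w
    return w_sum * ((1.0 - mix) * additive_part + mix * (u * w))


def choice_probability(v_left, v_right):
    """P(choose right) under a unit-temperature softmax on V_right - V_left."""
    return special.expit(np.asarray(v_right, dtype=float) - np.asarray(v_left, dtype=float))


def prepare_choice_data(trials: pd.DataFrame, rescale: str = "participant") -> pd.DataFrame:
    """Build the fitting frame from a trial table.

    Magnitudes of both options are pooled and rescaled to [1, 10] before
    fitting; ``rescale='participant'`` (default) maps the participant's own
    min/max, ``rescale='global'`` uses the task's theoretical magnitude
    range [1, 81].  The returned frame has columns ``m_left``, ``m_right``
    (rescaled), ``p_left``, ``p_right``, and ``choice_right``.
    """
    required = {"m_left", "m_right", "p_left", "p_right", "value_choice"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    pooled = np.concatenate([trials["m_left"].to_numpy(float), trials["m_right"].to_numpy(float)])
    if rescale == "participant":
        lo_src, hi_src = float(pooled.min()), float(pooled.max())
    elif rescale == "global":
        lo_src, hi_src = 1.0, 81.0
    else:
        raise ValueError(f"unknown rescale mode {rescale!r}")
    if hi_src == lo_src:
        raise ValueError("cannot rescale a constant magnitude vector")

    def _map(x: np.ndarray) -> np.ndarray:
        return 1.0 + 9.0 * (x - lo_src) / (hi_src - lo_src)

    return pd.DataFrame(
        {
            "m_left": _map(trials["m_left"].to_numpy(float)),
            "m_right": _map(trials["m_right"].to_numpy(float)),
            "p_left": trials["p_left"].to_numpy(float),
            "p_right": trials["p_right"].to_numpy(float),
            "choice_right": (trials["value_choice"].astype(str) == "right").astype(int),
        }
    )


def negative_log_likelihood(
    data: pd.DataFrame, params: ValueModelParams, spec: ValueModelSpec
) -> float:
    """-sum log P(observed choice); per-trial probabilities floored at
    1e-12 so the objective stays finite at extreme parameters."""
    if len(data) == 0:
        raise ValueError("empty trial set")
    v_l = option_value(data["m_left"].to_numpy(), data["p_left"].to_numpy(), params, spec)
    v_r = option_value(data["m_right"].to_numpy(), data["p_right"].to_numpy(), params, spec)
    p_right = choice_probability(v_l, v_r)
    y = data["choice_right"].to_numpy()
    p_obs = np.where(y == 1, p_right, 1.0 - p_right)
    return float(-np.sum(np.log(np.maximum(p_obs, LIKELIHOOD_FLOOR))))


def simulate_choices(
    data: pd.DataFrame,
    params: ValueModelParams,
    spec: ValueModelSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample binary right-choices from the model's softmax probabilities."""
    v_l = option_value(data["m_left"].to_numpy(), data["p_left"].to_numpy(), params, spec)
    v_r = option_value(data["m_right"].to_numpy(), data["p_right"].to_numpy(), params, spec)
    return (rng.random(len(data)) < choice_probability(v_l, v_r)).astype(int)


def fit_model(
    data: pd.DataFrame,
    spec: ValueModelSpec,
    seed: int | np.random.Generator | None = None,
) -> FitResult:
    """Constrained multi-start maximum-likelihood fit.

    Starting points are uniform draws within the per-parameter bounds;
    each is refined with L-BFGS-B under the same bounds, and the lowest
    NLL over starts is returned.  Deterministic given the seed.
    """
    if len(data) == 0:
        raise ValueError("empty trial set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    free = spec.free_parameters
    n = len(data)

    if not free:
        params = spec.make_params()
        nll = negative_log_likelihood(data, params, spec)
        return FitResult(
            spec=spec,
            params=params,
            nll=nll,
            bic=2.0 * nll,
            n_trials=n,
            start_nlls=np.array([nll]),
            converged=np.array([True]),
            seed=seed if isinstance(seed, int) else None,
        )

    bounds = [spec.bounds[name] for name in free]

    def objective(x: np.ndarray) -> float:
        try:
            return negative_log_likelihood(data, spec.make_params(x), spec)
        except (ValueError, FloatingPointError):
            return np.inf

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = rng.uniform(lo, hi, size=(spec.n_starts, len(free)))

    start_nlls = np.full(spec.n_starts, np.nan)
    converged = np.zeros(spec.n_starts, dtype=bool)
    best_x: np.ndarray | None = None
    best_nll = np.inf
    for i, x0 in enumerate(starts):
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        start_nlls[i] = res.fun
        converged[i] = bool(res.success)
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_x = res.x
    if best_x is None:
        raise RuntimeError(
            f"all {spec.n_starts} optimizer starts failed for {spec.family}/{spec.distortion}"
        )
    k = len(free)
    bic = k * math.log(n) + 2.0 * best_nll
    return FitResult(
        spec=spec,
        params=spec.make_params(best_x),
        nll=best_nll,
        bic=bic,
        n_trials=n,
        start_nlls=start_nlls,
        converged=converged,
        seed=seed if isinstance(seed, int) else None,
    )


def compare_models_bic(fits: Sequence[FitResult]) -> dict:
    """Rank fits on the same data by BIC (ties broken toward fewer free
    parameters); returns the ranking and the winner."""
    if not fits:
        raise ValueError("no fits to compare")
    n_set = {f.n_trials for f in fits}
    if len(n_set) > 1:
        raise ValueError(f"fits cover different trial counts: {sorted(n_set)}")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].bic, fits[i].spec.n_free))
    ranking = [
        {
            "family": fits[i].spec.family,
            "distortion": fits[i].spec.distortion,
            "k": fits[i].spec.n_free,
            "nll": fits[i].nll,
            "bic": fits[i].bic,
        }
        for i in order
    ]
    return {"ranking": ranking, "winner": fits[order[0]], "winner_index": order[0]}


def recover_parameters(
    spec: ValueModelSpec,
    n_sets: int,
    trials_template: pd.DataFrame,
    seed: int | None = None,
    *,
    true_sampler=None,
) -> dict:
    """Parameter-recovery study for one model.

    For each of ``n_sets`` random true parameter vectors (uniform within
    bounds unless ``true_sampler(rng)`` is supplied), choices are simulated
    on the template trials, the model is refit, and true vs recovered
    values are recorded; per-parameter Pearson correlations summarize
    recoverability.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    free = spec.free_parameters
    rows = []
    for i in range(n_sets):
        if true_sampler is None:
            truth = [rng.uniform(*spec.bounds[name]) for name in free]
        else:
            truth = true_sampler(rng)
        true_params = spec.make_params(truth)
        sim = trials_template.copy()
        sim["choice_right"] = simulate_choices(sim, true_params, spec, rng)
        fit = fit_model(sim, spec, rng)
        row = {"set": i}
        for name, t in zip(free, truth):
            row[f"true_{name}"] = t
            row[f"recovered_{name}"] = getattr(fit.params, name)
        rows.append(row)
    table = pd.DataFrame(rows)
    correlations = {}
    for name in free:
        if n_sets >= 3:
            r, _ = stats.pearsonr(table[f"true_{name}"], table[f"recovered_{name}"])
        else:
            r = np.nan
        correlations[name] = float(r)
    return {"table": table, "correlations": correlations}
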