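"""Generative models of canalized (targeted) growth.

Individual development is modelled as fluctuation around an unobserved,
individual-specific target trajectory (Waddington's "chreod").  In continuous
time this is a mean-reverting Ornstein-Uhlenbeck process; at discrete
observation ages it becomes an autoregressive process of order 1 whose
reversion coefficient theta is the *strength of canalization*: the fraction
of the current deviation from the target removed per time step.

The population simulator extends this with time-varying target trajectories:
the chreod of each individual evolves by a shared deterministic growth
increment, an individual "deterministic" innovation g_t (newly expressed
gene effects), and a divergence term zeta_t * mu_t that makes existing
trajectory differences grow or shrink.  Observed values add measurement
error on top of the true trait.  All simulators return the latent truth so
estimators can be validated against the generating process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_ou",
    "simulate_population",
    "simulate_multivariate_population",
    "simulate_timing_variation",
    "simulate_landmark_growth",
]


def _per_step(value, n_steps: int, name: str) -> np.ndarray:
    """Broadcast a scalar or sequence to one value per age step."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_steps, float(arr))
    if arr.shape != (n_steps,):
        raise ValueError(
            f"{name} must be scalar or length {n_steps}, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def _per_step_matrix(value, n_steps: int, p: int, name: str) -> np.ndarray:
    """Broadcast scalar / p-vector / p x p matrix / per-step stack to (n_steps, p, p)."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.eye(p) * float(arr)
    if arr.ndim == 1:
        if arr.shape != (p,):
            raise ValueError(f"{name}: vector form must have length {p}")
        arr = np.diag(arr)
    if arr.ndim == 2:
        if arr.shape != (p, p):
            raise ValueError(f"{name}: matrix form must be {p}x{p}, got {arr.shape}")
        arr = np.broadcast_to(arr, (n_steps, p, p)).copy()
    if arr.shape != (n_steps, p, p):
        raise ValueError(f"{name}: per-step form must be ({n_steps},{p},{p})")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of the canalized-growth population simulator.

    Parameters
    ----------
    n_individuals : int
        Number of simulated individuals.
    ages : sequence of float
        Strictly increasing observation ages (years).
    theta_t : float or sequence
        Strength of canalization per age step (scalar, per-step vector, or a
        p x p matrix / per-step stack of matrices in the multivariate case).
        theta = 1 reverts the full deviation in one step; 1 < theta < 2
        overshoots (damped oscillation); theta = 0 is a random walk.
    zeta_t : float or sequence
        Divergence coefficient of target trajectories per step; positive
        values make existing chreod differences grow.
    var_g_t : float or sequence
        Variance of newly arising deterministic (chreod) innovations per step.
    var_eps_t : float or sequence
        Variance of stochastic developmental perturbations per step
        (covariance matrix per step in the multivariate case).
    var_eta : float
        Measurement-error variance (per trait).
    mu0_mean, var_mu0 : float
        Mean and between-individual variance of the initial chreod value.
    var_d0 : float
        Variance of the initial deviation from the chreod (default 0:
        individuals start exactly on their target trajectory).
    baseline_growth : float or sequence
        Shared deterministic growth increment per step (shifts the mean
        trajectory without adding variance).
    n_groups : int
        Number of groups (e.g. sexes); individuals are split evenly.
    group_offset_t : float or sequence
        Per-step chreod increment added to group 1 and subtracted from
        group 0 (and alternating for further groups), producing diverging
        group means such as sexual dimorphism.
    seed : int or None
        Seed for the single generator driving all draws.
    """

    n_individuals: int
    ages: Sequence[float]
    theta_t: float | Sequence = 0.5
    zeta_t: float | Sequence = 0.0
    var_g_t: float | Sequence = 0.0
    var_eps_t: float | Sequence = 1.0
    var_eta: float = 0.0
    mu0_mean: float = 0.0
    var_mu0: float = 0.0
    var_d0: float = 0.0
    baseline_growth: float | Sequence = 0.0
    n_groups: int = 1
    group_offset_t: float | Sequence = 0.0
    seed: int | None = None
    trait_names: Sequence[str] = field(default_factory=lambda: ["trait"])

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.ndim != 1 or len(self.ages) < 2:
            raise ValueError("ages must be a 1-d grid with at least 2 entries")
        if not np.all(np.isfinite(self.ages)) or np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be finite and strictly increasing")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("var_eta", "var_mu0", "var_d0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")

    @property
    def n_steps(self) -> int:
        return len(self.ages) - 1


@dataclass
class SimulationTruth:
    """Latent state of a simulated population.

    Arrays are (n_individuals, n_ages) univariate or
    (n_individuals, n_ages, p) multivariate.  ``x_true = mu + d`` exactly;
    ``x_obs = x_true + eta`` with independent measurement error eta.
    """

    ages: np.ndarray
    mu: np.ndarray          # chreod value per individual per age
    d: np.ndarray           # deviation from the chreod
    c: np.ndarray           # chreod increments per step
    x_true: np.ndarray
    x_obs: np.ndarray
    group: np.ndarray       # group label per individual
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of the latent truth (univariate only)."""
        if self.mu.ndim != 2:
            raise NotImplementedError("to_frame supports univariate truth only")
        n, T = self.mu.shape
        return pd.DataFrame(
            {
                "individual_id": np.repeat([f"ind{i:04d}" for i in range(n)], T),
                "age": np.tile(self.ages, n),
                "mu": self.mu.ravel(),
                "d": self.d.ravel(),
                "x_true": self.x_true.ravel(),
                "x_obs": self.x_obs.ravel(),
            }
        )


def _dataset_from_matrix(
    x_obs: np.ndarray, ages: np.ndarray, group: np.ndarray, trait_names
) -> pd.DataFrame:
    """Long-format records `individual_id,group,age,trait,value`."""
    if x_obs.ndim == 2:
        x_obs = x_obs[:, :, None]
    n, T, p = x_obs.shape
    ids = [f"ind{i:04d}" for i in range(n)]
    frames = []
    for j in range(p):
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": np.repeat(ids, T),
                    "group": np.repeat(group, T),
                    "age": np.tile(ages, n),
                    "trait": trait_names[j],
                    "value": x_obs[:, :, j].ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_ou(
    theta_ou: float,
    mu_ou: float,
    sigma: float,
    x0: float,
    times: Sequence[float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample an Ornstein-Uhlenbeck path by exact discretization.

    The process dx = -theta (x - mu) dt + sigma dW is sampled exactly at the
    given times: between consecutive times the conditional distribution is
    Gaussian with mean mu + (x - mu) exp(-theta dt) and variance
    sigma^2/(2 theta) (1 - exp(-2 theta dt)), so the step size never biases
    the path.  The stationary variance is sigma^2 / (2 theta).

    Parameters
    ----------
    theta_ou : float
        Mean-reversion strength; must be > 0.
    mu_ou : float
        Long-run mean (the target value).
    sigma : float
        Diffusion coefficient; sigma = 0 gives deterministic exponential
        decay toward ``mu_ou``.
    x0 : float
        Value at ``times[0]``.
    times : sequence of float
        Strictly increasing observation times.

    Returns
    -------
    ndarray of shape (len(times),)
    """
    if theta_ou <= 0:
        raise ValueError("theta_ou must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("times must be a 1-d array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(seed)

    x = np.empty(len(times))
    x[0] = x0
    dts = np.diff(times)
    decay = np.exp(-theta_ou * dts)
    sd = np.sqrt(sigma**2 / (2 * theta_ou) * (1 - decay**2))
    shocks = rng.standard_normal(len(dts)) * sd
    for i in range(len(dts)):
        x[i + 1] = mu_ou + (x[i] - mu_ou) * decay[i] + shocks[i]
    return x


def _groups(n: int, n_groups: int) -> np.ndarray:
    return np.arange(n) % n_groups


def _group_sign(group: np.ndarray) -> np.ndarray:
    # alternate -1, +1, -1, ... so the grand mean is (nearly) unshifted
    return np.where(group % 2 == 0, -1.0, 1.0)


def simulate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a univariate longitudinal population under canalized growth.

    Per individual the chreod evolves as

        mu_{t+1} = mu_t + baseline_growth_t + g_t + zeta_t * mu_t  (+ group offset)

    with g_t ~ Normal(0, var_g_t), and the deviation from the chreod as

        d_{t+1} = (1 - theta_t) d_t + eps_t,   eps_t ~ Normal(0, var_eps_t).

    The observed value is mu + d + eta with measurement error
    eta ~ Normal(0, var_eta), drawn independently at every age.

    Returns
    -------
    (dataset, truth)
        ``dataset`` is a long-format DataFrame with columns
        ``individual_id, group, age, trait, value`` (the observed values);
        ``truth`` retains the latent trajectories and the config.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_individuals, len(cfg.ages)
    S = cfg.n_steps
    theta = _per_step(cfg.theta_t, S, "theta_t")
    zeta = _per_step(cfg.zeta_t, S, "zeta_t")
    var_g = _per_step(cfg.var_g_t, S, "var_g_t")
    var_eps = _per_step(cfg.var_eps_t, S, "var_eps_t")
    growth = _per_step(cfg.baseline_growth, S, "baseline_growth")
    offset = _per_step(cfg.group_offset_t, S, "group_offset_t")
    if np.any(var_g < 0) or np.any(var_eps < 0):
        raise ValueError("variances must be >= 0")

    group = _groups(n, cfg.n_groups)
    sign = _group_sign(group)

    mu = np.empty((n, T))
    d = np.empty((n, T))
    c = np.zeros((n, S))
    mu[:, 0] = cfg.mu0_mean + np.sqrt(cfg.var_mu0) * rng.standard_normal(n)
    d[:, 0] = np.sqrt(cfg.var_d0) * rng.standard_normal(n)
    for t in range(S):
        g = np.sqrt(var_g[t]) * rng.standard_normal(n)
        eps = np.sqrt(var_eps[t]) * rng.standard_normal(n)
        c[:, t] = growth[t] + g + zeta[t] * mu[:, t] + sign * offset[t]
        mu[:, t + 1] = mu[:, t] + c[:, t]
        d[:, t + 1] = (1 - theta[t]) * d[:, t] + eps

    x_true = mu + d
    eta = np.sqrt(cfg.var_eta) * rng.standard_normal((n, T))
    x_obs = x_true + eta

    truth = SimulationTruth(
        ages=np.asarray(cfg.ages), mu=mu, d=d, c=c,
        x_true=x_true, x_obs=x_obs, group=group, config=cfg,
    )
    dataset = _dataset_from_matrix(x_obs, truth.ages, group, list(cfg.trait_names))
    return dataset, truth


def simulate_multivariate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a p-variate population with a canalization/compensation matrix.

    The deviation (row) vector of each individual updates as

        d_{t+1} = d_t - d_t @ Theta_t + eps_t,

    so the diagonal entries of Theta are per-trait canalization strengths and
    the off-diagonal entry Theta[i, j] is the strength by which a deviation
    in trait i induces compensating change in trait j.  ``var_eps_t`` may be
    a scalar (isotropic), a p-vector of variances, or a full covariance
    matrix (optionally per step).

    Returns (dataset, truth) as :func:`simulate_population`, with trait arrays
    of shape (n, n_ages, p).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p = len(cfg.trait_names)
    if p < 1:
        raise ValueError("trait_names must name at least one trait")
    n, T, S = cfg.n_individuals, len(cfg.ages), cfg.n_steps
    theta = _per_step_matrix(cfg.theta_t, S, p, "theta_t")

    eps_cov = np.asarray(cfg.var_eps_t, dtype=float)
    if eps_cov.ndim == 0:
        eps_cov = np.eye(p) * float(eps_cov)
    elif eps_cov.ndim == 1:
        eps_cov = np.diag(eps_cov)
    if eps_cov.ndim == 2:
        eps_cov = np.broadcast_to(eps_cov, (S, p, p)).copy()
    if eps_cov.shape != (S, p, p):
        raise ValueError("var_eps_t must be scalar, p-vector, pxp, or per-step stack")

    zeta = _per_step(cfg.zeta_t, S, "zeta_t")
    var_g = _per_step(cfg.var_g_t, S, "var_g_t")
    growth = _per_step(cfg.baseline_growth, S, "baseline_growth")

    group = _groups(n, cfg.n_groups)

    mu = np.empty((n, T, p))
    d = np.empty((n, T, p))
    c = np.zeros((n, S, p))
    mu[:, 0, :] = cfg.mu0_mean + np.sqrt(cfg.var_mu0) * rng.standard_normal((n, p))
    d[:, 0, :] = np.sqrt(cfg.var_d0) * rng.standard_normal((n, p))
    eye = np.eye(p)
    for t in range(S):
        g = np.sqrt(var_g[t]) * rng.standard_normal((n, p))
        eps = rng.multivariate_normal(np.zeros(p), eps_cov[t], size=n,
                                      method="cholesky" if _is_posdef(eps_cov[t]) else "svd")
        c[:, t, :] = growth[t] + g + zeta[t] * mu[:, t, :]
        mu[:, t + 1, :] = mu[:, t, :] + c[:, t, :]
        d[:, t + 1, :] = d[:, t, :] @ (eye - theta[t]) + eps

    x_true = mu + d
    eta = np.sqrt(cfg.var_eta) * rng.standard_normal((n, T, p))
    x_obs = x_true + eta

    truth = SimulationTruth(
        ages=np.asarray(cfg.ages), mu=mu, d=d, c=c,
        x_true=x_true, x_obs=x_obs, group=group, config=cfg,
    )
    dataset = _dataset_from_matrix(x_obs, truth.ages, group, list(cfg.trait_names))
    return dataset, truth


def _is_posdef(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def simulate_timing_variation(
    curve_params: dict,
    onset_sd: float,
    n: int,
    ages: Sequence[float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Growth curves of identical shape with individually shifted spurt onset.

    Each individual follows the same location-shifted logistic growth curve

        x(a) = baseline + amplitude / (1 + exp(-(a - onset_i) / scale)),

    with onset_i ~ Normal(mean_onset, onset_sd).  Variation purely in the
    timing of the growth spurt makes cross-sectional variance rise while the
    spurts are under way and fall again once all individuals have completed
    them — a statistical signal that mimics canalization without any
    mean-reverting mechanism.

    Parameters
    ----------
    curve_params : dict
        Keys ``amplitude``, ``mean_onset``, ``scale`` and optional
        ``baseline`` (default 0).
    onset_sd : float
        Standard deviation of the onset shift (years); must be >= 0.

    Returns
    -------
    Long-format DataFrame ``individual_id, group, age, trait, value``.
    """
    if onset_sd < 0:
        raise ValueError("onset_sd must be >= 0")
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(seed)
    amp = float(curve_params["amplitude"])
    onset0 = float(curve_params["mean_onset"])
    scale = float(curve_params["scale"])
    base = float(curve_params.get("baseline", 0.0))
    if scale <= 0:
        raise ValueError("scale must be > 0")

    onsets = onset0 + onset_sd * rng.standard_normal(n)
    values = base + amp / (1 + np.exp(-(ages[None, :] - onsets[:, None]) / scale))
    return _dataset_from_matrix(
        values, ages, np.zeros(n, dtype=int), ["trait"]
    )


def simulate_landmark_growth(
    n: int,
    ages: Sequence[float],
    mean_shape: np.ndarray,
    canalized_feature: np.ndarray,
    theta_t: float,
    noise: float,
    seed: int | None = None,
    feature_var0: float = 1.0,
    feature_eps_var: float = 0.0,
):
    """Landmark configurations whose variation along one shape feature is canalized.

    Each specimen's configuration at age t is

        mean_shape + s_i(t) * feature + isotropic landmark noise,

    where the feature scores s_i follow the AR(1) canalization model
    s_{t+1} = (1 - theta) s_t + eps, starting from s_0 ~ N(0, feature_var0).
    The residual noise is drawn independently at every age, so only the
    planted feature carries a persistent, mean-reverting signal; downstream
    cross-covariance analysis between shape and shape change should recover
    the feature as its leading axis.

    Parameters
    ----------
    mean_shape : (k, 2) array
    canalized_feature : (k, 2) or (2k,) array, unit norm
    theta_t : float
        Canalization strength of the feature scores.
    noise : float
        Standard deviation of isotropic per-coordinate landmark noise.

    Returns
    -------
    shapes : ndarray (n, n_ages, k, 2)
    scores : ndarray (n, n_ages) — the latent feature scores.
    """
    ages = np.asarray(ages, dtype=float)
    mean_shape = np.asarray(mean_shape, dtype=float)
    if mean_shape.ndim != 2 or mean_shape.shape[1] != 2:
        raise ValueError("mean_shape must be (k, 2)")
    k = mean_shape.shape[0]
    feat = np.asarray(canalized_feature, dtype=float).reshape(-1)
    if feat.size != 2 * k:
        raise ValueError("canalized_feature must have 2k entries")
    if not np.isclose(np.linalg.norm(feat), 1.0, atol=1e-8):
        raise ValueError("canalized_feature must have unit norm")
    if noise < 0 or feature_var0 < 0 or feature_eps_var < 0:
        raise ValueError("noise and variances must be >= 0")

    rng = np.random.default_rng(seed)
    T = len(ages)
    scores = np.empty((n, T))
    scores[:, 0] = np.sqrt(feature_var0) * rng.standard_normal(n)
    for t in range(T - 1):
        eps = np.sqrt(feature_eps_var) * rng.standard_normal(n)
        scores[:, t + 1] = (1 - theta_t) * scores[:, t] + eps

    shapes = (
        mean_shape[None, None, :, :]
        + scores[:, :, None, None] * feat.reshape(k, 2)[None, None, :, :]
        + noise * rng.standard_normal((n, T, k, 2))
    )
    return shapes, scores
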