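"""Univariate estimation of canalization strength and canalized variance.

The estimators work on a rectangular individuals-by-ages value grid
(:class:`AgeGridSeries`), usually obtained by locally smoothing irregular
longitudinal records onto a yearly age grid.  Central quantities per age
step t -> t+1:

* theta_hat — minus the OLS slope of the developmental change
  (x_{t+1} - x_t) on x_t; an unbiased estimate of the strength of
  canalization when all individuals share one target trajectory, and biased
  toward zero by between-individual trajectory variance otherwise.
* canalized variance — 1.5 * cov(x_{t+1} - x_t, x_t), a linear
  approximation to the exact variance change (theta^2 - 2 theta) var(d)
  attributable to mean reversion, valid for small-to-intermediate theta.
* variance decomposition — cross-sectional variance, canalized variance and
  the residual "newly added" variance per step; closure with the observed
  change in cross-sectional variance is exact by construction.

Measurement error mimics canalization (error present at t has vanished at
t+1); helpers quantify this bias from replicate measurements and correct the
lag covariance for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgeGridSeries",
    "CanalizationProfile",
    "ErrorModel",
    "smooth_to_grid",
    "remove_group_means",
    "pacf",
    "estimate_theta",
    "theta_bias",
    "canalized_variance",
    "exact_canalized_variance",
    "expected_variance_change",
    "decompose_variance",
    "estimate_measurement_error",
    "expected_theta_with_error",
    "correct_covariance_for_error",
    "estimate_theta_lags",
]


@dataclass
class AgeGridSeries:
    """One trait on a common age grid: individuals x grid-ages value matrix.

    Missing grid values (individuals with too few observations in a
    smoothing window) are NaN; step-wise estimators use only individuals
    observed at both ages of a step.
    """

    values: np.ndarray                    # (n_individuals, n_ages), NaN = missing
    grid_ages: np.ndarray                 # (n_ages,), years
    individual_ids: np.ndarray
    group_labels: np.ndarray | None = None
    trait: str = "trait"
    raw_values: np.ndarray | None = None  # pre-centering copy (for CV)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid_ages = np.asarray(self.grid_ages, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d (individuals x ages)")
        if self.values.shape[1] != len(self.grid_ages):
            raise ValueError("values column count must match grid_ages")
        self.individual_ids = np.asarray(self.individual_ids)
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValueError("one id per row required")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != self.values.shape[0]:
                raise ValueError("one group label per row required")
        if self.raw_values is None:
            self.raw_values = self.values.copy()

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_ages(self) -> int:
        return self.values.shape[1]


@dataclass
class CanalizationProfile:
    """Per-step canalization estimates along the age grid.

    One row per age step t (labelled by the left age): theta_hat, canalized
    variance, newly added variance, plus the per-age cross-sectional
    variance and coefficient of variation.  ``canalized_var + new_var``
    equals ``cross_var_{t+1} - cross_var_t`` exactly (the new-variance term
    is defined as the residual of the decomposition).
    """

    table: pd.DataFrame
    trait: str = "trait"

    def __getitem__(self, col):
        return self.table[col]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ErrorModel:
    """Measurement-error variance estimated from replicate measurements."""

    var_eta_by_age: pd.Series      # per-age pooled replicate variance
    var_eta_pooled: float          # df-weighted pooled value across ages
    n_replicates: int              # total replicate measurements used

    def var_eta(self, age=None) -> float:
        if age is None or age not in self.var_eta_by_age.index:
            return self.var_eta_pooled
        return float(self.var_eta_by_age.loc[age])


# ---------------------------------------------------------------------------
# smoothing and preprocessing


def smooth_to_grid(
    dataset: pd.DataFrame,
    grid_ages,
    window_width: float = 2.5,
    trait: str | None = None,
) -> AgeGridSeries:
    """Interpolate each individual's records onto an age grid by local linear fits.

    For every individual and grid age, an unweighted straight line is fitted
    by ordinary least squares to all observations inside the closed window
    [grid_age - w/2, grid_age + w/2] and evaluated at the grid age.  Windows
    with fewer than two observations (or zero age spread) yield NaN.

    Parameters
    ----------
    dataset : DataFrame
        Long-format records with columns ``individual_id, age, value`` and
        optionally ``group`` and ``trait``.
    grid_ages : sequence of float
    window_width : float
        Full window width in years (default 2.5).
    trait : str, optional
        Which trait to extract when the table holds several.
    """
    grid_ages = np.asarray(grid_ages, dtype=float)
    if window_width <= 0:
        raise ValueError("window_width must be > 0")
    df = dataset
    if "trait" in df.columns:
        if trait is None:
            traits = df["trait"].unique()
            if len(traits) > 1:
                raise ValueError(f"multiple traits present, pick one of {list(traits)}")
            trait = traits[0]
        df = df[df["trait"] == trait]
    trait = trait or "trait"

    ids = df["individual_id"].unique()
    has_group = "group" in df.columns
    groups = []
    values = np.full((len(ids), len(grid_ages)), np.nan)
    half = window_width / 2.0
    for i, ind in enumerate(ids):
        sub = df[df["individual_id"] == ind]
        ages = sub["age"].to_numpy(dtype=float)
        vals = sub["value"].to_numpy(dtype=float)
        if has_group:
            groups.append(sub["group"].iloc[0])
        for j, a in enumerate(grid_ages):
            inside = np.abs(ages - a) <= half + 1e-12
            if inside.sum() < 2 or np.ptp(ages[inside]) == 0:
                continue
            slope, intercept = np.polyfit(ages[inside], vals[inside], 1)
            values[i, j] = intercept + slope * a

    return AgeGridSeries(
        values=values,
        grid_ages=grid_ages,
        individual_ids=ids,
        group_labels=np.asarray(groups) if has_group else None,
        trait=trait,
    )


def remove_group_means(
    series: AgeGridSeries, group_labels=None
) -> AgeGridSeries:
    """Subtract the age- and group-specific mean from every individual.

    Removes group mean differences (e.g. sexual dimorphism) so that
    diverging group means are not mistaken for trajectory divergence or
    spurious canalization.  Within each group at each age the centred values
    have mean exactly zero.  The pre-centring values are retained in
    ``raw_values`` so coefficients of variation stay meaningful.
    """
    labels = group_labels if group_labels is not None else series.group_labels
    if labels is None:
        labels = np.zeros(series.n_individuals, dtype=int)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = uniq[counts < 2]
        raise ValueError(f"singleton group(s) {list(bad)}: cannot centre")

    centred = series.values.copy()
    for g in uniq:
        rows = labels == g
        means = np.nanmean(series.values[rows], axis=0)
        centred[rows] = series.values[rows] - means
    return AgeGridSeries(
        values=centred,
        grid_ages=series.grid_ages,
        individual_ids=series.individual_ids,
        group_labels=labels,
        trait=series.trait,
        raw_values=series.raw_values,
    )


# ---------------------------------------------------------------------------
# core per-step estimators


def _step_pairs(series: AgeGridSeries, t: int) -> tuple[np.ndarray, np.ndarray]:
    if not 0 <= t < series.n_ages - 1:
        raise IndexError(f"step index {t} out of range")
    x0 = series.values[:, t]
    x1 = series.values[:, t + 1]
    ok = np.isfinite(x0) & np.isfinite(x1)
    return x0[ok], x1[ok]


def estimate_theta(series: AgeGridSeries, t: int) -> float:
    """Estimate the strength of canalization at step t.

    Returns minus the OLS slope of (x_{t+1} - x_t) on x_t across
    individuals, so positive values indicate canalization (reversion toward
    the mean trajectory).  Requires at least 3 paired observations and
    nonzero cross-sectional variance at age t.
    """
    x0, x1 = _step_pairs(series, t)
    if len(x0) < 3:
        raise ValueError(f"step {t}: need >= 3 individuals with both ages, got {len(x0)}")
    v = np.var(x0, ddof=1)
    if v <= 0:
        raise ValueError(f"step {t}: zero cross-sectional variance, slope undefined")
    cov = np.cov(x1 - x0, x0, ddof=1)[0, 1]
    return float(-cov / v)


def canalized_variance(series: AgeGridSeries, t: int) -> float:
    """Approximate canalized variance at step t as 1.5 * cov(x_{t+1} - x_t, x_t).

    Negative values mean cross-sectional variance removed by reversion
    toward the target trajectories; positive values indicate amplification
    of existing differences (diverging trajectories).  The factor 1.5 is the
    linear approximation of (theta^2 - 2 theta) / (-theta) over small to
    intermediate theta.
    """
    x0, x1 = _step_pairs(series, t)
    if len(x0) < 3:
        raise ValueError(f"step {t}: need >= 3 individuals with both ages, got {len(x0)}")
    if np.var(x0, ddof=1) <= 0:
        raise ValueError(f"step {t}: zero cross-sectional variance")
    return float(1.5 * np.cov(x1 - x0, x0, ddof=1)[0, 1])


def exact_canalized_variance(theta: float, var_d: float) -> float:
    """Exact variance change from canalization: (theta^2 - 2 theta) * var(d).

    Most negative at theta = 1 (complete reversion removes exactly var(d));
    zero at theta = 0 and theta = 2.
    """
    if var_d < 0:
        raise ValueError("var_d must be >= 0")
    return (theta**2 - 2 * theta) * var_d


def theta_bias(theta: float, var_mu: float, var_d: float, zeta: float = 0.0) -> float:
    """Expected (biased) estimate of theta under trajectory heterogeneity.

    With between-individual target-trajectory variance var(mu) and
    divergence coefficient zeta, the regression of developmental change on
    the current value converges to

        theta / (1 + var_mu / var_d) - zeta / (1 + var_d / var_mu),

    assuming cov(mu, d) = 0.  Trajectory variance shrinks the estimate
    toward zero; trajectory divergence (zeta > 0) pushes it negative.
    """
    if var_mu < 0 or var_d < 0:
        raise ValueError("variances must be >= 0")
    if var_mu == 0 and var_d == 0:
        raise ValueError("var_mu and var_d cannot both be zero")
    first = 0.0 if var_d == 0 else theta / (1 + var_mu / var_d)
    second = 0.0 if var_mu == 0 else zeta / (1 + var_d / var_mu)
    return first - second


def expected_theta_with_error(
    theta: float, var_d: float, var_mu: float, cov_c_mu: float, var_eta: float
) -> float:
    """Expected estimate of theta when values carry independent measurement error.

    Converges to (theta * var_d - cov(c, mu) + var_eta) /
    (var_d + var_mu + var_eta): error variance inflates the apparent
    canalization because error present at age t has vanished by t+1
    (regression to the mean), while trajectory variance and trajectory
    trends bias it as in :func:`theta_bias`.
    """
    if var_d < 0 or var_mu < 0 or var_eta < 0:
        raise ValueError("variances must be >= 0")
    denom = var_d + var_mu + var_eta
    if denom <= 0:
        raise ValueError("var_d + var_mu + var_eta must be > 0")
    return (theta * var_d - cov_c_mu + var_eta) / denom


def correct_covariance_for_error(observed_cov: float, var_eta: float) -> float:
    """Correct the lag covariance cov(x_{t+1} - x_t, x_t) for measurement error.

    Independent error subtracts var_eta from the true lag covariance, so
    adding it back recovers the error-free quantity (and hence an unbiased
    1.5x canalized-variance approximation).
    """
    if var_eta < 0:
        raise ValueError("var_eta must be >= 0")
    return observed_cov + var_eta


def expected_variance_change(
    var_g: float,
    zeta: float,
    var_mu: float,
    theta: float,
    var_d: float,
    var_eps: float,
) -> float:
    """Expected change in cross-sectional variance over one age step.

    var(x_{t+1}) - var(x_t) =
        var(g) + (zeta^2 + 2 zeta) var(mu) + (theta^2 - 2 theta) var(d) + var(eps).

    New deterministic variation and stochastic perturbations add variance;
    canalization (0 < theta < 2) removes it; trajectory divergence
    (zeta > 0) amplifies it.
    """
    for name, v in (("var_g", var_g), ("var_mu", var_mu),
                    ("var_d", var_d), ("var_eps", var_eps)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return (
        var_g
        + (zeta**2 + 2 * zeta) * var_mu
        + (theta**2 - 2 * theta) * var_d
        + var_eps
    )


def estimate_theta_lags(series: AgeGridSeries, t: int, p: int) -> np.ndarray:
    """Estimate lagged canalization coefficients by multiple regression.

    Regresses the change x_{t+1} - x_t on (x_t, x_{t-1}, ..., x_{t-p+1})
    and returns the negated coefficients, one per lag (lag 1 first).  With
    p = 1 this coincides with :func:`estimate_theta`.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if t - (p - 1) < 0:
        raise IndexError(f"step {t} does not admit {p} lags")
    cols = [series.values[:, t + 1] - series.values[:, t]] + [
        series.values[:, t - i] for i in range(p)
    ]
    stack = np.column_stack(cols)
    ok = np.all(np.isfinite(stack), axis=1)
    stack = stack[ok]
    if stack.shape[0] < p + 2:
        raise ValueError(f"step {t}: need more than {p + 1} individuals for {p} lags")
    y = stack[:, 0]
    X = np.column_stack([np.ones(stack.shape[0]), stack[:, 1:]])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"step {t}: collinear lagged values, coefficients unidentified")
    return -coef[1:]


# ---------------------------------------------------------------------------
# lag selection


def pacf(series: AgeGridSeries, max_lag: int) -> pd.DataFrame:
    """Partial autocorrelation of the trait with its own lagged values.

    For each lag k, the values x_t and x_{t-k} are regressed (per age pair,
    across individuals) on the intervening values x_{t-1}, ..., x_{t-k+1};
    the standardized residuals are pooled over all valid age pairs and
    correlated.  Lag 1 is the pooled plain correlation of consecutive ages.
    Used to choose the autoregressive order: under a first-order canalized
    process only lag 1 falls outside the approximate 95% band
    +/- 1.96 / sqrt(number of pooled pairs).

    Returns a DataFrame with columns ``lag, pacf, n_pairs, band``.
    """
    if max_lag >= series.n_ages - 1:
        raise ValueError("max_lag must be < number of grid ages - 1")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    V = series.values
    rows = []
    for k in range(1, max_lag + 1):
        res_now, res_lag = [], []
        for t in range(k, series.n_ages):
            block = np.column_stack([V[:, t], V[:, t - k]] +
                                    [V[:, t - i] for i in range(1, k)])
            ok = np.all(np.isfinite(block), axis=1)
            block = block[ok]
            if block.shape[0] < k + 2:
                continue
            y1, y2 = block[:, 0], block[:, 1]
            if k > 1:
                Z = np.column_stack([np.ones(block.shape[0]), block[:, 2:]])
                y1 = y1 - Z @ np.linalg.lstsq(Z, y1, rcond=None)[0]
                y2 = y2 - Z @ np.linalg.lstsq(Z, y2, rcond=None)[0]
            else:
                y1 = y1 - y1.mean()
                y2 = y2 - y2.mean()
            s1, s2 = y1.std(ddof=1), y2.std(ddof=1)
            if s1 == 0 or s2 == 0:
                # a degenerate (constant) residual carries no correlation signal
                if s1 == 0 and s2 == 0 and np.allclose(V[ok, t], V[ok, t - k]):
                    pass
                continue
            res_now.append(y1 / s1)
            res_lag.append(y2 / s2)
        if not res_now:
            # no age pair with variation: perfectly persistent trait
            const_pairs = 0
            val = np.nan
            for t in range(k, series.n_ages):
                both = np.isfinite(V[:, t]) & np.isfinite(V[:, t - k])
                if both.sum() >= 2 and np.allclose(V[both, t], V[both, t - k]):
                    const_pairs += both.sum()
                    val = 1.0
            rows.append({"lag": k, "pacf": val, "n_pairs": const_pairs,
                         "band": np.nan if const_pairs == 0 else 1.96 / np.sqrt(const_pairs)})
            continue
        a = np.concatenate(res_now)
        b = np.concatenate(res_lag)
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"lag": k, "pacf": r, "n_pairs": len(a),
                     "band": 1.96 / np.sqrt(len(a))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full decomposition


def decompose_variance(series: AgeGridSeries) -> CanalizationProfile:
    """Decompose the age-to-age change in cross-sectional variance.

    Per age step: cross-sectional variance, the canalized-variance
    approximation 1.5 * cov(x_{t+1} - x_t, x_t), the newly added variance as
    the residual (cross_var_{t+1} - cross_var_t) - canalized_var (closure is
    therefore exact by construction), the estimated strength of canalization
    theta_hat, and the per-age coefficient of variation computed from the
    raw (pre-centring) values.  The final grid age carries its cross-
    sectional variance and CV with step quantities NaN.
    """
    V = series.values
    T = series.n_ages
    rows = []
    for t in range(T):
        col = V[:, t]
        okc = np.isfinite(col)
        cross = float(np.var(col[okc], ddof=1)) if okc.sum() >= 2 else np.nan
        raw = series.raw_values[:, t]
        okr = np.isfinite(raw)
        m = raw[okr].mean() if okr.sum() >= 2 else np.nan
        sd = raw[okr].std(ddof=1) if okr.sum() >= 2 else np.nan
        cv = np.nan if (not np.isfinite(m) or abs(m) < 1e-12) else sd / abs(m)
        rows.append({"age": series.grid_ages[t], "cross_var": cross, "cv": cv})

    prof = pd.DataFrame(rows)
    theta_col = np.full(T, np.nan)
    canal_col = np.full(T, np.nan)
    new_col = np.full(T, np.nan)
    n_col = np.zeros(T, dtype=int)
    for t in range(T - 1):
        x0, x1 = _step_pairs(series, t)
        n_col[t] = len(x0)
        if len(x0) < 3 or np.var(x0, ddof=1) <= 0:
            continue
        theta_col[t] = estimate_theta(series, t)
        canal_col[t] = canalized_variance(series, t)
        # closure: new variance is the residual against the reported per-age
        # cross-sectional variances, so the decomposition closes exactly even
        # when the pair set at a step differs from the per-age sets
        dv = prof["cross_var"][t + 1] - prof["cross_var"][t]
        new_col[t] = dv - canal_col[t]
    prof["n"] = n_col
    prof["theta_hat"] = theta_col
    prof["canalized_var"] = canal_col
    prof["new_var"] = new_col
    prof = prof[["age", "n", "theta_hat", "canalized_var", "new_var", "cross_var", "cv"]]
    return CanalizationProfile(table=prof, trait=series.trait)


# ---------------------------------------------------------------------------
# measurement error


def estimate_measurement_error(replicate_table: pd.DataFrame) -> ErrorModel:
    """Estimate measurement-error variance from repeated measurements.

    Expects long-format columns ``individual_id, age, replicate, value``
    (an optional ``trait`` column must be single-valued).  The within-
    (individual, age) replicate variance is pooled per age weighting by
    degrees of freedom, and across ages the same way.
    """
    df = replicate_table
    if "trait" in df.columns and df["trait"].nunique() > 1:
        raise ValueError("replicate table holds several traits; filter to one")
    grouped = df.groupby(["individual_id", "age"])["value"]
    counts = grouped.count()
    if (counts < 2).all():
        raise ValueError("need >= 2 replicates for at least one (individual, age)")
    stats = pd.DataFrame({"var": grouped.var(ddof=1), "df": counts - 1})
    stats = stats[stats["df"] >= 1]

    by_age = stats.groupby(level="age").apply(
        lambda s: np.average(s["var"], weights=s["df"])
    )
    pooled = float(np.average(stats["var"], weights=stats["df"]))
    return ErrorModel(
        var_eta_by_age=by_age,
        var_eta_pooled=pooled,
        n_replicates=int(counts.sum()),
    )
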