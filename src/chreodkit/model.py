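"""Model/Results interface over the canalization estimators.

:class:`CanalizationModel` is built from a long-format longitudinal table
(or an existing :class:`~chreodkit.univariate.AgeGridSeries`); ``fit()``
smooths to the age grid, optionally removes group means, runs the
per-step estimators and returns :class:`CanalizationResults` carrying the
profile, per-step standard errors, the PACF-based lag diagnostic and a
``summary()`` table.

:class:`MultivariateCanalization` pairs two age blocks of a multi-trait (or
shape-coordinate) dataset and ``fit()`` returns the two-block PLS
decomposition plus, when the sample size allows, the estimated
canalization/compensation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import multivariate as mv
from . import univariate as uv

__all__ = [
    "CanalizationModel",
    "CanalizationResults",
    "MultivariateCanalization",
    "MultivariateResults",
]


class CanalizationModel:
    """Single-trait canalization model for longitudinal growth data.

    Parameters
    ----------
    data : DataFrame or AgeGridSeries
        Long-format records (``individual_id, age, value`` plus optional
        ``group`` / ``trait`` columns) or an already-gridded series.
    grid_ages : sequence of float, optional
        Target age grid (years); required when ``data`` is a DataFrame.
    window : float
        Full width of the local-linear smoothing window (years).
    trait : str, optional
        Trait to analyse when the table holds several.
    group_column : str, optional
        Column holding group labels (e.g. sex); when given, age- and
        group-specific means are removed before estimation so diverging
        group means are not read as (anti-)canalization.
    error_model : ErrorModel, optional
        Replicate-based measurement-error estimate; when provided the
        results additionally carry error-corrected canalized variances.
    """

    def __init__(
        self,
        data,
        grid_ages=None,
        window: float = 2.5,
        trait: str | None = None,
        group_column: str | None = None,
        error_model: uv.ErrorModel | None = None,
    ):
        if isinstance(data, uv.AgeGridSeries):
            self.series = data
        else:
            df = data
            if group_column and group_column != "group" and group_column in df.columns:
                df = df.rename(columns={group_column: "group"})
            if grid_ages is None:
                raise ValueError("grid_ages is required for long-format input")
            self.series = uv.smooth_to_grid(df, grid_ages, window, trait=trait)
        self.window = window
        self.group_column = group_column
        self.error_model = error_model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CanalizationModel":
        return cls(df, **kwargs)

    def fit(self, max_lag: int | None = None) -> "CanalizationResults":
        """Estimate the canalization profile.

        ``max_lag`` controls the PACF diagnostic depth (default: up to 5 or
        the grid length limit, whichever is smaller).
        """
        series = self.series
        if self.group_column is not None and series.group_labels is not None:
            series = uv.remove_group_means(series)
        profile = uv.decompose_variance(series)

        if max_lag is None:
            max_lag = min(5, series.n_ages - 2)
        pacf_table = uv.pacf(series, max_lag) if max_lag >= 1 else None

        table = profile.table.copy()
        if self.error_model is not None:
            corrected = []
            for _, row in table.iterrows():
                if np.isfinite(row["canalized_var"]):
                    cov = row["canalized_var"] / 1.5
                    corrected.append(
                        1.5 * uv.correct_covariance_for_error(
                            cov, self.error_model.var_eta(row["age"])
                        )
                    )
                else:
                    corrected.append(np.nan)
            table["canalized_var_corrected"] = corrected

        return CanalizationResults(
            model=self,
            series=series,
            profile=uv.CanalizationProfile(table=table, trait=profile.trait),
            pacf=pacf_table,
        )


@dataclass
class CanalizationResults:
    """Fitted canalization profile with diagnostics."""

    model: CanalizationModel
    series: uv.AgeGridSeries
    profile: uv.CanalizationProfile
    pacf: pd.DataFrame | None = None

    @property
    def theta(self) -> pd.Series:
        t = self.profile.table
        return pd.Series(t["theta_hat"].to_numpy(), index=t["age"], name="theta_hat")

    @property
    def canalized_variance(self) -> pd.Series:
        t = self.profile.table
        return pd.Series(t["canalized_var"].to_numpy(), index=t["age"], name="canalized_var")

    def suggested_order(self) -> int | None:
        """Autoregressive order suggested by the PACF diagnostic.

        The largest lag whose partial autocorrelation falls outside the
        approximate 95% band; None when no PACF was computed.
        """
        if self.pacf is None or self.pacf.empty:
            return None
        outside = self.pacf[np.abs(self.pacf["pacf"]) > self.pacf["band"]]
        return int(outside["lag"].max()) if len(outside) else 0

    def summary(self) -> str:
        t = self.profile.table
        lines = [
            "Canalization model results",
            "==========================",
            f"trait: {self.profile.trait}",
            f"individuals: {self.series.n_individuals}   "
            f"grid ages: {self.series.grid_ages[0]:g}-{self.series.grid_ages[-1]:g} "
            f"({self.series.n_ages} points)",
            f"group means removed: {self.model.group_column is not None}",
        ]
        order = self.suggested_order()
        if order is not None:
            lines.append(f"PACF-suggested AR order: {order}")
        lines.append("")
        with pd.option_context("display.float_format", "{:10.4f}".format):
            lines.append(t.to_string(index=False))
        return "\n".join(lines)


class MultivariateCanalization:
    """Canalization/compensation analysis of a multi-trait age step.

    Built from two blocks of the same individuals: trait values at age t
    and at age t+1 (columns in identical order).
    """

    def __init__(self, X_t, X_next, trait_names=None):
        self.X_t = np.asarray(X_t, dtype=float)
        self.X_next = np.asarray(X_next, dtype=float)
        if self.X_t.shape != self.X_next.shape:
            raise ValueError("blocks must have identical shape")
        p = self.X_t.shape[1]
        self.trait_names = (
            list(trait_names) if trait_names is not None else [f"v{i}" for i in range(p)]
        )

    @classmethod
    def from_long_frame(
        cls,
        df: pd.DataFrame,
        age_a: float,
        age_b: float,
        grid_ages,
        window: float = 2.5,
        group_column: str | None = None,
    ) -> "MultivariateCanalization":
        """Build the two age blocks from a long-format multi-trait table.

        Each trait is smoothed to the grid independently; individuals with a
        missing value in either block are dropped.  Group means (per age and
        trait) are removed when ``group_column`` is given.
        """
        if group_column and group_column != "group" and group_column in df.columns:
            df = df.rename(columns={group_column: "group"})
        grid_ages = np.asarray(grid_ages, dtype=float)
        ia = int(np.argmin(np.abs(grid_ages - age_a)))
        ib = int(np.argmin(np.abs(grid_ages - age_b)))
        traits = list(df["trait"].unique())
        cols_a, cols_b = [], []
        ids = None
        for trait in traits:
            series = uv.smooth_to_grid(df, grid_ages, window, trait=trait)
            if group_column is not None and series.group_labels is not None:
                series = uv.remove_group_means(series)
            if ids is None:
                ids = series.individual_ids
            cols_a.append(series.values[:, ia])
            cols_b.append(series.values[:, ib])
        A = np.column_stack(cols_a)
        B = np.column_stack(cols_b)
        ok = np.all(np.isfinite(A), axis=1) & np.all(np.isfinite(B), axis=1)
        return cls(A[ok], B[ok], trait_names=traits)

    def fit(self, k: int | None = None) -> "MultivariateResults":
        """Run the two-block PLS (always) and Theta estimation (when n > p + 1)."""
        n, p = self.X_t.shape
        if k is None:
            k = min(p, n - 1)
        pls = mv.pls_canalization(self.X_t, self.X_next, k=k)
        theta = None
        if n > p + 1:
            try:
                theta = mv.estimate_theta_matrix(self.X_t, self.X_next)
            except ValueError:
                theta = None
        return MultivariateResults(model=self, pls=pls, theta=theta)


@dataclass
class MultivariateResults:
    """PLS decomposition (and Theta estimate where available) of one age step."""

    model: MultivariateCanalization
    pls: mv.PLSResult
    theta: mv.ThetaMatrixEstimate | None = None

    def dimension_table(self) -> pd.DataFrame:
        r = self.pls
        return pd.DataFrame(
            {
                "dimension": np.arange(1, r.k + 1),
                "singular_value": r.singular_values,
                "pct_squared_covariance": r.pct_squared_covariance,
                "slope": r.slopes,
                "correlation": r.correlations,
                "canalization_index": r.canalization_index,
            }
        )

    def summary(self) -> str:
        lines = [
            "Multivariate canalization results",
            "=================================",
            f"individuals: {self.model.X_t.shape[0]}   traits: {self.model.X_t.shape[1]}",
        ]
        if self.theta is not None:
            lines.append(
                f"Theta estimated (condition {self.theta.condition_estimate:.3g}, "
                f"asymmetry {self.theta.symmetry_departure():.3f})"
            )
        else:
            lines.append("Theta not estimated (n too small relative to p); PLS only")
        lines.append("")
        with pd.option_context("display.float_format", "{:10.4f}".format):
            lines.append(self.dimension_table().to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dimension_table().to_csv(out / "pls_dimensions.csv", index=False)
        names = self.model.trait_names
        pd.DataFrame(self.pls.left_vectors, index=names).to_csv(out / "pls_left_vectors.csv")
        pd.DataFrame(self.pls.right_vectors, index=names).to_csv(out / "pls_right_vectors.csv")
        if self.pls.state_scores is not None:
            pd.DataFrame(self.pls.state_scores).to_csv(out / "pls_state_scores.csv", index=False)
            pd.DataFrame(self.pls.change_scores).to_csv(out / "pls_change_scores.csv", index=False)
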