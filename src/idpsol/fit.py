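"""Parameter estimation and validation statistics.

The solubility surface ``S = alpha*L + beta*|Q|**2 + gamma*|Q| + delta``
is re-estimated from observations by least squares.  Although it is fit
with a generic non-linear least-squares solver (the route used to derive
the published coefficients), the surface is linear in its parameters, so
the optimum is the unique solution of an ordinary linear system whenever
the design matrix ``[L, |Q|**2, |Q|, 1]`` has full rank; the closed-form
solution is exposed as ``method="linear"`` and serves as an internal
cross-check of the iterative route.

Validation against experimental aggregation observables (elongation
constants, lag times, measured solubility) is an ordinary least-squares
regression of the observable on the predicted solubility, reported with
R² and the two-tailed p-value of the slope
(``t = r * sqrt((n-2) / (1-r²))``, n−2 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .charge import net_charge
from .errors import DegenerateDesignError, ZeroVarianceError
from .model import PUBLISHED_PARAMS, SolubilityModelParams, predict_solubility
from .profile import lipophilicity_profile
from .scales import IonizationTable, LipophilicityScale
from .sequence_io import ProteinSequence

__all__ = [
    "TrainingObservation",
    "SolubilityModel",
    "SolubilityFitResults",
    "ExperimentalSeries",
    "RegressionResult",
    "fit_parameters",
    "validate_predictions",
]

_COLUMNS = ("variant", "ph", "lipophilicity", "abs_net_charge", "solubility")


@dataclass(frozen=True)
class TrainingObservation:
    """One (variant, pH) data point: computed predictors + measured solubility."""

    variant: str
    ph: float
    lipophilicity: float
    abs_net_charge: float
    solubility: float

    def __post_init__(self) -> None:
        if self.abs_net_charge < 0:
            raise ValueError("abs_net_charge must be non-negative")
        vals = (self.ph, self.lipophilicity, self.abs_net_charge, self.solubility)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite observation for {self.variant!r}")


def _as_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        missing = set(_COLUMNS) - set(observations.columns)
        if missing:
            raise ValueError(
                "observations frame is missing columns: " + ", ".join(sorted(missing))
            )
        return observations.loc[:, list(_COLUMNS)].reset_index(drop=True)
    rows = list(observations)
    return pd.DataFrame([vars(o) if not isinstance(o, dict) else o for o in rows])[
        list(_COLUMNS)
    ]


class SolubilityModel:
    """Solubility surface to be estimated from (L, |Q|, S) observations.

    Parameters
    ----------
    observations : DataFrame or iterable of TrainingObservation
        Must provide columns ``variant, ph, lipophilicity,
        abs_net_charge, solubility``.

    Use :meth:`from_sequences` to build the predictors directly from
    sequences and measured solubilities.
    """

    def __init__(self, observations):
        self.data = _as_frame(observations)
        if len(self.data) < 5:
            raise ValueError(
                f"need at least 5 observations to fit 4 parameters, "
                f"got {len(self.data)}"
            )
        if not np.all(np.isfinite(self.data[list(_COLUMNS[1:])].to_numpy())):
            raise ValueError("observations contain non-finite values")
        if np.any(self.data["abs_net_charge"].to_numpy() < 0):
            raise ValueError("abs_net_charge must be non-negative")
        self._check_design()

    @classmethod
    def from_sequences(
        cls,
        measurements: pd.DataFrame,
        sequences: Iterable[ProteinSequence],
        scale: LipophilicityScale,
        table: IonizationTable,
    ) -> "SolubilityModel":
        """Build the design from raw measurements.

        ``measurements`` needs columns ``variant, ph, solubility``; the
        lipophilicity and |net charge| predictors are computed here for
        each (variant, pH) pair.
        """
        seq_by_id = {s.id: s for s in sequences}
        rows = []
        for rec in measurements.itertuples(index=False):
            try:
                seq = seq_by_id[rec.variant]
            except KeyError:
                raise KeyError(
                    f"measurement references unknown variant {rec.variant!r}"
                ) from None
            prof = lipophilicity_profile(seq, rec.ph, scale, table)
            q = net_charge(seq, rec.ph, table)
            rows.append(
                TrainingObservation(
                    variant=rec.variant,
                    ph=rec.ph,
                    lipophilicity=prof.global_lipophilicity,
                    abs_net_charge=q.abs_net_charge,
                    solubility=rec.solubility,
                )
            )
        return cls(rows)

    # -- design -----------------------------------------------------------

    @property
    def exog(self) -> np.ndarray:
        """Design matrix [L, |Q|**2, |Q|, 1]."""
        lipo = self.data["lipophilicity"].to_numpy()
        q = self.data["abs_net_charge"].to_numpy()
        return np.column_stack([lipo, q**2, q, np.ones_like(q)])

    @property
    def endog(self) -> np.ndarray:
        return self.data["solubility"].to_numpy()

    exog_names = ("alpha", "beta", "gamma", "delta")

    def _check_design(self) -> None:
        x = self.exog
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name the columns involved in the deficiency
            bad = [
                name
                for j, name in enumerate(self.exog_names[:-1])
                if np.ptp(x[:, j]) == 0
            ]
            detail = (
                f"constant columns: {', '.join(bad)}"
                if bad
                else "collinear combination of lipophilicity and charge columns"
            )
            raise DegenerateDesignError(
                f"design matrix has rank {rank} < 4; {detail}. "
                "Vary both lipophilicity and net charge across observations."
            )

    # -- estimation -------------------------------------------------------

    def fit(
        self,
        init: SolubilityModelParams | None = None,
        method: str = "nlls",
        xtol: float = 1e-10,
    ) -> "SolubilityFitResults":
        """Estimate alpha, beta, gamma, delta by least squares.

        ``method="nlls"`` runs scipy's trust-region reflective solver from
        ``init`` (default: the published coefficients); ``method="linear"``
        solves the normal equations directly.  Both land on the same unique
        optimum because the model is linear in its parameters.
        """
        x, y = self.exog, self.endog
        if method == "linear":
            theta, *_ = np.linalg.lstsq(x, y, rcond=None)
        elif method == "nlls":
            theta0 = (init or PUBLISHED_PARAMS).as_array()
            sol = optimize.least_squares(
                lambda th: x @ th - y, theta0, xtol=xtol, ftol=None, gtol=None
            )
            if not sol.success:
                raise RuntimeError(
                    f"least-squares fit did not converge: {sol.message} "
                    f"(status {sol.status})"
                )
            theta = sol.x
        else:
            raise ValueError(f"unknown method {method!r}; use 'nlls' or 'linear'")

        resid = y - x @ theta
        rss = float(resid @ resid)
        n, p = x.shape
        sigma2 = rss / (n - p) if n > p else np.nan
        cov = sigma2 * np.linalg.inv(x.T @ x)
        bse = np.sqrt(np.diag(cov))
        return SolubilityFitResults(
            model=self,
            params=SolubilityModelParams.from_array(theta),
            bse={name: float(v) for name, v in zip(self.exog_names, bse)},
            rss=rss,
            nobs=int(n),
            method=method,
        )


@dataclass(frozen=True)
class SolubilityFitResults:
    """Fitted surface: estimates, standard errors and diagnostics."""

    model: SolubilityModel
    params: SolubilityModelParams
    bse: dict
    rss: float
    nobs: int
    method: str

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params.as_array()

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def predict(self, lipophilicity, abs_net_charge):
        """Evaluate the fitted surface at new (L, |Q|) points."""
        return predict_solubility(lipophilicity, abs_net_charge, self.params)

    def summary(self) -> str:
        lines = [
            "Solubility surface fit",
            "=" * 46,
            f"method: least squares ({self.method})   n = {self.nobs}",
            f"residual sum of squares: {self.rss:.6g}",
            "-" * 46,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        theta = self.params.as_array()
        for name, est in zip(self.model.exog_names, theta):
            lines.append(f"{name:<8}{est:>14.5g}{self.bse[name]:>14.3g}")
        lines.append("=" * 46)
        return "\n".join(lines)


def fit_parameters(
    observations,
    init: SolubilityModelParams | None = None,
    method: str = "nlls",
) -> SolubilityFitResults:
    """Convenience wrapper: build a :class:`SolubilityModel` and fit it."""
    return SolubilityModel(observations).fit(init=init, method=method)


@dataclass(frozen=True)
class ExperimentalSeries:
    """An experimental aggregation observable measured across pH values.

    ``aggregation_oriented`` records whether larger values mean more
    aggregation (True for elongation constants and fibrillation rates,
    False for lag times and measured solubility); it sets the expected
    sign of the regression slope against predicted solubility, which is
    reported but never enforced.
    """

    ph: tuple
    values: tuple
    label: str = "observable"
    aggregation_oriented: bool = True

    def __post_init__(self) -> None:
        if len(self.ph) != len(self.values):
            raise ValueError("ph and values must have equal length")


@dataclass(frozen=True)
class RegressionResult:
    """OLS of an experimental observable on predicted solubility."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float
    intercept_stderr: float
    x_mean: float
    x_ss: float
    resid_std: float
    expected_slope_sign: int | None = None

    @property
    def slope_sign_consistent(self) -> bool | None:
        if self.expected_slope_sign is None:
            return None
        return bool(np.sign(self.slope) == self.expected_slope_sign)

    def confidence_band(self, x, level: float = 0.95):
        """(lower, upper) of the mean-response confidence band at points ``x``.

        Standard OLS band: fit ± t_{n−2} · s · sqrt(1/n + (x − x̄)²/Sxx).
        """
        x = np.asarray(x, dtype=float)
        fit = self.intercept + self.slope * x
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        half = tcrit * self.resid_std * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.x_ss
        )
        return fit - half, fit + half


def validate_predictions(
    predicted: Sequence[float],
    experimental,
) -> RegressionResult:
    """Regress an experimental series on predicted solubility values.

    ``experimental`` may be an :class:`ExperimentalSeries` or a plain
    sequence of values aligned with ``predicted``.  R² and the two-tailed
    p-value are invariant under affine rescaling of the predictions, so
    the arbitrary units of the solubility score do not affect them.
    """
    x = np.asarray(predicted, dtype=float)
    if isinstance(experimental, ExperimentalSeries):
        y = np.asarray(experimental.values, dtype=float)
        expected_sign = -1 if experimental.aggregation_oriented else +1
    else:
        y = np.asarray(experimental, dtype=float)
        expected_sign = None
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and experimental must be 1-D and aligned")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points for a regression, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("regression inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError(
            "cannot regress: predicted values and experimental values must "
            "both vary"
        )
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = len(x) - 2
    resid_std = float(np.sqrt(resid @ resid / dof)) if dof > 0 else float("nan")
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
        x_mean=float(np.mean(x)),
        x_ss=float(np.sum((x - np.mean(x)) ** 2)),
        resid_std=resid_std,
        expected_slope_sign=expected_sign,
    )
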