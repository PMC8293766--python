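"""Two-phase least-squares calibration of the litter model.

Calibration against destructive-sampling time series proceeds in two
phases, mirroring the model's one-way coupling (water drives decay, never
the reverse):

1. **Evaporation** — the drying curve ``LWC_t = LWC_max (1 − e)^t`` is fit
   to pooled replicate water-content observations to estimate the
   evaporation rate ``e``. The saturation capacity ``LWC_max`` is not fit:
   it is set from the first measured water content, rounded up to the
   integer (e.g. a day-2 mean of 21.56 gives 22), and doubles as the day-0
   water content.
2. **Decay** — with ``e`` and ``LWC_max`` frozen, the remaining-mass
   recursion driven by the modelled (not observed) water trajectory and the
   bunnell moisture function is fit to the mass observations to estimate
   ``k_max``, ``c`` and ``d``, under box constraints ``k_max > 0`` and
   ``0 < c, d ≤ LWC_max``.

Both phases minimise a plain sum of squared residuals over all pooled
replicates and are fully deterministic: phase 1 uses a dense grid with
bounded local refinement; phase 2 a fixed 3×3×3 multistart of bounded
trust-region least squares, best objective wins, ties broken
lexicographically on the parameter vector. The rate function is invariant
under swapping the pole pair {c, d} at fixed amplitude ``k_max·d``, so
fitted triples are reported in the canonical ``c ≤ d`` form; beyond that,
``c`` and ``d`` remain weakly identified when the litter stays on the
plateau of the moisture response — real fits routinely push both to their
upper bound — so downstream use should trust ``k_max`` more than the
individual Michaelis–Menten constants.

The estimators follow the scikit-learn protocol (``fit(X, y)`` on a column
of days, fitted attributes with trailing underscores, ``get_params`` /
``set_params``) and compose with sklearn model-selection tooling; the
module-level ``fit_evaporation`` / ``fit_decay`` functions are thin
wrappers accepting :class:`ObservationSeries`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .params import LitterParams

__all__ = [
    "DataError",
    "FitError",
    "ObservationSeries",
    "FitResult",
    "TwoPhaseFit",
    "EvaporationCurve",
    "BunnellMassCurve",
    "initial_lwc_from_obs",
    "fit_evaporation",
    "fit_decay",
    "calibrate_litter",
]

VARIABLES = ("lwc", "mass_fraction")

#: generous physical ceiling on the daily mass-loss fraction
K_MAX_UPPER = 0.5
_EPS = 1e-9


class DataError(ValueError):
    """Observation data are missing, malformed or degenerate."""


class FitError(RuntimeError):
    """The optimiser failed to produce a finite solution from any start."""


@dataclass(frozen=True)
class ObservationSeries:
    """Day-stamped replicate observations of one litter treatment.

    ``data`` holds one row per measurement with columns ``day`` (int ≥ 0),
    ``replicate`` (id), ``variable`` (``"lwc"`` or ``"mass_fraction"``) and
    ``value``. Mass fractions must lie in (0, 1]; water contents must be
    non-negative.
    """

    litter: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"day", "replicate", "variable", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataError(f"observation table lacks columns {sorted(missing)}")
        if len(self.data) == 0:
            raise DataError("observation table is empty")
        bad_var = set(self.data["variable"]) - set(VARIABLES)
        if bad_var:
            raise DataError(f"unknown variables {sorted(bad_var)}")
        if (self.data["day"] < 0).any():
            raise DataError("days must be >= 0")
        mass = self.data.loc[self.data["variable"] == "mass_fraction", "value"]
        if ((mass <= 0) | (mass > 1)).any():
            raise DataError("mass_fraction values must lie in (0, 1]")
        lwc = self.data.loc[self.data["variable"] == "lwc", "value"]
        if (lwc < 0).any():
            raise DataError("lwc values must be >= 0")
        for var in VARIABLES:
            sub = self.data[self.data["variable"] == var]
            if len(sub) and sub["day"].nunique() < 2:
                raise DataError(
                    f"variable {var!r} observed on fewer than 2 distinct days"
                )

    def variable(self, name: str) -> pd.DataFrame:
        """Rows for one variable, sorted by day then replicate."""
        if name not in VARIABLES:
            raise DataError(f"unknown variable {name!r}")
        sub = self.data[self.data["variable"] == name]
        if len(sub) == 0:
            raise DataError(f"no {name!r} observations for {self.litter!r}")
        return sub.sort_values(["day", "replicate"]).reset_index(drop=True)

    def xy(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(days, values) arrays for one variable, pooled over replicates."""
        sub = self.variable(name)
        return (sub["day"].to_numpy(dtype=float),
                sub["value"].to_numpy(dtype=float))


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares phase."""

    values: Dict[str, float]
    sse: float
    bounds_active: Dict[str, Optional[str]]
    n_obs: int
    params: Optional[LitterParams] = None


@dataclass(frozen=True)
class TwoPhaseFit:
    """Complete calibration of one litter: both phases plus the merged set."""

    params: LitterParams
    evaporation: FitResult
    decay: FitResult


def initial_lwc_from_obs(series: ObservationSeries) -> int:
    """Saturation capacity from the earliest water-content measurement.

    Returns the ceiling of the replicate-mean water content at the first
    sampled day; used both as ``lwc_max`` and as the day-0 water content.
    """
    days, values = series.xy("lwc")
    first = days.min()
    return int(math.ceil(values[days == first].mean() - 1e-12))


class EvaporationCurve(RegressorMixin, BaseEstimator):
    """Discrete negative-exponential drying curve ``lwc_max (1 − e)^t``.

    Parameters
    ----------
    lwc_max:
        Fixed curve intercept (saturation capacity). If ``None``, set
        during ``fit`` from the earliest observations via the ceiling rule.
    grid_size:
        Number of points of the dense scan of e over [0, 1] that brackets
        the bounded local refinement.

    Attributes
    ----------
    e_ : float
        Fitted evaporation rate, d⁻¹.
    lwc_max_ : float
        Intercept actually used.
    sse_ : float
        Sum of squared residuals at the optimum.
    """

    def __init__(self, lwc_max: Optional[float] = None, grid_size: int = 1000):
        self.lwc_max = lwc_max
        self.grid_size = grid_size

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_2d=True)
        days = X[:, 0].astype(float)
        if np.unique(days).size < 2:
            raise DataError("need observations on at least 2 distinct days")
        if self.lwc_max is not None:
            lwc_max = float(self.lwc_max)
        else:
            first = days.min()
            lwc_max = float(math.ceil(y[days == first].mean() - 1e-12))

        def sse(e: float) -> float:
            return float(np.sum((y - lwc_max * (1.0 - e) ** days) ** 2))

        grid = np.linspace(0.0, 1.0, self.grid_size)
        # vectorised scan over the grid
        pred = lwc_max * (1.0 - grid)[:, None] ** days[None, :]
        sses = np.sum((y[None, :] - pred) ** 2, axis=1)
        best = int(np.argmin(sses))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if lo == hi:
            e_opt = float(grid[best])
        else:
            res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-12})
            e_opt = float(res.x)
            if sse(e_opt) > sses[best]:
                e_opt = float(grid[best])
        self.e_ = min(max(e_opt, 0.0), 1.0)
        self.lwc_max_ = lwc_max
        self.sse_ = sse(self.e_)
        self.n_obs_ = int(len(y))
        return self

    def predict(self, X):
        check_is_fitted(self, "e_")
        X = check_array(X, ensure_2d=True)
        days = X[:, 0].astype(float)
        return self.lwc_max_ * (1.0 - self.e_) ** days


class BunnellMassCurve(RegressorMixin, BaseEstimator):
    """Remaining-mass recursion under the bunnell moisture function.

    The predicted mass fraction at integer day ``t`` is
    ``∏_{s=1..t} (1 − k(LWC_s))`` with ``LWC_s = lwc_max (1 − e)^s`` and
    ``k(L) = k_max · L/(c+L) · d/(d+L)``. ``lwc_max`` and ``e`` come frozen
    from phase 1; ``fit`` estimates ``(k_max, c, d)`` inside the box
    ``(0, k_max_upper] × (0, lwc_max]²`` by deterministic multistart
    bounded least squares.

    Attributes
    ----------
    k_max_, c_, d_ : float
        Fitted kinetic constants.
    sse_ : float
        Sum of squared residuals at the optimum.
    bounds_active_ : dict
        Per-parameter flag: ``"lower"``, ``"upper"`` or ``None``.
    """

    def __init__(self, lwc_max: float = 1.0, e: float = 0.0,
                 k_max_upper: float = K_MAX_UPPER):
        self.lwc_max = lwc_max
        self.e = e
        self.k_max_upper = k_max_upper

    def _mass_model(self, theta: np.ndarray, days: np.ndarray,
                    lwc_path: np.ndarray) -> np.ndarray:
        k_max, c, d = theta
        k = k_max * lwc_path / (c + lwc_path) * d / (d + lwc_path)
        mass = np.concatenate([[1.0], np.cumprod(1.0 - k)])
        return mass[days.astype(int)]

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_2d=True)
        days = X[:, 0].astype(float)
        if np.unique(days).size < 2:
            raise DataError("need observations on at least 2 distinct days")
        if not (days >= 0).all() or not np.allclose(days, np.round(days)):
            raise DataError("days must be non-negative integers")
        lwc_max, e = float(self.lwc_max), float(self.e)
        t_max = int(np.round(days.max()))
        t = np.arange(1, t_max + 1, dtype=float)
        lwc_path = lwc_max * (1.0 - e) ** t

        lower = np.array([_EPS, _EPS, _EPS])
        upper = np.array([self.k_max_upper, lwc_max, lwc_max])

        def residuals(theta):
            return y - self._mass_model(theta, days, lwc_path)

        starts = [
            lower + frac * (upper - lower)
            for frac in itertools.product((0.25, 0.5, 0.75), repeat=3)
        ]
        candidates = []
        for x0 in starts:
            sol = least_squares(residuals, np.asarray(x0), bounds=(lower, upper),
                                method="trf", x_scale="jac",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if np.isfinite(sol.cost):
                theta = _canonicalize(sol.x)
                sse = float(np.sum(residuals(theta) ** 2))
                candidates.append((sse, tuple(np.round(theta, 12)), theta))
        if not candidates:
            raise FitError(
                "decay fit failed from every start "
                f"(lwc_max={lwc_max}, e={e}, n={len(y)})"
            )
        # best SSE; lexicographic tie-break on the rounded parameter vector
        candidates.sort(key=lambda item: (item[0], item[1]))
        sse, _, theta = candidates[0]
        self.k_max_, self.c_, self.d_ = (float(v) for v in theta)
        self.sse_ = sse
        self.n_obs_ = int(len(y))
        self.bounds_active_ = {
            name: _bound_flag(value, lo, hi)
            for name, value, lo, hi in zip(
                ("k_max", "c", "d"), theta, lower, upper
            )
        }
        self._lwc_path_ = lwc_path
        return self

    def predict(self, X):
        check_is_fitted(self, "k_max_")
        X = check_array(X, ensure_2d=True)
        days = X[:, 0].astype(float)
        t_max = int(np.round(days.max()))
        t = np.arange(1, t_max + 1, dtype=float)
        lwc_path = float(self.lwc_max) * (1.0 - float(self.e)) ** t
        theta = np.array([self.k_max_, self.c_, self.d_])
        return self._mass_model(theta, days, lwc_path)


def _canonicalize(theta: np.ndarray) -> np.ndarray:
    """Resolve the rate function's label symmetry by enforcing c <= d.

    k(L) = k_max · L · d / ((c+L)(d+L)) depends on (k_max, c, d) only
    through the unordered pole pair {c, d} and the amplitude k_max·d, so
    (k_max, c, d) and (k_max·d/c, d, c) describe the same curve. The
    representative with c <= d is reported (the swap can only lower k_max,
    so the box constraint is preserved).
    """
    k_max, c, d = theta
    if c > d:
        return np.array([k_max * d / c, d, c])
    return np.asarray(theta, dtype=float)


def _bound_flag(value: float, lower: float, upper: float,
                rel_tol: float = 1e-3) -> Optional[str]:
    span = upper - lower
    if value - lower <= rel_tol * span:
        return "lower"
    if upper - value <= rel_tol * span:
        return "upper"
    return None


def _as_column(days: np.ndarray) -> np.ndarray:
    return np.asarray(days, dtype=float).reshape(-1, 1)


def fit_evaporation(series: ObservationSeries,
                    lwc_max: Optional[float] = None) -> FitResult:
    """Phase 1: estimate the evaporation rate from water-content records.

    ``lwc_max`` defaults to the ceiling rule applied to the series itself.
    Residuals pool all replicates.
    """
    if lwc_max is None:
        lwc_max = initial_lwc_from_obs(series)
    days, values = series.xy("lwc")
    est = EvaporationCurve(lwc_max=float(lwc_max)).fit(_as_column(days), values)
    e = est.e_
    return FitResult(
        values={"e": e, "lwc_max": est.lwc_max_},
        sse=est.sse_,
        bounds_active={"e": _bound_flag(e, 0.0, 1.0, rel_tol=1e-9)},
        n_obs=est.n_obs_,
    )


def fit_decay(series: ObservationSeries, lwc_max: float, e: float,
              name: Optional[str] = None) -> FitResult:
    """Phase 2: estimate ``k_max, c, d`` from remaining-mass records.

    The water trajectory driving the decay rate is the phase-1 model curve,
    not the observed water contents. Returns a complete bunnell
    :class:`~litmix.params.LitterParams` alongside the fitted values.
    """
    days, values = series.xy("mass_fraction")
    est = BunnellMassCurve(lwc_max=float(lwc_max), e=float(e)).fit(
        _as_column(days), values
    )
    params = LitterParams(
        name=name or series.litter,
        lwc_max=float(lwc_max),
        k_max=est.k_max_,
        e=float(e),
        model_kind="bunnell",
        c=est.c_,
        d=est.d_,
    )
    return FitResult(
        values={"k_max": est.k_max_, "c": est.c_, "d": est.d_},
        sse=est.sse_,
        bounds_active=est.bounds_active_,
        n_obs=est.n_obs_,
        params=params,
    )


def calibrate_litter(series: ObservationSeries,
                     name: Optional[str] = None) -> TwoPhaseFit:
    """Full two-phase calibration of one litter from its solo time series."""
    lwc_max = initial_lwc_from_obs(series)
    phase1 = fit_evaporation(series, lwc_max=lwc_max)
    phase2 = fit_decay(series, lwc_max=lwc_max, e=phase1.values["e"], name=name)
    assert phase2.params is not None
    return TwoPhaseFit(params=phase2.params, evaporation=phase1, decay=phase2)
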