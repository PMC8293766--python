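"""Goodness-of-fit and scenario-comparison statistics.

Validation compares four remaining-mass series on the observed sampling
days: the measured mixture, the additive expectation computed from the
litters measured alone, and the model's interaction and no-interaction
predictions. ``fit_stats`` quantifies agreement between any observed /
modelled pair (R², adjusted R², NRMSE); ``scenario_deltas`` reports the
nonadditive effect twice — as the model predicts it and as the experiment
shows it — in percentage points of initial mass, positive meaning synergy.

NRMSE is the root-mean-square error normalised by default by the mean of
the observed series; normalisation by the observed range is available,
since both conventions are in circulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["FitStats", "fit_stats", "scenario_deltas"]


@dataclass(frozen=True)
class FitStats:
    """Agreement between an observed and a modelled series."""

    r2: float
    r2_adj: Optional[float]
    nrmse: float
    n: int
    p: int


def fit_stats(observed, modeled, p: int = 0,
              normalization: str = "mean") -> FitStats:
    """R², adjusted R² and NRMSE of a modelled series against observations.

    Parameters
    ----------
    observed, modeled:
        Paired equal-length series (day alignment is the caller's job).
    p:
        Number of parameters charged in the R² adjustment; 0 for pure
        validation comparisons where nothing is estimated.
    normalization:
        ``"mean"`` (RMSE / mean of observed, default) or ``"range"``
        (RMSE / (max − min) of observed).

    The adjustment ``1 − (1 − R²)(n − 1)/(n − p − 1)`` is undefined for
    ``n ≤ p + 1`` and reported as ``None`` with a warning.
    """
    obs = np.asarray(observed, dtype=float)
    mod = np.asarray(modeled, dtype=float)
    if obs.shape != mod.shape:
        raise ValueError("observed and modeled series differ in length")
    n = obs.size
    if n < 3:
        raise ValueError("need at least 3 paired points")
    ss_res = float(np.sum((obs - mod) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    if n > p + 1:
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        warnings.warn(
            f"adjusted R^2 undefined for n={n}, p={p}; reporting None",
            stacklevel=2,
        )
        r2_adj = None
    rmse = np.sqrt(ss_res / n)
    if normalization == "mean":
        denom = float(obs.mean())
    elif normalization == "range":
        denom = float(obs.max() - obs.min())
    else:
        raise ValueError("normalization must be 'mean' or 'range'")
    if denom == 0.0:
        raise ValueError(f"degenerate observed series: {normalization} is 0")
    return FitStats(r2=r2, r2_adj=r2_adj, nrmse=rmse / denom, n=n, p=p)


def scenario_deltas(measured_mix, expected_mix, modeled_int,
                    modeled_no_int, days=None) -> pd.DataFrame:
    """Observed and modelled nonadditive effects, day by day.

    Parameters
    ----------
    measured_mix:
        Remaining mass measured on the real mixture.
    expected_mix:
        Additive expectation from the litters measured alone.
    modeled_int, modeled_no_int:
        Model predictions under the two scenarios, on the same days.
    days:
        Optional day labels for the output index.

    Returns a frame with columns ``observed_delta`` (expected − measured)
    and ``modeled_delta`` (no-interaction − interaction), both ×100 so they
    read as percentage points of initial mass; positive = synergistic.
    """
    arrays = [np.asarray(a, dtype=float)
              for a in (measured_mix, expected_mix, modeled_int, modeled_no_int)]
    n = arrays[0].size
    if any(a.shape != arrays[0].shape for a in arrays):
        raise ValueError("all four series must share the same day grid")
    measured, expected, m_int, m_no_int = arrays
    out = pd.DataFrame(
        {
            "observed_delta": 100.0 * (expected - measured),
            "modeled_delta": 100.0 * (m_no_int - m_int),
        }
    )
    if days is not None:
        days = np.asarray(days)
        if days.size != n:
            raise ValueError("days grid does not match the series")
        out.insert(0, "day", days)
    return out
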