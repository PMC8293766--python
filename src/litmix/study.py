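"""End-to-end calibration → prediction → validation pipeline.

Given observation series for two litters decomposing alone and for their
50:50 mixture, the study (a) calibrates each litter with the two-phase
least-squares procedure, (b) predicts the mixture's remaining mass under
the no-interaction and interaction scenarios, and (c) scores both
predictions against the experiment: the no-interaction curve against the
additive expectation computed from the measured singles, the interaction
curve against the measured mixture itself. The per-day nonadditive effect
is reported twice (modelled and observed, both in percentage points of
initial mass, positive = synergistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import DataError, ObservationSeries, TwoPhaseFit, calibrate_litter
from .metrics import FitStats, fit_stats, scenario_deltas
from .mixture import MixtureConfig, simulate_mixture

__all__ = ["ValidationReport", "mean_by_day", "validate_mixture"]


@dataclass(frozen=True)
class ValidationReport:
    """Everything the validation study produces."""

    fit_wet: TwoPhaseFit
    fit_dry: TwoPhaseFit
    days: np.ndarray
    measured_mix: np.ndarray
    expected_mix: np.ndarray
    modeled_no_int: np.ndarray
    modeled_int: np.ndarray
    stats_no_interaction: FitStats
    stats_interaction: FitStats
    deltas: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Per-day table of all four mass series plus both deltas."""
        out = pd.DataFrame(
            {
                "day": self.days,
                "measured_mix": self.measured_mix,
                "expected_mix": self.expected_mix,
                "modeled_no_interaction": self.modeled_no_int,
                "modeled_interaction": self.modeled_int,
            }
        )
        return out.merge(self.deltas, on="day")


def mean_by_day(series: ObservationSeries, variable: str,
                days: Optional[Sequence[int]] = None) -> pd.Series:
    """Replicate means of one variable, indexed by day."""
    sub = series.variable(variable)
    means = sub.groupby("day")["value"].mean()
    if days is not None:
        missing = [d for d in days if d not in means.index]
        if missing:
            raise DataError(
                f"{series.litter!r}: no {variable!r} observations on days "
                f"{missing}"
            )
        means = means.loc[list(days)]
    return means


def validate_mixture(
    obs_wet: ObservationSeries,
    obs_dry: ObservationSeries,
    obs_mix: ObservationSeries,
    fraction_wet: float = 0.5,
    p: int = 0,
    normalization: str = "mean",
) -> ValidationReport:
    """Calibrate on the singles, predict the mixture, score both scenarios.

    The comparison grid is the set of days on which the mixture's mass was
    observed; all four series are evaluated there.
    """
    fit_wet = calibrate_litter(obs_wet)
    fit_dry = calibrate_litter(obs_dry)

    days = np.asarray(sorted(obs_mix.variable("mass_fraction")["day"].unique()),
                      dtype=int)
    measured = mean_by_day(obs_mix, "mass_fraction", days).to_numpy()
    expected = (
        fraction_wet * mean_by_day(obs_wet, "mass_fraction", days).to_numpy()
        + (1.0 - fraction_wet)
        * mean_by_day(obs_dry, "mass_fraction", days).to_numpy()
    )

    horizon = int(days.max())
    modeled = {}
    for interaction in (False, True):
        cfg = MixtureConfig(litter_wet=fit_wet.params, litter_dry=fit_dry.params,
                            horizon=horizon, interaction=interaction,
                            fraction_wet=fraction_wet)
        modeled[interaction] = simulate_mixture(cfg).combined_mass[days]

    stats_no_int = fit_stats(expected, modeled[False], p=p,
                             normalization=normalization)
    stats_int = fit_stats(measured, modeled[True], p=p,
                          normalization=normalization)
    deltas = scenario_deltas(measured, expected, modeled[True], modeled[False],
                             days=days)
    return ValidationReport(
        fit_wet=fit_wet,
        fit_dry=fit_dry,
        days=days,
        measured_mix=measured,
        expected_mix=expected,
        modeled_no_int=modeled[False],
        modeled_int=modeled[True],
        stats_no_interaction=stats_no_int,
        stats_interaction=stats_int,
        deltas=deltas,
    )
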