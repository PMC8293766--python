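"""Synthetic observation data with the structure of a destructive-sampling
incubation experiment.

Laboratory calibration data for this model come from glassware incubations
sampled destructively: at each of a handful of dates, several replicate
samples per treatment (each litter alone, plus the 50:50 mixture) are
retrieved and their whole-sample water content and remaining dry mass are
measured. The default design follows that layout — seven sampling dates,
six replicates per date — with independent additive Gaussian measurement
noise on both variables.

Generators run the deterministic model forward and observe it at the sample
days, so they double as ground-truth oracles for calibration and
validation tests: with zero noise, observations equal the model exactly.

Noise defaults are an sd of 0.02 on the mass fraction and 5% of the day-0
water content on LWC; out-of-range draws are truncated into the physical
domain (a small, documented bias at extreme noise levels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import ObservationSeries
from .core import simulate_single
from .mixture import MixtureConfig, simulate_mixture
from .params import LitterParams

__all__ = [
    "DEFAULT_SAMPLE_DAYS",
    "DesignSpec",
    "generate_single_litter_obs",
    "generate_mixture_obs",
]

DEFAULT_SAMPLE_DAYS = (2, 7, 14, 28, 56, 84, 112)
DEFAULT_NOISE_SD_MASS = 0.02
#: LWC noise sd as a fraction of the day-0 water content, used when the
#: absolute sd is left unset
DEFAULT_LWC_NOISE_FRACTION = 0.05
_MASS_FLOOR = 1e-9


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design and error model of a synthetic incubation.

    Parameters
    ----------
    sample_days:
        Strictly increasing sampling dates (days ≥ 1).
    replicates:
        Destructive replicates per date and variable.
    noise_sd_lwc:
        Absolute sd of the water-content noise (g water g⁻¹ dm); ``None``
        means 5% of the litter's day-0 water content, resolved per litter
        at generation time.
    noise_sd_mass:
        Sd of the mass-fraction noise.
    seed:
        Seed of the generator's private RNG; same seed, same dataset.
    """

    sample_days: Sequence[int] = DEFAULT_SAMPLE_DAYS
    replicates: int = 6
    noise_sd_lwc: Optional[float] = None
    noise_sd_mass: float = DEFAULT_NOISE_SD_MASS
    seed: int = 0

    def __post_init__(self) -> None:
        days = list(self.sample_days)
        if len(days) == 0 or days[0] < 1:
            raise ValueError("sample_days must start at day >= 1")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sample_days must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd_lwc is not None and self.noise_sd_lwc < 0:
            raise ValueError("noise_sd_lwc must be >= 0")
        if self.noise_sd_mass < 0:
            raise ValueError("noise_sd_mass must be >= 0")

    @property
    def horizon(self) -> int:
        return int(max(self.sample_days))

    def resolve_sd_lwc(self, lwc0: float) -> float:
        if self.noise_sd_lwc is not None:
            return float(self.noise_sd_lwc)
        return DEFAULT_LWC_NOISE_FRACTION * float(lwc0)


def _observe(rng: np.random.Generator, truth_by_day: dict, design: DesignSpec,
             sd_lwc: float, sd_mass: float) -> pd.DataFrame:
    rows = []
    for day in design.sample_days:
        lwc_true, mass_true = truth_by_day[int(day)]
        lwc_obs = lwc_true + rng.normal(0.0, sd_lwc, design.replicates) \
            if sd_lwc > 0 else np.full(design.replicates, lwc_true)
        mass_obs = mass_true + rng.normal(0.0, sd_mass, design.replicates) \
            if sd_mass > 0 else np.full(design.replicates, mass_true)
        lwc_obs = np.clip(lwc_obs, 0.0, None)
        mass_obs = np.clip(mass_obs, _MASS_FLOOR, 1.0)
        for rep in range(1, design.replicates + 1):
            rows.append((int(day), rep, "lwc", float(lwc_obs[rep - 1])))
            rows.append((int(day), rep, "mass_fraction",
                         float(mass_obs[rep - 1])))
    return pd.DataFrame(rows, columns=["day", "replicate", "variable", "value"])


def generate_single_litter_obs(params: LitterParams,
                               design: DesignSpec) -> ObservationSeries:
    """Noisy observations of one litter decomposing alone.

    Simulates the deterministic trajectory out to the last sample day and
    emits ``replicates`` observations of both variables at each date:
    ``2 · replicates · len(sample_days)`` records in total.
    """
    traj = simulate_single(params, horizon=design.horizon)
    truth = {int(d): (float(traj.lwc[i]), float(traj.mass_fraction[i]))
             for i, d in enumerate(traj.day)}
    rng = np.random.default_rng(design.seed)
    sd_lwc = design.resolve_sd_lwc(traj.lwc[0])
    data = _observe(rng, truth, design, sd_lwc, design.noise_sd_mass)
    return ObservationSeries(litter=params.name, data=data)


def generate_mixture_obs(params_wet: LitterParams, params_dry: LitterParams,
                         design: DesignSpec, true_interaction: bool,
                         fraction_wet: float = 0.5) -> ObservationSeries:
    """Noisy whole-mixture observations under a known scenario.

    The observed variables are the combined remaining mass (fraction-
    weighted mean of the two litters) and the whole-mixture water content
    (mean of the two litters' LWC) — destructive sampling measures the
    sample as a whole, not the litters individually.
    """
    cfg = MixtureConfig(litter_wet=params_wet, litter_dry=params_dry,
                        horizon=design.horizon, interaction=true_interaction,
                        fraction_wet=fraction_wet)
    result = simulate_mixture(cfg)
    whole_lwc = 0.5 * (result.traj_wet.lwc + result.traj_dry.lwc)
    truth = {int(d): (float(whole_lwc[i]), float(result.combined_mass[i]))
             for i, d in enumerate(result.day)}
    rng = np.random.default_rng(design.seed)
    sd_lwc = design.resolve_sd_lwc(whole_lwc[0])
    data = _observe(rng, truth, design, sd_lwc, design.noise_sd_mass)
    label = f"mixture({params_wet.name}+{params_dry.name})"
    return ObservationSeries(litter=label, data=data)
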