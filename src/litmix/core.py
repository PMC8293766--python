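"""Single-litter daily dynamics: evaporation, moisture-dependent decay.

The model advances in daily steps. Each day the litter first loses a fixed
fraction *e* of its current water (a discrete negative-exponential drying
curve), the decomposition rate *k* is then evaluated from the new water
content through one of two double-Michaelis–Menten moisture functions, and
finally the remaining mass loses the fraction *k*:

    LWC_t = LWC_{t-1} · (1 − e)
    k_t   = f(LWC_t)            (moyano or bunnell form)
    M_t   = M_{t-1} · (1 − k_t)

Mass is tracked as a fraction of the initial dry mass, so trajectories start
at 1.0 and the 50:50 mixture expectation is a plain average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .params import ConfigurationError, LitterParams

__all__ = [
    "DomainError",
    "LitterState",
    "LitterTrajectory",
    "oxygen_availability",
    "rate_moyano",
    "rate_bunnell",
    "decay_rate",
    "evaporate",
    "decay_step",
    "step_single",
    "simulate_single",
]


class DomainError(ValueError):
    """A state variable left its physically meaningful domain."""


def oxygen_availability(lwc: float, lwc_max: float) -> float:
    """Oxygen-availability coefficient O_a = (LWC_max − LWC) / LWC_max.

    Equals 1 for fully dry litter and 0 at water saturation, where oxygen
    diffusion — and with it, in the moyano form, decomposition — stops.
    """
    if lwc_max <= 0:
        raise DomainError("lwc_max must be > 0")
    if lwc < 0 or lwc > lwc_max:
        raise DomainError(
            f"lwc={lwc} outside [0, lwc_max={lwc_max}] — corrupted state"
        )
    return (lwc_max - lwc) / lwc_max


def rate_moyano(lwc: float, params: LitterParams) -> float:
    """Decay rate with oxygen as a substrate: zero at saturation.

    k = k_max · LWC/(a + LWC) · O_a/(b + O_a). Both water and oxygen act as
    Michaelis–Menten substrates, so k vanishes at both ends of the moisture
    range (dry: no water; saturated: no oxygen).
    """
    if params.a is None or params.b is None:
        raise ConfigurationError(
            f"{params.name!r}: moyano rate needs constants a and b"
        )
    o_a = oxygen_availability(lwc, params.lwc_max)
    return params.k_max * lwc / (params.a + lwc) * o_a / (params.b + o_a)


def rate_bunnell(lwc: float, params: LitterParams) -> float:
    """Decay rate allowing biological activity at saturation.

    k = k_max · LWC/(c + LWC) · d/(d + LWC). The first factor is the water
    dependence; the second is a gas-exchange facilitation term, maximal when
    dry and still positive at saturation — litter, unlike bulk soil, keeps
    an air interface even when waterlogged.
    """
    if params.c is None or params.d is None:
        raise ConfigurationError(
            f"{params.name!r}: bunnell rate needs constants c and d"
        )
    if lwc < 0:
        raise DomainError(f"lwc={lwc} must be >= 0")
    return params.k_max * lwc / (params.c + lwc) * params.d / (params.d + lwc)


def decay_rate(lwc: float, params: LitterParams) -> float:
    """Decay rate under the litter's configured moisture model."""
    if params.model_kind == "moyano":
        return rate_moyano(lwc, params)
    return rate_bunnell(lwc, params)


def evaporate(lwc: float, e: float) -> float:
    """One day of drying: LWC ← LWC · (1 − e)."""
    if not 0.0 <= e <= 1.0:
        raise DomainError(f"evaporation rate e={e} outside [0, 1]")
    if lwc < 0:
        raise DomainError(f"lwc={lwc} must be >= 0")
    return lwc * (1.0 - e)


def decay_step(mass_fraction: float, k: float) -> float:
    """One day of mass loss: M ← M · (1 − k)."""
    if not 0.0 <= k < 1.0:
        raise DomainError(f"decay rate k={k} outside [0, 1)")
    if not 0.0 < mass_fraction <= 1.0:
        raise DomainError(f"mass_fraction={mass_fraction} outside (0, 1]")
    return mass_fraction * (1.0 - k)


@dataclass(frozen=True)
class LitterState:
    """Snapshot of one litter on one day."""

    day: int
    lwc: float
    mass_fraction: float
    k_current: float


@dataclass(frozen=True)
class LitterTrajectory:
    """Daily series of water content, decay rate and remaining mass.

    Day 0 holds the initial state (LWC at its configured start, mass 1.0)
    before any update; days are consecutive integers.
    """

    params: LitterParams
    day: np.ndarray
    lwc: np.ndarray
    k: np.ndarray
    mass_fraction: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.day)
        if not (len(self.lwc) == len(self.k) == len(self.mass_fraction) == n):
            raise ValueError("trajectory arrays must have equal length")

    def __len__(self) -> int:
        return len(self.day)

    @property
    def horizon(self) -> int:
        return int(self.day[-1])

    def state(self, day: int) -> LitterState:
        """The snapshot at a given day (day must be on the grid)."""
        idx = int(day) - int(self.day[0])
        if idx < 0 or idx >= len(self.day) or self.day[idx] != day:
            raise KeyError(f"day {day} not in trajectory")
        return LitterState(
            day=int(self.day[idx]),
            lwc=float(self.lwc[idx]),
            mass_fraction=float(self.mass_fraction[idx]),
            k_current=float(self.k[idx]),
        )

    def states(self) -> Iterator[LitterState]:
        for i in range(len(self)):
            yield LitterState(
                day=int(self.day[i]),
                lwc=float(self.lwc[i]),
                mass_fraction=float(self.mass_fraction[i]),
                k_current=float(self.k[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-form table with columns day, litter, lwc, k, mass_fraction."""
        return pd.DataFrame(
            {
                "day": self.day,
                "litter": self.params.name,
                "lwc": self.lwc,
                "k": self.k,
                "mass_fraction": self.mass_fraction,
            }
        )


def step_single(state: LitterState, params: LitterParams) -> LitterState:
    """Advance one litter by one day: evaporate, re-rate, decay."""
    lwc = evaporate(state.lwc, params.e)
    k = decay_rate(lwc, params)
    mass = decay_step(state.mass_fraction, k)
    return LitterState(day=state.day + 1, lwc=lwc, mass_fraction=mass, k_current=k)


def simulate_single(
    params: LitterParams,
    horizon: int,
    lwc0: Optional[float] = None,
) -> LitterTrajectory:
    """Run one litter alone for ``horizon`` days.

    Parameters
    ----------
    params:
        The litter's constants.
    horizon:
        Number of daily steps; the trajectory has ``horizon + 1`` rows
        (day 0 through day ``horizon``).
    lwc0:
        Initial water content; defaults to ``params.lwc_max`` (litters
        start saturated).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    start = params.lwc_max if lwc0 is None else float(lwc0)
    if not 0.0 <= start <= params.lwc_max:
        raise DomainError(
            f"initial lwc {start} outside [0, lwc_max={params.lwc_max}]"
        )
    n = horizon + 1
    day = np.arange(n, dtype=np.int64)
    lwc = np.empty(n)
    k = np.empty(n)
    mass = np.empty(n)
    state = LitterState(day=0, lwc=start, mass_fraction=1.0,
                        k_current=decay_rate(start, params))
    lwc[0], k[0], mass[0] = state.lwc, state.k_current, state.mass_fraction
    for t in range(1, n):
        state = step_single(state, params)
        lwc[t], k[t], mass[t] = state.lwc, state.k_current, state.mass_fraction
    return LitterTrajectory(params=params, day=day, lwc=lwc, k=k,
                            mass_fraction=mass)
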