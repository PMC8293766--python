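"""Two-litter mixtures with and without inter-litter water transfer.

In the "no interaction" scenario the two litters decompose independently and
the mixture's remaining mass is the mass-fraction-weighted average of the
two single-litter curves (the additive expectation).

In the "interaction" scenario, each day — after each litter has evaporated
at its own rate — water flows from the currently wettest litter to the
driest one. The flow refills the dry litter up to its saturation capacity
as long as the donor stays the wetter of the two; once the gradient is
exhausted both litters share the average water content. A single rule
captures both regimes:

    τ = min(lwc_max_receiver − lwc_receiver, (lwc_donor − lwc_receiver)/2)

The transfer conserves water (per unit dry matter, the 50:50 equal-mass
bookkeeping) and never overfills the receiver. Because the transferred
water subsequently evaporates at the receiver's rate, the two scenarios'
water totals diverge over time even though each individual transfer is
conservative — and the decay rates, hence the mixture's remaining mass,
diverge with them. The sign of that divergence is the nonadditive effect:
synergistic when interaction accelerates decomposition, antagonistic when
it slows it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DomainError, LitterTrajectory, decay_rate, decay_step, evaporate
from .params import LitterParams

__all__ = [
    "OrientationError",
    "MixtureConfig",
    "MixtureResult",
    "transfer_water",
    "simulate_mixture",
    "nonadditive_delta",
]


class OrientationError(ValueError):
    """transfer_water was called with litters in the wrong wet/dry order."""


@dataclass(frozen=True)
class MixtureConfig:
    """Configuration of one two-litter mixture run.

    ``litter_wet`` / ``litter_dry`` name the litters by their *initial*
    roles; during an interaction run the engine re-evaluates which litter is
    currently the wetter one each day, so roles may swap mid-run.
    """

    litter_wet: LitterParams
    litter_dry: LitterParams
    horizon: int
    interaction: bool
    fraction_wet: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_wet < 1.0:
            raise ValueError("fraction_wet must lie in (0, 1)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass(frozen=True)
class MixtureResult:
    """Paired trajectories plus the combined remaining-mass curve."""

    scenario: str
    traj_wet: LitterTrajectory
    traj_dry: LitterTrajectory
    combined_mass: np.ndarray
    fraction_wet: float = 0.5

    @property
    def day(self) -> np.ndarray:
        return self.traj_wet.day

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per day and litter, plus combined mass."""
        frames = []
        for traj in (self.traj_wet, self.traj_dry):
            frame = traj.to_frame()
            frame.insert(1, "scenario", self.scenario)
            frame["combined_mass"] = self.combined_mass
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def transfer_water(
    lwc_wet: float, lwc_dry: float, lwc_max_dry: float
) -> tuple[float, float]:
    """Move water from the wetter litter toward the drier one.

    The transferred amount is ``min(deficit, half_gap)`` where ``deficit``
    is the receiver's headroom to saturation and ``half_gap`` half the
    water-content difference. Small deficits are refilled outright (the
    donor stays wettest); large ones equalise the two litters at their
    average. The caller must orient the arguments so ``lwc_wet >= lwc_dry``.

    Returns the pair ``(lwc_wet', lwc_dry')``; their sum is unchanged.
    """
    if lwc_dry < 0:
        raise DomainError(f"lwc_dry={lwc_dry} must be >= 0")
    if lwc_wet < lwc_dry:
        raise OrientationError(
            f"lwc_wet={lwc_wet} < lwc_dry={lwc_dry}: caller must pass the "
            "currently wetter litter first"
        )
    if lwc_dry > lwc_max_dry:
        raise DomainError(
            f"receiver lwc={lwc_dry} already exceeds its lwc_max={lwc_max_dry}"
        )
    tau = min(lwc_max_dry - lwc_dry, (lwc_wet - lwc_dry) / 2.0)
    return lwc_wet - tau, lwc_dry + tau


def simulate_mixture(config: MixtureConfig) -> MixtureResult:
    """Run a two-litter mixture for ``config.horizon`` days.

    Each day, in order: both litters evaporate at their own rates; if the
    interaction scenario is active, one transfer event moves water from the
    currently wetter to the currently drier litter; each litter's decay rate
    is evaluated from its post-transfer water content; each mass decays.
    Without interaction this reduces exactly to two independent
    single-litter runs.
    """
    p_a, p_b = config.litter_wet, config.litter_dry
    n = config.horizon + 1
    day = np.arange(n, dtype=np.int64)
    lwc = np.empty((2, n))
    k = np.empty((2, n))
    mass = np.empty((2, n))
    lwc[0, 0], lwc[1, 0] = p_a.lwc_max, p_b.lwc_max
    mass[:, 0] = 1.0
    k[0, 0] = decay_rate(lwc[0, 0], p_a)
    k[1, 0] = decay_rate(lwc[1, 0], p_b)

    for t in range(1, n):
        la = evaporate(lwc[0, t - 1], p_a.e)
        lb = evaporate(lwc[1, t - 1], p_b.e)
        if config.interaction:
            # donor/receiver re-oriented from current contents each day
            if la >= lb:
                la, lb = transfer_water(la, lb, p_b.lwc_max)
            else:
                lb, la = transfer_water(lb, la, p_a.lwc_max)
        lwc[0, t], lwc[1, t] = la, lb
        k[0, t] = decay_rate(la, p_a)
        k[1, t] = decay_rate(lb, p_b)
        mass[0, t] = decay_step(mass[0, t - 1], k[0, t])
        mass[1, t] = decay_step(mass[1, t - 1], k[1, t])

    traj_wet = LitterTrajectory(params=p_a, day=day, lwc=lwc[0], k=k[0],
                                mass_fraction=mass[0])
    traj_dry = LitterTrajectory(params=p_b, day=day, lwc=lwc[1], k=k[1],
                                mass_fraction=mass[1])
    fw = config.fraction_wet
    combined = fw * mass[0] + (1.0 - fw) * mass[1]
    scenario = "interaction" if config.interaction else "no_interaction"
    return MixtureResult(scenario=scenario, traj_wet=traj_wet,
                         traj_dry=traj_dry, combined_mass=combined,
                         fraction_wet=fw)


def nonadditive_delta(
    result_no_int: MixtureResult, result_int: MixtureResult
) -> np.ndarray:
    """Per-day nonadditive effect, in percentage points of initial mass.

    delta[t] = 100 · (combined_no_interaction[t] − combined_interaction[t]).
    Positive values mean the interaction left *less* mass, i.e. accelerated
    decomposition (synergistic); negative values mean antagonistic; values
    near zero mean the mixture behaved additively.
    """
    if result_no_int.combined_mass.shape != result_int.combined_mass.shape:
        raise ValueError("mismatched horizons between the two scenarios")
    if result_no_int.fraction_wet != result_int.fraction_wet:
        raise ValueError("mismatched mixing fractions between the two scenarios")
    return 100.0 * (result_no_int.combined_mass - result_int.combined_mass)
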