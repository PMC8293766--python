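"""Packaged numerical experiments on the water-transfer mixture model.

Two experiments ship with the package, each run under both the
"no interaction" and "interaction" scenarios:

* **Model Comparison** — two litters identical in every respect except
  evaporation rate (slow wet litter, fast dry litter), simulated once with
  the moyano moisture function and once with the bunnell one. Letting water
  flow keeps both litters moist and accelerates the mixture's mass loss
  under either model (a synergistic effect).

* **Rate Combinations** — litters that also differ in saturation capacity,
  maximum decay rate and moisture sensitivity (bunnell model only).
  Simulation 1 pairs the slow decomposer with slow evaporation and yields
  synergy; simulation 2 swaps the evaporation rates so the wet litter
  drains the dry one's small water stock, yielding antagonism.

The parameter sets are loaded from the packaged YAML fixtures and the whole
pipeline is deterministic: repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import pandas as pd

from .io import packaged_params
from .mixture import MixtureConfig, MixtureResult, nonadditive_delta, simulate_mixture
from .params import LitterParams

__all__ = [
    "DEFAULT_HORIZON",
    "ExperimentSpec",
    "ScenarioPair",
    "run_model_comparison",
    "run_rate_combinations",
    "classify_effect",
    "summarize",
]

DEFAULT_HORIZON = 80
#: classification margin, percentage points of initial mass
DEFAULT_TOLERANCE = 0.01


@dataclass(frozen=True)
class ScenarioPair:
    """An interaction / no-interaction pair for one litter combination."""

    name: str
    no_interaction: MixtureResult
    interaction: MixtureResult

    @property
    def delta(self):
        """Per-day nonadditive effect, pp of initial mass (+ = synergy)."""
        return nonadditive_delta(self.no_interaction, self.interaction)


@dataclass(frozen=True)
class ExperimentSpec:
    """A named set of litter pairs to run under both scenarios."""

    name: str
    pairs: Dict[str, tuple[LitterParams, LitterParams]]
    horizon: int = DEFAULT_HORIZON

    def run(self) -> Dict[str, ScenarioPair]:
        out = {}
        for label, (wet, dry) in self.pairs.items():
            results = {}
            for interaction in (False, True):
                cfg = MixtureConfig(litter_wet=wet, litter_dry=dry,
                                    horizon=self.horizon,
                                    interaction=interaction)
                results[interaction] = simulate_mixture(cfg)
            out[label] = ScenarioPair(name=label,
                                      no_interaction=results[False],
                                      interaction=results[True])
        return out


def _spec_model_comparison(horizon: int) -> ExperimentSpec:
    litters = packaged_params("table1_model_comparison")
    return ExperimentSpec(
        name="model_comparison",
        pairs={
            "moyano": (litters["WET-LIT-moyano"], litters["DRY-LIT-moyano"]),
            "bunnell": (litters["WET-LIT-bunnell"], litters["DRY-LIT-bunnell"]),
        },
        horizon=horizon,
    )


def _spec_rate_combinations(horizon: int) -> ExperimentSpec:
    litters = packaged_params("table1_rate_combinations")
    return ExperimentSpec(
        name="rate_combinations",
        pairs={
            "sim1": (litters["WET-LIT-sim1"], litters["DRY-LIT-sim1"]),
            "sim2": (litters["WET-LIT-sim2"], litters["DRY-LIT-sim2"]),
        },
        horizon=horizon,
    )


def run_model_comparison(horizon: int = DEFAULT_HORIZON) -> Dict[str, ScenarioPair]:
    """Run the Model Comparison experiment; keys ``moyano`` and ``bunnell``."""
    return _spec_model_comparison(horizon).run()


def run_rate_combinations(horizon: int = DEFAULT_HORIZON) -> Dict[str, ScenarioPair]:
    """Run the Rate Combinations experiment; keys ``sim1`` and ``sim2``."""
    return _spec_rate_combinations(horizon).run()


def classify_effect(delta_at_horizon: float,
                    tolerance: float = DEFAULT_TOLERANCE) -> str:
    """Label a nonadditive delta (pp of initial mass) by its sign.

    Deltas within ``tolerance`` of zero are called additive; larger positive
    values synergistic; larger negative values antagonistic.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if delta_at_horizon > tolerance:
        return "synergistic"
    if delta_at_horizon < -tolerance:
        return "antagonistic"
    return "additive"


def summarize(results: Dict[str, ScenarioPair],
              tolerance: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """One row per litter pair: delta at the horizon and its classification."""
    rows = []
    for label, pair in results.items():
        delta_end = float(pair.delta[-1])
        rows.append(
            {
                "pair": label,
                "horizon": pair.no_interaction.day[-1],
                "delta_pp": delta_end,
                "effect": classify_effect(delta_end, tolerance),
            }
        )
    return pd.DataFrame(rows)
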