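"""Litter parameter sets and their validation.

A litter is described by its water-holding capacity (``lwc_max``, g water
per g dry matter), its maximum decomposition rate (``k_max``, d⁻¹), its
evaporation rate (``e``, the daily fraction of currently held water that is
lost), and the Michaelis–Menten constants of one of two moisture-sensitivity
functions for the decay rate:

* ``moyano`` — biological activity vanishes at water saturation; needs
  constants ``a`` (g water g⁻¹ dm, half-saturation on water) and ``b``
  (dimensionless, half-saturation on the oxygen-availability coefficient).
* ``bunnell`` — activity persists at saturation; needs constants ``c`` and
  ``d`` (both g water g⁻¹ dm).

Constants belonging to the inactive model kind may be left unset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "MODEL_KINDS",
    "ConfigurationError",
    "LitterParams",
]

MODEL_KINDS = ("moyano", "bunnell")


class ConfigurationError(ValueError):
    """A litter parameter set is internally inconsistent or incomplete."""


@dataclass(frozen=True)
class LitterParams:
    """Physical and biological constants of one litter.

    Parameters
    ----------
    name:
        Free-form label (species or treatment name).
    lwc_max:
        Litter water content at saturation, g water g⁻¹ dry matter; also
        the initial water content of simulations.
    k_max:
        Maximum decomposition rate, d⁻¹ (daily fraction of remaining mass).
    e:
        Evaporation rate, d⁻¹ (daily fraction of currently held water).
    model_kind:
        Which moisture-sensitivity function drives the decay rate,
        ``"moyano"`` or ``"bunnell"``.
    a, b:
        Michaelis–Menten constants of the moyano form (``a`` in g water
        g⁻¹ dm; ``b`` dimensionless, applied to the oxygen-availability
        coefficient). Required iff ``model_kind == "moyano"``.
    c, d:
        Michaelis–Menten constants of the bunnell form, g water g⁻¹ dm.
        Required iff ``model_kind == "bunnell"``.
    """

    name: str
    lwc_max: float
    k_max: float
    e: float
    model_kind: str = "bunnell"
    a: Optional[float] = None
    b: Optional[float] = None
    c: Optional[float] = None
    d: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ConfigurationError(
                f"{self.name!r}: unknown model_kind {self.model_kind!r}; "
                f"expected one of {MODEL_KINDS}"
            )
        if not self.lwc_max > 0:
            raise ConfigurationError(f"{self.name!r}: lwc_max must be > 0")
        if self.k_max < 0:
            raise ConfigurationError(f"{self.name!r}: k_max must be >= 0")
        if not 0.0 <= self.e <= 1.0:
            raise ConfigurationError(f"{self.name!r}: e must lie in [0, 1]")
        required = ("a", "b") if self.model_kind == "moyano" else ("c", "d")
        for const in required:
            value = getattr(self, const)
            if value is None:
                raise ConfigurationError(
                    f"{self.name!r}: constant {const!r} is required for the "
                    f"{self.model_kind} model"
                )
            if not value > 0:
                raise ConfigurationError(
                    f"{self.name!r}: constant {const!r} must be > 0"
                )

    def with_updates(self, **changes: object) -> "LitterParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)
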