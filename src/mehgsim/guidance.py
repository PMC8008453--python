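"""Health-based guidance values used to contextualize intake.

The Food Safety Commission of Japan set a methylmercury tolerable weekly
intake (TWI) of 2.0 µg/kg bw/week for women who are or may become pregnant.
Single-day simulation output is compared against a tolerable daily intake
(TDI) obtained as TWI/7 ≈ 0.286 µg/kg bw/day; full precision is kept
internally and values are rendered to 3 decimals in reports.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidParameterError

__all__ = ["DEFAULT_TWI", "ReferenceValues", "tdi_from_twi"]

#: µg/kg bw/week, Food Safety Commission of Japan.
DEFAULT_TWI = 2.0


def tdi_from_twi(twi: float) -> float:
    """Tolerable daily intake (µg/kg bw/day) from a weekly one: TWI / 7."""
    if not twi > 0:
        raise InvalidParameterError("TWI must be positive")
    return twi / 7.0


@dataclass(frozen=True)
class ReferenceValues:
    """A TWI (µg/kg bw/week) and its derived TDI (µg/kg bw/day)."""

    twi: float = DEFAULT_TWI
    tdi: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tdi", tdi_from_twi(self.twi))
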