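"""Transport strategies compared by the model."""

from __future__ import annotations

from enum import Enum

__all__ = ["Strategy"]


class Strategy(str, Enum):
    """One of the five modelled modes of transportation.

    ``HPV``: privately owned human-piloted vehicle.
    ``AV``: privately owned autonomous vehicle at today's price.
    ``AV_5YR``: privately owned AV at its projected price five years out
    (price falls by Moore's-law halving; safety unchanged).
    ``AV_TAXI``: autonomous taxi (AV crash profile, taxi cost structure,
    no driver salary).
    ``HPT``: human-piloted taxi.
    """

    HPV = "HPV"
    AV = "AV"
    AV_5YR = "AV_5YR"
    AV_TAXI = "AV_TAXI"
    HPT = "HPT"

    @property
    def is_autonomous(self) -> bool:
        """AV platform: shares the AV crash profile and AV crash costs."""
        return self in (Strategy.AV, Strategy.AV_5YR, Strategy.AV_TAXI)

    @property
    def is_taxi(self) -> bool:
        return self in (Strategy.AV_TAXI, Strategy.HPT)

    @classmethod
    def parse(cls, name: str) -> "Strategy":
        try:
            return cls[name.strip().upper().replace("-", "_")]
        except KeyError:
            raise ValueError(
                f"unknown strategy {name!r}; expected one of "
                f"{', '.join(s.name for s in cls)}"
            ) from None
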