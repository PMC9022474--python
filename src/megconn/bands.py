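"""Frequency-band definitions for band-limited oscillatory analysis.

The canonical set covers the five bands commonly used in paediatric MEG
resting-state work: theta (4–7 Hz), alpha (8–14 Hz), beta (15–29 Hz),
low gamma (30–55 Hz) and gamma (65–80 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with low/high edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )

    @property
    def centre(self) -> float:
        """Band centre frequency in Hz."""
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low

    def check_nyquist(self, sampling_rate: float) -> None:
        """Raise if the band's upper edge is not below the Nyquist frequency."""
        if self.high >= sampling_rate / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz is not below "
                f"Nyquist ({sampling_rate / 2.0} Hz at {sampling_rate} Hz sampling)"
            )


THETA = BandDefinition("theta", 4.0, 7.0)
ALPHA = BandDefinition("alpha", 8.0, 14.0)
BETA = BandDefinition("beta", 15.0, 29.0)
LOW_GAMMA = BandDefinition("low_gamma", 30.0, 55.0)
GAMMA = BandDefinition("gamma", 65.0, 80.0)

CANONICAL_BANDS: tuple[BandDefinition, ...] = (THETA, ALPHA, BETA, LOW_GAMMA, GAMMA)

_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by name (e.g. ``"alpha"``)."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; canonical bands: {sorted(_BY_NAME)}"
        ) from None
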