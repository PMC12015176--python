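"""Canonical spectral band definitions.

The ten bands tile 0.5-70 Hz without gaps; edges are half-open [lo, hi)
except the top band, which is closed at 70 Hz, so shared edges are counted
exactly once when band powers are summed.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta1", 4.0, 6.0),
    BandDefinition("theta2", 6.0, 8.0),
    BandDefinition("alpha1", 8.0, 11.0),
    BandDefinition("alpha2", 11.0, 14.0),
    BandDefinition("sigma", 14.0, 16.0),
    BandDefinition("beta1", 16.0, 18.0),
    BandDefinition("beta2", 18.0, 32.0),
    BandDefinition("gamma1", 32.0, 48.0),
    BandDefinition("gamma2", 48.0, 70.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

#: full analyzed range (Hz)
F_TOTAL_LO = 0.5
F_TOTAL_HI = 70.0
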