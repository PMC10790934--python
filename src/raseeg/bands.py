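"""Spectral band definitions.

The five conventional EEG bands: delta 1-4 Hz, theta 4-8 Hz, alpha 8-12 Hz,
beta 12-30 Hz, gamma 30-50 Hz. Band edges are shared between neighbours as
printed; for discrete *assignment* (e.g. tone-classification in tests) the
half-open convention [low, high) applies, while the analogue filters
naturally overlap at their edges.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float   # Hz
    high: float  # Hz

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name}: need 0 < low < high, got "
                             f"({self.low}, {self.high})")

    @property
    def center(self) -> float:
        """Arithmetic centre frequency in Hz (used for 1/f amplitude weights)."""
        return 0.5 * (self.low + self.high)

    def contains(self, freq: float) -> bool:
        return self.low <= freq < self.high


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str, bands=DEFAULT_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise ValueError(f"unknown band {name!r}; known: {[b.name for b in bands]}")
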