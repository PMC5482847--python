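"""Frequency-band definitions used throughout the pipeline.

The canonical montage analyses four bands below the 20 Hz low-pass:
delta (1-3 Hz), theta (4-8 Hz), alpha (9-12 Hz) and beta (15-20 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with inclusive corner frequencies in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})")

    def validate_rate(self, rate: float) -> None:
        """Raise if the band is not representable at sampling rate ``rate``."""
        if self.hi >= rate / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.hi} Hz >= Nyquist ({rate / 2.0} Hz)"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 3.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 9.0, 12.0),
    BandSpec("beta", 15.0, 20.0),
)


def band_by_name(name: str, bands=CANONICAL_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(name)
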