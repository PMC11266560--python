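"""Axis-aligned rectangular regions of interest.

All coordinates in this package are in nanometres. The default ROI mirrors
a 120 x 120 pixel analysis crop at 78 nm square pixels (9360 x 9360 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

PIXEL_SIZE_NM = 78.0
DEFAULT_CROP_PX = 120


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle, coordinates in nm."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate ROI: ({self.x_min}, {self.y_min}) .. "
                f"({self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x, y):
        """Vectorized membership test (closed rectangle)."""
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )

    @classmethod
    def default(cls) -> "ROI":
        side = DEFAULT_CROP_PX * PIXEL_SIZE_NM
        return cls(0.0, 0.0, side, side)
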