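"""Raster grid geometry.

All rasters participating in one pipeline run must share an identical grid:
same shape, same affine transform, same CRS. Inputs are never resampled or
reprojected — a mismatch is an error, not an interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class GridAlignmentError(ValueError):
    """Rasters do not share one grid (shape, transform or CRS differ)."""


@dataclass(frozen=True)
class RasterGrid:
    """Georeferenced pixel grid.

    ``transform`` is the GDAL-style geotransform
    ``(x_origin, pixel_width, 0, y_origin, 0, -pixel_height)`` mapping the
    *outer corner* of pixel (0, 0) to world coordinates. Rows increase
    southwards (pixel_height entry is negative). The working resolution of
    the method is 10 m, i.e. one pixel covers 100 m².
    """

    width: int
    height: int
    transform: tuple[float, float, float, float, float, float] = (
        0.0, 10.0, 0.0, 0.0, 0.0, -10.0,
    )
    crs: str = "EPSG:32648"
    nodata: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.transform[1] <= 0 or self.transform[5] >= 0:
            raise ValueError("pixel width must be positive, pixel height entry negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def pixel_size(self) -> float:
        return self.transform[1]

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in m² (100 m² at the 10 m working resolution)."""
        return self.transform[1] * (-self.transform[5])

    def xy_of(self, row: int, col: int) -> tuple[float, float]:
        """World coordinates of the centre of pixel (row, col)."""
        x0, px, _, y0, _, py = self.transform
        return (x0 + (col + 0.5) * px, y0 + (row + 0.5) * py)

    def pixel_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel whose half-open footprint contains (x, y).

        A point on a pixel boundary belongs to the pixel whose origin corner
        it touches, which makes point-to-pixel assignment deterministic.
        """
        x0, px, _, y0, _, py = self.transform
        col = math.floor((x - x0) / px)
        row = math.floor((y - y0) / py)
        return (row, col)

    def contains(self, x: float, y: float) -> bool:
        row, col = self.pixel_of(x, y)
        return 0 <= row < self.height and 0 <= col < self.width

    def matches(self, other: "RasterGrid") -> bool:
        return (
            self.width == other.width
            and self.height == other.height
            and self.transform == other.transform
            and self.crs == other.crs
        )

    def require_match(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.matches(other):
            raise GridAlignmentError(
                f"{what} is not on the pipeline grid "
                f"(got {other.width}x{other.height} @ {other.transform}, "
                f"expected {self.width}x{self.height} @ {self.transform}); "
                "inputs must be pre-aligned, no implicit resampling is done"
            )
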