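"""Domain containers: temporal stacks, crop calendar, labelled sample points."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid

OPTICAL_BANDS = (
    "blue", "green", "red", "re1", "re2", "re3",
    "nir", "nnir", "swir1", "swir2",
)
SAR_BANDS = ("vh", "vv")

STAGES = ("sowing", "transplanting", "growing", "maturity")

#: Label vocabulary for sample points. Everything but "rice" maps to the
#: binary non-rice class.
LABELS = (
    "rice", "water", "built-up", "natural-vegetation", "dry-land",
    "non-rice-other",
)


class SchemaError(ValueError):
    """Input does not carry the declared bands/columns."""


class VocabularyError(ValueError):
    """A sample label is outside the declared vocabulary."""


def doy(date: _dt.date) -> int:
    return date.timetuple().tm_yday


@dataclass
class TemporalStack:
    """Date-indexed, co-registered raster bands on one grid.

    values has shape (n_dates, n_bands, height, width); invalid pixels are
    NaN. ``kind`` is one of {"optical-reflectance", "sar-db", "dem"}.
    """

    dates: list[_dt.date]
    bands: list[str]
    values: np.ndarray
    grid: RasterGrid
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.dates), len(self.bands), *self.grid.shape):
            raise SchemaError(
                f"stack values shape {self.values.shape} does not match "
                f"{len(self.dates)} dates x {len(self.bands)} bands x {self.grid.shape}"
            )
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("acquisition dates must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if self.kind == "optical-reflectance" and finite.size:
            if finite.min() < 0.0 or finite.max() > 1.0:
                raise ValueError("optical reflectance must lie in [0, 1] or be nodata")
        if self.kind == "sar-db" and finite.size:
            if finite.min() < -60.0 or finite.max() > 20.0:
                raise ValueError("SAR backscatter in dB is implausible (outside [-60, 20])")

    def band(self, name: str, date_index: int) -> np.ndarray:
        try:
            return self.values[date_index, self.bands.index(name)]
        except ValueError as exc:
            raise SchemaError(f"band {name!r} not in stack bands {self.bands}") from exc

    @property
    def n_dates(self) -> int:
        return len(self.dates)


@dataclass(frozen=True)
class CropCalendar:
    """Ordered phenological stages as half-open day-of-year windows.

    A DOY on a boundary belongs to the later stage ([start, end) windows).
    The defaults are the study-area single-season rice calendar: sowing
    DOY 60-110, transplanting 110-130, growing 130-230, maturity 230-270.
    """

    stages: tuple[tuple[str, int, int], ...] = (
        ("sowing", 60, 110),
        ("transplanting", 110, 130),
        ("growing", 130, 230),
        ("maturity", 230, 270),
    )

    def __post_init__(self) -> None:
        names = [s[0] for s in self.stages]
        if list(names[:4]) != list(STAGES):
            raise ValueError(f"calendar must declare the four stages {STAGES} in order")
        prev_end = -1
        for name, start, end in self.stages:
            if start >= end:
                raise ValueError(f"stage {name}: empty DOY window [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"stage {name} overlaps the previous stage")
            prev_end = end

    def stage_of(self, date: _dt.date) -> str | None:
        """Stage whose window contains the date's DOY, or None (fallow)."""
        d = doy(date)
        for name, start, end in self.stages:
            if start <= d < end:
                return name
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "CropCalendar":
        return cls(tuple((name, int(v[0]), int(v[1])) for name, v in d.items()))

    def to_dict(self) -> dict:
        return {name: [start, end] for name, start, end in self.stages}


@dataclass
class SamplePointSet:
    """Labelled ground points in world coordinates.

    ``points`` is a list of (x, y, label); ``role`` is "training" or
    "validation". ``binary_labels`` collapses every non-rice label.
    """

    points: list[tuple[float, float, str]]
    role: str = "training"
    dropped_outside: int = 0

    def __post_init__(self) -> None:
        for x, y, label in self.points:
            if label not in LABELS:
                raise VocabularyError(
                    f"unknown sample label {label!r}; allowed: {', '.join(LABELS)}"
                )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def labels(self) -> list[str]:
        return [p[2] for p in self.points]

    @property
    def binary_labels(self) -> list[str]:
        return ["rice" if p[2] == "rice" else "non-rice" for p in self.points]

    def pixels(self, grid: RasterGrid) -> list[tuple[int, int]]:
        return [grid.pixel_of(x, y) for x, y, _ in self.points]

    def subset(self, label: str) -> "SamplePointSet":
        return SamplePointSet(
            [p for p in self.points if p[2] == label], role=self.role
        )
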