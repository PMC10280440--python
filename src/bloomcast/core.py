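"""Core domain types for chlorophyll-a image time series.

A satellite-derived chlorophyll-a map is distributed as a color-mapped RGB
raster: each display color ("grade") stands for a concentration band in
µg/L, described by a per-image legend.  The types here carry that structure:

* :class:`ColorScale` — the legend: ordered grades with concentration bounds
  and display colors.
* :class:`Frame` — one dated raster with a water (lake) mask and a mask of
  pixels lost to cloud cover or inversion anomalies.
* :class:`FrameSeries` — a date-ordered sequence of frames sharing one scale.
* :class:`WindowedSample` — thirty consecutive daily frames plus the
  following day's frame, the unit consumed by the forecasting model.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GradeBand", "ColorScale", "Frame", "FrameSeries", "WindowedSample",
    "SENTINEL_COLORS", "snap_to_palette",
]

#: Colors that mark unusable pixels in the source imagery: gray and black
#: (cloud cover) and white (inversion anomaly).
SENTINEL_COLORS = {
    "gray": (128, 128, 128),
    "black": (0, 0, 0),
    "white": (255, 255, 255),
}


@dataclass(frozen=True)
class GradeBand:
    """One legend row: grade index, concentration band (µg/L), display color."""
    index: int
    conc_min: float
    conc_max: float
    color: tuple[int, int, int]


@dataclass(frozen=True)
class ColorScale:
    """An ordered chlorophyll-a legend of G grades (G = 9 for this imagery)."""

    grades: tuple[GradeBand, ...]

    def __post_init__(self):
        if not self.grades:
            raise ValueError("no scales")
        for g in self.grades:
            if not g.conc_min < g.conc_max:
                raise ValueError(
                    f"grade {g.index}: conc_min {g.conc_min} must be < conc_max {g.conc_max}")
        mins = [g.conc_min for g in self.grades]
        if any(a > b for a, b in zip(mins, mins[1:])):
            raise ValueError("grades must be ordered by increasing conc_min")
        colors = [g.color for g in self.grades]
        if len(set(colors)) != len(colors):
            raise ValueError("grade colors must be pairwise distinct")

    def __len__(self):
        return len(self.grades)

    @property
    def colors(self) -> np.ndarray:
        """(G, 3) uint8 palette, grade order."""
        return np.array([g.color for g in self.grades], dtype=np.uint8)

    @property
    def bounds(self) -> np.ndarray:
        """(G, 2) array of (conc_min, conc_max)."""
        return np.array([(g.conc_min, g.conc_max) for g in self.grades], dtype=float)

    def grade_of_color(self) -> dict[tuple[int, int, int], int]:
        """Exact color -> 0-based grade position lookup."""
        return {tuple(g.color): i for i, g in enumerate(self.grades)}

    def quantize(self, conc: np.ndarray) -> np.ndarray:
        """Map concentrations (µg/L) to 0-based grade positions.

        A concentration belongs to the highest grade whose lower bound it
        reaches; values below the first band clamp to grade 0, values above
        the last band clamp to the top grade.
        """
        lows = self.bounds[:, 0]
        idx = np.searchsorted(lows, conc, side="right") - 1
        return np.clip(idx, 0, len(self.grades) - 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.index, g.conc_min, g.conc_max, *g.color) for g in self.grades],
            columns=["grade", "conc_min", "conc_max", "r", "g", "b"],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ColorScale":
        grades = tuple(
            GradeBand(int(row.grade), float(row.conc_min), float(row.conc_max),
                      (int(row.r), int(row.g), int(row.b)))
            for row in df.itertuples()
        )
        return cls(grades)


def snap_to_palette(values: np.ndarray, palette: np.ndarray) -> np.ndarray:
    """Snap float RGB values (..., 3) to the nearest palette color (Euclidean).

    Ties go to the lowest grade index.  Returns uint8 colors of the same
    leading shape.
    """
    flat = values.reshape(-1, 3).astype(np.float64)
    pal = palette.astype(np.float64)  # (G, 3)
    d2 = ((flat[:, None, :] - pal[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin takes first minimum: lowest grade wins
    return palette[idx].reshape(values.shape).astype(np.uint8)


@dataclass
class Frame:
    """A dated color-mapped raster with lake and missing-pixel masks."""

    date: _dt.date
    pixels: np.ndarray            # (H, W, 3) uint8
    missing_mask: np.ndarray      # (H, W) bool — needs repair
    lake_mask: np.ndarray         # (H, W) bool — water pixels
    interpolated: bool = False    # True for frames inserted by daily filling

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        h, w = self.pixels.shape[:2]
        if self.missing_mask is None:
            self.missing_mask = np.zeros((h, w), dtype=bool)
        if self.lake_mask is None:
            self.lake_mask = np.ones((h, w), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.lake_mask = np.asarray(self.lake_mask, dtype=bool)
        if self.pixels.shape != (h, w, 3):
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.missing_mask.shape != (h, w) or self.lake_mask.shape != (h, w):
            raise ValueError("masks must match pixel grid shape")
        if (self.missing_mask & ~self.lake_mask).any():
            raise ValueError("missing_mask must be a subset of lake_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def copy(self) -> "Frame":
        return Frame(self.date, self.pixels.copy(), self.missing_mask.copy(),
                     self.lake_mask.copy(), self.interpolated)


@dataclass
class FrameSeries:
    """Date-ordered frames on one color scale."""

    frames: list[Frame]
    scale: ColorScale | None = None

    def __post_init__(self):
        dates = [f.date for f in self.frames]
        if any(a >= b for a, b in zip(dates, dates[1:])):
            dup = [b for a, b in zip(dates, dates[1:]) if a >= b]
            raise ValueError(f"dates must be strictly increasing; offending: {dup}")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"all frames must share one shape, got {shapes}")

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def dates(self) -> list[_dt.date]:
        return [f.date for f in self.frames]

    def is_daily(self) -> bool:
        return all((b - a).days == 1 for a, b in zip(self.dates, self.dates[1:]))


@dataclass(frozen=True)
class WindowedSample:
    """Thirty consecutive daily input frames and the next day's target."""

    inputs: tuple[Frame, ...]
    target: Frame

    def __post_init__(self):
        if (self.target.date - self.inputs[-1].date).days != 1:
            raise ValueError("target date must be last input date + 1 day")
        dates = [f.date for f in self.inputs]
        if any((b - a).days != 1 for a, b in zip(dates, dates[1:])):
            raise ValueError("input frames must be consecutive days")
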