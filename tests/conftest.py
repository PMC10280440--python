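import datetime as dt

import numpy as np
import pytest

from bloomcast.core import ColorScale, Frame, FrameSeries, GradeBand
from bloomcast.synthdata import default_palette


@pytest.fixture
def palette() -> ColorScale:
    return default_palette()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def make_scale(bounds, colors=None) -> ColorScale:
    """Build a scale from [(lo, hi), ...]; colors default to distinct grays."""
    if colors is None:
        colors = [(10 * (i + 1), 10 * (i + 1), 10 * (i + 1))
                  for i in range(len(bounds))]
    return ColorScale(tuple(
        GradeBand(i + 1, lo, hi, tuple(c))
        for i, ((lo, hi), c) in enumerate(zip(bounds, colors))))


def constant_frame(date, shape, color, lake=None, missing=None,
                   interpolated=False) -> Frame:
    h, w = shape
    pixels = np.zeros((h, w, 3), np.uint8)
    pixels[...] = color
    lake = np.ones((h, w), bool) if lake is None else lake
    missing = np.zeros((h, w), bool) if missing is None else missing
    return Frame(date, pixels, missing, lake, interpolated)


def daily_series(n, shape=(8, 8), color=(40, 60, 200), scale=None,
                 start=dt.date(2010, 3, 11)) -> FrameSeries:
    frames = [constant_frame(start + dt.timedelta(days=i), shape, color)
              for i in range(n)]
    return FrameSeries(frames, scale)
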