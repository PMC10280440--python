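"""Seeded synthetic lake-image series with every defect the preprocessing fixes.

The generator emulates the structure of color-mapped chlorophyll-a imagery
over a shallow lake without any real downloads:

* a lake-shaped water region (a perturbed super-ellipse) on a land
  background;
* a drifting 2-D Gaussian bloom whose amplitude follows a slow sinusoid —
  deliberately simple dynamics a reduced model can demonstrably learn;
* pixels quantised to a 9-grade concentration palette;
* per-image legend jitter (multiplicative noise on the grade bounds),
  emulating inversion differences between acquisitions;
* gray/black cloud blobs and white anomaly speckles with matching masks;
* randomly dropped acquisition days (irregular sampling).

Both the defective "raw" series and the clean daily ground truth are
returned so the preprocessing stages can be scored pixel-by-pixel against
truth via :func:`score_preprocessing`.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .core import (ColorScale, Frame, FrameSeries, GradeBand, SENTINEL_COLORS,
                   snap_to_palette)

__all__ = ["SynthConfig", "default_palette", "generate_series",
           "score_preprocessing", "mean_fill_baseline"]

#: 9-grade display palette, low (blue) to high (red) concentration.
_PALETTE_COLORS = (
    (40, 60, 200), (40, 120, 220), (60, 180, 220), (80, 200, 150),
    (120, 210, 80), (200, 220, 60), (240, 180, 40), (240, 120, 30),
    (220, 40, 30),
)

#: Concentration band edges in µg/L (9 bands), typical of a eutrophic lake.
_BAND_EDGES = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 60.0, 80.0, 120.0)

#: Land/background display color (distinct from palette and sentinels).
LAND_COLOR = (205, 190, 160)


def default_palette() -> ColorScale:
    """The base 9-grade legend shared by all synthetic images."""
    grades = tuple(
        GradeBand(i + 1, _BAND_EDGES[i], _BAND_EDGES[i + 1], _PALETTE_COLORS[i])
        for i in range(9))
    return ColorScale(grades)


@dataclass
class SynthConfig:
    """Synthetic-series parameters.

    Defaults mirror the sparsity profile of the real test-year imagery:
    75 calendar days of which roughly a quarter survive as acquisitions
    (18 of 75), clouds on about a third of the kept frames, multiplicative
    legend jitter of 5%, and sparse white anomaly speckles.
    """

    shape: tuple = (128, 128)
    n_days: int = 75
    start_date: _dt.date = _dt.date(2011, 10, 17)
    seed: int = 0
    # bloom dynamics
    drift: tuple = (0.35, 0.6)       # px/day displacement of the bloom center
    amplitude: float = 70.0          # peak added concentration, µg/L
    amp_period: float = 40.0         # days per amplitude sinusoid cycle
    sigma: float = 22.0              # spatial std of the bloom, px
    base_conc: float = 8.0           # background water concentration, µg/L
    # defect rates
    p_scale_jitter: float = 1.0      # probability an image's legend is jittered
    sigma_scale: float = 0.05        # multiplicative legend-noise std
    p_cloud: float = 0.35            # probability a kept frame gets a cloud blob
    cloud_radius: tuple = (4, 14)    # min/max cloud radius, px
    p_anomaly: float = 0.002         # per-water-pixel white speckle rate
    p_drop: float = 0.76             # probability a non-endpoint day is dropped

    def __post_init__(self):
        for name in ("p_scale_jitter", "p_cloud", "p_anomaly", "p_drop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_days < 32:
            raise ValueError("n_days must be >= 32 to yield at least one window")


def _lake_mask(shape, rng: np.random.Generator) -> np.ndarray:
    """Perturbed super-ellipse water region on a land background."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    ry, rx = h * 0.36, w * 0.42
    ang = np.arctan2((yy - cy) / ry, (xx - cx) / rx)
    wobble = 1.0 + 0.12 * np.sin(3 * ang + rng.uniform(0, 2 * np.pi)) \
        + 0.08 * np.sin(5 * ang + rng.uniform(0, 2 * np.pi))
    r = ((np.abs(xx - cx) / rx) ** 2.5 + (np.abs(yy - cy) / ry) ** 2.5) ** (1 / 2.5)
    mask = r <= wobble
    if not mask.any():
        raise ValueError("degenerate lake mask: no water pixels")
    return mask


def _bloom_concentration(cfg: SynthConfig, lake: np.ndarray, day: int) -> np.ndarray:
    h, w = cfg.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy0, cx0 = h * 0.45, w * 0.4
    # bounce the bloom center inside the central box so it stays on the lake
    span_y, span_x = h * 0.25, w * 0.3
    dy = (cfg.drift[0] * day) % (2 * span_y)
    dx = (cfg.drift[1] * day) % (2 * span_x)
    cy = cy0 + (dy if dy <= span_y else 2 * span_y - dy)
    cx = cx0 + (dx if dx <= span_x else 2 * span_x - dx)
    amp = cfg.amplitude * (0.6 + 0.4 * np.sin(2 * np.pi * day / cfg.amp_period))
    field = cfg.base_conc + amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * cfg.sigma ** 2))
    return np.where(lake, field, 0.0)


def _render(conc: np.ndarray, lake: np.ndarray, scale: ColorScale) -> np.ndarray:
    """Quantise a concentration field to palette colors; land gets LAND_COLOR."""
    pixels = np.empty(conc.shape + (3,), dtype=np.uint8)
    pixels[...] = LAND_COLOR
    grades = scale.quantize(conc[lake])
    pixels[lake] = scale.colors[grades]
    return pixels


def _jitter_scale(base: ColorScale, rng: np.random.Generator,
                  sigma: float) -> ColorScale:
    """Multiplicative noise on the band edges, preserving ordering."""
    edges = np.array(_BAND_EDGES)
    factors = rng.normal(1.0, sigma, size=edges.shape)
    jittered = np.sort(np.maximum(edges * factors, 0.0))
    jittered[0] = 0.0
    # keep bands non-degenerate
    for i in range(1, len(jittered)):
        if jittered[i] <= jittered[i - 1]:
            jittered[i] = jittered[i - 1] + 0.1
    grades = tuple(
        GradeBand(g.index, float(jittered[i]), float(jittered[i + 1]), g.color)
        for i, g in enumerate(base.grades))
    return ColorScale(grades)


def _cloud_blob(shape, rng: np.random.Generator, lake: np.ndarray,
                radius_range) -> np.ndarray:
    h, w = shape
    water = np.argwhere(lake)
    cy, cx = water[rng.integers(len(water))]
    r = rng.integers(radius_range[0], radius_range[1] + 1)
    yy, xx = np.mgrid[0:h, 0:w]
    blob = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r
    return blob & lake


def generate_series(cfg: SynthConfig):
    """Build the defective raw series and the clean daily ground truth.

    Returns ``(raw_frames, raw_scales, truth)`` where ``raw_frames`` are the
    surviving dated frames with defects applied and masks set,
    ``raw_scales`` their per-image (possibly jittered) legends, and
    ``truth`` the complete daily palette-quantised :class:`FrameSeries` on
    the base legend.
    """
    rng = np.random.default_rng(cfg.seed)
    base = default_palette()
    lake = _lake_mask(cfg.shape, rng)

    truth_frames = []
    concs = []
    for day in range(cfg.n_days):
        conc = _bloom_concentration(cfg, lake, day)
        concs.append(conc)
        truth_frames.append(Frame(
            cfg.start_date + _dt.timedelta(days=day), _render(conc, lake, base),
            np.zeros(cfg.shape, bool), lake.copy()))
    truth = FrameSeries(truth_frames, base)

    # decide which days survive as acquisitions (endpoints always kept)
    kept = [0] + [d for d in range(1, cfg.n_days - 1)
                  if rng.random() >= cfg.p_drop] + [cfg.n_days - 1]

    raw_frames, raw_scales = [], []
    sentinels = list(SENTINEL_COLORS.values())
    for day in kept:
        # legend jitter is metadata: the reported concentration bounds of each
        # color drift between acquisitions (inversion uncertainty), while the
        # colors themselves are assigned from the base bands
        scale = base
        if rng.random() < cfg.p_scale_jitter:
            scale = _jitter_scale(base, rng, cfg.sigma_scale)
        pixels = _render(concs[day], lake, base)
        missing = np.zeros(cfg.shape, bool)
        if rng.random() < cfg.p_cloud:
            blob = _cloud_blob(cfg.shape, rng, lake, cfg.cloud_radius)
            color = sentinels[rng.integers(0, 2)]          # gray or black
            pixels[blob] = color
            missing |= blob
        if cfg.p_anomaly > 0:
            speckle = (rng.random(cfg.shape) < cfg.p_anomaly) & lake
            pixels[speckle] = SENTINEL_COLORS["white"]
            missing |= speckle
        raw_frames.append(Frame(truth_frames[day].date, pixels, missing, lake.copy()))
        raw_scales.append(scale)
    return raw_frames, raw_scales, truth


def _grade_image(frame: Frame, scale: ColorScale) -> np.ndarray:
    """0-based grade index per pixel (nearest palette color)."""
    flat = frame.pixels.reshape(-1, 3).astype(np.float64)
    pal = scale.colors.astype(np.float64)
    d2 = ((flat[:, None, :] - pal[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).reshape(frame.shape)


def score_preprocessing(repaired: FrameSeries, truth: FrameSeries,
                        repaired_masks: dict | None = None) -> dict:
    """Grade accuracy of a preprocessed series against ground truth.

    Returns the fraction of water pixel-days whose grade matches truth,
    stratified into (a) ``untouched`` pixels passed through unchanged,
    (b) ``inpainted`` pixels filled by spatial-weight repair and
    (c) ``interpolated`` pixel-days inserted by daily filling.
    ``repaired_masks`` maps dates to the pre-repair missing masks
    (as produced by :func:`bloomcast.preprocess.preprocess_series`).
    """
    if len(repaired) != len(truth):
        raise ValueError(f"length mismatch: {len(repaired)} vs {len(truth)}")
    if repaired.dates != truth.dates:
        raise ValueError("date mismatch between repaired and truth series")
    scale = truth.scale
    repaired_masks = repaired_masks or {}
    hits = {"untouched": 0, "inpainted": 0, "interpolated": 0}
    totals = {"untouched": 0, "inpainted": 0, "interpolated": 0}
    for rf, tf in zip(repaired, truth):
        match = _grade_image(rf, scale) == _grade_image(tf, scale)
        lake = tf.lake_mask
        if rf.interpolated:
            strata = {"interpolated": lake}
        else:
            inpaint = repaired_masks.get(rf.date,
                                         np.zeros(rf.shape, bool)) & lake
            strata = {"inpainted": inpaint, "untouched": lake & ~inpaint}
        for name, mask in strata.items():
            hits[name] += int(match[mask].sum())
            totals[name] += int(mask.sum())
    # an empty stratum is vacuously perfect (e.g. no clouds -> nothing inpainted)
    return {name: (hits[name] / totals[name] if totals[name] else 1.0)
            for name in hits}


def mean_fill_baseline(frame: Frame, scale: ColorScale) -> Frame:
    """Fill missing pixels with the global mean water color, then snap.

    A deliberately crude reference against which the spatial-weight repair
    is compared.
    """
    out = frame.copy()
    known = frame.lake_mask & ~frame.missing_mask
    mean_color = frame.pixels[known].astype(np.float64).mean(axis=0)
    fill = snap_to_palette(np.broadcast_to(
        mean_color, (int(frame.missing_mask.sum()), 3)), scale.colors)
    out.pixels[frame.missing_mask] = fill
    out.missing_mask = np.zeros_like(frame.missing_mask)
    return out
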