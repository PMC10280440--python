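"""File formats: PNG frames, legend CSVs, series manifests, window indices.

On disk a series is a directory of RGB PNGs named ``YYYY-MM-DD.png``, one
legend CSV per image (or one shared) with columns
``grade,conc_min,conc_max,r,g,b``, optional mask PNGs (nonzero = missing),
and a manifest CSV with columns ``date,image_path,legend_path,mask_path``
tying them together.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import ColorScale, Frame, FrameSeries, SENTINEL_COLORS

__all__ = [
    "read_legend", "write_legend", "read_manifest", "write_manifest",
    "detect_missing", "infer_lake_mask", "load_series", "write_series",
    "write_windows_index", "read_windows_index", "load_frames_dir",
]

log = logging.getLogger(__name__)


def read_legend(path) -> ColorScale:
    return ColorScale.from_dataframe(pd.read_csv(path))


def write_legend(scale: ColorScale, path) -> None:
    scale.to_dataframe().to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"date", "image_path", "legend_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    if "mask_path" not in df.columns:
        df["mask_path"] = ""
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _color_close(pixels: np.ndarray, color, tol: int) -> np.ndarray:
    c = np.asarray(color, dtype=np.int16)
    return (np.abs(pixels.astype(np.int16) - c) <= tol).all(axis=-1)


def detect_missing(pixels: np.ndarray, tol: int = 10) -> np.ndarray:
    """Pixels matching a sentinel defect color (gray/black/white) within ±tol."""
    mask = np.zeros(pixels.shape[:2], dtype=bool)
    for color in SENTINEL_COLORS.values():
        mask |= _color_close(pixels, color, tol)
    return mask


def infer_lake_mask(pixels: np.ndarray, scale: ColorScale, missing: np.ndarray,
                    tol: int = 10) -> np.ndarray:
    """Water = palette-colored pixels plus flagged-missing pixels.

    Background/land carries none of the legend colors, so palette membership
    (within ±tol per channel) identifies water; masked defects are included
    because only water pixels are repairable targets.
    """
    lake = missing.copy()
    for color in scale.colors:
        lake |= _color_close(pixels, color, tol)
    return lake


def load_series(manifest_path, sentinel_tol: int = 10):
    """Load frames + legends from a manifest CSV.

    Missing masks come from the optional mask PNGs (nonzero = missing) and
    from sentinel-color detection; lake masks are inferred from palette
    membership.  Returns ``(frames, scales)`` lists in date order.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    frames, scales = [], []
    for row in df.itertuples():
        date = _dt.date.fromisoformat(row.date)
        pixels = np.asarray(iio.imread(base / row.image_path))[..., :3]
        scale = read_legend(base / row.legend_path)
        missing = detect_missing(pixels, tol=sentinel_tol)
        if row.mask_path:
            m = np.asarray(iio.imread(base / row.mask_path))
            if m.ndim == 3:
                m = m[..., 0]
            missing |= m > 0
        lake = infer_lake_mask(pixels, scale, missing, tol=sentinel_tol)
        frames.append(Frame(date, pixels, missing & lake, lake))
        scales.append(scale)
    order = np.argsort([f.date for f in frames])
    frames = [frames[i] for i in order]
    scales = [scales[i] for i in order]
    log.info("load_series: %d frames from %s", len(frames), manifest_path)
    return frames, scales


def write_series(series: FrameSeries, out_dir) -> pd.DataFrame:
    """Write one PNG per frame plus the unified legend; return a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    legend_path = out_dir / "legend.csv"
    if series.scale is not None:
        write_legend(series.scale, legend_path)
    rows = []
    for f in series:
        name = f"{f.date.isoformat()}.png"
        iio.imwrite(out_dir / name, f.pixels)
        rows.append({"date": f.date.isoformat(), "image_path": name,
                     "legend_path": legend_path.name, "mask_path": "",
                     "interpolated": f.interpolated})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def write_windows_index(windows, path) -> None:
    """JSON index of the sliding windows: input dates + target date each."""
    payload = [{"inputs": [f.date.isoformat() for f in w.inputs],
                "target": w.target.date.isoformat()} for w in windows]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_windows_index(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def load_frames_dir(frames_dir, scale: ColorScale | None = None) -> FrameSeries:
    """Load a directory of YYYY-MM-DD.png frames (a preprocessed series)."""
    frames_dir = Path(frames_dir)
    if scale is None and (frames_dir / "legend.csv").exists():
        scale = read_legend(frames_dir / "legend.csv")
    frames = []
    for p in sorted(frames_dir.glob("*.png")):
        try:
            date = _dt.date.fromisoformat(p.stem)
        except ValueError:
            continue
        pixels = np.asarray(iio.imread(p))[..., :3]
        h, w = pixels.shape[:2]
        none_missing = np.zeros((h, w), bool)
        lake = (infer_lake_mask(pixels, scale, none_missing) if scale is not None
                else np.ones((h, w), bool))
        frames.append(Frame(date, pixels, none_missing, lake))
    if not frames:
        raise FileNotFoundError(f"no YYYY-MM-DD.png frames in {frames_dir}")
    return FrameSeries(frames, scale)
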