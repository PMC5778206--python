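"""Image and table I/O with spatial calibration.

All measurements downstream are expressed in centimetres via a single
isotropic ``cm_per_pixel`` scale attached to each image at read time.
Images are held as 8-bit-per-channel RGB arrays; deeper rasters are
rescaled to 8 bits on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: Lower bounds (cm^2) of the ten default particle-area classes; the last
#: class is open-ended.  Anchors: the smallest class tops out at 0.1 cm^2
#: (intrinsic pork-meat fat) and the largest starts at 5 cm^2.
DEFAULT_AREA_CLASS_EDGES: tuple[float, ...] = (
    0.0, 0.1, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0,
)


@dataclass(frozen=True)
class CalibratedImage:
    """An RGB raster plus the physical size of one pixel.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols, 3), uint8
        8-bit RGB image data.
    cm_per_pixel : float
        Isotropic pixel pitch in centimetres. Areas in cm^2 are pixel
        counts times ``cm_per_pixel ** 2``.
    source_id : str
        Free-text provenance, e.g. ``"E_07"`` for sample E, replicate 7.
    """

    pixels: np.ndarray
    cm_per_pixel: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be (rows, cols, 3), got {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        if not (self.cm_per_pixel > 0):
            raise ValueError(f"cm_per_pixel must be > 0, got {self.cm_per_pixel}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def pixel_area_cm2(self) -> float:
        """Area of one pixel in cm^2."""
        return self.cm_per_pixel ** 2


@dataclass
class PipelineConfig:
    """Tunable parameters of the segmentation/measurement pipeline.

    The published protocol names a contrast enhancement, filtering and a
    dilation-erosion (closing) step but fixes none of their parameters;
    they are all collected here so a run is fully reproducible from the
    config alone.
    """

    contrast_percentiles: tuple[float, float] = (1.0, 99.0)
    filter_window: int = 3
    threshold_mode: str = "automatic"  # "automatic" (between-class variance) or "fixed"
    fixed_threshold: int = 128
    closing_radius: int = 1  # square structuring element of side 2r+1
    min_particle_area_px: int = 4
    area_class_edges: tuple[float, ...] = DEFAULT_AREA_CLASS_EDGES
    fill_holes: bool = True
    #: minimum Ashman D between the two gray classes inside the slice for
    #: the automatic threshold to count as a real fat/matrix separation;
    #: below it the slice is treated as fat-free (a unimodal histogram
    #: split by the between-class criterion yields D ~= 2.6 on pure noise)
    bimodality_min_d: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.contrast_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"contrast percentiles must be ordered in [0, 100]: {self.contrast_percentiles}")
        if self.filter_window < 1 or self.filter_window % 2 == 0:
            raise ValueError(f"filter_window must be an odd integer >= 1, got {self.filter_window}")
        if self.threshold_mode not in ("automatic", "fixed"):
            raise ValueError(f"threshold_mode must be 'automatic' or 'fixed', got {self.threshold_mode!r}")
        if not (0 <= self.fixed_threshold <= 255):
            raise ValueError("fixed_threshold must be a gray level in [0, 255]")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.min_particle_area_px < 0:
            raise ValueError("min_particle_area_px must be >= 0")
        if self.bimodality_min_d < 0:
            raise ValueError("bimodality_min_d must be >= 0")
        edges = tuple(float(e) for e in self.area_class_edges)
        if len(edges) != 10:
            raise ValueError("area_class_edges must list the 10 lower class bounds (last class open-ended)")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("area_class_edges must be strictly increasing")
        self.area_class_edges = edges

    def asdict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def read_image(path: str | Path, cm_per_pixel: float | None, source_id: str | None = None) -> CalibratedImage:
    """Read a PNG/TIFF/JPEG raster as an 8-bit RGB :class:`CalibratedImage`.

    Grayscale rasters are promoted to RGB by channel replication; 16-bit
    data is rescaled to the 0-255 range.  If ``cm_per_pixel`` is None the
    calibration defaults to 1 (outputs are then in px / px^2) and a
    warning is logged.
    """
    path = Path(path)
    if cm_per_pixel is None:
        logger.warning("no cm_per_pixel calibration for %s: cm-labelled outputs are in pixel units", path)
        cm_per_pixel = 1.0
    elif not (cm_per_pixel > 0):
        raise ValueError(f"cm_per_pixel must be > 0, got {cm_per_pixel}")
    try:
        with Image.open(path) as img:
            arr = np.asarray(img)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if arr.dtype == np.uint16:
        arr = np.round(arr / 257.0).astype(np.uint8)
    elif arr.dtype == np.int32:  # PIL mode "I"
        arr = np.round(np.clip(arr, 0, 65535) / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return CalibratedImage(arr, float(cm_per_pixel), source_id if source_id is not None else path.stem)


def write_image(pixels: np.ndarray, path: str | Path) -> Path:
    """Write an RGB uint8 array (or boolean mask, saved as 0/255) to disk."""
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = (arr * np.uint8(255)).astype(np.uint8)
    Image.fromarray(arr).save(path)
    return path


def write_labels_png(labels: np.ndarray, path: str | Path) -> Path:
    """Write a label raster as a 16-bit grayscale PNG (0 = background)."""
    path = Path(path)
    lab = np.asarray(labels)
    if lab.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit export")
    Image.fromarray(lab.astype(np.uint16)).save(path, format="PNG")
    return path


# ---------------------------------------------------------------------------
# Measurement tables

_IMAGE_COLUMNS = [
    "source_id", "n", "area_slice_cm2", "n_per_area", "vfc_pct",
    "af_mean_cm2", "af_max_cm2", "rf_mean", "rf_max",
]
_PARTICLE_COLUMNS = [
    "source_id", "label", "area_cm2", "perimeter_cm", "roundness",
    "centroid_row", "centroid_col", "touches_border",
]


def write_measurements(measurements: Sequence, path: str | Path) -> Path:
    """Write per-particle rows plus per-image summary rows to one CSV.

    Each row carries a ``row_type`` of ``"particle"`` or ``"image"``.
    Numbers survive a write/read round trip to at least 6 significant
    digits (they are written at full repr precision).
    """
    if not measurements:
        raise ValueError("measurements list is empty")
    path = Path(path)
    prows, irows = [], []
    for m in measurements:
        for p in m.particles:
            prows.append({
                "row_type": "particle", "source_id": m.source_id, "label": p.label,
                "area_cm2": p.area_cm2, "perimeter_cm": p.perimeter_cm,
                "roundness": p.roundness, "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1], "touches_border": p.touches_border,
            })
        irows.append({
            "row_type": "image", "source_id": m.source_id, "n": m.n,
            "area_slice_cm2": m.area_slice_cm2, "n_per_area": m.n_per_area,
            "vfc_pct": m.vfc_pct, "af_mean_cm2": m.af_mean_cm2,
            "af_max_cm2": m.af_max_cm2, "rf_mean": m.rf_mean, "rf_max": m.rf_max,
        })
    df = pd.DataFrame(prows + irows)
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise IOError(f"cannot write measurements to {path}: {exc}") from exc
    return path


def read_measurements(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a measurement CSV back as ``(image_rows, particle_rows)`` frames."""
    df = pd.read_csv(path)
    images = df[df["row_type"] == "image"][["row_type"] + _IMAGE_COLUMNS].drop(columns="row_type")
    particles = df[df["row_type"] == "particle"][["row_type"] + _PARTICLE_COLUMNS].drop(columns="row_type")
    return images.reset_index(drop=True), particles.reset_index(drop=True)


def read_sample_summary(path: str | Path) -> pd.DataFrame:
    """Read a per-sample summary table (one row per sample).

    Expected columns: ``sample`` plus ``<stat>_mean`` / ``<stat>_sd`` (and
    optionally ``<stat>_letters``) for each reported statistic.  This is
    the shape produced by the summarize step and also the shape of
    published per-sample tables.
    """
    df = pd.read_csv(path)
    if "sample" not in df.columns:
        raise ValueError(f"summary table {path} lacks a 'sample' column")
    return df


# ---------------------------------------------------------------------------
# Plain key = value config files

def write_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for key, val in config.asdict().items():
        if isinstance(val, tuple):
            val = ", ".join(repr(v) for v in val)
        lines.append(f"{key} = {val}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config(path: str | Path) -> PipelineConfig:
    kw: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        kw[key] = val
    conv: dict = {}
    defaults = PipelineConfig()
    for f in fields(PipelineConfig):
        if f.name not in kw:
            continue
        raw = kw.pop(f.name)
        default = getattr(defaults, f.name)
        if isinstance(default, bool):
            conv[f.name] = raw.lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            conv[f.name] = int(raw)
        elif isinstance(default, tuple):
            conv[f.name] = tuple(float(x) for x in raw.split(","))
        elif isinstance(default, str):
            conv[f.name] = raw
        else:
            conv[f.name] = float(raw)
    if kw:
        raise ValueError(f"unknown config keys: {sorted(kw)}")
    return PipelineConfig(**conv)
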