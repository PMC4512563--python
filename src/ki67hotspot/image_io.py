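"""Slide/tile reading, resolution geometry and color representations.

Images are 8-bit RGB rasters with physical resolution metadata (µm/pixel).
All rectangle coordinates are 0-based ``(row, col)`` with half-open extents
``[row, row+h) × [col, col+w)`` expressed in level-0 pixels.

A field of quantification is an axis-aligned rectangle matched in area to one
microscope field at 400x magnification (about 0.12 mm² of tissue): 1424×1064
pixels at 0.279 µm/px, or 1024×766 pixels at 0.38895 µm/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage
from skimage import color as skcolor

#: Default physical resolution assumed for plain tiles without metadata
#: (µm per pixel; matches a common 400x scan setting).
DEFAULT_MPP = 0.279


@dataclass(frozen=True)
class SlideMetadata:
    """Physical geometry of a slide's resolution pyramid.

    ``mpp_x``/``mpp_y`` are µm per pixel at level 0; ``level_downsamples``
    is ascending and starts at 1.
    """

    mpp_x: float = DEFAULT_MPP
    mpp_y: float = DEFAULT_MPP
    level_count: int = 1
    level_downsamples: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.mpp_x <= 0 or self.mpp_y <= 0:
            raise ValueError("mpp must be positive")
        ds = tuple(float(d) for d in self.level_downsamples)
        if len(ds) != self.level_count:
            raise ValueError("level_downsamples length must equal level_count")
        if ds[0] != 1.0 or any(a >= b for a, b in zip(ds, ds[1:])):
            raise ValueError("level_downsamples must ascend starting at 1")
        object.__setattr__(self, "level_downsamples", ds)


@dataclass
class RGBImage:
    """An 8-bit-per-channel H×W×3 raster plus its slide metadata."""

    pixels: np.ndarray
    meta: SlideMetadata = field(default_factory=SlideMetadata)
    level: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H×W×3")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, idx: int) -> "ScalarPlane":
        names = "RGB"
        return ScalarPlane(self.pixels[:, :, idx].astype(np.float64), names[idx])


@dataclass
class ScalarPlane:
    """A single real-valued H×W channel (R, G, B, C, M, Y, K, u, u+C, gray)."""

    values: np.ndarray
    name: str = "gray"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)):
            raise ValueError("plane contains non-finite values")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FieldGeometry:
    """Half-open axis-aligned rectangle in level-0 pixel coordinates."""

    width_px: int
    height_px: int
    level: int = 0
    origin: tuple[int, int] = (0, 0)  # (row, col)

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("field dimensions must be positive")


def load_tile(path: str | Path, mpp: float = DEFAULT_MPP) -> RGBImage:
    """Read a plain RGB tile (TIFF or PNG) into an :class:`RGBImage`.

    Tiles carry no embedded resolution; ``mpp`` supplies it.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(PILImage.open(path).convert("RGB"))
    except Exception as exc:  # pragma: no cover - passthrough of I/O failure
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return RGBImage(arr.astype(np.uint8), SlideMetadata(mpp, mpp))


def read_region(source: RGBImage | str | Path, level: int,
                rect: FieldGeometry, mpp: float = DEFAULT_MPP) -> RGBImage:
    """Extract the exact pixel block of ``rect`` from a slide or tile.

    ``source`` may be an in-memory image or a TIFF/PNG path. For pyramidal
    TIFFs, ``level`` indexes the stored pyramid; for plain images only
    level 0 exists. Rectangles are half-open, (row, col), 0-based.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() in {".tif", ".tiff"}:
            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                n_levels = len(series.levels)
                if not 0 <= level < n_levels:
                    raise IndexError(f"level {level} outside pyramid of {n_levels}")
                arr = series.levels[level].asarray()
                ds = tuple(
                    series.levels[0].shape[0] / lvl.shape[0]
                    for lvl in series.levels
                )
                meta = SlideMetadata(mpp, mpp, n_levels, ds)
                img = RGBImage(arr, meta, level)
        else:
            if level != 0:
                raise IndexError("plain tiles have a single level")
            img = load_tile(path, mpp)
    else:
        img = source
        if level != img.level:
            raise IndexError(f"image holds level {img.level}, not {level}")
    r0, c0 = rect.origin
    h, w = rect.height_px, rect.width_px
    H, W = img.shape
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise IndexError(
            f"rect [{r0}:{r0 + h}, {c0}:{c0 + w}) outside image {H}×{W}"
        )
    return RGBImage(img.pixels[r0:r0 + h, c0:c0 + w].copy(), img.meta, level)


def downsample(img: RGBImage, factor: int) -> RGBImage:
    """Block-mean (anti-aliased) reduction of each channel by ``factor``.

    Output dimensions are ``ceil(dim/factor)``; partial edge blocks average
    the pixels they contain. The µm/pixel metadata is scaled by the factor.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return RGBImage(img.pixels.copy(), img.meta, img.level)
    H, W = img.shape
    oh, ow = -(-H // factor), -(-W // factor)
    px = img.pixels.astype(np.float64)
    pad_h, pad_w = oh * factor - H, ow * factor - W
    padded = np.pad(px, ((0, pad_h), (0, pad_w), (0, 0)), mode="edge")
    # mean over full blocks, but weight edge padding out by averaging counts
    counts = np.pad(np.ones((H, W)), ((0, pad_h), (0, pad_w)), mode="constant")
    sums = padded * counts[..., None]
    block = sums.reshape(oh, factor, ow, factor, 3).sum(axis=(1, 3))
    nblk = counts.reshape(oh, factor, ow, factor).sum(axis=(1, 3))
    out = np.rint(block / nblk[..., None]).clip(0, 255).astype(np.uint8)
    meta = replace(
        img.meta, mpp_x=img.meta.mpp_x * factor, mpp_y=img.meta.mpp_y * factor,
        level_count=1, level_downsamples=(1.0,),
    )
    return RGBImage(out, meta, img.level)


def rgb_to_cmyk(img: RGBImage) -> tuple[ScalarPlane, ScalarPlane, ScalarPlane, ScalarPlane]:
    """Naive (device, non-ICC) CMYK conversion on unit-scaled channels.

    ``K = 1 − max(r, g, b)``; ``C = (1−r−K)/(1−K)`` and likewise M, Y,
    with C = M = Y = 0 where K = 1. All outputs lie in [0, 1].
    """
    rgb = img.pixels.astype(np.float64) / 255.0
    k = 1.0 - rgb.max(axis=2)
    denom = np.where(k < 1.0, 1.0 - k, 1.0)
    c = np.where(k < 1.0, (1.0 - rgb[:, :, 0] - k) / denom, 0.0)
    m = np.where(k < 1.0, (1.0 - rgb[:, :, 1] - k) / denom, 0.0)
    y = np.where(k < 1.0, (1.0 - rgb[:, :, 2] - k) / denom, 0.0)
    return (ScalarPlane(c, "C"), ScalarPlane(m, "M"),
            ScalarPlane(y, "Y"), ScalarPlane(k, "K"))


def rgb_to_luv_u(img: RGBImage) -> ScalarPlane:
    """The u* component of CIE L*u*v* (sRGB primaries, D65 white).

    u* is strongly associated with red: DAB-brown pixels score high and
    hematoxylin-blue pixels low, which the hot-spot detector exploits.
    """
    luv = skcolor.rgb2luv(img.pixels.astype(np.float64) / 255.0)
    return ScalarPlane(luv[:, :, 1], "u")


def _minmax01(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def combined_u_plus_c(u: ScalarPlane, c: ScalarPlane) -> ScalarPlane:
    """Sum of the independently min-max-normalized u and C planes.

    Each plane is scaled to [0, 1] over the image (constant planes map to 0),
    so the result lies in [0, 2].
    """
    if u.shape != c.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {c.shape}")
    return ScalarPlane(_minmax01(u.values) + _minmax01(c.values), "u+C")


def fov_area_mm2(geom: FieldGeometry, meta: SlideMetadata) -> float:
    """Physical area of a field of view in mm²."""
    return geom.width_px * geom.height_px * meta.mpp_x * meta.mpp_y / 1e6
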