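"""Binary tissue (specimen) map at the working resolution.

The map is built in three stages on the 8x-downsampled slide:

1. brightness equalization — each RGB channel is divided by its grayscale
   opening with a large disk, cancelling slowly varying illumination so that
   glass ≈ 1 and tissue < 1;
2. Otsu thresholding of the equalized B and R channels (tissue is the dark
   side; the channel masks are combined by union);
3. morphological cleanup — erosion, dilation and hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, erosion, dilation

from .image_io import RGBImage


@dataclass
class SpecimenMap:
    """Binary tissue mask at working (downsampled) resolution."""

    mask: np.ndarray
    working_downsample: int = 8
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            if not np.isin(m, (0, 1)).all():
                raise ValueError("mask must be binary")
            m = m.astype(bool)
        self.mask = m

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _background_envelope(channel: np.ndarray, radius: int) -> np.ndarray:
    # bright upper envelope: dark structures smaller than the disk are
    # removed (dilation then erosion), leaving the local glass brightness
    footprint = disk(radius, decomposition="sequence")
    return erosion(dilation(channel, footprint), footprint)


def brightness_equalize(img: RGBImage, disk_radius: int = 100) -> np.ndarray:
    """Divide each RGB channel by its morphologically smoothed background.

    The background estimate is the bright envelope of the channel (grayscale
    dilation then erosion with a large disk), which removes tissue structures
    smaller than the disk and keeps the slowly varying glass brightness.
    Division flattens illumination — glass ≈ 1, tissue < 1 — and is invariant
    to global multiplicative brightness changes. Returns a float H×W×3 array.
    """
    H, W = img.shape
    if H <= 2 * disk_radius or W <= 2 * disk_radius:
        raise ValueError(f"image {H}×{W} smaller than disk radius {disk_radius}")
    px = img.pixels.astype(np.float64)
    out = np.empty_like(px)
    eps = 1e-6
    for ch in range(3):
        background = _background_envelope(px[:, :, ch], disk_radius)
        out[:, :, ch] = px[:, :, ch] / np.maximum(background, eps)
    return out


def tissue_threshold(equalized: np.ndarray) -> np.ndarray:
    """Union of Otsu masks of the equalized B and R channels.

    Tissue is darker than glass after equalization, so each channel's mask is
    the below-threshold side. A constant channel has no Otsu threshold and
    contributes an empty mask (with a warning).
    """
    mask = np.zeros(equalized.shape[:2], dtype=bool)
    for ch, name in ((2, "B"), (0, "R")):
        channel = equalized[:, :, ch]
        if np.ptp(channel) == 0:
            warnings.warn(f"channel {name} is constant; skipping its Otsu mask")
            continue
        mask |= channel < threshold_otsu(channel)
    return mask


def clean_mask(mask: np.ndarray, erosion_radius: int = 2,
               dilation_radius: int = 2, fill_holes: bool = True) -> np.ndarray:
    """Erosion, dilation and hole filling of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if erosion_radius > 0:
        mask = erosion(mask, disk(erosion_radius))
    if dilation_radius > 0:
        mask = dilation(mask, disk(dilation_radius))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def build_specimen_map(img: RGBImage, disk_radius: int = 100,
                       erosion_radius: int = 2, dilation_radius: int = 2,
                       working_downsample: int = 8) -> SpecimenMap:
    """Equalize → threshold → clean; the step-1 specimen map."""
    equalized = brightness_equalize(img, disk_radius)
    raw = tissue_threshold(equalized)
    cleaned = clean_mask(raw, erosion_radius, dilation_radius)
    return SpecimenMap(
        cleaned, working_downsample,
        provenance=[
            f"brightness_equalize(disk_radius={disk_radius})",
            "tissue_threshold(otsu, channels=B|R, side=below)",
            f"clean_mask(erosion={erosion_radius}, dilation={dilation_radius},"
            " fill_holes=True)",
        ],
    )
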