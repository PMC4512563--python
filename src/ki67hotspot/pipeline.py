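"""End-to-end composition of the hot-spot pipeline.

Glues the stages together in the published order: downsample to working
resolution → specimen map → hemorrhage exclusion (texture SVM) → brown-mark
detection → density map → dispersion-controlled field selection → optional
full-resolution Ki-67 scoring. Used by the command-line interface and by the
synthetic-study helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import dilation, disk

from .image_io import FieldGeometry, RGBImage, downsample, read_region, rgb_to_luv_u
from .specimen_map import SpecimenMap, build_specimen_map
from .texture_features import build_feature_bank
from .hemorrhage_classifier import (
    RegionSample, TextureClassifier, classify_map, exclude_hemorrhage, train,
)
from .hotspot_selection import (
    DensityMap, PenaltyParams, SelectionSet, density_map,
    immunopositive_marks, select_fields,
)
from .ki67_quantification import Ki67Score, score_slide
from . import synthetic_slides


@dataclass
class PipelineResult:
    """All intermediate products of one hot-spot run."""

    working: RGBImage
    specimen: SpecimenMap
    hemorrhage: np.ndarray | None
    marks: np.ndarray
    density: DensityMap
    selection: SelectionSet
    score: Ki67Score | None = None


def run_hotspots(full: RGBImage, fov: FieldGeometry,
                 working_downsample: int = 8, n_fields: int = 20,
                 rho: float = 0.2, opening_radius: int = 100,
                 classifier: TextureClassifier | None = None,
                 block: int = 32, hem_margin_px: "int | None" = None,
                 stride: int = 1, slide_id: str = "") -> PipelineResult:
    """Run specimen map → hemorrhage exclusion → density → selection.

    ``classifier`` is optional; without one, hemorrhage exclusion is skipped.
    ``hem_margin_px`` dilates the predicted hemorrhage mask before exclusion
    so strongly red boundary pixels cannot masquerade as brown marks; the
    default, block//2 + 2, covers the patch-grid quantization of the
    classifier.
    """
    working = downsample(full, working_downsample)
    specimen = build_specimen_map(working, disk_radius=opening_radius,
                                  working_downsample=working_downsample)
    hem = None
    if classifier is not None:
        stack = build_feature_bank(working)
        hem = classify_map(stack, specimen, classifier, block=block)
        if hem_margin_px is None:
            hem_margin_px = block // 2 + 2
        margin = dilation(hem, disk(hem_margin_px)) if hem_margin_px else hem
        specimen = exclude_hemorrhage(specimen, margin & specimen.mask)
    marks = immunopositive_marks(rgb_to_luv_u(working), specimen)
    dmap = density_map(marks, fov, working_downsample)
    selection = select_fields(dmap, specimen, n=n_fields,
                              params=PenaltyParams(rho), fov=fov,
                              stride=stride, slide_id=slide_id)
    return PipelineResult(working, specimen, hem, marks, dmap, selection)


def score_selection(full: RGBImage, result: PipelineResult,
                    **segment_kwargs) -> PipelineResult:
    """Score the selected fields at full resolution; fills ki67_pct."""
    result.score = score_slide(result.selection,
                               lambda g: read_region(full, 0, g),
                               **segment_kwargs)
    return result


def train_synthetic_classifier(seed: int = 0, n_slides: int = 2,
                               block: int = 8, k: int = 25,
                               working_downsample: int = 8
                               ) -> TextureClassifier:
    """Teach the hemorrhage SVM on synthetic slides with known masks.

    Pools the 64-layer bank over ``block``-sized patches that lie fully
    inside the planted hemorrhage or the nucleated tissue, on ``n_slides``
    generated slides.
    """
    samples: list[RegionSample] = []
    for i in range(n_slides):
        params = synthetic_slides.SynthParams(seed=seed + 1000 * i)
        img, truth = synthetic_slides.generate_slide(params)
        working = downsample(img, working_downsample)
        stack = build_feature_bank(working)
        arr = stack.as_array(sorted(stack.maps))
        ds = working_downsample
        hem = _downsample_mask(truth.hemorrhage_mask, ds)
        tum = _downsample_mask(truth.tissue_mask, ds) & ~dilation(hem, disk(2))
        H, W = hem.shape
        for r in range(0, H - block + 1, block):
            for c in range(0, W - block + 1, block):
                win = (slice(r, r + block), slice(c, c + block))
                for label, m in (("hemorrhage", hem), ("tumor", tum)):
                    if m[win].mean() >= 0.9:
                        region = np.zeros_like(m)
                        region[win] = True
                        samples.append(RegionSample(
                            arr[:, region].mean(axis=1), label,
                            origin=f"slide{i}:{r},{c}"))
    return train(samples, k=k)


def _downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    H, W = mask.shape
    h, w = H // factor, W // factor
    return mask[:h * factor, :w * factor].reshape(
        h, factor, w, factor).mean(axis=(1, 3)) > 0.5
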