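"""Hot-spot detection and dispersion-controlled field selection.

Immunopositive (DAB-brown) nuclei appear as local minima of a brownness
plane derived from the CIE L*u*v* u* channel. The extended regional minima
transformation isolates one mark per stained object; convolving the marks
with a normalized disk kernel gives a density map whose local maxima are the
hot spots.

Fields of quantification are then chosen greedily. Each candidate center is
scored by ``density × penalty`` where

    penalty = max(0, 1 − ρ · Σ_i 1 / dist(candidate, selected_i))

with distances measured in field-of-view widths. ρ = 0 packs all fields into
the dominant hot spot; larger ρ disperses them across the specimen while
still preferring the densest regions (the default, ρ = 0.2, is calibrated
against expert selections via the LCM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import local_minima, reconstruction

from .image_io import FieldGeometry, ScalarPlane
from .specimen_map import SpecimenMap


@dataclass
class DensityMap:
    """Local density of immunopositive-cell marks at working resolution."""

    values: np.ndarray
    kernel_radius: int
    mark_count: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if (v < -1e-12).any():
            raise ValueError("density must be non-negative")
        self.values = np.maximum(v, 0.0)


@dataclass(frozen=True)
class PenaltyParams:
    """Dispersion penalty: strength ρ (distances in FOV widths, floor 0)."""

    rho: float = 0.2

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


@dataclass
class FieldOfView:
    """A selected quantification rectangle with its selection score."""

    geometry: FieldGeometry
    center: tuple[float, float]  # (row, col), working-resolution pixels
    score: float
    ki67_pct: float | None = None


@dataclass
class SelectionSet:
    """Ordered fields of quantification for one slide."""

    fields: list[FieldOfView]
    params: PenaltyParams
    fov: FieldGeometry
    slide_id: str = ""

    def __len__(self) -> int:
        return len(self.fields)

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.fields], dtype=float)


def immunopositive_marks(u: ScalarPlane, specimen: SpecimenMap,
                         h_frac: float = 0.1) -> np.ndarray:
    """Extended regional minima of the brownness plane within tissue.

    u* increases with redness, so DAB-brown objects are maxima of u and the
    brownness plane is −u (they become its deepest minima; hematoxylin-blue
    nuclei sit on the opposite side). Minima whose depth relative to their
    surroundings exceeds ``h = h_frac · (max − min within tissue)`` each
    yield one connected mark. Hemorrhage is also strongly red, which is why
    the specimen map must already be hemorrhage-excluded. Empty specimen
    map → no marks.
    """
    mask = specimen.mask
    if not mask.any():
        return np.zeros_like(mask)
    plane = -u.values.astype(np.float64)
    inside = plane[mask]
    # robust dynamic range: a handful of extreme pixels (e.g. residual
    # hemorrhage rim) must not inflate the minima depth
    lo, hi = np.percentile(inside, [0.5, 99.5])
    rng = float(hi - lo)
    if rng == 0:
        return np.zeros_like(mask)
    h = h_frac * rng
    # push non-tissue to the maximum so background creates no minima
    work = np.where(mask, plane, inside.max())
    # extended minima: regional minima of the h-minima transform
    hmin = reconstruction(work + h, work, method="erosion")
    marks = local_minima(hmin, connectivity=2) & mask
    # color gate: a mark must be distinctly browner than typical tissue,
    # otherwise bare-tissue pools enclosed by blue-nucleus ridges qualify
    # as deep minima too
    brown_cut = float(np.median(inside)) - 0.5 * h
    labels = cc_label(marks, connectivity=2)
    keep = np.zeros_like(marks)
    for prop in regionprops(labels, intensity_image=plane):
        if prop.intensity_min <= brown_cut:
            keep[labels == prop.label] = True
    return keep


def density_map(marks: np.ndarray, fov: FieldGeometry,
                working_downsample: int = 8) -> DensityMap:
    """Convolve mark centroids with a normalized disk kernel.

    The kernel radius is half the FOV diagonal at working resolution, so a
    pixel's density is (approximately) the number of marks a field centered
    there would capture, normalized to integrate to one per mark.
    """
    marks = np.asarray(marks, dtype=bool)
    w = fov.width_px / working_downsample
    h = fov.height_px / working_downsample
    radius = max(1, int(round(0.5 * float(np.hypot(w, h)))))
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    kernel = (yy * yy + xx * xx <= radius * radius).astype(np.float64)
    kernel /= kernel.sum()
    impulses = np.zeros(marks.shape, dtype=np.float64)
    count = 0
    if marks.any():
        for prop in regionprops(cc_label(marks, connectivity=2)):
            r, c = prop.centroid
            impulses[int(round(r)), int(round(c))] += 1.0
            count += 1
    values = ndimage.convolve(impulses, kernel, mode="constant", cval=0.0)
    return DensityMap(values, radius, count)


def penalty(candidate: tuple[float, float],
            selected: "list[tuple[float, float]] | np.ndarray",
            params: PenaltyParams, fov_width: float) -> float:
    """1 − ρ · Σ_i 1/dist(candidate, selected_i), clipped below at 0.

    Distances are Euclidean between centers, in units of the FOV width
    (``fov_width``, working-resolution pixels).
    """
    selected = np.asarray(selected, dtype=float).reshape(-1, 2)
    if len(selected) == 0:
        return 1.0
    d = np.hypot(selected[:, 0] - candidate[0], selected[:, 1] - candidate[1])
    d = d / fov_width
    if (d == 0).any():
        raise ValueError("candidate coincides with a selected center")
    return max(0.0, 1.0 - params.rho * float((1.0 / d).sum()))


def _coverage_map(mask: np.ndarray, h: int, w: int) -> np.ndarray:
    """Fraction of each h×w window (centered per pixel) covered by mask."""
    return ndimage.uniform_filter(mask.astype(np.float64), size=(h, w),
                                  mode="constant", cval=0.0)


def select_fields(dmap: DensityMap, specimen: SpecimenMap, n: int = 20,
                  params: PenaltyParams = PenaltyParams(),
                  fov: FieldGeometry = FieldGeometry(1424, 1064),
                  tumor_cover: float = 0.8, stride: int = 1,
                  max_overlap: float = 0.5, slide_id: str = "") -> SelectionSet:
    """Greedy dispersion-controlled selection of up to ``n`` fields.

    At every step the candidate center maximizing ``density × penalty`` is
    selected, among centers whose field is at least ``tumor_cover`` covered
    by the (hemorrhage-excluded) specimen map, lies inside the slide, and
    overlaps every already-selected field by at most ``max_overlap`` of the
    field area. Selection stops at ``n`` fields or when no candidate has a
    positive adjusted score.
    """
    values = dmap.values
    mask = specimen.mask
    if values.shape != mask.shape:
        raise ValueError("density map and specimen map are not aligned")
    H, W = mask.shape
    ds = specimen.working_downsample
    fh = max(1, int(round(fov.height_px / ds)))
    fw = max(1, int(round(fov.width_px / ds)))
    cover = _coverage_map(mask, fh, fw)

    rows = np.arange(fh // 2, H - (fh - 1) // 2, stride)
    cols = np.arange(fw // 2, W - (fw - 1) // 2, stride)
    if len(rows) == 0 or len(cols) == 0:
        warnings.warn("slide smaller than one field of view; empty selection")
        return SelectionSet([], params, fov, slide_id)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    eligible = cover[rr, cc] >= tumor_cover
    rr, cc = rr[eligible], cc[eligible]
    if len(rr) == 0:
        warnings.warn("no candidate satisfies the tissue-coverage rule")
        return SelectionSet([], params, fov, slide_id)
    dens = values[rr, cc]

    selected: list[FieldOfView] = []
    alive = np.ones(len(rr), dtype=bool)
    inv_sum = np.zeros(len(rr), dtype=float)  # running Σ 1/dist per candidate
    for _ in range(n):
        pen = np.maximum(0.0, 1.0 - params.rho * inv_sum)
        score = dens * pen * alive
        best = int(np.argmax(score))
        if score[best] <= 0:
            break
        r0, c0 = float(rr[best]), float(cc[best])
        geometry = FieldGeometry(
            fov.width_px, fov.height_px, level=0,
            origin=(int(round((r0 - fh / 2) * ds)),
                    int(round((c0 - fw / 2) * ds))),
        )
        selected.append(FieldOfView(geometry, (r0, c0), float(score[best])))
        # kill candidates overlapping the new field by more than max_overlap
        dr = np.abs(rr - r0)
        dc = np.abs(cc - c0)
        ovl = (np.clip(fh - dr, 0, fh) * np.clip(fw - dc, 0, fw)) / (fh * fw)
        alive &= ovl <= max_overlap
        dist = np.hypot(rr - r0, cc - c0) / fw
        # finite cap so rho = 0 stays exactly penalty-free (0 * inf is nan)
        inv = np.where(dist > 0, 1.0 / np.maximum(dist, 1e-12), 1e12)
        inv_sum += inv
    return SelectionSet(selected, params, fov, slide_id)


def selection_to_frame(sel: SelectionSet):
    """Selection as a table: slide_id, rank, row, col, width, height,
    density_score, ki67_pct (level-0 pixel coordinates)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "slide_id": sel.slide_id, "rank": i,
            "row": f.geometry.origin[0], "col": f.geometry.origin[1],
            "width": f.geometry.width_px, "height": f.geometry.height_px,
            "density_score": f.score,
            "ki67_pct": f.ki67_pct if f.ki67_pct is not None else float("nan"),
        }
        for i, f in enumerate(sel.fields)
    ])


def selection_from_frame(frame, params: "PenaltyParams | None" = None,
                         working_downsample: int = 8) -> SelectionSet:
    """Rebuild a :class:`SelectionSet` from its CSV table."""
    rows = frame.sort_values("rank") if "rank" in frame else frame
    fields = []
    fov = None
    slide_id = ""
    for _, rec in rows.iterrows():
        geometry = FieldGeometry(int(rec["width"]), int(rec["height"]),
                                 origin=(int(rec["row"]), int(rec["col"])))
        fov = fov or FieldGeometry(int(rec["width"]), int(rec["height"]))
        center = ((rec["row"] + rec["height"] / 2) / working_downsample,
                  (rec["col"] + rec["width"] / 2) / working_downsample)
        ki = rec.get("ki67_pct", float("nan"))
        fields.append(FieldOfView(
            geometry, center, float(rec.get("density_score", 0.0)),
            None if ki is None or not np.isfinite(ki) else float(ki)))
        slide_id = str(rec.get("slide_id", ""))
    if fov is None:
        raise ValueError("empty field table")
    return SelectionSet(fields, params or PenaltyParams(), fov, slide_id)


def calibrate_rho(cases: "list[tuple[DensityMap, SpecimenMap, object]]",
                  rho_grid: "list[float] | np.ndarray" = tuple(
                      np.round(np.arange(0.1, 0.501, 0.05), 2)),
                  n: int = 20, fov: FieldGeometry = FieldGeometry(1424, 1064),
                  stride: int = 1, ki67_lookup=None,
                  **select_kwargs) -> tuple[float, list[dict]]:
    """Grid-search ρ against reference (expert-proxy) field sets via the LCM.

    ``cases`` pairs each slide's density and specimen maps with a reference
    :class:`~ki67hotspot.concordance_stats.ObserverFieldSet`. For each ρ in
    the grid, fields are selected on every slide and scored against the
    reference with the LCM; the ρ minimizing the mean LCM is returned along
    with the full curve (ρ, mean LCM, mean Ki-67). Per-field Ki-67 values for
    the curve come from ``ki67_lookup(slide_index, field)`` when given.
    """
    from .concordance_stats import LCMParams, ObserverFieldSet, lcm

    rho_grid = [float(r) for r in rho_grid]
    if not rho_grid:
        raise ValueError("empty rho grid")
    if not cases:
        raise ValueError("at least one slide with a reference set required")
    ds = cases[0][1].working_downsample
    fov_w = fov.width_px / ds
    curve: list[dict] = []
    for rho in rho_grid:
        lcms, kis = [], []
        for i, (dmap, spec, ref) in enumerate(cases):
            sel = select_fields(dmap, spec, n=n, params=PenaltyParams(rho),
                                fov=fov, stride=stride, **select_kwargs)
            if len(sel) == 0:
                continue
            ki = [
                float(ki67_lookup(i, f)) if ki67_lookup is not None else 0.0
                for f in sel.fields
            ]
            test = ObserverFieldSet(
                fields=[(f.center[0], f.center[1], k)
                        for f, k in zip(sel.fields, ki)],
                observer_id=f"auto(rho={rho})", slide_id=sel.slide_id,
            )
            lcms.append(lcm(ref, test, LCMParams(fov_size=fov_w)))
            kis.extend(ki)
        curve.append({
            "rho": rho,
            "mean_lcm": float(np.mean(lcms)) if lcms else float("inf"),
            "mean_ki67": float(np.mean(kis)) if kis else float("nan"),
        })
    best = min(curve, key=lambda rec: rec["mean_lcm"])
    return best["rho"], curve
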