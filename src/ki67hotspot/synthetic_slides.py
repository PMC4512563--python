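"""Seed-reproducible synthetic IHC-like slides with known ground truth.

A synthetic slide emulates the structure the pipeline consumes: bright
glass background, pale tissue blobs carrying blue (hematoxylin-like,
immunonegative) and brown (DAB-like, immunopositive) elliptical nuclei,
localized hot-spot disks where the nucleus density and the immunopositive
fraction are elevated, and hemorrhage patches rendered as a coarse
red-dominant blotch texture without nuclei.

Nuclei are placed by a hard-core point process (Poisson intensity with a
minimum center spacing so rendered nuclei never merge); hot spots carry a
Gaussian-peaked density surplus so the planted center is the local density
maximum. Nucleus classes realize the locally planted Ki-67 fraction
exactly within half-field spatial strata, so the planted index is well
defined at the scale fields are scored at. The
ground truth records the tissue and hemorrhage masks, hot-spot centers and
the per-nucleus table, so every pipeline stage can be scored against what
was planted.

Geometry is scaled down relative to clinical scans (slide ~2048 px,
field of view 112×84 px at full resolution) so the full pipeline runs in
seconds; the working resolution stays 8x below full resolution as in the
clinical setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from scipy import ndimage

from .image_io import FieldGeometry, RGBImage, SlideMetadata
from .concordance_stats import ObserverFieldSet

#: Named palette (RGB 0-255) used for rendering.
PALETTE = {
    "glass": (235, 235, 240),
    "tissue": (208, 172, 188),
    "nucleus_negative": (60, 70, 140),   # hematoxylin blue
    "nucleus_positive": (120, 80, 40),   # DAB brown
    "hemorrhage": (170, 60, 60),
}


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration; defaults define the study conditions."""

    slide_size_px: tuple[int, int] = (2048, 2048)
    mpp: float = 0.279
    tissue_blob_count: int = 3
    tissue_blob_radius: tuple[int, int] = (480, 620)
    background_rgb: tuple[int, int, int] = PALETTE["glass"]
    nucleus_radius_px: tuple[int, int] = (4, 6)
    base_density: float = 0.5            # nuclei per 1000 full-res px²
    hotspot_count: int = 5
    hotspot_density_multiplier: float = 6.0
    hotspot_radius: int = 200
    planted_ki67_background_pct: float = 5.0
    planted_ki67_hotspot_pct: float = 30.0
    hemorrhage_patch_count: int = 2
    hemorrhage_patch_radius: int = 130
    hemorrhage_texture_scale: int = 16
    noise_sigma: float = 3.0
    fov: FieldGeometry = FieldGeometry(112, 84)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_density <= 0:
            raise ValueError("base_density must be positive")
        if self.hotspot_density_multiplier < 1:
            raise ValueError("hotspot multiplier must be >= 1")
        for pct in (self.planted_ki67_background_pct,
                    self.planted_ki67_hotspot_pct):
            if not 0 <= pct <= 100:
                raise ValueError("planted percentages must lie in [0, 100]")


@dataclass
class GroundTruth:
    """Everything that was planted, for scoring pipeline stages."""

    tissue_mask: np.ndarray
    hemorrhage_mask: np.ndarray
    hotspot_centers: list[tuple[int, int]]      # (row, col), full-res px
    nucleus_table: np.ndarray                   # columns: row, col, is_positive
    params: SynthParams = None

    def planted_index_at(self, row: float, col: float) -> float:
        """Locally planted Ki-67 percentage at a full-resolution point."""
        p = self.params
        for hr, hc in self.hotspot_centers:
            if (row - hr) ** 2 + (col - hc) ** 2 <= p.hotspot_radius ** 2:
                return p.planted_ki67_hotspot_pct
        return p.planted_ki67_background_pct

    def ki67_in_rect(self, geom: FieldGeometry) -> float:
        """Ground-truth Ki-67 percentage of the nuclei inside a rectangle."""
        if len(self.nucleus_table) == 0:
            return float("nan")
        r0, c0 = geom.origin
        t = self.nucleus_table
        inside = ((t[:, 0] >= r0) & (t[:, 0] < r0 + geom.height_px)
                  & (t[:, 1] >= c0) & (t[:, 1] < c0 + geom.width_px))
        if not inside.any():
            return float("nan")
        return 100.0 * float(t[inside, 2].mean())


class _HardcoreGrid:
    """Spatial hash enforcing a minimum center distance between points."""

    def __init__(self, min_dist: float) -> None:
        self.min_dist = min_dist
        self.cell = max(min_dist, 1.0)
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _key(self, r: float, c: float) -> tuple[int, int]:
        return int(r // self.cell), int(c // self.cell)

    def ok(self, r: float, c: float) -> bool:
        kr, kc = self._key(r, c)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for (pr, pc) in self.grid.get((kr + dr, kc + dc), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < self.min_dist ** 2:
                        return False
        return True

    def add(self, r: float, c: float) -> None:
        self.grid.setdefault(self._key(r, c), []).append((r, c))


def _place_hardcore(rng: np.random.Generator, propose, count: int,
                    grid: _HardcoreGrid, valid,
                    max_tries_per_point: int = 150) -> list[tuple[int, int]]:
    """Dart-throwing placement of up to ``count`` points.

    ``propose() -> (r, c)`` draws a candidate; ``valid(r, c)`` checks the
    region constraint; ``grid`` enforces the hard-core spacing and is shared
    across calls so point sets never collide.
    """
    placed: list[tuple[int, int]] = []
    tries = count * max_tries_per_point
    while len(placed) < count and tries > 0:
        r, c = propose()
        # snap to the pixel grid before the spacing check so the recorded
        # integer coordinates honor the hard core exactly
        r, c = float(int(r)), float(int(c))
        tries -= 1
        if valid(r, c) and grid.ok(r, c):
            grid.add(r, c)
            placed.append((int(r), int(c)))
    return placed


def _mask_sampler(rng: np.random.Generator, mask: np.ndarray):
    rows, cols = np.nonzero(mask)

    def propose() -> tuple[float, float]:
        i = int(rng.integers(0, len(rows)))
        return float(rows[i]), float(cols[i])

    return propose if len(rows) else None


def _render_nucleus(canvas: np.ndarray, rng: np.random.Generator,
                    r: int, c: int, radius: float, rgb: tuple[int, int, int]
                    ) -> None:
    a = radius * rng.uniform(0.85, 1.15)
    b = radius * rng.uniform(0.75, 1.0)
    theta = rng.uniform(0, np.pi)
    rr, cc = draw_ellipse(r, c, a, b, shape=canvas.shape[:2], rotation=theta)
    jitter = rng.normal(0, 6, size=3)
    canvas[rr, cc] = np.clip(np.asarray(rgb, float) + jitter, 0, 255)


def _blotch_texture(rng: np.random.Generator, shape: tuple[int, int],
                    scale: int) -> np.ndarray:
    """Coarse multiplicative blotch field in ~[0.6, 1.4]."""
    small = rng.normal(0, 1, (max(2, shape[0] // scale + 2),
                              max(2, shape[1] // scale + 2)))
    up = ndimage.zoom(small, scale, order=3)[: shape[0], : shape[1]]
    up = ndimage.gaussian_filter(up, scale / 3)
    sd = up.std() or 1.0
    return 1.0 + 0.4 * np.clip(up / (2.5 * sd), -1, 1)


def generate_slide(params: SynthParams = SynthParams()
                   ) -> tuple[RGBImage, GroundTruth]:
    """Render a full synthetic slide plus its ground truth.

    Fully determined by ``params.seed``. Hot spots that cannot be placed
    inside tissue after bounded retries raise a RuntimeError.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.slide_size_px
    canvas = np.empty((H, W, 3), dtype=np.float64)
    canvas[:] = np.asarray(params.background_rgb, float)

    # tissue blobs: ellipses with some eccentricity, unioned
    tissue = np.zeros((H, W), dtype=bool)
    lo, hi = params.tissue_blob_radius
    blob_centers: list[tuple[float, float]] = []
    for _ in range(params.tissue_blob_count):
        radius = rng.uniform(lo, hi)
        # spread blobs: keep centers apart so hot spots have room
        for _try in range(100):
            r = rng.uniform(radius, H - radius)
            c = rng.uniform(radius, W - radius)
            if all(np.hypot(r - pr, c - pc) >= 0.9 * lo
                   for pr, pc in blob_centers):
                break
        blob_centers.append((r, c))
        rr, cc = draw_ellipse(r, c, radius * rng.uniform(0.75, 1.0),
                              radius * rng.uniform(0.75, 1.0),
                              shape=(H, W), rotation=rng.uniform(0, np.pi))
        tissue[rr, cc] = True
    tint = np.asarray(PALETTE["tissue"], float)
    canvas[tissue] = tint + rng.normal(0, 2, size=(int(tissue.sum()), 3))

    # hemorrhage patches inside tissue, blotchy red, no nuclei
    hemorrhage = np.zeros((H, W), dtype=bool)
    tissue_idx = np.transpose(np.nonzero(tissue))
    for _ in range(params.hemorrhage_patch_count):
        for _try in range(100):
            r, c = tissue_idx[rng.integers(0, len(tissue_idx))]
            rr, cc = draw_ellipse(
                r, c, params.hemorrhage_patch_radius * rng.uniform(0.8, 1.0),
                params.hemorrhage_patch_radius * rng.uniform(0.6, 0.9),
                shape=(H, W), rotation=rng.uniform(0, np.pi))
            patch = np.zeros((H, W), dtype=bool)
            patch[rr, cc] = True
            if (patch & tissue).sum() >= 0.9 * patch.sum():
                hemorrhage |= patch & tissue
                break
    if hemorrhage.any():
        blotch = _blotch_texture(rng, (H, W), params.hemorrhage_texture_scale)
        base = np.asarray(PALETTE["hemorrhage"], float)
        hm = hemorrhage
        canvas[hm] = np.clip(base[None, :] * blotch[hm, None]
                             + rng.normal(0, 4, size=(int(hm.sum()), 3)),
                             0, 255)

    # hot-spot disks well inside nucleus-bearing tissue: centers are chosen
    # by farthest-point sampling among positions where the disk is >= 90%
    # covered by tissue, enforcing non-overlap (separation >= 2 radii)
    nucleus_zone = tissue & ~hemorrhage
    hs_r = params.hotspot_radius
    yy, xx = np.mgrid[-hs_r:hs_r + 1, -hs_r:hs_r + 1]
    hs_kernel = (yy * yy + xx * xx <= hs_r * hs_r).astype(np.float64)
    hs_kernel /= hs_kernel.sum()
    from scipy.signal import fftconvolve
    coverage = fftconvolve(nucleus_zone.astype(np.float64), hs_kernel,
                           mode="same")
    cand_r, cand_c = np.nonzero(coverage >= 0.9)
    hotspot_centers: list[tuple[int, int]] = []
    hs_mask = np.zeros((H, W), dtype=bool)
    if len(cand_r) > 0 and params.hotspot_count > 0:
        take = min(4000, len(cand_r))
        pick = rng.choice(len(cand_r), size=take, replace=False)
        cr, cc_ = cand_r[pick].astype(float), cand_c[pick].astype(float)
        first = int(rng.integers(0, take))
        chosen = [first]
        mind = np.hypot(cr - cr[first], cc_ - cc_[first])
        while len(chosen) < params.hotspot_count:
            nxt = int(np.argmax(mind))
            if mind[nxt] < 2.0 * hs_r:
                break
            chosen.append(nxt)
            mind = np.minimum(mind, np.hypot(cr - cr[nxt], cc_ - cc_[nxt]))
        for i in chosen:
            r, c = int(cr[i]), int(cc_[i])
            hotspot_centers.append((r, c))
            rr, cc = draw_ellipse(r, c, hs_r, hs_r, shape=(H, W))
            hs_mask[rr, cc] = True
    if len(hotspot_centers) < params.hotspot_count:
        raise RuntimeError("could not place all hot spots inside tissue")

    # nucleus placement: hard-core Poisson background everywhere, plus a
    # Gaussian-peaked surplus centered on every hot spot (sigma = R/2) so
    # the local density is maximal at the planted center and tapers to the
    # background level at the hot-spot rim
    r_lo, r_hi = params.nucleus_radius_px
    min_dist = 2 * r_hi + 2
    grid = _HardcoreGrid(min_dist)
    rate = params.base_density / 1000.0
    n_bg = int(rng.poisson(rate * int(nucleus_zone.sum())))
    sampler = _mask_sampler(rng, nucleus_zone)
    pts_bg = []
    if sampler is not None:
        pts_bg = _place_hardcore(rng, sampler, n_bg, grid,
                                 lambda r, c: True)
    pts_hs: list[tuple[int, int]] = []
    sigma = hs_r / 2.0
    lam_extra = ((params.hotspot_density_multiplier - 1.0) * rate
                 * 2.0 * np.pi * sigma ** 2
                 * (1.0 - np.exp(-hs_r ** 2 / (2.0 * sigma ** 2))))
    for (hr, hc) in hotspot_centers:
        n_extra = int(rng.poisson(lam_extra))

        def propose() -> tuple[float, float]:
            return (hr + rng.normal(0, sigma), hc + rng.normal(0, sigma))

        def valid(r: float, c: float) -> bool:
            if not (0 <= r < H and 0 <= c < W):
                return False
            if (r - hr) ** 2 + (c - hc) ** 2 > hs_r ** 2:
                return False
            return bool(nucleus_zone[int(r), int(c)])

        pts_hs.extend(_place_hardcore(rng, propose, n_extra, grid, valid))

    # class assignment: the planted positive fraction is enforced locally
    # (spatial strata of roughly half a field of view), so the Ki-67 index of
    # any field-sized window is the planted value up to rounding — the
    # planted index is then well defined at the scale it is scored at
    pts = pts_bg + pts_hs
    classes = np.zeros(len(pts), dtype=bool)
    cell = max(params.fov.width_px, params.fov.height_px) // 2
    strata: dict[tuple[int, int, float], list[int]] = {}
    for i, (r, c) in enumerate(pts):
        p = (params.planted_ki67_hotspot_pct if hs_mask[r, c]
             else params.planted_ki67_background_pct) / 100.0
        strata.setdefault((r // cell, c // cell, p), []).append(i)
    for (_, _, p), idx in strata.items():
        n_pos_f = p * len(idx)
        n_pos = int(n_pos_f) + int(rng.random() < (n_pos_f - int(n_pos_f)))
        chosen = rng.choice(len(idx), size=min(n_pos, len(idx)), replace=False)
        for j in chosen:
            classes[idx[j]] = True

    table = []
    for (r, c), positive in zip(pts, classes):
        table.append((r, c, bool(positive)))
        color = (PALETTE["nucleus_positive"] if positive
                 else PALETTE["nucleus_negative"])
        _render_nucleus(canvas, rng, r, c, rng.uniform(r_lo, r_hi), color)

    if params.noise_sigma > 0:
        canvas += rng.normal(0, params.noise_sigma, canvas.shape)
    img = RGBImage(np.clip(canvas, 0, 255).astype(np.uint8),
                   SlideMetadata(params.mpp, params.mpp))
    truth = GroundTruth(
        tissue_mask=tissue,
        hemorrhage_mask=hemorrhage,
        hotspot_centers=hotspot_centers,
        nucleus_table=np.array(table, dtype=np.float64).reshape(-1, 3),
        params=params,
    )
    return img, truth


def generate_field(tile_size: tuple[int, int], n_pos: int, n_neg: int,
                   seed: int, nucleus_radius_px: tuple[int, int] = (4, 6),
                   noise_sigma: float = 3.0, mpp: float = 0.279
                   ) -> tuple[RGBImage, "tuple[int, int]"]:
    """One full-resolution tissue tile with exactly the requested nuclei.

    Non-overlapping dart-throwing placement; raises if the counts do not fit
    at the given radius and tile size. Returns the tile and the planted
    (positive, negative) counts.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    H, W = tile_size
    canvas = np.empty((H, W, 3), dtype=np.float64)
    canvas[:] = np.asarray(PALETTE["tissue"], float)
    r_lo, r_hi = nucleus_radius_px
    margin = r_hi + 2
    allowed = np.zeros((H, W), dtype=bool)
    allowed[margin:H - margin, margin:W - margin] = True
    min_dist = 2 * r_hi + 2
    sampler = _mask_sampler(rng, allowed)
    pts = _place_hardcore(rng, sampler, n_pos + n_neg, _HardcoreGrid(min_dist),
                          lambda r, c: True) if sampler else []
    if len(pts) < n_pos + n_neg:
        raise ValueError(
            f"cannot place {n_pos + n_neg} nuclei of radius <= {r_hi} "
            f"in a {H}×{W} tile")
    for i, (r, c) in enumerate(pts):
        color = (PALETTE["nucleus_positive"] if i < n_pos
                 else PALETTE["nucleus_negative"])
        _render_nucleus(canvas, rng, r, c, rng.uniform(r_lo, r_hi), color)
    if noise_sigma > 0:
        canvas += rng.normal(0, noise_sigma, canvas.shape)
    img = RGBImage(np.clip(canvas, 0, 255).astype(np.uint8),
                   SlideMetadata(mpp, mpp))
    return img, (n_pos, n_neg)


def generate_observer_proxy(truth: GroundTruth, jitter_px: float = 0.0,
                            dropout_frac: float = 0.0, seed: int = 0,
                            working_downsample: int = 8) -> ObserverFieldSet:
    """Simulated pathologist selection: hot-spot centers with positional
    jitter and random dropout, Ki-67 set to the planted local index plus
    bounded noise. Centers are in working-resolution pixels."""
    if jitter_px < 0:
        raise ValueError("jitter must be non-negative")
    if not 0 <= dropout_frac < 1:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    fields = []
    for (r, c) in truth.hotspot_centers:
        if rng.random() < dropout_frac:
            continue
        jr = rng.normal(0, jitter_px) if jitter_px > 0 else 0.0
        jc = rng.normal(0, jitter_px) if jitter_px > 0 else 0.0
        level = truth.planted_index_at(r, c) + rng.uniform(-1, 1)
        fields.append(((r + jr) / working_downsample,
                       (c + jc) / working_downsample,
                       float(np.clip(level, 0, 100))))
    if not fields:
        raise ValueError("all fields dropped; nothing to return")
    return ObserverFieldSet(fields, observer_id=f"proxy(seed={seed})")
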