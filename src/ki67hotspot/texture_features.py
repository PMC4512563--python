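"""Sum/difference-image (Unser-style) texture features.

Instead of co-occurrence matrices, texture is described through the sum and
difference images

    s(k,l) = f(k,l) + f(k+d1, l+d2)
    d(k,l) = f(k,l) − f(k+d1, l+d2)

for a fixed displacement (d1, d2), and eight local statistics of s and d over
a disk neighborhood Ω centered at every pixel:

    f1 mean               Σ s / (2 N_Ω)                  (= µ_Ω)
    f2 variance           ½ [Σ (s − 2µ_Ω)² + Σ d²] / N_Ω
    f3 energy             (Σ s² · Σ d²) / N_Ω²
    f4 correlation        ½ [Σ (s − 2µ_Ω)² − Σ d²] / N_Ω
    f5 contrast           Σ d² / N_Ω
    f6 homogeneity        Σ 1/(1+d²) / N_Ω
    f7 cluster shade      Σ (s − 2µ_Ω)³ / N_Ω
    f8 cluster prominence Σ (s − 2µ_Ω)⁴ / N_Ω

Every statistic is a disk-mask sum of an element-wise transform of s or d, so
the whole map is computed by linear filtering: the centered moments expand
binomially (e.g. Σ(s−2µ)² = Σs² − 4µΣs + 4µ²N_Ω, with µ varying per center
pixel), giving maps identical to the per-pixel definition to ~1e−12.

The per-image feature bank holds 8 features × 8 color channels = 64 layers,
indexed 1..64 in channel blocks R(1–8), G(9–16), B(17–24), u+C(25–32),
C(33–40), M(41–48), Y(49–56), K(57–64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk

from .image_io import (
    RGBImage,
    ScalarPlane,
    combined_u_plus_c,
    rgb_to_cmyk,
    rgb_to_luv_u,
)

FEATURE_NAMES = {
    1: "mean", 2: "variance", 3: "energy", 4: "correlation",
    5: "contrast", 6: "homogeneity", 7: "cluster_shade",
    8: "cluster_prominence",
}

CHANNEL_BLOCKS = ("R", "G", "B", "u+C", "C", "M", "Y", "K")

#: Default subset of the 64-layer bank retained by Fisher ranking on the
#: original teaching data: energy+contrast on R and G, six statistics each on
#: u+C, C and M, mean+homogeneity on Y, cluster shade on K.
DEFAULT_SELECTED_FEATURES = (
    3, 5,
    11, 13,
    25, 26, 27, 29, 30, 32,
    33, 34, 35, 37, 38, 40,
    41, 42, 43, 45, 46, 48,
    49, 54,
    63,
)


@dataclass
class SumDiffPair:
    """Sum and difference images for one displacement."""

    S: ScalarPlane
    D: ScalarPlane
    displacement: tuple[int, int]

    def __post_init__(self) -> None:
        if self.S.shape != self.D.shape:
            raise ValueError("S and D must share a shape")


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Disk neighborhood Ω: radius in pixels and its pixel count N_Ω."""

    radius: int

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def mask(self) -> np.ndarray:
        return _disk(self.radius).astype(bool)

    @property
    def n_omega(self) -> int:
        return int(self.mask.sum())


@dataclass
class FeatureMap:
    """One per-pixel texture statistic map (feature_id 1..8)."""

    values: ScalarPlane
    feature_id: int

    def __post_init__(self) -> None:
        if self.feature_id not in FEATURE_NAMES:
            raise ValueError(f"unknown feature id {self.feature_id}")


@dataclass
class FeatureStack:
    """The 64-layer bank with (channel_block, feature_id) → 1..64 indexing."""

    maps: dict[int, FeatureMap]

    def layer(self, index: int) -> FeatureMap:
        return self.maps[index]

    @staticmethod
    def layer_index(channel: str, feature_id: int) -> int:
        return CHANNEL_BLOCKS.index(channel) * 8 + feature_id

    @staticmethod
    def layer_label(index: int) -> tuple[str, int]:
        """Inverse of :meth:`layer_index`: 1..64 → (channel, feature_id)."""
        if not 1 <= index <= 64:
            raise ValueError(f"layer index {index} outside 1..64")
        block, fid = divmod(index - 1, 8)
        return CHANNEL_BLOCKS[block], fid + 1

    def as_array(self, indices: "list[int] | None" = None) -> np.ndarray:
        """Stack layers (all, or the given 1-based indices) as (n, H, W)."""
        idx = sorted(self.maps) if indices is None else list(indices)
        return np.stack([self.maps[i].values.values for i in idx])


@dataclass
class LocalHistogram:
    """Normalized integer-binned histograms of s and d over a region."""

    probs_sum: dict[int, float]
    probs_diff: dict[int, float]
    N: int


def sum_difference_images(plane: ScalarPlane,
                          displacement: tuple[int, int] = (3, 3)) -> SumDiffPair:
    """Compute s = f + f_shifted and d = f − f_shifted.

    The translated partner of a border pixel is taken by edge replication
    (indices clamped to the image), so s and d are defined everywhere.
    """
    d1, d2 = displacement
    f = plane.values
    H, W = f.shape
    if abs(d1) >= H or abs(d2) >= W:
        raise ValueError(f"displacement {displacement} exceeds image {H}×{W}")
    rows = np.clip(np.arange(H) + d1, 0, H - 1)
    cols = np.clip(np.arange(W) + d2, 0, W - 1)
    shifted = f[np.ix_(rows, cols)]
    return SumDiffPair(
        ScalarPlane(f + shifted, f"s({plane.name})"),
        ScalarPlane(f - shifted, f"d({plane.name})"),
        (d1, d2),
    )


def local_histograms(pair: SumDiffPair, region: np.ndarray) -> LocalHistogram:
    """Normalized probabilities P̂s(i) = h_s(i)/N and P̂d(i) = h_d(i)/N.

    Values are binned at integer resolution (rounded) inside ``region``.
    """
    region = np.asarray(region, dtype=bool)
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")

    def _probs(values: np.ndarray) -> dict[int, float]:
        binned = np.rint(values[region]).astype(int)
        uniq, counts = np.unique(binned, return_counts=True)
        return {int(u): float(c) / n for u, c in zip(uniq, counts)}

    return LocalHistogram(_probs(pair.S.values), _probs(pair.D.values), n)


def _disk_sum(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    # disk-mask sum at every center; edge replication outside the image
    return ndimage.correlate(arr, mask.astype(np.float64), mode="nearest")


def unser_feature_maps(pair: SumDiffPair, spec: NeighborhoodSpec,
                       features: "tuple[int, ...] | list[int]" = tuple(range(1, 9)),
                       ) -> list[FeatureMap]:
    """Per-pixel feature maps over the disk neighborhood.

    Implemented with linear filtering of element-wise transformed sum and
    difference planes; equals the naive per-pixel disk computation to
    floating-point accuracy.
    """
    features = list(features)
    for fid in features:
        if fid not in FEATURE_NAMES:
            raise ValueError(f"unknown feature id {fid}")
    mask = spec.mask
    n = float(spec.n_omega)
    S, D = pair.S.values, pair.D.values

    sum_s = _disk_sum(S, mask)
    mu = sum_s / (2.0 * n)
    need_d2 = any(f in features for f in (2, 3, 4, 5))
    sum_d2 = _disk_sum(D * D, mask) if need_d2 else None

    def central_moment(p: int) -> np.ndarray:
        # Σ_Ω (s − 2µ)^p with per-center µ, expanded binomially so each term
        # is a plain disk filter of a power of s
        powers = {0: np.full_like(S, n)}
        for q in range(1, p + 1):
            powers[q] = sum_s if q == 1 else _disk_sum(S ** q, mask)
        out = np.zeros_like(S)
        from math import comb
        for q in range(p + 1):
            out += comb(p, q) * powers[p - q] * (-2.0 * mu) ** q
        return out

    out: list[FeatureMap] = []
    for fid in features:
        if fid == 1:
            vals = mu
        elif fid == 2:
            vals = 0.5 * (central_moment(2) + sum_d2) / n
        elif fid == 3:
            vals = _disk_sum(S * S, mask) * sum_d2 / (n * n)
        elif fid == 4:
            vals = 0.5 * (central_moment(2) - sum_d2) / n
        elif fid == 5:
            vals = sum_d2 / n
        elif fid == 6:
            vals = _disk_sum(1.0 / (1.0 + D * D), mask) / n
        elif fid == 7:
            vals = central_moment(3) / n
        else:
            vals = central_moment(4) / n
        name = f"{FEATURE_NAMES[fid]}[{pair.S.name}]"
        out.append(FeatureMap(ScalarPlane(vals, name), fid))
    return out


def channel_planes(img: RGBImage) -> dict[str, ScalarPlane]:
    """The eight analysis planes: R, G, B, u+C, C, M, Y, K.

    RGB stays on the 0–255 scale; CMYK planes are on [0, 1] and u+C on
    [0, 2] by construction.
    """
    c, m, y, k = rgb_to_cmyk(img)
    u = rgb_to_luv_u(img)
    return {
        "R": img.channel(0), "G": img.channel(1), "B": img.channel(2),
        "u+C": combined_u_plus_c(u, c),
        "C": c, "M": m, "Y": y, "K": k,
    }


def build_feature_bank(img: RGBImage, displacement: tuple[int, int] = (3, 3),
                       radius: int = 10,
                       layers: "list[int] | None" = None) -> FeatureStack:
    """Compute the 64-layer texture bank (or the requested layer subset).

    8 features × 8 channel planes, indexed per channel blocks R(1–8),
    G(9–16), B(17–24), u+C(25–32), C(33–40), M(41–48), Y(49–56), K(57–64).
    """
    H, W = img.shape
    if H <= 2 * radius or W <= 2 * radius:
        raise ValueError(f"image {H}×{W} too small for disk radius {radius}")
    wanted = set(range(1, 65)) if layers is None else set(layers)
    spec = NeighborhoodSpec(radius)
    maps: dict[int, FeatureMap] = {}
    for block, (name, plane) in enumerate(channel_planes(img).items()):
        fids = [fid for fid in range(1, 9) if block * 8 + fid in wanted]
        if not fids:
            continue
        pair = sum_difference_images(plane, displacement)
        for fmap in unser_feature_maps(pair, spec, fids):
            maps[block * 8 + fmap.feature_id] = fmap
    return FeatureStack(maps)


def fisher_rank(samples: np.ndarray, labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by the Fisher discriminant score J = (µ₁−µ₂)²/(σ₁²+σ₂²).

    ``samples`` is (n_samples, n_features); ``labels`` binary. Features with
    zero variance in both classes score 0. Returns (ranked 1-based indices
    descending by J, scores in feature order). Ties break toward the lower
    index.
    """
    samples = np.asarray(samples, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    a, b = samples[labels == classes[0]], samples[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per class")
    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    den = a.var(axis=0, ddof=0) + b.var(axis=0, ddof=0)
    scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order + 1, scores


def select_features(ranked: np.ndarray, k: int = 25) -> tuple[int, ...]:
    """Keep the first ``k`` of a ranking (stable, deterministic)."""
    ranked = np.asarray(ranked)
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds {len(ranked)} ranked features")
    return tuple(int(i) for i in ranked[:k])
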