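"""Hemorrhage removal from the specimen map by texture classification.

Hemorrhage (extravasated erythrocytes) shows a coarse red-dominant texture
without the nucleated blue/brown pattern of tumor tissue. Patches of the
working-resolution slide are described by pooled Unser texture features;
a Fisher-ranked subset of the 64-layer bank feeds a Gaussian-kernel SVM
which labels each patch tumor vs hemorrhage. Hemorrhage-labelled patches
are removed from the specimen map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .specimen_map import SpecimenMap
from .texture_features import FeatureStack, fisher_rank, select_features

LABELS = ("tumor", "hemorrhage")


@dataclass
class RegionSample:
    """Pooled feature vector of one patch with its class label."""

    features: np.ndarray
    label: str
    origin: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite features")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


@dataclass
class TextureClassifier:
    """Gaussian-kernel SVM over z-scored, Fisher-selected texture features."""

    selected_features: tuple[int, ...]
    C: float = 1.0
    gamma: float | None = None
    scaler: StandardScaler | None = None
    svm: SVC | None = None
    feature_space: int = 64

    @property
    def fitted(self) -> bool:
        return self.svm is not None

    def predict(self, feature_vectors: np.ndarray) -> np.ndarray:
        """Labels for (n, feature_space) pooled vectors."""
        if not self.fitted:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(feature_vectors, dtype=np.float64)
        idx = np.asarray(self.selected_features) - 1
        return self.svm.predict(self.scaler.transform(X)[:, idx])


def pool_region_features(stack: FeatureStack, region_mask: np.ndarray
                         ) -> np.ndarray:
    """Mean of each feature map over the region — the patch descriptor."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty region")
    idx = sorted(stack.maps)
    arr = stack.as_array(idx)
    return arr[:, region_mask].mean(axis=1)


def train(samples: list[RegionSample], k: int = 25, C: float = 1.0,
          gamma: float | None = None) -> TextureClassifier:
    """Fit scaler → Fisher ranking → top-k selection → RBF-SVM.

    ``gamma`` defaults to 1/(k · median feature variance) computed on the
    z-scored training matrix (≈ 1/k). Deterministic for a fixed sample order.
    """
    labels = np.array([s.label for s in samples])
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present")
    for lab in LABELS:
        if (labels == lab).sum() < 5:
            raise ValueError(f"need >= 5 samples of class {lab!r}")
    X = np.stack([s.features for s in samples])
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    ranked, _ = fisher_rank(Z, labels)
    selected = select_features(ranked, k)
    idx = np.asarray(selected) - 1
    Zs = Z[:, idx]
    if gamma is None:
        med_var = float(np.median(Zs.var(axis=0)))
        gamma = 1.0 / (k * med_var) if med_var > 0 else 1.0 / k
    svm = SVC(kernel="rbf", C=C, gamma=gamma).fit(Zs, labels)
    return TextureClassifier(selected, C, gamma, scaler, svm,
                             feature_space=X.shape[1])


def classify_map(stack: FeatureStack, specimen: SpecimenMap,
                 clf: TextureClassifier, block: int = 32,
                 min_tissue_frac: float = 0.25) -> np.ndarray:
    """Hemorrhage mask: block×block patches of the tissue area, pooled,
    predicted; the union of hemorrhage patches intersected with the map.

    Patches whose tissue fraction is below ``min_tissue_frac`` are skipped.
    """
    if not clf.fitted:
        raise RuntimeError("classifier is not fitted")
    mask = specimen.mask
    H, W = mask.shape
    idx = sorted(stack.maps)
    arr = stack.as_array(idx)
    hem = np.zeros((H, W), dtype=bool)
    patches, coords = [], []
    for r in range(0, H, block):
        for c in range(0, W, block):
            tile = mask[r:r + block, c:c + block]
            if tile.mean() < min_tissue_frac:
                continue
            region = np.zeros_like(mask)
            region[r:r + block, c:c + block] = tile
            patches.append(arr[:, region].mean(axis=1))
            coords.append((r, c))
    if not patches:
        return hem
    preds = clf.predict(np.stack(patches))
    for (r, c), pred in zip(coords, preds):
        if pred == "hemorrhage":
            hem[r:r + block, c:c + block] = True
    return hem & mask


def save_classifier(clf: TextureClassifier, path) -> None:
    """Persist a fitted classifier (versioned pickle bundle)."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"format_version": 1, "classifier": clf}, fh)


def load_classifier(path) -> TextureClassifier:
    """Load a classifier saved by :func:`save_classifier`."""
    import pickle

    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    if bundle.get("format_version") != 1:
        raise ValueError(f"unsupported classifier bundle in {path}")
    return bundle["classifier"]


def exclude_hemorrhage(specimen: SpecimenMap, hem: np.ndarray) -> SpecimenMap:
    """Remove hemorrhage pixels from the specimen map (map AND NOT hem)."""
    hem = np.asarray(hem, dtype=bool)
    if hem.shape != specimen.mask.shape:
        raise ValueError("shape mismatch between map and hemorrhage mask")
    return replace(
        specimen,
        mask=specimen.mask & ~hem,
        provenance=specimen.provenance + ["exclude_hemorrhage"],
    )
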