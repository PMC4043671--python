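"""Sliding-block classification of mixed-condition scenes.

A mosaic pastes together whole images from both irrigation treatments.  A
square block (default 50x50 pixels) is taken at every pixel location, the
eight-statistic descriptor is computed on the block alone (with its own
Otsu plant mask), and the SVM/GPC/fused classifiers trained on whole
images are applied.  The per-pixel GPC probability P_s is turned into a
confidence score

    C_s = P_s        where the block is labelled stressed (N-I)
    C_s = 1 - P_s    where it is labelled well-watered (I)

so bright regions of the confidence map mark confident calls and dark
regions (typically near treatment seams) mark uncertain ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .classifiers import (GPCModel, STRESSED, SVMModel, fuse,
                          gpc_predict, svm_predict)
from .features import (DegenerateMaskError, FEATURE_NAMES, FeatureVector,
                       LabImage, PlantMask, compute_features, otsu_mask,
                       rgb_to_lab)
from .thermal_io import ThermalImage

__all__ = [
    "MosaicScene",
    "BlockClassificationResult",
    "ConfidenceSummary",
    "classify_blocks",
    "confidence_map",
    "summarize_confidence",
]


@dataclass
class MosaicScene:
    """A composed mixed-treatment scene with per-pixel ground truth
    (True = stressed / N-I region)."""

    thermal: ThermalImage
    visible_rgb: np.ndarray
    ground_truth: np.ndarray

    def __post_init__(self) -> None:
        shape = self.thermal.temperatures.shape
        if (self.visible_rgb.shape[:2] != shape
                or self.ground_truth.shape != shape):
            raise ValueError("mosaic grids must share dimensions")


@dataclass
class BlockClassificationResult:
    """Per-pixel outputs of the sliding-block classifiers."""

    label_map: np.ndarray   # fused labels, +1 / -1
    svm_map: np.ndarray
    p_s_map: np.ndarray
    c_s_map: np.ndarray
    block_size: int
    degenerate_blocks: int = 0


@dataclass
class ConfidenceSummary:
    mean_c_s: float
    sd_c_s: float
    interior_mean: float
    boundary_mean: float
    pixel_accuracy: float
    interior_accuracy: float
    boundary_accuracy: float


def _block_features(T, lab, a, global_thr, r0, r1, c0, c1,
                    row_norm) -> tuple[FeatureVector, bool]:
    """Descriptor of one block; falls back to the whole-scene Otsu
    threshold (then to an unmasked computation) when the block's own mask
    degenerates.  Returns (features, used_fallback)."""
    Tb = T[r0:r1, c0:c1]
    labb = LabImage(L=lab.L[r0:r1, c0:c1], a=a[r0:r1, c0:c1],
                    b=lab.b[r0:r1, c0:c1])
    try:
        mask = otsu_mask(labb.a)
        return compute_features(Tb, labb, mask, row_norm=row_norm), False
    except DegenerateMaskError:
        pass
    try:
        mask = PlantMask(is_plant=labb.a < global_thr, threshold=global_thr)
        return compute_features(Tb, labb, mask, row_norm=row_norm), True
    except DegenerateMaskError:
        # single-population block: plant statistics degrade to whole-block
        row_med = np.median(Tb, axis=1, keepdims=True)
        Tn = Tb / row_med if row_norm == "divide" else Tb - row_med
        return FeatureVector(
            mu_LT=float(np.mean(Tb * labb.L)),
            mu_a=float(np.mean(labb.a)), mu_b=float(np.mean(labb.b)),
            sigma_nT=float(np.std(Tn)),
            mu_aT=float(np.mean(Tb)), sigma_aT=float(np.std(Tb)),
            mu_T=float(np.mean(Tb)), sigma_T=float(np.std(Tb)),
        ), True


def classify_blocks(scene: MosaicScene, svm: SVMModel, gpc: GPCModel,
                    block_size: int = 50, stride: int = 1,
                    feature_names: tuple[str, ...] | None = None,
                    fuse_hi: float = 0.8, fuse_lo: float = 0.2,
                    row_norm: str = "divide") -> BlockClassificationResult:
    """Classify the block centred at every pixel of the mosaic.

    Pixels closer than half a block to an edge reuse the nearest fully
    interior block.  With ``stride > 1`` the block grid is subsampled and
    the maps are filled in by nearest-neighbour upsampling, which
    accelerates desk-scale runs; ``stride = 1`` evaluates every pixel.
    """
    T = scene.thermal.temperatures
    H, W = T.shape
    if block_size > min(H, W):
        raise ValueError("block larger than the mosaic")
    if feature_names is None:
        feature_names = FEATURE_NAMES

    lab = rgb_to_lab(scene.visible_rgb)
    global_thr = otsu_mask(lab.a).threshold
    half = block_size // 2

    rows = np.arange(0, H, stride)
    cols = np.arange(0, W, stride)
    r0s = np.clip(rows - half, 0, H - block_size)
    c0s = np.clip(cols - half, 0, W - block_size)

    feats = np.empty((len(rows) * len(cols), len(feature_names)))
    n_degenerate = 0
    k = 0
    cache: dict[tuple[int, int], np.ndarray] = {}
    for r0 in r0s:
        for c0 in c0s:
            key = (int(r0), int(c0))
            cached = cache.get(key)
            if cached is None:
                fv, fallback = _block_features(
                    T, lab, lab.a, global_thr, r0, r0 + block_size,
                    c0, c0 + block_size, row_norm)
                cached = fv.as_array(feature_names)
                cache[key] = cached
                n_degenerate += fallback
            feats[k] = cached
            k += 1

    svm_labels = svm_predict(svm, feats)
    p_s = gpc_predict(gpc, feats)
    fused = fuse(svm_labels, p_s, hi=fuse_hi, lo=fuse_lo)

    shape_grid = (len(rows), len(cols))
    ri = np.minimum(np.arange(H) // stride, len(rows) - 1)
    ci = np.minimum(np.arange(W) // stride, len(cols) - 1)

    def upsample(grid_vals, dtype):
        g = grid_vals.reshape(shape_grid)
        return g[np.ix_(ri, ci)].astype(dtype)

    p_map = upsample(p_s, float)
    label_map = upsample(fused, int)
    return BlockClassificationResult(
        label_map=label_map,
        svm_map=upsample(svm_labels, int),
        p_s_map=p_map,
        c_s_map=confidence_map(p_map, label_map),
        block_size=block_size,
        degenerate_blocks=n_degenerate,
    )


def confidence_map(p_s_map: np.ndarray, label_map: np.ndarray) -> np.ndarray:
    """C_s = P_s where labelled stressed, 1 - P_s where labelled
    well-watered."""
    p = np.asarray(p_s_map, dtype=float)
    labels = np.asarray(label_map)
    if p.shape != labels.shape:
        raise ValueError("p_s and label maps must align")
    return np.where(labels == STRESSED, p, 1.0 - p)


def _seam_band(ground_truth: np.ndarray, band: int) -> np.ndarray:
    """Pixels within ``band`` of a treatment boundary in the ground truth."""
    gt = np.asarray(ground_truth, dtype=bool)
    seam = np.zeros_like(gt)
    seam[:-1, :] |= gt[:-1, :] != gt[1:, :]
    seam[1:, :] |= gt[:-1, :] != gt[1:, :]
    seam[:, :-1] |= gt[:, :-1] != gt[:, 1:]
    seam[:, 1:] |= gt[:, :-1] != gt[:, 1:]
    if not seam.any():
        return np.zeros_like(gt)
    return distance_transform_edt(~seam) <= band


def summarize_confidence(result: BlockClassificationResult,
                         ground_truth: np.ndarray,
                         boundary_band: int | None = None) -> ConfidenceSummary:
    """Overall and seam-stratified confidence statistics plus pixel-level
    accuracy against the ground-truth treatment pattern."""
    gt = np.asarray(ground_truth, dtype=bool)
    cs = result.c_s_map
    if cs.shape != gt.shape:
        raise ValueError("result and ground truth must align")
    if boundary_band is None:
        boundary_band = result.block_size
    band = _seam_band(gt, boundary_band)
    correct = (result.label_map == STRESSED) == gt

    def mean_or_nan(values, sel):
        return float(values[sel].mean()) if sel.any() else float("nan")

    return ConfidenceSummary(
        mean_c_s=float(cs.mean()),
        sd_c_s=float(cs.std()),
        interior_mean=mean_or_nan(cs, ~band),
        boundary_mean=mean_or_nan(cs, band),
        pixel_accuracy=100.0 * float(correct.mean()),
        interior_accuracy=100.0 * mean_or_nan(correct, ~band),
        boundary_accuracy=100.0 * mean_or_nan(correct, band),
    )
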