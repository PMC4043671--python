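"""The eight-statistic colour+thermal descriptor of a registered image.

Each registered (thermal, visible) pair is summarised by eight statistics
that mix canopy temperature with colour information from the CIE L*a*b*
representation of the visible image:

==========  =============================================================
mu_LT       mean over pixels of temperature scaled (multiplied) by the
            L (luminance) channel, L rescaled to [0, 1]
mu_a        mean of the a (green-red opponent) channel; green canopy is
            LOW in a, soil background HIGH
mu_b        mean of the b (blue-yellow opponent) channel
sigma_nT    std of temperatures after dividing each row by its median
            (dimensionless within-canopy variation)
mu_aT       mean temperature over plant pixels only (background removed
            by Otsu thresholding of the a channel)
sigma_aT    std of temperature over plant pixels only
mu_T        mean temperature over all pixels
sigma_T     std of temperature over all pixels
==========  =============================================================

All standard deviations use the population convention (divide by N).
Colour-dependent statistics are computed over pixels whose registration
valid-mask is true; purely thermal statistics use every thermal pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .registration import RegisteredPair

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_SUBSETS",
    "LabImage",
    "PlantMask",
    "FeatureVector",
    "DegenerateMaskError",
    "rgb_to_lab",
    "otsu_threshold",
    "otsu_mask",
    "compute_features",
    "extract_features",
]

FEATURE_NAMES = ("mu_LT", "mu_a", "mu_b", "sigma_nT",
                 "mu_aT", "sigma_aT", "mu_T", "sigma_T")

#: Named feature groupings used throughout the evaluation harness:
#: "colour" and "thermal" are the single-modality baselines, "full" is all
#: eight statistics, and "proposed" drops the global temperature mean/std
#: (which were found to dilute the combined descriptor).
FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "colour": ("mu_a", "mu_b"),
    "thermal": ("mu_T", "sigma_T"),
    "full": FEATURE_NAMES,
    "proposed": ("mu_LT", "mu_a", "mu_b", "sigma_nT", "mu_aT", "sigma_aT"),
}


class DegenerateMaskError(ValueError):
    """Raised when Otsu thresholding cannot split the a-channel."""


@dataclass
class LabImage:
    """CIE L*a*b* representation; L rescaled from [0, 100] to [0, 1]."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise ValueError("L, a, b grids must share dimensions")


@dataclass
class PlantMask:
    """Boolean plant/background segmentation of the a-channel.

    ``is_plant`` is true where the a-channel lies strictly below the Otsu
    threshold (green canopy sits at the low end of the green-red axis);
    pixels exactly at the threshold count as background.
    """

    is_plant: np.ndarray
    threshold: float


@dataclass(frozen=True)
class FeatureVector:
    mu_LT: float
    mu_a: float
    mu_b: float
    sigma_nT: float
    mu_aT: float
    sigma_aT: float
    mu_T: float
    sigma_T: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature vector contains non-finite values")
        for name in ("sigma_nT", "sigma_aT", "sigma_T"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self, names: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)


def rgb_to_lab(visible_rgb: np.ndarray, *, scale_255: bool | None = None) -> LabImage:
    """Convert an sRGB image (D65) to L*a*b*, with L rescaled to [0, 1].

    Parameters
    ----------
    scale_255 : bool, optional
        Whether RGB values are on the [0, 255] scale; inferred from the
        data maximum when omitted.
    """
    rgb = np.asarray(visible_rgb, dtype=float)
    if scale_255 is None:
        scale_255 = rgb.max() > 1.0
    if scale_255:
        rgb = rgb / 255.0
    lab = skcolor.rgb2lab(np.clip(rgb, 0.0, 1.0))
    return LabImage(L=lab[..., 0] / 100.0, a=lab[..., 1], b=lab[..., 2])


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximising histogram threshold.

    The histogram spans the data's min-max range; candidate cuts fall
    between adjacent bins and the returned threshold is the centre of the
    last bin of the lower class.  Exact ties (e.g. cuts inside an empty
    gap between modes) are broken deterministically towards the lowest
    cut.
    """
    counts, edges = np.histogram(values, bins=nbins,
                                 range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)[:-1].astype(float)
    w1 = counts.sum() - w0
    csum = np.cumsum(counts * centers)[:-1]
    m0 = csum / w0            # w0 > 0: the first bin holds the minimum
    m1 = (counts @ centers - csum) / w1  # w1 > 0: last bin holds the max
    scores = w0 * w1 * (m0 - m1) ** 2
    return float(centers[int(np.argmax(scores))])


def otsu_mask(a_channel: np.ndarray, valid: np.ndarray | None = None) -> PlantMask:
    """Otsu-threshold the a-channel into plant (below) vs background.

    The threshold maximises between-class variance over a 256-bin histogram
    spanning the channel's min-max range.  Invalid pixels (outside the
    registered visible frame) are excluded from the histogram and are never
    plant.
    """
    a = np.asarray(a_channel, dtype=float)
    vals = a[valid] if valid is not None else a.ravel()
    if vals.size == 0 or np.ptp(vals) == 0:
        raise DegenerateMaskError("a-channel is constant; cannot threshold")
    thr = otsu_threshold(vals)
    is_plant = a < thr
    if valid is not None:
        is_plant &= valid
    return PlantMask(is_plant=is_plant, threshold=thr)


def compute_features(temperatures: np.ndarray, lab: LabImage, mask: PlantMask,
                     valid: np.ndarray | None = None,
                     row_norm: str = "divide") -> FeatureVector:
    """Evaluate the eight statistics on aligned temperature/colour grids.

    Parameters
    ----------
    valid : bool array, optional
        Registration validity mask; colour-dependent statistics are
        restricted to valid pixels.  Thermal-only statistics always use
        the full temperature grid.
    row_norm : {"divide", "subtract"}
        How each row is normalised by its median for ``sigma_nT``.
        Division (the default) yields a dimensionless relative-variation
        measure.
    """
    T = np.asarray(temperatures, dtype=float)
    if valid is None:
        valid = np.ones(T.shape, dtype=bool)
    if not (T.shape == lab.L.shape == mask.is_plant.shape == valid.shape):
        raise ValueError("temperature, Lab, mask and valid grids must align")
    if not valid.any():
        raise ValueError("no valid visible pixels")

    row_med = np.median(T, axis=1, keepdims=True)
    if row_norm == "divide":
        if np.any(row_med == 0):
            raise ValueError("a temperature row has zero median; cannot "
                             "row-normalise by division")
        T_norm = T / row_med
    elif row_norm == "subtract":
        T_norm = T - row_med
    else:
        raise ValueError(f"unknown row_norm {row_norm!r}")

    plant = mask.is_plant & valid
    if not plant.any() or not (~plant & valid).any():
        raise DegenerateMaskError("plant mask is degenerate (all plant or "
                                  "all background)")

    return FeatureVector(
        mu_LT=float(np.mean((T * lab.L)[valid])),
        mu_a=float(np.mean(lab.a[valid])),
        mu_b=float(np.mean(lab.b[valid])),
        sigma_nT=float(np.std(T_norm)),
        mu_aT=float(np.mean(T[plant])),
        sigma_aT=float(np.std(T[plant])),
        mu_T=float(np.mean(T)),
        sigma_T=float(np.std(T)),
    )


def extract_features(pair: RegisteredPair, row_norm: str = "divide") -> FeatureVector:
    """Full descriptor of a registered pair: Lab conversion, Otsu plant
    masking, then the eight statistics."""
    lab = rgb_to_lab(pair.visible_rgb)
    mask = otsu_mask(lab.a, valid=pair.valid_mask)
    return compute_features(pair.thermal.temperatures, lab, mask,
                            valid=pair.valid_mask, row_norm=row_norm)
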