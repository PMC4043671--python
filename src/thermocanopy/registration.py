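"""Visible-to-thermal registration and visible-image denoising.

A dual-sensor camera has a fixed geometric relationship between its thermal
and visible-light frames, so a single planar (projective) transform —
estimated once from manually picked control points — aligns every visible
image onto the thermal pixel grid.  The visible image is denoised with
Perona-Malik anisotropic diffusion before any colour features are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import ProjectiveTransform, warp

from .thermal_io import ThermalImage

__all__ = [
    "ControlPointSet",
    "PlanarTransform",
    "RegisteredPair",
    "fit_transform",
    "warp_to_thermal",
    "anisotropic_diffusion",
    "diffuse_rgb",
    "load_control_points",
    "save_transform",
    "load_transform",
]


@dataclass
class ControlPointSet:
    """Matched (visible, thermal) pixel coordinates, as (n, 2) float arrays."""

    visible: np.ndarray  # (x_vis, y_vis)
    thermal: np.ndarray  # (x_th, y_th)

    def __post_init__(self) -> None:
        self.visible = np.asarray(self.visible, dtype=float)
        self.thermal = np.asarray(self.thermal, dtype=float)
        if self.visible.shape != self.thermal.shape or self.visible.ndim != 2 \
                or self.visible.shape[1] != 2:
            raise ValueError("control points must be two (n, 2) arrays")
        if len(self.visible) < 4:
            raise ValueError("at least 4 control-point pairs are required")
        if len(np.unique(self.visible, axis=0)) != len(self.visible):
            raise ValueError("duplicated source control points")


@dataclass(frozen=True)
class PlanarTransform:
    """3x3 homogeneous projective matrix mapping visible -> thermal coords."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise ValueError("transform matrix must be a finite 3x3 matrix")
        if abs(m[2, 2]) < 1e-12 or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("transform matrix is singular or unnormalizable")
        object.__setattr__(self, "matrix", m / m[2, 2])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) visible (x, y) coordinates to thermal coordinates."""
        return ProjectiveTransform(self.matrix)(np.asarray(points, float))

    @property
    def inverse_matrix(self) -> np.ndarray:
        inv = np.linalg.inv(self.matrix)
        return inv / inv[2, 2]


@dataclass
class RegisteredPair:
    """A thermal image with a pixel-aligned visible image on the same grid."""

    thermal: ThermalImage
    visible_rgb: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = self.thermal.temperatures.shape
        if self.visible_rgb.shape[:2] != shape or self.valid_mask.shape != shape:
            raise ValueError("thermal, visible and mask grids must align")


def fit_transform(points: ControlPointSet) -> PlanarTransform:
    """Least-squares projective transform from control points.

    Uses the normalized direct linear transform; with exactly four exact
    pairs the residual is zero to numerical tolerance.

    Raises
    ------
    ValueError
        For degenerate configurations (e.g. three of four source points
        collinear), detected by failure or singularity of the estimate.
    """
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(points.visible,
                                                  points.thermal)
        ok = bool(tform)
    else:  # scikit-image < 0.26
        tform = ProjectiveTransform()
        ok = tform.estimate(points.visible, points.thermal)
    if not ok or not np.all(np.isfinite(tform.params)):
        raise ValueError("degenerate control-point configuration")
    return PlanarTransform(matrix=tform.params)


def warp_to_thermal(visible_rgb: np.ndarray, transform: PlanarTransform,
                    out_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Resample the visible image onto the thermal grid.

    Inverse mapping with bilinear interpolation per channel.  Returns the
    aligned image and a boolean mask that is False wherever the sample
    point fell outside the source image.
    """
    h_out, w_out = out_shape
    vis = np.asarray(visible_rgb, dtype=float)
    inv = ProjectiveTransform(transform.inverse_matrix)
    aligned = warp(vis, inverse_map=inv, output_shape=(h_out, w_out),
                   order=1, mode="constant", cval=0.0, preserve_range=True)

    xx, yy = np.meshgrid(np.arange(w_out), np.arange(h_out))
    src = inv(np.column_stack([xx.ravel(), yy.ravel()]))
    h_src, w_src = vis.shape[:2]
    valid = ((src[:, 0] >= 0) & (src[:, 0] <= w_src - 1)
             & (src[:, 1] >= 0) & (src[:, 1] <= h_src - 1))
    return aligned, valid.reshape(h_out, w_out)


def anisotropic_diffusion(image: np.ndarray, n_iter: int = 10,
                          kappa: float = 15.0, gamma: float = 0.2) -> np.ndarray:
    """Perona-Malik edge-preserving smoothing of a single-channel image.

    Four-neighbour explicit scheme with the exponential conduction function
    ``g(d) = exp(-(d / kappa)**2)``, which favours high-contrast edges.
    ``gamma`` must lie in (0, 0.25] for stability of the 4-neighbour
    scheme; the discrete extremum principle then holds (output range is
    contained in the input range).

    Parameters
    ----------
    kappa : float
        Edge-stopping constant, in the intensity units of the image
        (default tuned for a 0-255 scale).
    """
    if not 0.0 < gamma <= 0.25:
        raise ValueError("gamma must lie in (0, 0.25]")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    img = np.asarray(image, dtype=float).copy()
    for _ in range(n_iter):
        p = np.pad(img, 1, mode="edge")
        dn = p[:-2, 1:-1] - img
        ds = p[2:, 1:-1] - img
        de = p[1:-1, 2:] - img
        dw = p[1:-1, :-2] - img
        flux = sum(np.exp(-(d / kappa) ** 2) * d for d in (dn, ds, de, dw))
        img += gamma * flux
    return img


def diffuse_rgb(visible_rgb: np.ndarray, n_iter: int = 10, kappa: float = 15.0,
                gamma: float = 0.2) -> np.ndarray:
    """Apply anisotropic diffusion independently to each RGB channel."""
    vis = np.asarray(visible_rgb, dtype=float)
    return np.stack([anisotropic_diffusion(vis[..., c], n_iter, kappa, gamma)
                     for c in range(vis.shape[-1])], axis=-1)


def load_control_points(path: str | Path) -> ControlPointSet:
    """Read control points from CSV with columns x_vis, y_vis, x_th, y_th."""
    df = pd.read_csv(path)
    required = ["x_vis", "y_vis", "x_th", "y_th"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"control-point CSV lacks columns: {missing}")
    return ControlPointSet(visible=df[["x_vis", "y_vis"]].to_numpy(),
                           thermal=df[["x_th", "y_th"]].to_numpy())


def save_transform(transform: PlanarTransform, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"matrix": transform.matrix.tolist()}))


def load_transform(path: str | Path) -> PlanarTransform:
    data = json.loads(Path(path).read_text())
    return PlanarTransform(matrix=np.asarray(data["matrix"], dtype=float))
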