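"""Synthetic thermal/visible scene generator.

Emulates the statistical structure that the detection pipeline assumes of
field data, so every stage is testable without camera imagery:

* two treatment classes — irrigated ("I") and non-irrigated ("N-I") —
  where stressed canopies run warmer (higher minimum and maximum
  temperature, similar within-image range);
* soil moisture negatively coupled to canopy temperature;
* green canopy pixels LOW in the Lab a-channel against soil background
  HIGH in a, with the background dark in the b-channel;
* a smooth luminance gradient across the scene;
* a known planar transform between the thermal and visible frames, and a
  rendered temperature scale bar in the package's own glyph layout.

Canopy texture is modelled as random elliptical leaf blobs with per-blob
temperature offsets — the simplest structure that makes Otsu masking,
row-median normalisation and block-wise classification non-trivial.  No
botanical realism is attempted; see docs/methods.md for what this does and
does not establish about real field data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as skcolor
from skimage.draw import ellipse
from skimage.transform import ProjectiveTransform, warp

from .features import extract_features
from .mosaic import MosaicScene
from .registration import (ControlPointSet, PlanarTransform, RegisteredPair,
                           diffuse_rgb, fit_transform, warp_to_thermal)
from .thermal_io import (DigitTemplateSet, RawThermalCapture, ScaleBarLayout,
                         TemperatureScale, ThermalImage, default_templates,
                         intensity_to_temperature, recognize_scale)

__all__ = [
    "TreatmentParams",
    "SceneSpec",
    "SyntheticPair",
    "default_irrigated",
    "default_non_irrigated",
    "render_scale_bar",
    "generate_pair",
    "process_pair",
    "generate_dataset",
    "compose_mosaic",
]


@dataclass(frozen=True)
class TreatmentParams:
    """Statistical description of one irrigation treatment."""

    canopy_temp_mean: float        # degC
    canopy_temp_sd: float          # degC, per-pixel
    soil_temp_offset: float        # degC, background warmer than canopy
    green_fraction: float          # target canopy cover in (0, 1)
    a_plant_mean: float            # Lab a units; plant LOW
    a_bg_mean: float
    a_sd: float
    b_plant_mean: float            # Lab b units; background dark in b
    b_bg_mean: float
    b_sd: float
    luminance_base: float          # L on the 0-100 Lab scale
    luminance_gradient: float      # peak-to-peak L variation across columns
    luminance_sd: float
    soil_moisture_mean: float      # % v/v
    soil_moisture_sd: float
    moisture_temp_coupling: float  # degC per % v/v, negative
    blob_temp_sd: float = 0.4      # degC, per-leaf-blob smooth offset
    scene_temp_sd: float = 1.0     # degC, whole-scene temperature jitter
    soil_offset_sd: float = 2.0    # degC, scene-level soil-warmth jitter
    soil_ramp_sd: float = 16.0     # degC, patchy soil-warmth gradient
    green_fraction_sd: float = 0.10  # scene-level canopy-cover jitter
    colour_scene_sd: float = 3.0   # Lab units, scene-level colour jitter
    illumination_L_sd: float = 6.0   # L units, scene illumination jitter
    illumination_temp_coupling: float = 0.4  # degC apparent warming per L unit
    texture_log_sd: float = 0.35   # lognormal sd of per-scene thermal texture

    def __post_init__(self) -> None:
        if not 0.0 < self.green_fraction < 1.0:
            raise ValueError("green_fraction must lie in (0, 1)")
        if not self.a_plant_mean < self.a_bg_mean:
            raise ValueError("plant must be lower than background in the "
                             "a-channel")
        if not self.b_bg_mean < self.b_plant_mean:
            raise ValueError("background must be darker than plant in the "
                             "b-channel")
        for name in ("canopy_temp_sd", "a_sd", "b_sd", "luminance_sd",
                     "soil_moisture_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_irrigated() -> TreatmentParams:
    """Well-watered treatment: cool canopy, moist soil, lush colour."""
    return TreatmentParams(
        canopy_temp_mean=23.0, canopy_temp_sd=0.8, soil_temp_offset=6.0,
        green_fraction=0.58,
        a_plant_mean=-31.5, a_bg_mean=12.0, a_sd=5.0,
        b_plant_mean=25.0, b_bg_mean=5.0, b_sd=4.0,
        luminance_base=60.0, luminance_gradient=15.0, luminance_sd=3.0,
        soil_moisture_mean=30.0, soil_moisture_sd=3.0,
        moisture_temp_coupling=-0.25,
    )


def default_non_irrigated() -> TreatmentParams:
    """Soil-moisture-deficit treatment: warmer canopy (higher minimum and
    maximum, similar range), drier soil, slightly less and less-green
    cover."""
    return TreatmentParams(
        canopy_temp_mean=30.5, canopy_temp_sd=0.8, soil_temp_offset=6.0,
        green_fraction=0.58,
        a_plant_mean=-28.5, a_bg_mean=12.0, a_sd=5.0,
        b_plant_mean=25.0, b_bg_mean=5.0, b_sd=4.0,
        luminance_base=60.0, luminance_gradient=15.0, luminance_sd=3.0,
        soil_moisture_mean=10.0, soil_moisture_sd=3.0,
        moisture_temp_coupling=-0.25,
    )


def _default_homography() -> np.ndarray:
    # visible -> thermal: small rigid offset of a dual-sensor mount
    return np.array([[1.0, 0.0, 5.0],
                     [0.0, 1.0, 3.0],
                     [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and rendering configuration of a generated scene."""

    height: int = 240
    width: int = 320
    leaf_blob_count: int = 80
    blob_size_range: tuple[int, int] = (8, 30)
    registration_offset: np.ndarray = field(default_factory=_default_homography)
    scale_bar_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("scene must be at least 2x2 pixels")


@dataclass
class SyntheticPair:
    """One generated sample with its hidden ground truth."""

    capture: RawThermalCapture
    visible_rgb: np.ndarray          # camera (visible-frame) RGB, uint8
    true_mask: np.ndarray            # plant pixels on the thermal grid
    true_temperatures: np.ndarray    # degC before 8-bit quantization
    soil_moisture: float             # % v/v
    scale: TemperatureScale
    homography: PlanarTransform      # visible -> thermal
    control_points: ControlPointSet
    label: str                       # "I" or "N-I"


def render_scale_bar(scale: TemperatureScale,
                     templates: DigitTemplateSet | None = None,
                     noise_amplitude: float = 0.0,
                     rng: np.random.Generator | None = None,
                     layout: ScaleBarLayout | None = None) -> np.ndarray:
    """Render (t_max on top, t_min below) in the recogniser's layout.

    ``noise_amplitude`` adds seeded uniform noise in [-amp, +amp] intensity
    units, clipped back to [0, 255].
    """
    templates = templates or default_templates()
    layout = layout or ScaleBarLayout()
    bar = np.zeros((layout.bar_height, layout.bar_width))
    for text, y0 in ((f"{scale.t_max:.1f}", layout.top_row_y),
                     (f"{scale.t_min:.1f}", layout.bottom_row_y)):
        if len(text) > layout.max_chars:
            raise ValueError(f"{text!r} does not fit the scale-bar layout")
        for slot, ch in enumerate(text):
            x0 = layout.margin_x + slot * layout.pitch
            bar[y0:y0 + layout.glyph_height,
                x0:x0 + layout.glyph_width] = templates.glyphs[ch]
    if noise_amplitude > 0:
        rng = rng or np.random.default_rng()
        bar = bar + rng.uniform(-noise_amplitude, noise_amplitude, bar.shape)
    return np.clip(bar, 0.0, 255.0)


def _paint_canopy(spec: SceneSpec, params: TreatmentParams, target: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random elliptical leaf blobs until the target cover is reached.

    Returns (plant mask, per-pixel smooth temperature offset field)."""
    H, W = spec.height, spec.width
    mask = np.zeros((H, W), dtype=bool)
    offsets = np.zeros((H, W))
    lo, hi = spec.blob_size_range
    for _ in range(4 * spec.leaf_blob_count):
        if mask.mean() >= target:
            break
        r, c = rng.uniform(0, H), rng.uniform(0, W)
        r_rad, c_rad = rng.uniform(lo, hi, size=2)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(r, c, r_rad, c_rad, shape=(H, W), rotation=rot)
        mask[rr, cc] = True
        offsets[rr, cc] = rng.normal(0.0, params.blob_temp_sd)
    return mask, offsets


def generate_pair(params: TreatmentParams, spec: SceneSpec,
                  rng: np.random.Generator, label: str) -> SyntheticPair:
    """Generate one thermal capture + camera-frame visible image.

    The canopy mean temperature is shifted by the drawn soil moisture
    through ``moisture_temp_coupling``; plant pixels are cooler than the
    soil background by ``soil_temp_offset``.  The true temperatures are
    quantized to 8 bits against the scene min/max, and the scale bar is
    rendered from the digit templates.  The visible image is pushed into
    its own camera frame by the known registration homography.
    """
    H, W = spec.height, spec.width
    soil_moisture = float(max(0.0, rng.normal(params.soil_moisture_mean,
                                              params.soil_moisture_sd)))
    # scene-level draws: whole-scene temperature jitter, soil warmth,
    # canopy cover and colour vary between beds of the same treatment
    canopy_T = (params.canopy_temp_mean + params.moisture_temp_coupling
                * (soil_moisture - params.soil_moisture_mean)
                + rng.normal(0.0, params.scene_temp_sd))
    soil_offset = max(1.0, params.soil_temp_offset
                      + rng.normal(0.0, params.soil_offset_sd))
    green_target = float(np.clip(
        rng.normal(params.green_fraction, params.green_fraction_sd),
        0.2, 0.9))
    a_plant = params.a_plant_mean + rng.normal(0.0, params.colour_scene_sd)
    a_bg = params.a_bg_mean + rng.normal(0.0, params.colour_scene_sd)
    b_plant = params.b_plant_mean + rng.normal(0.0, params.colour_scene_sd)
    b_bg = params.b_bg_mean + rng.normal(0.0, params.colour_scene_sd)

    # canopy thermal texture (leaf angles, self-shading) varies between
    # scenes: one lognormal factor scales pixel noise and blob offsets
    texture = float(np.exp(rng.normal(0.0, params.texture_log_sd)))
    mask, blob_offsets = _paint_canopy(spec, params, green_target, rng)
    blob_offsets = blob_offsets * texture
    # bare soil dries patchily: a zero-mean planar gradient in a random
    # direction modulates the soil warmth across the scene
    theta = rng.uniform(0, 2 * np.pi)
    ramp_amp = rng.normal(0.0, params.soil_ramp_sd)
    yy, xx = np.meshgrid(np.linspace(-0.5, 0.5, H), np.linspace(-0.5, 0.5, W),
                         indexing="ij")
    soil_ramp = ramp_amp * (np.cos(theta) * xx + np.sin(theta) * yy)
    # scene illumination: brighter (sunnier) scenes also read warmer, the
    # confound that luminance-scaled temperature features exist to absorb
    illum = rng.normal(0.0, params.illumination_L_sd)
    T = np.where(mask, canopy_T + blob_offsets,
                 np.maximum(canopy_T + soil_offset + soil_ramp,
                            canopy_T + 0.5))
    T = (T + params.illumination_temp_coupling * illum
         + rng.normal(0.0, params.canopy_temp_sd * texture, (H, W)))

    a = np.where(mask, a_plant, a_bg) + rng.normal(0.0, params.a_sd, (H, W))
    b = np.where(mask, b_plant, b_bg) + rng.normal(0.0, params.b_sd, (H, W))
    ramp = np.linspace(-0.5, 0.5, W)[None, :]
    L = (params.luminance_base + illum
         + params.luminance_gradient * ramp
         + rng.normal(0.0, params.luminance_sd, (H, W)))
    L = np.clip(L, 1.0, 99.0)
    rgb_aligned = np.clip(skcolor.lab2rgb(np.stack([L, a, b], axis=-1)), 0, 1)

    # 8-bit quantization against the printed one-decimal scene range
    t_min = float(f"{math.floor(T.min() * 10) / 10:.1f}")
    t_max = float(f"{math.ceil(T.max() * 10) / 10:.1f}")
    if t_max <= t_min:
        t_max = t_min + 0.1
    scale = TemperatureScale(t_min=t_min, t_max=t_max)
    v = np.rint(255.0 * (T - t_min) / (t_max - t_min)).astype(np.uint8)
    bar = render_scale_bar(scale, noise_amplitude=spec.scale_bar_noise,
                           rng=rng)

    hom = PlanarTransform(matrix=np.asarray(spec.registration_offset, float))
    # camera_vis(q) = aligned(H q): warping it back with H restores alignment
    camera_vis = warp(rgb_aligned, ProjectiveTransform(hom.matrix),
                      mode="reflect", preserve_range=True)
    camera_vis = (np.clip(camera_vis, 0, 1) * 255).astype(np.uint8)

    gx, gy = np.meshgrid(np.linspace(10, W - 10, 4), np.linspace(10, H - 10, 3))
    vis_pts = np.column_stack([gx.ravel(), gy.ravel()])
    cps = ControlPointSet(visible=vis_pts, thermal=hom.apply(vis_pts))

    return SyntheticPair(
        capture=RawThermalCapture(intensity_image=v, scale_bar=bar),
        visible_rgb=camera_vis, true_mask=mask, true_temperatures=T,
        soil_moisture=soil_moisture, scale=scale, homography=hom,
        control_points=cps, label=label,
    )


def process_pair(pair: SyntheticPair,
                 transform: PlanarTransform | None = None,
                 diffuse: bool = True) -> RegisteredPair:
    """Run the pre-processing pipeline on a generated sample: scale-bar
    recognition, intensity-to-temperature conversion, visible warping onto
    the thermal grid and anisotropic diffusion."""
    scale = recognize_scale(pair.capture.scale_bar)
    thermal = intensity_to_temperature(pair.capture, scale)
    if transform is None:
        transform = fit_transform(pair.control_points)
    aligned, valid = warp_to_thermal(pair.visible_rgb, transform,
                                     thermal.temperatures.shape)
    if diffuse:
        aligned = diffuse_rgb(aligned)
    return RegisteredPair(thermal=thermal, visible_rgb=aligned,
                          valid_mask=valid)


def generate_dataset(n_per_class: int = 54,
                     params_i: TreatmentParams | None = None,
                     params_ni: TreatmentParams | None = None,
                     spec: SceneSpec | None = None,
                     seed: int = 0,
                     out_dir: str | Path | None = None,
                     diffuse: bool = True) -> pd.DataFrame:
    """Generate a class-balanced dataset and extract its feature table.

    Each scene gets an independent child seed derived from ``seed``; the
    registration transform is fitted once (from the first scene's control
    points) and reused, matching a fixed dual-sensor mount.  Returns one
    row per image: ``image_id``, the eight features, ``label`` and
    ``soil_moisture``.  With ``out_dir``, images and a manifest are also
    written to disk as PNGs/CSV.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params_i = params_i or default_irrigated()
    params_ni = params_ni or default_non_irrigated()
    spec = spec or SceneSpec()
    children = np.random.SeedSequence(seed).spawn(2 * n_per_class)

    rows = []
    transform = None
    writer = _ImageWriter(out_dir) if out_dir is not None else None
    for idx in range(2 * n_per_class):
        label = "I" if idx < n_per_class else "N-I"
        params = params_i if label == "I" else params_ni
        rng = np.random.default_rng(children[idx])
        pair = generate_pair(params, spec, rng, label)
        if transform is None:
            transform = fit_transform(pair.control_points)
        reg = process_pair(pair, transform=transform, diffuse=diffuse)
        fv = extract_features(reg)
        row = {"image_id": f"scene_{idx:04d}", **{
            name: getattr(fv, name) for name in
            ("mu_LT", "mu_a", "mu_b", "sigma_nT", "mu_aT", "sigma_aT",
             "mu_T", "sigma_T")},
            "label": label, "soil_moisture": pair.soil_moisture}
        rows.append(row)
        if writer is not None:
            writer.write(row["image_id"], pair)
    df = pd.DataFrame(rows)
    if writer is not None:
        writer.finish(df)
    return df


class _ImageWriter:
    """Persists generated scenes as PNGs plus a CSV manifest."""

    def __init__(self, out_dir: str | Path):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)

    def write(self, image_id: str, pair: SyntheticPair) -> None:
        import imageio.v3 as iio

        iio.imwrite(self.out_dir / f"{image_id}_thermal.png",
                    pair.capture.intensity_image)
        iio.imwrite(self.out_dir / f"{image_id}_scalebar.png",
                    pair.capture.scale_bar.astype(np.uint8))
        iio.imwrite(self.out_dir / f"{image_id}_visible.png", pair.visible_rgb)
        iio.imwrite(self.out_dir / f"{image_id}_truemask.png",
                    (pair.true_mask * 255).astype(np.uint8))

    def finish(self, df: pd.DataFrame) -> None:
        df.to_csv(self.out_dir / "features.csv", index=False)


def compose_mosaic(tiles: list[tuple[np.ndarray, np.ndarray, str]],
                   layout: list[list[int]]) -> MosaicScene:
    """Tile registered (temperature grid, aligned RGB, label) triples into
    a mixed-condition scene; ground truth is painted from the labels
    (N-I = True)."""
    shapes = {tuple(t[0].shape) for t in tiles}
    if len(shapes) != 1:
        raise ValueError("all tiles must share dimensions")
    lay = np.asarray(layout, dtype=int)
    if lay.ndim != 2:
        raise ValueError("layout must be a 2-D grid of tile indices")

    def assemble(extract):
        return np.block([[extract(tiles[idx]) for idx in row] for row in lay])

    T = assemble(lambda t: np.asarray(t[0], dtype=float))
    vis = np.concatenate(
        [np.concatenate([np.asarray(tiles[idx][1], dtype=float)
                         for idx in row], axis=1) for row in lay], axis=0)
    gt = assemble(lambda t: np.full(t[0].shape, t[2] == "N-I", dtype=bool))
    scale = TemperatureScale(t_min=math.floor(T.min() * 10) / 10 - 0.1,
                             t_max=math.ceil(T.max() * 10) / 10 + 0.1)
    return MosaicScene(thermal=ThermalImage(temperatures=T, scale=scale),
                       visible_rgb=vis, ground_truth=gt)
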