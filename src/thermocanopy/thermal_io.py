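"""Decoding of 8-bit thermal-camera exports.

Radiometric thermal cameras of the class used for field phenotyping often
export an 8-bit single-channel image (intensities 0-255) together with a
rendered temperature scale bar that prints the minimum and maximum
temperature of the scene.  This module recognises the printed temperatures
by template cross-correlation and replaces pixel intensities with degrees
Celsius via an affine map over the 8-bit range.

The glyph font and scale-bar layout are defined here (they are
camera-specific and otherwise arbitrary); the synthetic renderer in
:mod:`thermocanopy.synthetic` uses the exact same layout, so rendering
followed by recognition round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CHAR_ORDER",
    "DigitTemplateSet",
    "ScaleBarLayout",
    "TemperatureScale",
    "RawThermalCapture",
    "ThermalImage",
    "ScaleBarParseError",
    "default_templates",
    "recognize_scale",
    "intensity_to_temperature",
    "save_thermal_image",
    "load_thermal_image",
]

#: Template matching order; ties in correlation are broken by this order.
CHAR_ORDER = "0123456789.-"

# 5x7 glyphs, '#' = bright (255), '.' = dark (0).
_GLYPH_ART = {
    "0": (".###.",
          "#...#",
          "#..##",
          "#.#.#",
          "##..#",
          "#...#",
          ".###."),
    "1": ("..#..",
          ".##..",
          "..#..",
          "..#..",
          "..#..",
          "..#..",
          ".###."),
    "2": (".###.",
          "#...#",
          "....#",
          "...#.",
          "..#..",
          ".#...",
          "#####"),
    "3": (".###.",
          "#...#",
          "....#",
          "..##.",
          "....#",
          "#...#",
          ".###."),
    "4": ("...#.",
          "..##.",
          ".#.#.",
          "#..#.",
          "#####",
          "...#.",
          "...#."),
    "5": ("#####",
          "#....",
          "####.",
          "....#",
          "....#",
          "#...#",
          ".###."),
    "6": (".###.",
          "#....",
          "#....",
          "####.",
          "#...#",
          "#...#",
          ".###."),
    "7": ("#####",
          "....#",
          "...#.",
          "..#..",
          "..#..",
          ".#...",
          ".#..."),
    "8": (".###.",
          "#...#",
          "#...#",
          ".###.",
          "#...#",
          "#...#",
          ".###."),
    "9": (".###.",
          "#...#",
          "#...#",
          ".####",
          "....#",
          "....#",
          ".###."),
    ".": (".....",
          ".....",
          ".....",
          ".....",
          ".....",
          ".##..",
          ".##.."),
    "-": (".....",
          ".....",
          ".....",
          ".###.",
          ".....",
          ".....",
          "....."),
}


class ScaleBarParseError(ValueError):
    """Raised when a scale bar cannot be parsed into a temperature range."""


@dataclass(frozen=True)
class DigitTemplateSet:
    """Binary glyph templates for the characters printed in the scale bar."""

    glyphs: dict[str, np.ndarray]
    glyph_height: int
    glyph_width: int

    def __post_init__(self) -> None:
        for ch, g in self.glyphs.items():
            if g.shape != (self.glyph_height, self.glyph_width):
                raise ValueError(f"glyph {ch!r} has shape {g.shape}, expected "
                                 f"{(self.glyph_height, self.glyph_width)}")


def default_templates() -> DigitTemplateSet:
    """The package's built-in 5x7 font covering digits, '.' and '-'."""
    glyphs = {
        ch: np.array([[255.0 if c == "#" else 0.0 for c in row] for row in art])
        for ch, art in _GLYPH_ART.items()
    }
    return DigitTemplateSet(glyphs=glyphs, glyph_height=7, glyph_width=5)


@dataclass(frozen=True)
class ScaleBarLayout:
    """Fixed-pitch, two-run scale-bar layout: maximum on top, minimum below.

    Characters are placed left-aligned at ``margin_x + slot * pitch``; the
    run ends at the first blank slot.
    """

    margin_x: int = 2
    margin_y: int = 2
    row_gap: int = 3
    pitch: int = 6  # glyph_width + 1 px spacing
    max_chars: int = 8
    glyph_height: int = 7
    glyph_width: int = 5
    #: a slot whose peak-to-peak intensity is below this is treated as blank
    blank_ptp: float = 100.0

    @property
    def bar_width(self) -> int:
        return 2 * self.margin_x + self.max_chars * self.pitch

    @property
    def bar_height(self) -> int:
        return 2 * self.margin_y + 2 * self.glyph_height + self.row_gap

    @property
    def top_row_y(self) -> int:
        return self.margin_y

    @property
    def bottom_row_y(self) -> int:
        return self.margin_y + self.glyph_height + self.row_gap


@dataclass(frozen=True)
class TemperatureScale:
    """Temperature range of a thermal capture, in degrees Celsius."""

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_min) and np.isfinite(self.t_max)):
            raise ValueError("temperature scale endpoints must be finite")
        if not self.t_max > self.t_min:
            raise ValueError(
                f"t_max ({self.t_max}) must exceed t_min ({self.t_min})")

    @property
    def span(self) -> float:
        return self.t_max - self.t_min


@dataclass
class RawThermalCapture:
    """An 8-bit thermal export plus its rendered scale-bar sub-image."""

    intensity_image: np.ndarray
    scale_bar: np.ndarray

    def __post_init__(self) -> None:
        img = np.asarray(self.intensity_image)
        if img.ndim != 2 or img.size == 0:
            raise ValueError("intensity_image must be a non-empty 2-D grid")
        if img.min() < 0 or img.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.intensity_image = img

    @property
    def height(self) -> int:
        return self.intensity_image.shape[0]

    @property
    def width(self) -> int:
        return self.intensity_image.shape[1]


@dataclass
class ThermalImage:
    """Per-pixel temperatures in degrees Celsius, tied to their scale."""

    temperatures: np.ndarray
    scale: TemperatureScale

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        eps = 1e-9 * max(1.0, abs(self.scale.span))
        if t.min() < self.scale.t_min - eps or t.max() > self.scale.t_max + eps:
            raise ValueError("temperatures fall outside the attached scale")
        self.temperatures = t


def _zncc(patch: np.ndarray, template: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two same-shape patches."""
    p = patch - patch.mean()
    t = template - template.mean()
    denom = np.linalg.norm(p) * np.linalg.norm(t)
    if denom == 0.0:
        return -1.0
    return float(np.dot(p.ravel(), t.ravel()) / denom)


def _read_run(bar: np.ndarray, y0: int, layout: ScaleBarLayout,
              templates: DigitTemplateSet, run_name: str) -> str:
    chars = []
    h, w = layout.glyph_height, layout.glyph_width
    for slot in range(layout.max_chars):
        x0 = layout.margin_x + slot * layout.pitch
        if x0 + w > bar.shape[1] or y0 + h > bar.shape[0]:
            break
        patch = bar[y0:y0 + h, x0:x0 + w].astype(float)
        if np.ptp(patch) < layout.blank_ptp:
            break
        scores = [_zncc(patch, templates.glyphs[ch]) for ch in CHAR_ORDER]
        chars.append(CHAR_ORDER[int(np.argmax(scores))])
    text = "".join(chars)
    try:
        float(text)
    except ValueError:
        raise ScaleBarParseError(
            f"{run_name} run of the scale bar parsed to {text!r}, "
            "which is not a number") from None
    return text


def recognize_scale(scale_bar: np.ndarray,
                    templates: DigitTemplateSet | None = None,
                    layout: ScaleBarLayout | None = None) -> TemperatureScale:
    """Read the printed (t_min, t_max) off a rendered scale-bar sub-image.

    Each character slot is matched against every glyph template by
    zero-mean normalized cross-correlation; the best-scoring template wins
    (ties broken by ``CHAR_ORDER``).  The top run holds the maximum
    temperature, the bottom run the minimum.

    Raises
    ------
    ScaleBarParseError
        If either run does not parse as a decimal number, or if the parsed
        maximum does not exceed the minimum (e.g. the runs are swapped).
    """
    templates = templates or default_templates()
    layout = layout or ScaleBarLayout()
    bar = np.asarray(scale_bar, dtype=float)
    top = _read_run(bar, layout.top_row_y, layout, templates, "top")
    bottom = _read_run(bar, layout.bottom_row_y, layout, templates, "bottom")
    t_max, t_min = float(top), float(bottom)
    if not t_max > t_min:
        raise ScaleBarParseError(
            f"parsed t_max={t_max} <= t_min={t_min}; scale-bar runs are "
            "inverted or corrupted")
    return TemperatureScale(t_min=t_min, t_max=t_max)


def intensity_to_temperature(capture: RawThermalCapture,
                             scale: TemperatureScale) -> ThermalImage:
    """Affine map of 8-bit intensities onto [t_min, t_max] degrees Celsius.

    ``T(v) = t_min + (v / 255) * (t_max - t_min)``, so v=0 maps to t_min and
    v=255 to t_max.
    """
    v = np.asarray(capture.intensity_image, dtype=float)
    temps = scale.t_min + (v / 255.0) * scale.span
    return ThermalImage(temperatures=temps, scale=scale)


def save_thermal_image(image: ThermalImage, path: str | Path) -> None:
    """Persist as float32 TIFF plus a JSON sidecar with the scale."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.temperatures.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"t_min": image.scale.t_min, "t_max": image.scale.t_max}))


def load_thermal_image(path: str | Path) -> ThermalImage:
    import tifffile

    path = Path(path)
    temps = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ThermalImage(temperatures=temps,
                        scale=TemperatureScale(meta["t_min"], meta["t_max"]))
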