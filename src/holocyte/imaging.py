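"""Forward model: quantitative phase maps and off-axis holograms.

The cell-induced phase delay follows the thin-specimen relation

    dphi(x, y) = (2*pi/lambda) * d(x, y) * (n_cell - n_medium)

with the geometric thickness d(x, y) of a sphere (or ellipsoid) of
radius R. An off-axis hologram is the two-beam interference of the unit
object wave exp(i*dphi) with a tilted plane reference, giving carrier
fringes whose sideband encodes the complex object wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .optics import OpticalConfig
from .phantoms import CellPhantom

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseImage:
    """2-D quantitative phase map in radians, relative to the medium."""

    phase: np.ndarray
    pixel_scale_um: float
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("phase must be a 2-D array")
        if not np.isfinite(self.phase).all():
            raise ValueError("phase must be finite")

    def save(self, path) -> None:
        tifffile.imwrite(
            path,
            self.phase.astype(np.float32),
            metadata={"pixel_scale_um": self.pixel_scale_um,
                      "provenance": self.provenance},
        )

    @classmethod
    def load(cls, path, pixel_scale_um: float | None = None) -> "PhaseImage":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        scale = pixel_scale_um or float(meta.get("pixel_scale_um", 0.0))
        if scale <= 0:
            raise ValueError("pixel_scale_um missing from file and argument")
        return cls(arr.astype(float), scale,
                   provenance=str(meta.get("provenance", "loaded")))


@dataclass
class Hologram:
    """Recorded off-axis intensity frame plus its optical configuration."""

    intensity: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.config.image_shape:
            raise ValueError("hologram shape must match config.image_shape")
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensity must be finite")
        if (self.intensity < 0).any():
            raise ValueError("intensity must be non-negative")

    def save(self, path) -> None:
        tifffile.imwrite(path, self.intensity.astype(np.float32),
                         metadata=self.config.to_dict())


def _coordinate_grids_um(shape: tuple[int, int], pixel_scale_um: float):
    rows, cols = shape
    y = np.arange(rows, dtype=float)[:, None] * pixel_scale_um
    x = np.arange(cols, dtype=float)[None, :] * pixel_scale_um
    return x, y


def projected_thickness_um(phantom: CellPhantom, x_um: np.ndarray,
                           y_um: np.ndarray) -> np.ndarray:
    """Chord length through the cell at each (x, y), in µm."""
    cx, cy = phantom.center_um
    dx = x_um - cx
    dy = y_um - cy
    if phantom.shape == "sphere":
        arg = phantom.radius_um**2 - (dx * dx + dy * dy)
        return 2.0 * np.sqrt(np.maximum(arg, 0.0))
    # ellipsoid: projected semi-axes (R*ar, R), thickness semi-axis R
    ct, st = np.cos(phantom.orientation_rad), np.sin(phantom.orientation_rad)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    a = phantom.radius_um * phantom.axis_ratio
    b = phantom.radius_um
    arg = 1.0 - (u / a) ** 2 - (v / b) ** 2
    return 2.0 * phantom.radius_um * np.sqrt(np.maximum(arg, 0.0))


def render_phase_image(
    phantoms: CellPhantom | list[CellPhantom],
    config: OpticalConfig,
    check_fit: bool = True,
) -> PhaseImage:
    """Render the noiseless quantitative phase map of one or more phantoms.

    Each pixel holds (2*pi/lambda) * d(x, y) * (n_cell - n_medium); the
    peak at the centre of a sphere is (2*pi/lambda) * 2R * (n_cell - n_medium).

    Raises if a phantom does not fit inside the field of view with a
    2-px margin, or if its projected radius is below 3 px (the sphere
    fit would be degenerate at that sampling).
    """
    if isinstance(phantoms, CellPhantom):
        phantoms = [phantoms]
    s = config.pixel_scale_um
    rows, cols = config.image_shape
    x, y = _coordinate_grids_um(config.image_shape, s)
    phase = np.zeros(config.image_shape)
    for ph in phantoms:
        ph.check_contrast(config.n_medium)
        r_proj = ph.radius_um * ph.axis_ratio
        if check_fit:
            cx, cy = ph.center_um
            margin = 2.0 * s
            if (cx - r_proj < margin or cy - r_proj < margin
                    or cx + r_proj > (cols - 1) * s - margin
                    or cy + r_proj > (rows - 1) * s - margin):
                raise ValueError("phantom does not fit in the field of view "
                                 "with a 2-px margin")
            if ph.radius_um / s < 3.0:
                raise ValueError("projected radius below 3 px; pixel scale "
                                 "too coarse for a meaningful fit")
        d = projected_thickness_um(ph, x, y)
        phase += (TWO_PI / config.wavelength_um) * d * (ph.n_cell - config.n_medium)
    return PhaseImage(phase, s, provenance="synthetic")


def center_phantom(phantom: CellPhantom, config: OpticalConfig) -> CellPhantom:
    """Return a copy of ``phantom`` placed at the field-of-view centre."""
    rows, cols = config.image_shape
    s = config.pixel_scale_um
    phantom.center_um = ((cols - 1) / 2.0 * s, (rows - 1) / 2.0 * s)
    return phantom


def carrier_ramp(config: OpticalConfig) -> np.ndarray:
    """Phase ramp 2*pi*(f_r*row + f_c*col) of the tilted reference."""
    rows, cols = config.image_shape
    fr, fc = config.carrier_freq
    r = np.arange(rows, dtype=float)[:, None]
    c = np.arange(cols, dtype=float)[None, :]
    return TWO_PI * (fr * r + fc * c)


def synthesize_hologram(
    phase: PhaseImage,
    config: OpticalConfig,
    rng: int | np.random.Generator | None = None,
) -> Hologram:
    """Two-beam off-axis hologram |O + R|^2 of a unit-amplitude object wave.

    O = exp(i*phase), R = tilted plane wave at ``config.carrier_freq``,
    so the noiseless intensity is 2 + 2*cos(phase - carrier ramp):
    carrier fringes modulated by the object phase. Gaussian intensity
    noise of scale ``config.noise_sigma`` is added when non-zero
    (clipped at zero: a sensor records non-negative counts).

    The carrier must be strong enough that the object sideband separates
    from the DC term in Fourier space; a carrier magnitude below
    0.15 cycles/px is rejected for the cell sizes this model targets.
    """
    if phase.phase.shape != config.image_shape:
        raise ValueError("phase image shape must match config.image_shape")
    if config.carrier_magnitude < 0.15:
        raise ValueError(
            "carrier frequency too low for sideband separation "
            f"(|f| = {config.carrier_magnitude:.3f} < 0.15 cycles/px)"
        )
    intensity = 2.0 + 2.0 * np.cos(phase.phase - carrier_ramp(config))
    if config.noise_sigma > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        intensity = intensity + rng.normal(0.0, config.noise_sigma,
                                           size=intensity.shape)
        intensity = np.clip(intensity, 0.0, None)
    return Hologram(intensity, config)
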