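"""Optical configuration of the off-axis holographic microscope.

All lengths are micrometres; spatial frequencies are cycles per pixel.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, asdict
from pathlib import Path


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging geometry and illumination of the DHM system.

    Parameters
    ----------
    wavelength_um : float
        Vacuum wavelength of the coherent source (default 0.532 µm,
        a 532 nm solid-state laser).
    n_medium : float
        Refractive index of the suspension buffer (default 1.337,
        an isotonic PBS-type medium).
    pixel_scale_um : float
        Object-space sampling (µm per pixel). Default 0.1 µm/px, the
        order of magnitude of a 40x system on a small-pitch CMOS sensor.
    image_shape : (int, int)
        (rows, cols) of recorded frames.
    carrier_freq : (float, float)
        Spatial frequency (cycles/px, row- and column-direction) of the
        tilted off-axis reference wave. Must be below Nyquist per axis
        and large enough that the object sideband separates from DC.
    noise_sigma : float
        Standard deviation of additive Gaussian intensity noise on the
        hologram, on the scale of a unit-amplitude two-beam pattern
        (fringe intensity spans [0, 4]).
    """

    wavelength_um: float = 0.532
    n_medium: float = 1.337
    pixel_scale_um: float = 0.1
    image_shape: tuple[int, int] = (128, 128)
    carrier_freq: tuple[float, float] = (0.3, 0.3)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if self.n_medium <= 1:
            raise ValueError("n_medium must exceed 1 (aqueous buffer)")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale must be positive")
        shape = tuple(int(s) for s in self.image_shape)
        if len(shape) != 2 or min(shape) < 64:
            raise ValueError("image_shape must be at least (64, 64)")
        object.__setattr__(self, "image_shape", shape)
        cf = tuple(float(f) for f in self.carrier_freq)
        if len(cf) != 2 or not all(0.0 < abs(f) < 0.5 for f in cf):
            raise ValueError(
                "carrier_freq components must lie in (0, 0.5) cycles/px "
                "(below Nyquist)"
            )
        object.__setattr__(self, "carrier_freq", cf)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def carrier_magnitude(self) -> float:
        fr, fc = self.carrier_freq
        return float((fr * fr + fc * fc) ** 0.5)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        if "carrier_freq" in d:
            d["carrier_freq"] = tuple(d["carrier_freq"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "OpticalConfig":
        """Load from TOML or JSON; the format follows the suffix."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
        else:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        if "optics" in data:  # allow a [optics] table inside a run config
            data = data["optics"]
        return cls.from_dict(data)
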