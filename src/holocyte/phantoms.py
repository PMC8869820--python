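"""Ground-truth cell phantoms for hologram synthesis.

A phantom is a suspended, near-spherical cell parameterised by its
in-plane position, radius and integral (volume-averaged) refractive
index. Populations are drawn from truncated normal distributions whose
defaults match suspended lymphocyte / monocyte biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default radius distributions (µm): mean radii chosen so that the
#: spherical volume matches the preoperative population means of
#: ~208 µm³ (lymphocytes) and ~390 µm³ (monocytes).
LYMPHOCYTE_RADIUS_UM = 3.675
MONOCYTE_RADIUS_UM = 4.533
DEFAULT_N_CELL = 1.3497


@dataclass
class CellPhantom:
    """A single ground-truth cell.

    ``shape`` is ``"sphere"`` or ``"ellipsoid"``; for ellipsoids the
    projected outline has semi-axes ``R*axis_ratio`` and ``R`` with the
    out-of-plane (thickness) semi-axis equal to ``R``.
    """

    center_um: tuple[float, float]  # (x, y) = (col, row) in µm
    radius_um: float
    n_cell: float
    shape: str = "sphere"
    axis_ratio: float = 1.0
    orientation_rad: float = 0.0
    label: str = "lymphocyte"

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.axis_ratio < 1.0:
            raise ValueError("axis_ratio must be >= 1")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def volume_um3(self) -> float:
        """Spherical ground-truth volume (4/3)πR³ in µm³."""
        return 4.0 / 3.0 * np.pi * self.radius_um**3

    def check_contrast(self, n_medium: float) -> None:
        if self.n_cell <= n_medium:
            raise ValueError(
                f"n_cell={self.n_cell} must exceed n_medium={n_medium}: "
                "cells are optically denser than buffer"
            )


def make_phantom_population(
    n: int,
    radius_mean_um: float = LYMPHOCYTE_RADIUS_UM,
    radius_sd_um: float = 0.05,
    n_cell_mean: float = DEFAULT_N_CELL,
    n_cell_sd: float = 0.0005,
    n_medium: float = 1.337,
    center_um: tuple[float, float] | None = None,
    label: str = "lymphocyte",
    seed: int | np.random.Generator | None = None,
) -> list[CellPhantom]:
    """Draw ``n`` sphere phantoms with normally distributed R and n_cell.

    Draws are rejected (redrawn) until ``R > 0`` and
    ``n_cell > n_medium``; distributions violating these invariants with
    appreciable probability raise instead of looping forever.

    Parameters mirror the study populations: radii ~ N(3.675, 0.05) µm
    give lymphocyte-like volumes near 208 µm³, radii ~ N(4.533, 0.05) µm
    monocyte-like volumes near 390 µm³, and n_cell ~ N(1.3497, 0.0005)
    in buffer of index 1.337.

    ``center_um=None`` leaves the centre unset at (0, 0); callers place
    phantoms in the field of view before rendering.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    # A distribution whose mean sits below the invariant bound cannot be
    # repaired by truncation without grossly distorting the moments.
    if radius_mean_um <= 0 or n_cell_mean <= n_medium:
        raise ValueError(
            "distribution means must satisfy R > 0 and n_cell > n_medium"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def _draw(mean: float, sd: float, lower: float) -> np.ndarray:
        vals = rng.normal(mean, sd, size=n)
        for _ in range(100):
            bad = vals <= lower
            if not bad.any():
                return vals
            vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        raise ValueError("could not satisfy invariants by truncation")

    radii = _draw(radius_mean_um, radius_sd_um, 0.0)
    indices = _draw(n_cell_mean, n_cell_sd, n_medium)
    center = (0.0, 0.0) if center_um is None else tuple(center_um)
    return [
        CellPhantom(center_um=center, radius_um=float(r), n_cell=float(nc), label=label)
        for r, nc in zip(radii, indices)
    ]
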