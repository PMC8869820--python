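"""Off-axis hologram reconstruction.

Single-shot Fourier demodulation: the hologram is multiplied by the
conjugate reference ramp, which shifts the +1-order sideband to the
spectral origin; a Butterworth low-pass isolates it, and the inverse
FFT yields the complex object wave. Phase = argument, unwrapped and
background-corrected. Numerical refocusing uses the angular-spectrum
propagator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, ifft2, fftfreq
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .imaging import Hologram, PhaseImage, carrier_ramp
from .optics import OpticalConfig

TWO_PI = 2.0 * np.pi


@dataclass
class ComplexField:
    """Demodulated complex object wave."""

    data: np.ndarray
    pixel_scale_um: float
    wavelength_um: float
    n_medium: float = 1.337

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("field must be 2-D")
        if not np.isfinite(self.data).all():
            raise ValueError("field must be finite")

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))


# ---------------------------------------------------------------- carrier

def detect_carrier(intensity: np.ndarray, dc_exclude_cyc: float = 0.04
                   ) -> tuple[float, float]:
    """Locate the off-axis carrier as the strongest non-DC spectral peak.

    Returns (f_row, f_col) in cycles/px, refined to sub-bin precision by
    parabolic interpolation of log-magnitude. Of the conjugate +/-1 pair
    the peak in the upper half-plane (f_row > 0, ties toward f_col > 0)
    is returned so the choice is deterministic.

    Raises if no sideband stands above the noise floor (the frame is not
    an off-axis hologram).
    """
    arr = np.asarray(intensity, dtype=float)
    rows, cols = arr.shape
    F = fft2(arr - arr.mean())
    mag = np.abs(F)
    f_r = fftfreq(rows)[:, None]
    f_c = fftfreq(cols)[None, :]
    radius = np.hypot(f_r, f_c)
    search = mag.copy()
    search[radius < dc_exclude_cyc] = 0.0
    # deterministic half-plane: keep f_row > 0, or f_row == 0 and f_col > 0
    keep = (f_r > 1e-12) | ((np.abs(f_r) <= 1e-12) & (f_c > 1e-12))
    search[~np.broadcast_to(keep, search.shape)] = 0.0
    peak_flat = int(np.argmax(search))
    pr, pc = np.unravel_index(peak_flat, search.shape)
    floor = np.median(mag[radius >= dc_exclude_cyc])
    if search[pr, pc] < 10.0 * floor:
        raise ValueError("no off-axis sideband found above the noise floor")

    def _refine(m1: float, m0: float, p1: float) -> float:
        # parabolic vertex of log-magnitudes at offsets -1, 0, +1
        l1, l0, lp = (np.log(max(v, 1e-30)) for v in (m1, m0, p1))
        denom = l1 - 2.0 * l0 + lp
        if abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (l1 - lp) / denom, -0.5, 0.5))

    dr = _refine(mag[(pr - 1) % rows, pc], mag[pr, pc], mag[(pr + 1) % rows, pc])
    dc_ = _refine(mag[pr, (pc - 1) % cols], mag[pr, pc], mag[pr, (pc + 1) % cols])
    fr = fftfreq(rows)[pr] + dr / rows
    fc = fftfreq(cols)[pc] + dc_ / cols
    return float(fr), float(fc)


# ------------------------------------------------------------ demodulation

def _butterworth_lowpass(shape: tuple[int, int], radius_cyc: float,
                         order: int = 6) -> np.ndarray:
    f_r = fftfreq(shape[0])[:, None]
    f_c = fftfreq(shape[1])[None, :]
    rho = np.hypot(f_r, f_c)
    return 1.0 / (1.0 + (rho / radius_cyc) ** (2 * order))


def default_window_radius(carrier: tuple[float, float]) -> float:
    """Half-bandwidth of the sideband filter, in cycles/px.

    Chosen as 45% of the carrier-to-DC distance: wide enough for the
    object band of cell-sized phase objects, with margin to both the DC
    term and the wrapped conjugate sideband.
    """
    return 0.45 * float(np.hypot(*carrier))


def _tukey2d(shape: tuple[int, int], alpha: float = 0.25) -> np.ndarray:
    from scipy.signal.windows import tukey

    return np.outer(tukey(shape[0], alpha), tukey(shape[1], alpha))


def demodulate(
    holo: Hologram,
    carrier: tuple[float, float] | None = None,
    window_radius: float | None = None,
    order: int = 6,
    apodize: float = 0.25,
) -> ComplexField:
    """Extract the complex object wave from an off-axis hologram.

    The configured carrier is used when available; ``carrier=None`` with
    a zeroed config falls back to auto-detection. The detected peak must
    lie within 2 FFT bins of the configured carrier, otherwise the frame
    is rejected as inconsistent with its configuration.

    The frame is apodized with a Tukey window (taper fraction
    ``apodize``) before the FFT: a carrier that is not an integer number
    of cycles across the frame otherwise leaks DC/conjugate energy
    through the pass-band and produces edge artifacts. The apodization
    is a positive real factor on the object wave, so the extracted phase
    is unaffected wherever the field amplitude is usable.
    """
    cfg = holo.config
    if carrier is None:
        detected = detect_carrier(holo.intensity)
        configured = cfg.carrier_freq
        bin_r, bin_c = 1.0 / cfg.image_shape[0], 1.0 / cfg.image_shape[1]
        # match the detected peak to the configured carrier (either sign)
        cands = [configured, tuple(-f for f in configured)]
        dists = [np.hypot(detected[0] - f[0], detected[1] - f[1]) for f in cands]
        if min(dists) > 2.0 * max(bin_r, bin_c):
            raise ValueError(
                "detected sideband is more than 2 FFT bins from the "
                "configured carrier; hologram/config mismatch"
            )
        carrier = configured
    if window_radius is None:
        window_radius = default_window_radius(carrier)
    rows, cols = holo.intensity.shape
    fr, fc = carrier
    r = np.arange(rows, dtype=float)[:, None]
    c = np.arange(cols, dtype=float)[None, :]
    apod = _tukey2d((rows, cols), apodize) if apodize > 0 else 1.0
    # intensity = 2 + exp(+i(phi - ramp)) + exp(-i(phi - ramp)); multiplying
    # by exp(+i*ramp) brings the +1 order exp(i*phi) to baseband
    centered = (holo.intensity - holo.intensity.mean()) * apod
    demod = centered * np.exp(1j * TWO_PI * (fr * r + fc * c))
    window = _butterworth_lowpass((rows, cols), window_radius, order)
    field = ifft2(fft2(demod) * window)
    return ComplexField(field, cfg.pixel_scale_um, cfg.wavelength_um,
                        cfg.n_medium)


# ---------------------------------------------------------------- unwrap

def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """2-D phase unwrapping (reliability-ordered, residue-tolerant).

    The output is congruent to the input modulo 2*pi at every pixel and
    the global 2*pi-multiple offset is normalised away, which makes the
    operation idempotent on already-smooth inputs.
    """
    w = np.asarray(wrapped, dtype=float)
    u = np.asarray(_skimage_unwrap(w))
    offset = TWO_PI * np.round(np.median(u - w) / TWO_PI)
    return u - offset


# ------------------------------------------------------------ background

def remove_background(
    phase: np.ndarray,
    degree: int = 2,
    min_range_rad: float = 0.1,
    margin_px: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit and subtract a low-order polynomial background.

    Cell-free pixels are those below the Otsu threshold of |phase|,
    with the cell regions dilated by ``margin_px`` so the low-phase
    skirt of a cell (below threshold but not background) cannot drag
    the polynomial; an empty frame (dynamic range below
    ``min_range_rad``) uses all pixels. Returns (corrected phase,
    background mask); the median of the cell-free region is zero after
    correction.
    """
    ph = np.asarray(phase, dtype=float)
    amp = np.abs(ph)
    if amp.max() - amp.min() > min_range_rad:
        thr = threshold_otsu(amp)
        fg = ndimage.binary_dilation(amp >= thr, iterations=margin_px)
        bg = ~fg
        if bg.sum() < ph.size // 20:  # threshold collapsed; keep everything
            bg = np.ones_like(bg)
    else:
        bg = np.ones(ph.shape, dtype=bool)
    rows, cols = ph.shape
    yy = (np.arange(rows)[:, None] / rows) * np.ones((1, cols))
    xx = np.ones((rows, 1)) * (np.arange(cols)[None, :] / cols)
    terms = [np.ones_like(ph)]
    for total in range(1, degree + 1):
        for i in range(total + 1):
            terms.append(xx ** (total - i) * yy ** i)
    A = np.stack([t[bg] for t in terms], axis=1)
    coeffs, *_ = np.linalg.lstsq(A, ph[bg], rcond=None)
    background = sum(c * t for c, t in zip(coeffs, terms))
    out = ph - background
    out -= np.median(out[bg])
    return out, bg


# ----------------------------------------------------------- reconstruct

def reconstruct_hologram(
    holo: Hologram,
    refocus_um: float = 0.0,
    window_radius: float | None = None,
    bg_degree: int = 2,
) -> PhaseImage:
    """Full reconstruction: demodulate, unwrap, flatten, sign-normalise.

    Cells are optically denser than the buffer, so in-mask phase must be
    positive; a frame reconstructing predominantly negative is
    sign-flipped and flagged (``meta["sign_flipped"]``). The cell-free
    median is ~0 after background correction.
    """
    field = demodulate(holo, window_radius=window_radius)
    if refocus_um != 0.0:
        field = refocus(field, refocus_um)
    amp = np.abs(field.data)
    wrapped = np.angle(field.data)
    # the apodization taper leaves border pixels with negligible
    # amplitude; their phase is undefined and is zeroed rather than
    # letting numerical noise through
    wrapped[amp < 0.05 * np.median(amp)] = 0.0
    ph = unwrap_phase(wrapped)
    ph, bg = remove_background(ph, degree=bg_degree)
    meta = {"sign_flipped": False}
    cell = ~bg
    if cell.any() and np.mean(ph[cell]) < 0:
        ph = -ph
        meta["sign_flipped"] = True
    return PhaseImage(ph, holo.config.pixel_scale_um,
                      provenance="reconstructed", meta=meta)


# -------------------------------------------------------------- refocus

def _effective_bandwidth(field: ComplexField, energy_frac: float = 0.9999
                         ) -> float:
    """Radius (cycles/µm) enclosing ``energy_frac`` of spectral energy."""
    F = fft2(field.data)
    p = np.abs(F).ravel() ** 2
    f_r = fftfreq(field.data.shape[0], d=field.pixel_scale_um)[:, None]
    f_c = fftfreq(field.data.shape[1], d=field.pixel_scale_um)[None, :]
    rho = np.hypot(f_r, f_c).ravel()
    order = np.argsort(rho)
    cum = np.cumsum(p[order])
    idx = int(np.searchsorted(cum, energy_frac * cum[-1]))
    return float(rho[order[min(idx, len(rho) - 1)]])


def refocus(field: ComplexField, distance_um: float) -> ComplexField:
    """Angular-spectrum propagation by ``distance_um`` in the medium.

    Evanescent components (spatial frequencies beyond n_medium/lambda)
    are zeroed; on band-limited fields the propagator is unitary, so
    energy is conserved and refocus(d) inverts refocus(-d).

    Raises when the propagation phase would alias at the field's
    effective bandwidth (kernel undersampled for that distance).
    """
    if distance_um == 0.0:
        return ComplexField(field.data.copy(), field.pixel_scale_um,
                            field.wavelength_um, field.n_medium)
    lam_medium = field.wavelength_um / field.n_medium
    f_max_prop = 1.0 / lam_medium
    rows, cols = field.data.shape
    f_r = fftfreq(rows, d=field.pixel_scale_um)[:, None]
    f_c = fftfreq(cols, d=field.pixel_scale_um)[None, :]
    fsq = f_r**2 + f_c**2
    band = min(_effective_bandwidth(field), 0.98 * f_max_prop)
    if band > 0:
        # phase-gradient-per-bin at the band edge must stay below pi
        df = 1.0 / (min(rows, cols) * field.pixel_scale_um)
        grad = TWO_PI * abs(distance_um) * band / np.sqrt(f_max_prop**2 - band**2)
        if grad * df > np.pi:
            raise ValueError(
                f"refocus distance {distance_um} µm exceeds the alias-free "
                "range for this field's bandwidth"
            )
    kz_sq = f_max_prop**2 - fsq
    propagating = kz_sq > 0.0
    H = np.zeros_like(fsq, dtype=complex)
    H[propagating] = np.exp(1j * TWO_PI * distance_um *
                            np.sqrt(kz_sq[propagating]))
    out = ifft2(fft2(field.data) * H)
    return ComplexField(out, field.pixel_scale_um, field.wavelength_um,
                        field.n_medium)


def autofocus(
    field: ComplexField,
    distances_um: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Sweep propagation distances and pick the sharpest focus.

    For a pure phase object the in-focus plane has the flattest
    amplitude, so the metric is the coefficient of variation of |field|,
    evaluated over the central half of the frame (the border carries the
    apodization taper, which is focus-independent); returns
    (best distance, metric per distance).
    """
    distances_um = np.asarray(distances_um, dtype=float)
    rows, cols = field.data.shape
    rs = slice(rows // 4, rows - rows // 4)
    cs = slice(cols // 4, cols - cols // 4)
    metrics = np.empty(distances_um.shape)
    for i, d in enumerate(distances_um):
        amp = np.abs(refocus(field, float(d)).data[rs, cs])
        metrics[i] = amp.std() / max(amp.mean(), 1e-30)
    best = int(np.argmin(metrics))
    return float(distances_um[best]), metrics
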