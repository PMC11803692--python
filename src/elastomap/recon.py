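"""Elastogram reconstruction from wrapped multi-phase acquisitions.

The chain mirrors the standard local-homogeneity MRE reconstruction:

1. per-slice 2-D phase unwrapping,
2. inter-slice offset alignment (each slice is unwrapped only up to a
   global multiple of 2 pi),
3. temporal first-harmonic extraction over the four sampled wave phases,
4. curl of the complex displacement field (annihilates the curl-free
   compressional component),
5. voxelwise algebraic Helmholtz inversion
   G* = -rho w^2 (sum_c q_c lap(q_c)*) / (sum_c |lap(q_c)|^2),
6. |G*| = sqrt(Gd^2 + Gl^2) and phase angle Y = (2/pi) atan2(Gl, Gd),
   which runs from 0 (purely elastic) to 1 (purely viscous).

Spatially constant phase offsets that survive unwrapping/alignment are
harmless: the curl differentiates them away before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.restoration import unwrap_phase as _unwrap_2d

from .wavesim import WAVE_PHASE_OFFSETS, ComplexWaveField, WaveAcquisition

__all__ = [
    "CurlField",
    "Elastogram",
    "unwrap_phase_stack",
    "align_slice_offsets",
    "extract_first_harmonic",
    "compute_curl",
    "invert_helmholtz",
    "compose_elastogram",
    "reconstruct_elastogram",
]


@dataclass
class CurlField:
    """Curl of the complex displacement field, per-voxel 3-vector."""

    q: np.ndarray  # (nx, ny, nz, 3) complex, units 1/m * displacement-scale
    validity: np.ndarray  # bool, False on the 1-voxel finite-difference rim
    spacing_mm: tuple[float, float, float]
    frequency: float


@dataclass
class Elastogram:
    """Reconstructed viscoelastic parameter maps."""

    gd: np.ndarray  # storage modulus, Pa (clipped at 0)
    gl: np.ndarray  # loss modulus, Pa (clipped at 0)
    g_magnitude: np.ndarray  # |G*|, Pa
    y: np.ndarray  # phase angle, dimensionless in [0, 1]
    validity: np.ndarray
    gd_raw: np.ndarray | None = None  # unclipped diagnostics
    gl_raw: np.ndarray | None = None
    clipped: np.ndarray | None = None


def unwrap_phase_stack(acq: WaveAcquisition) -> np.ndarray:
    """Unwrap each 2-D slice of every (direction, wave phase) image.

    Returns an array shaped like ``acq.phase_images``. Each slice is
    restored up to one global multiple of 2 pi (fixed later by
    `align_slice_offsets`); output minus input is everywhere an integer
    multiple of 2 pi.
    """
    phases = acq.phase_images
    out = np.empty_like(phases)
    nz = phases.shape[2]
    for d in range(phases.shape[3]):
        for n in range(phases.shape[4]):
            for k in range(nz):
                out[:, :, k, d, n] = _unwrap_2d(phases[:, :, k, d, n])
    return out


def align_slice_offsets(unwrapped: np.ndarray) -> np.ndarray:
    """Remove per-slice 2 pi offsets so the volume is consistent in z.

    Slice 0 is the reference; for each subsequent slice the integer number
    of 2 pi turns closest to the median inter-slice phase difference is
    subtracted, leaving the median jump in (-pi, pi]. Operates on arrays
    shaped (nx, ny, nz) or (nx, ny, nz, ...) (trailing axes independent).
    """
    out = unwrapped.copy()
    lead = out.reshape(out.shape[:3] + (-1,))
    nz = lead.shape[2]
    for m in range(lead.shape[3]):
        vol = lead[:, :, :, m]
        for k in range(1, nz):
            d = np.median(vol[:, :, k] - vol[:, :, k - 1])
            r = d / (2 * np.pi)
            # ceil(r - 1/2) leaves the residual jump in (-pi, pi]; an
            # exactly-ambiguous +-pi jump resolves to the smaller offset
            turns = np.ceil(r - 0.5)
            if r - 0.5 == turns:
                warnings.warn(
                    f"ambiguous inter-slice jump of pi at slice {k}; "
                    "keeping the smaller 2-pi offset", stacklevel=2,
                )
            if turns:
                vol[:, :, k:] -= 2 * np.pi * turns
    return out


def extract_first_harmonic(
    aligned: np.ndarray,
    scale: float,
    frequency: float,
    spacing_mm: tuple[float, float, float],
    phase_offsets: np.ndarray | None = None,
) -> ComplexWaveField:
    """Temporal 4-point DFT: first harmonic of the sampled wave phases.

    H = (2/N) sum_n s_n exp(-i theta_n). For s_n = Re{U exp(i theta_n)}
    this returns U exactly, so the noiseless encode/decode round trip is
    the identity (up to the encoding scale, which is divided out here).
    """
    if aligned.ndim != 5 or aligned.shape[4] != 4:
        raise ValueError("expected (nx, ny, nz, 3, 4) with exactly 4 wave phases")
    theta = WAVE_PHASE_OFFSETS if phase_offsets is None else np.asarray(phase_offsets)
    h = (2.0 / theta.size) * np.sum(aligned * np.exp(-1j * theta), axis=4)
    return ComplexWaveField(h / scale, frequency, spacing_mm)



def _central_diff(a: np.ndarray, axis: int, h_m: float) -> np.ndarray:
    out = np.zeros_like(a)
    sl = [slice(None)] * a.ndim
    sp_, sm = list(sl), list(sl)
    sl[axis] = slice(1, -1)
    sp_[axis] = slice(2, None)
    sm[axis] = slice(0, -2)
    out[tuple(sl)] = (a[tuple(sp_)] - a[tuple(sm)]) / (2 * h_m)
    return out


def compute_curl(field: ComplexWaveField) -> CurlField:
    """Curl of the displacement by central differences with physical spacing.

    The validity mask erodes the domain by one voxel on every face. Fewer
    than three slices leave no interior for z-derivatives and are rejected.
    """
    u = field.displacement
    if min(u.shape[:3]) < 3:
        raise ValueError("need at least 3 voxels along every axis for the curl")
    hx, hy, hz = (s * 1e-3 for s in field.spacing_mm)

    d = {}
    for comp in range(3):
        d[(comp, 0)] = _central_diff(u[..., comp], 0, hx)
        d[(comp, 1)] = _central_diff(u[..., comp], 1, hy)
        d[(comp, 2)] = _central_diff(u[..., comp], 2, hz)

    q = np.empty_like(u)
    q[..., 0] = d[(2, 1)] - d[(1, 2)]
    q[..., 1] = d[(0, 2)] - d[(2, 0)]
    q[..., 2] = d[(1, 0)] - d[(0, 1)]

    validity = np.zeros(u.shape[:3], bool)
    validity[1:-1, 1:-1, 1:-1] = True
    return CurlField(q=q, validity=validity, spacing_mm=field.spacing_mm,
                     frequency=field.frequency)


def _laplacian(a: np.ndarray, h: tuple[float, float, float]) -> np.ndarray:
    out = np.zeros_like(a)
    core = (slice(1, -1),) * 3
    acc = np.zeros_like(a[core])
    for ax in range(3):
        sl_p = [slice(1, -1)] * 3
        sl_m = [slice(1, -1)] * 3
        sl_p[ax] = slice(2, None)
        sl_m[ax] = slice(0, -2)
        acc = acc + (a[tuple(sl_p)] - 2 * a[core] + a[tuple(sl_m)]) / h[ax] ** 2
    out[core] = acc
    return out


def invert_helmholtz(
    curl: CurlField,
    frequency: float | None = None,
    density: float = 1000.0,
    smooth_sigma_vox: float = 0.0,
    exclusion_eps: float = 1e-3,
    combine: str = "least_squares",
) -> Elastogram:
    """Algebraic local inversion of the Helmholtz relation on curl components.

    Under local homogeneity each curl component obeys
    G* lap(q_c) = -rho w^2 q_c; the three components are combined by
    unweighted least squares (default) or a per-component median. Voxels
    whose summed |lap(q_c)| falls below ``exclusion_eps`` times the valid
    median are excluded (no wave curvature to invert). Negative real or
    imaginary parts are clipped to zero for the reported maps and kept in
    the raw diagnostic channels.
    """
    freq = curl.frequency if frequency is None else frequency
    w = 2 * np.pi * freq
    h = tuple(s * 1e-3 for s in curl.spacing_mm)

    q = curl.q
    if smooth_sigma_vox > 0:
        q = np.empty_like(curl.q)
        for c in range(3):
            q[..., c] = (
                gaussian_filter(curl.q[..., c].real, smooth_sigma_vox)
                + 1j * gaussian_filter(curl.q[..., c].imag, smooth_sigma_vox)
            )

    lap = np.empty_like(q)
    for c in range(3):
        lap[..., c] = _laplacian(q[..., c], h)

    validity = np.zeros(q.shape[:3], bool)
    validity[1:-1, 1:-1, 1:-1] = True
    validity &= curl.validity
    # the Laplacian stencil needs its own 1-voxel rim inside the curl's
    validity[[0, 1, -2, -1], :, :] = False
    validity[:, [0, 1, -2, -1], :] = False
    validity[:, :, [0, 1, -2, -1]] = False

    lap_mag = np.abs(lap).sum(axis=-1)
    valid_mag = lap_mag[validity]
    if valid_mag.size == 0:
        raise ValueError("no valid voxels after erosion; grid too small")
    floor = exclusion_eps * np.median(valid_mag)
    validity &= lap_mag > floor
    if not validity.any():
        raise ValueError(
            "all voxels excluded by the curvature floor; the shear wavelength "
            "is probably under-resolved on this grid"
        )

    if combine == "least_squares":
        num = np.sum(q * np.conj(lap), axis=-1)
        den = np.sum(np.abs(lap) ** 2, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            gstar = -density * w**2 * num / den
    elif combine == "median":
        with np.errstate(divide="ignore", invalid="ignore"):
            per = -density * w**2 * q / lap
        gstar = np.nanmedian(per.real, axis=-1) + 1j * np.nanmedian(per.imag, axis=-1)
    else:
        raise ValueError("combine must be 'least_squares' or 'median'")

    gstar = np.where(validity, gstar, 0.0)
    gd_raw = gstar.real
    gl_raw = gstar.imag
    clipped = validity & ((gd_raw < 0) | (gl_raw < 0))
    gd = np.clip(gd_raw, 0.0, None)
    gl = np.clip(gl_raw, 0.0, None)
    g_mag, y = compose_elastogram(gd, gl)
    validity = validity & ~((gd == 0) & (gl == 0))
    return Elastogram(gd=gd, gl=gl, g_magnitude=g_mag, y=np.nan_to_num(y),
                      validity=validity, gd_raw=gd_raw, gl_raw=gl_raw,
                      clipped=clipped)


def compose_elastogram(gd, gl):
    """|G*| and phase angle Y from storage and loss modulus.

    |G*| = sqrt(gd^2 + gl^2); Y = (2/pi) atan2(gl, gd), exactly 0 for a
    purely elastic material (gl = 0) and exactly 1 in the purely viscous
    limit (gd = 0, gl > 0). Y is NaN where both moduli vanish.
    """
    gd = np.asarray(gd, float)
    gl = np.asarray(gl, float)
    g_mag = np.hypot(gd, gl)
    with np.errstate(invalid="ignore"):
        y = np.where(g_mag > 0, (2.0 / np.pi) * np.arctan2(gl, gd), np.nan)
    return g_mag, y


def reconstruct_elastogram(
    acq: WaveAcquisition,
    density: float = 1000.0,
    smooth_sigma_vox: float = 0.0,
    combine: str = "least_squares",
) -> Elastogram:
    """Full chain: unwrap, align, first harmonic, curl, invert."""
    unwrapped = unwrap_phase_stack(acq) if acq.wrap_applied else acq.phase_images
    aligned = align_slice_offsets(unwrapped)
    field = extract_first_harmonic(
        aligned, acq.scale, acq.frequency, acq.spacing_mm, acq.phase_offsets
    )
    curl = compute_curl(field)
    return invert_helmholtz(
        curl, density=density, smooth_sigma_vox=smooth_sigma_vox, combine=combine
    )
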