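"""Diffusion-tensor fitting and the ADC / FA scalar maps.

Per voxel the log signal ratio obeys ln(S_g/S_0) = -b g^T D g, linear in
the six unique tensor components; the fit is plain least squares against
the fixed design matrix of the direction set. ADC is taken as the mean
diffusivity (trace/3) and FA is the usual normalized eigenvalue dispersion

    FA = sqrt(3/2) * sqrt(sum (lam_i - lam_mean)^2) / sqrt(sum lam_i^2),

with negative eigenvalues clamped to zero (and flagged) before the FA so
it stays within [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWISet

__all__ = ["TensorMap", "design_matrix", "fit_diffusion_tensor", "tensor_scalars"]


@dataclass
class TensorMap:
    tensor: np.ndarray  # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz (mm^2/s)
    adc: np.ndarray  # mean diffusivity (mm^2/s)
    fa: np.ndarray  # in [0, 1] on valid voxels
    validity: np.ndarray
    eig_clipped: np.ndarray | None = None  # negative-eigenvalue flag
    condition_number: float = np.nan  # of the direction design matrix


def design_matrix(directions: np.ndarray) -> np.ndarray:
    """(n_dir, 6) matrix mapping tensor components to g^T D g."""
    g = np.asarray(directions, float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz])


def fit_diffusion_tensor(dwi: DWISet) -> TensorMap:
    """Least-squares tensor fit of a DWI set, vectorized over voxels.

    Requires at least six non-collinear directions plus the b=0 reference;
    voxels with non-positive signal in any volume are invalidated rather
    than fit on a truncated log.
    """
    b = np.asarray(dwi.bvalues, float)
    dwi_idx = b > 0
    if dwi_idx.sum() < 6:
        raise ValueError("need at least 6 diffusion-weighted volumes")
    g = dwi.directions[dwi_idx]
    design = design_matrix(g) * b[dwi_idx, None]
    cond = float(np.linalg.cond(design))
    if cond > 1e8:
        raise ValueError(f"rank-deficient direction set (condition {cond:.2e})")

    s0 = dwi.signal[..., ~dwi_idx][..., 0]
    s = dwi.signal[..., dwi_idx]
    positive = (s0 > 0) & (s > 0).all(axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        y = -np.log(np.where(s > 0, s, 1.0) / np.where(s0 > 0, s0, 1.0)[..., None])
    pinv = np.linalg.pinv(design)  # (6, n_dir)
    tensor = y @ pinv.T  # (..., 6)

    adc, fa, eig_clipped, scal_valid = tensor_scalars(tensor)
    validity = positive & scal_valid
    tensor = np.where(positive[..., None], tensor, 0.0)
    return TensorMap(tensor=tensor, adc=np.where(validity, adc, 0.0),
                     fa=np.where(validity, fa, 0.0), validity=validity,
                     eig_clipped=eig_clipped & validity, condition_number=cond)


def _tensor_6_to_33(t6: np.ndarray) -> np.ndarray:
    out = np.empty(t6.shape[:-1] + (3, 3))
    out[..., 0, 0] = t6[..., 0]
    out[..., 1, 1] = t6[..., 1]
    out[..., 2, 2] = t6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = t6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = t6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = t6[..., 5]
    return out


def tensor_scalars(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """ADC (mean diffusivity), FA, negative-eigenvalue flag, validity.

    ADC is trace/3 of the raw tensor. FA uses eigenvalues clamped at zero;
    an all-zero tensor has undefined FA and is marked invalid.
    """
    t6 = np.asarray(tensor, float)
    adc = (t6[..., 0] + t6[..., 1] + t6[..., 2]) / 3.0
    lam = np.linalg.eigvalsh(_tensor_6_to_33(t6))
    eig_clipped = (lam < 0).any(axis=-1)
    lam = np.clip(lam, 0.0, None)
    lam_mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - lam_mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    valid = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * num / np.where(valid, den, 1.0)
    fa = np.clip(np.where(valid, fa, 0.0), 0.0, 1.0)
    return adc, fa, eig_clipped, valid
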