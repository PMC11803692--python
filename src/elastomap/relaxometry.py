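"""Voxelwise T2 relaxometry from multi-echo magnitude trains.

The decay model is mono-exponential, S(TE) = S0 exp(-TE/T2), fit by
log-linear least squares after a noise-floor filter: echo samples whose
magnitude does not exceed ``threshold_multiplier`` times the noise SD are
discarded before fitting, because at long TE the magnitude signal flattens
onto the Rayleigh noise floor and would otherwise bias T2 upward.

The noise SD is estimated from background (air) voxels. For two-channel
Gaussian noise of scale sigma the magnitude is Rayleigh with
SD = sigma*sqrt(2 - pi/2), which is inverted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import EchoTrain

__all__ = ["T2Map", "estimate_noise_level", "fit_t2_map"]

_RAYLEIGH_SD = np.sqrt(2.0 - np.pi / 2.0)


@dataclass
class T2Map:
    t2: np.ndarray  # ms, > 0 on valid voxels
    s0: np.ndarray  # fitted amplitude
    n_used: np.ndarray  # echoes retained per voxel
    validity: np.ndarray
    n_invalidated: int = 0  # voxels dropped for non-finite fits


def estimate_noise_level(train: EchoTrain, background_mask: np.ndarray) -> float:
    """Gaussian-channel noise SD from background magnitude voxels."""
    mask = np.asarray(background_mask, bool)
    if not mask.any():
        raise ValueError("background mask is empty")
    vals = train.signal[mask]  # (n_bg, n_echo)
    return float(vals.std() / _RAYLEIGH_SD)


def fit_t2_map(
    train: EchoTrain,
    noise_sd: float | None = None,
    threshold_multiplier: float = 4.0,
    filter_mode: str = "sample",
    background_mask: np.ndarray | None = None,
) -> T2Map:
    """Log-linear T2 fit with the 4-SD noise filter.

    filter_mode="sample" (default): drop individual echo samples at or
    below threshold_multiplier*noise_sd, then fit the survivors.
    filter_mode="voxel": the stricter whole-voxel reading of the same
    filter — a voxel is dropped entirely as soon as any of its echoes has
    fallen to the noise floor.

    The fit is log-linear least squares with the standard refinements for
    magnitude data: the Rician first-moment offset is removed before the
    log (S_corr = sqrt(S^2 - 2 sigma^2)) and samples are weighted by S^2,
    the inverse variance of ln S under propagation of the noise. Both
    reduce to the plain unweighted fit when noise_sd = 0, so noiseless
    recovery stays exact.

    Voxels with fewer than 3 surviving echoes are invalid; t2 = -1/slope,
    s0 = exp(intercept).
    """
    if train.te_list.size < 3:
        raise ValueError("need at least 3 echoes to fit T2")
    if filter_mode not in ("sample", "voxel"):
        raise ValueError("filter_mode must be 'sample' or 'voxel'")
    if noise_sd is None:
        if background_mask is None:
            raise ValueError("provide noise_sd or a background_mask to estimate it")
        noise_sd = estimate_noise_level(train, background_mask)

    te = train.te_list
    sig = train.signal
    floor = threshold_multiplier * noise_sd
    keep = sig > max(floor, 0.0)
    if filter_mode == "voxel":
        all_clear = keep.all(axis=-1, keepdims=True)
        keep = np.broadcast_to(all_clear, keep.shape).copy()

    # Rician first-moment correction, identity when noise_sd = 0
    sig_c = np.sqrt(np.clip(sig**2 - 2.0 * noise_sd**2, 0.0, None))
    keep = keep & (sig_c > 0)
    n_used = keep.sum(axis=-1)
    enough = n_used >= 3

    # S^2-weighted log-linear least squares, vectorized over voxels
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(keep, np.log(np.where(sig_c > 0, sig_c, 1.0)), 0.0)
    w = keep * sig**2
    n = w.sum(axis=-1)
    sx = (w * te).sum(axis=-1)
    sy = (w * logs).sum(axis=-1)
    sxx = (w * te**2).sum(axis=-1)
    sxy = (w * te * logs).sum(axis=-1)
    denom = n * sxx - sx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / np.where(n > 0, n, 1.0)
        t2 = -1.0 / slope
        s0 = np.exp(intercept)

    finite = np.isfinite(t2) & np.isfinite(s0) & (t2 > 0)
    validity = enough & finite & (denom > 0)
    if train.zero_t2_mask is not None:
        validity &= ~train.zero_t2_mask
    n_invalidated = int(np.count_nonzero(enough & ~validity))
    t2 = np.where(validity, t2, 0.0)
    s0 = np.where(validity, s0, 0.0)
    return T2Map(t2=t2, s0=s0, n_used=n_used, validity=validity,
                 n_invalidated=n_invalidated)
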