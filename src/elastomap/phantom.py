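"""Synthetic ground-truth phantoms and raw-signal generators.

Everything downstream of this module (wave simulation, elastogram
reconstruction, T2/DTI fitting, ROI statistics, histology quantification)
is validated by parameter recovery against the ground truth produced here,
so every generator is seeded and bitwise reproducible.

Geometry defaults follow the study acquisition: a 64 x 64 in-plane matrix
over a 19.2 x 19.2 mm field of view (0.3 mm isotropic in plane) with nine
0.3 mm slices, vibrated at 900 Hz for elastography; 30-echo T2 trains at
TE = 7..210 ms; diffusion weighting b = 1500 s/mm^2 over 30 directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "REGION_IDS",
    "REGION_PRIORITY",
    "RegionParams",
    "Ellipsoid",
    "Band",
    "PropertyPhantom",
    "EchoTrain",
    "DWISet",
    "HistoImage",
    "build_property_phantom",
    "homogeneous_phantom",
    "synthesize_echo_train",
    "synthesize_dwi",
    "synthesize_histology",
    "magnitude_noise",
]

DEFAULT_GRID = (64, 64, 9)
DEFAULT_SPACING_MM = (0.3, 0.3, 0.3)
DEFAULT_DENSITY = 1000.0  # kg/m^3, standard soft-tissue assumption

REGION_IDS = {
    "background": 0,
    "brain": 1,
    "corpus_callosum": 2,
    "tumor_core": 3,
    "needle_tract": 4,
    "contralateral": 5,
}

# When two region shapes overlap the higher-priority label wins.
REGION_PRIORITY = [
    "tumor_core",
    "corpus_callosum",
    "needle_tract",
    "contralateral",
    "brain",
]


@dataclass(frozen=True)
class RegionParams:
    """Tissue parameters assigned to every voxel of one labeled region.

    gd_pa, gl_pa : storage and loss shear modulus (Pa)
    t2_ms        : transverse relaxation time (ms)
    d_eigs       : diffusion-tensor eigenvalues (mm^2/s), largest first
    fiber_axis   : principal diffusion direction (unit 3-vector); None = x
    """

    gd_pa: float
    gl_pa: float = 0.0
    t2_ms: float = 40.0
    d_eigs: tuple[float, float, float] = (7e-4, 7e-4, 7e-4)
    fiber_axis: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.gd_pa <= 0:
            raise ValueError(f"storage modulus must be positive, got {self.gd_pa}")
        if self.gl_pa < 0:
            raise ValueError(f"loss modulus must be non-negative, got {self.gl_pa}")

    def tensor(self) -> np.ndarray:
        """3x3 diffusion tensor with the requested eigenvalues and axis."""
        lam = np.asarray(self.d_eigs, dtype=float)
        axis = np.array([1.0, 0.0, 0.0]) if self.fiber_axis is None else np.asarray(self.fiber_axis, float)
        axis = axis / np.linalg.norm(axis)
        # orthonormal frame with `axis` first
        trial = np.array([0.0, 1.0, 0.0]) if abs(axis[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(axis, trial)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(axis, e2)
        r = np.stack([axis, e2, e3], axis=1)
        return r @ np.diag(lam) @ r.T


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, all coordinates in mm.

    When ``target_volume_mm3`` is set (see `from_volume`) the voxelization
    selects exactly the voxels closest to the center in the normalized
    ellipsoidal metric until the requested volume is reached, so the
    labeled volume matches the request to within one voxel volume —
    plain inside/outside tests of voxel centers drift by a few percent for
    structures only a few voxels across.
    """

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    target_volume_mm3: float | None = None

    @staticmethod
    def from_volume(center_mm: tuple[float, float, float], volume_mm3: float,
                    aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> "Ellipsoid":
        """Ellipsoid of the requested volume with the given axis ratios."""
        a = np.asarray(aspect, float)
        scale = (3.0 * volume_mm3 / (4.0 * np.pi * np.prod(a))) ** (1.0 / 3.0)
        return Ellipsoid(center_mm, tuple(scale * a), target_volume_mm3=volume_mm3)

    def mask(self, coords: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        x, y, z = coords
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semiaxes_mm
        d2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        if self.target_volume_mm3 is None:
            return d2 <= 1.0
        # rank-threshold: take exactly k voxels, nearest first
        h3 = abs(
            (x[min(1, x.shape[0] - 1), 0, 0] - x[0, 0, 0])
            * (y[0, min(1, y.shape[1] - 1), 0] - y[0, 0, 0])
            * (z[0, 0, min(1, z.shape[2] - 1)] - z[0, 0, 0])
        )
        if h3 == 0:
            return d2 <= 1.0
        k = int(round(self.target_volume_mm3 / h3))
        k = max(1, min(k, d2.size))
        # exactly k voxels even when symmetry places several at the same
        # normalized distance (argpartition breaks the ties)
        flat = d2.ravel()
        mask = np.zeros(flat.size, bool)
        mask[np.argpartition(flat, k - 1)[:k]] = True
        return mask.reshape(d2.shape)


@dataclass(frozen=True)
class Band:
    """Curved band mimicking the corpus callosum: a parabolic sheet.

    Voxels within ``thickness/2`` of the curve y = y0 + curvature*(x-x0)^2,
    restricted to an x-extent and a z-extent. Coordinates in mm.
    """

    x0_mm: float
    y0_mm: float
    curvature_per_mm: float
    thickness_mm: float
    x_extent_mm: tuple[float, float]
    z_extent_mm: tuple[float, float]

    def mask(self, coords: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        x, y, z = coords
        yc = self.y0_mm + self.curvature_per_mm * (x - self.x0_mm) ** 2
        inside = np.abs(y - yc) <= self.thickness_mm / 2.0
        inside &= (x >= self.x_extent_mm[0]) & (x <= self.x_extent_mm[1])
        inside &= (z >= self.z_extent_mm[0]) & (z <= self.z_extent_mm[1])
        return inside


@dataclass
class PropertyPhantom:
    """Voxelized ground truth for one subject at one time point."""

    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    storage_modulus: np.ndarray  # Pa
    loss_modulus: np.ndarray  # Pa
    density: np.ndarray  # kg/m^3
    t2: np.ndarray  # ms
    tensors: np.ndarray  # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz in mm^2/s
    labels: np.ndarray  # int region ids, see REGION_IDS

    def __post_init__(self) -> None:
        shape = tuple(self.grid_shape)
        for name in ("storage_modulus", "loss_modulus", "density", "t2", "labels"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.tensors.shape != shape + (6,):
            raise ValueError(f"tensors have shape {self.tensors.shape}, expected {shape + (6,)}")
        tissue = self.labels > 0
        if np.any(self.storage_modulus[tissue] <= 0):
            raise ValueError("storage modulus must be positive inside tissue")
        if np.any(self.loss_modulus[tissue] < 0):
            raise ValueError("loss modulus must be non-negative inside tissue")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == REGION_IDS[region]

    def region_volume_mm3(self, region: str) -> float:
        return float(self.region_mask(region).sum()) * self.voxel_volume_mm3

    def complex_modulus(self) -> np.ndarray:
        return self.storage_modulus + 1j * self.loss_modulus

    def is_homogeneous(self) -> bool:
        tissue = self.labels > 0
        for arr in (self.storage_modulus, self.loss_modulus, self.density):
            vals = arr[tissue]
            if vals.size and not np.allclose(vals, vals.flat[0]):
                return False
        return True

    def voxel_coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center coordinates in mm."""
        axes = [
            (np.arange(n) + 0.5) * s
            for n, s in zip(self.grid_shape, self.spacing_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]


@dataclass
class EchoTrain:
    """Multi-echo magnitude signal per voxel."""

    te_list: np.ndarray  # ms, strictly increasing
    signal: np.ndarray  # (..., n_echo), >= 0
    noise_sd: float
    zero_t2_mask: np.ndarray | None = None  # voxels with non-positive truth T2

    def __post_init__(self) -> None:
        te = np.asarray(self.te_list, float)
        if te.ndim != 1 or te.size == 0 or np.any(np.diff(te) <= 0):
            raise ValueError("te_list must be non-empty and strictly increasing")
        if self.signal.shape[-1] != te.size:
            raise ValueError("signal last axis must match number of echoes")
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal must be non-negative")


@dataclass
class DWISet:
    """Diffusion-weighted magnitude volumes, one per b-value/direction."""

    bvalues: np.ndarray  # s/mm^2, one per volume
    directions: np.ndarray  # (n_vol, 3) unit vectors (b=0 row may be zero)
    signal: np.ndarray  # (..., n_vol)

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, float)
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if int(np.sum(b == 0)) != 1:
            raise ValueError("exactly one b=0 reference volume is required")
        dwi = b > 0
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("diffusion gradient directions must be unit-norm")


@dataclass
class HistoImage:
    """Synthetic RGB histology tile with recorded ground truth."""

    pixels: np.ndarray  # (h, w, 3) uint8
    pixel_size_um: float
    truth_stained_fraction: float
    truth_cell_density: float  # nuclei per 100 um^2
    truth_stain_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    truth_nucleus_centers: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    nucleus_radius_um: float = 0.0


def _default_regions() -> dict[str, object]:
    """Default shapes: striatal tumor, callosal band, needle tract, mirror ROI."""
    return {
        "corpus_callosum": Band(
            x0_mm=9.6, y0_mm=12.0, curvature_per_mm=-0.05,
            thickness_mm=0.9, x_extent_mm=(3.0, 16.2), z_extent_mm=(0.0, 2.7),
        ),
        "tumor_core": Ellipsoid.from_volume((13.0, 8.0, 1.35), 3.76),
        "needle_tract": Ellipsoid((13.0, 10.5, 1.35), (0.25, 2.0, 1.0)),
        "contralateral": Ellipsoid.from_volume((6.2, 8.0, 1.35), 3.76),
    }


def build_property_phantom(
    regions: Mapping[str, RegionParams],
    shapes: Mapping[str, object] | None = None,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    density: float = DEFAULT_DENSITY,
) -> PropertyPhantom:
    """Voxelize region shapes onto the grid and fill tissue parameter maps.

    ``regions`` must contain a ``"brain"`` entry used for all tissue voxels
    not claimed by a more specific region; other keys are drawn from
    ``REGION_PRIORITY`` and overlaps resolve in that priority order
    (tumor core beats corpus callosum beats needle tract).
    """
    if "brain" not in regions:
        raise ValueError("a 'brain' parameter set is required")
    unknown = set(regions) - set(REGION_IDS)
    if unknown:
        raise ValueError(f"unknown region keys: {sorted(unknown)}")
    if shapes is None:
        shapes = {k: v for k, v in _default_regions().items() if k in regions}

    shape = tuple(grid_shape)
    labels = np.full(shape, REGION_IDS["brain"], dtype=np.int16)
    gd = np.empty(shape)
    gl = np.empty(shape)
    t2 = np.empty(shape)
    tensors = np.empty(shape + (6,))

    coords = None
    # paint lowest priority first so high-priority shapes overwrite
    for name in reversed(REGION_PRIORITY):
        if name == "brain" or name not in regions:
            continue
        if name not in shapes:
            raise ValueError(f"region '{name}' has parameters but no shape")
        if coords is None:
            axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing_mm)]
            coords = tuple(np.meshgrid(*axes, indexing="ij"))
        mask = shapes[name].mask(coords)
        if not mask.any():
            raise ValueError(f"region '{name}' lies outside the grid")
        labels[mask] = REGION_IDS[name]

    for name, rid in REGION_IDS.items():
        mask = labels == rid
        if not mask.any():
            continue
        params = regions.get(name, regions["brain"])
        gd[mask] = params.gd_pa
        gl[mask] = params.gl_pa
        t2[mask] = params.t2_ms
        d = params.tensor()
        tensors[mask] = [d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]]

    return PropertyPhantom(
        grid_shape=shape,
        spacing_mm=tuple(spacing_mm),
        storage_modulus=gd,
        loss_modulus=gl,
        density=np.full(shape, float(density)),
        t2=t2,
        tensors=tensors,
        labels=labels,
    )


def homogeneous_phantom(
    gd_pa: float,
    gl_pa: float = 0.0,
    t2_ms: float = 40.0,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    density: float = DEFAULT_DENSITY,
) -> PropertyPhantom:
    """Uniform single-tissue phantom (every voxel labeled brain)."""
    return build_property_phantom(
        regions={"brain": RegionParams(gd_pa=gd_pa, gl_pa=gl_pa, t2_ms=t2_ms)},
        shapes={},
        grid_shape=grid_shape,
        spacing_mm=spacing_mm,
        density=density,
    )


def magnitude_noise(clean: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: |clean + n1 + i*n2| with n1,n2 ~ N(0, noise_sd)."""
    if noise_sd == 0:
        return np.abs(clean).astype(float)
    n1 = rng.normal(0.0, noise_sd, size=clean.shape)
    n2 = rng.normal(0.0, noise_sd, size=clean.shape)
    return np.hypot(clean + n1, n2)


def synthesize_echo_train(
    phantom: PropertyPhantom,
    te_list: Sequence[float] | None = None,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> EchoTrain:
    """Mono-exponential decay S(TE) = s0*exp(-TE/T2) plus magnitude noise.

    Voxels with non-positive T2 emit zero signal and are flagged.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    te = np.arange(7.0, 211.0, 7.0) if te_list is None else np.asarray(te_list, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t2 = phantom.t2
    bad = t2 <= 0
    t2_safe = np.where(bad, 1.0, t2)
    clean = s0 * np.exp(-te[None, None, None, :] / t2_safe[..., None])
    clean[bad] = 0.0
    sig = magnitude_noise(clean, noise_sd, rng)
    return EchoTrain(te_list=te, signal=sig, noise_sd=float(noise_sd), zero_t2_mask=bad)


def synthesize_dwi(
    phantom: PropertyPhantom,
    bvalue: float = 1500.0,
    directions: np.ndarray | None = None,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> DWISet:
    """Tensor-model diffusion signal S = s0*exp(-b g^T D g) plus noise.

    One b=0 volume is prepended. Default directions are the shipped
    electrostatic-repulsion 30-point set.
    """
    if bvalue < 0:
        raise ValueError("b-value must be non-negative")
    if directions is None:
        from ._directions import DIRECTIONS_30

        directions = DIRECTIONS_30
    g = np.asarray(directions, float)
    norms = np.linalg.norm(g, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise ValueError("directions must be unit-norm")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    d6 = phantom.tensors  # (..., 6)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    # g^T D g for the 6 unique components
    quad = (
        d6[..., None, 0] * gx**2
        + d6[..., None, 1] * gy**2
        + d6[..., None, 2] * gz**2
        + 2 * d6[..., None, 3] * gx * gy
        + 2 * d6[..., None, 4] * gx * gz
        + 2 * d6[..., None, 5] * gy * gz
    )
    clean_dwi = s0 * np.exp(-bvalue * quad)
    clean = np.concatenate(
        [np.full(phantom.grid_shape + (1,), float(s0)), clean_dwi], axis=-1
    )
    sig = magnitude_noise(clean, noise_sd, rng)
    bvals = np.concatenate([[0.0], np.full(len(g), float(bvalue))])
    dirs = np.concatenate([np.zeros((1, 3)), g], axis=0)
    return DWISet(bvalues=bvals, directions=dirs, signal=sig)


# Default palettes: Alcian-blue-like stain on an eosin-like background, dark
# hematoxylin nuclei. Means are separated by far more than 6 palette SDs.
STAIN_PALETTE = {"mean": (70.0, 130.0, 180.0), "sd": (5.0, 5.0, 5.0)}
BACKGROUND_PALETTE = {"mean": (240.0, 228.0, 234.0), "sd": (4.0, 4.0, 4.0)}
NUCLEUS_COLOR = (40.0, 35.0, 70.0)


def synthesize_histology(
    width: int = 256,
    height: int = 256,
    pixel_size_um: float = 0.25,
    stained_fraction: float = 0.0,
    cell_density_per_100um2: float = 0.0,
    stained_palette: Mapping[str, Sequence[float]] | None = None,
    background_palette: Mapping[str, Sequence[float]] | None = None,
    nucleus_radius_um: float = 0.28,
    seed: int | np.random.Generator = 0,
) -> HistoImage:
    """Histology tile with known stained-area fraction and nucleus density.

    Stained pixels share a common stain-depth factor across channels: each
    stained pixel is palette_mean + t*palette_sd + small jitter with a
    single zero-mean, unit-SD, bounded t (uniform over +-sqrt(3)) per
    pixel — stain uptake varies within a bounded range while the hue stays
    fixed, the regime the per-channel mean+-2SD thresholding rule is
    designed for. Nuclei are dark disks placed by dart throwing at the
    requested Poisson-mean density, kept at least one pixel apart so
    rasterized disks stay separable; placement failure after exhausting
    candidates raises (infeasible density).
    """
    if not 0.0 <= stained_fraction <= 1.0:
        raise ValueError("stained_fraction must lie in [0, 1]")
    stained_palette = stained_palette or STAIN_PALETTE
    background_palette = background_palette or BACKGROUND_PALETTE
    s_mean = np.asarray(stained_palette["mean"], float)
    s_sd = np.asarray(stained_palette["sd"], float)
    b_mean = np.asarray(background_palette["mean"], float)
    b_sd = np.asarray(background_palette["sd"], float)
    if np.any(np.abs(s_mean - b_mean) <= 6.0 * np.maximum(s_sd, b_sd)):
        raise ValueError("stained and background palettes are not separable (need >6 SD)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_px = height * width
    img = np.empty((height, width, 3), float)
    t_bg = rng.normal(size=(height, width, 1))
    jitter = rng.normal(scale=1.0, size=(height, width, 3))
    img[:] = b_mean + t_bg * b_sd + jitter

    # nuclei first: stained pixels are then drawn from the remainder
    area_um2 = n_px * pixel_size_um**2
    n_nuclei = int(rng.poisson(cell_density_per_100um2 * area_um2 / 100.0))
    nucleus_mask = np.zeros((height, width), bool)
    centers = np.zeros((0, 2), float)
    if n_nuclei > 0:
        r_px = nucleus_radius_um / pixel_size_um
        centers_list: list[tuple[float, float]] = []
        min_d = 2.0 * r_px + 1.0  # one clear pixel between rasterized disks
        min_d2 = min_d**2
        cell = max(min_d, 1e-9)
        grid: dict[tuple[int, int], list[int]] = {}
        attempts_per = 200
        for _ in range(n_nuclei):
            placed = False
            for _try in range(attempts_per):
                cy = rng.uniform(r_px, height - r_px)
                cx = rng.uniform(r_px, width - r_px)
                gy, gx_ = int(cy / cell), int(cx / cell)
                ok = True
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        for idx in grid.get((gy + dy, gx_ + dx), ()):
                            py, px = centers_list[idx]
                            if (py - cy) ** 2 + (px - cx) ** 2 < min_d2:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if ok:
                    grid.setdefault((gy, gx_), []).append(len(centers_list))
                    centers_list.append((cy, cx))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "nucleus density infeasible: cannot place disjoint disks"
                )
        centers = np.array(centers_list)
        yy, xx = np.mgrid[0:height, 0:width]
        for cy, cx in centers_list:
            # rasterize only a local window around each disk
            y0, y1 = int(cy - r_px - 1), int(cy + r_px + 2)
            x0, x1 = int(cx - r_px - 1), int(cx + r_px + 2)
            sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r_px**2
            nucleus_mask[y0:y1, x0:x1] |= sub

    free = np.flatnonzero(~nucleus_mask.ravel())
    n_stained = int(round(stained_fraction * n_px))
    if n_stained > free.size:
        raise ValueError("stained_fraction infeasible after nucleus placement")
    stain_mask = np.zeros(n_px, bool)
    if n_stained > 0:
        chosen = rng.choice(free, size=n_stained, replace=False)
        stain_mask[chosen] = True
    stain_mask = stain_mask.reshape(height, width)
    if n_stained > 0:
        t = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(n_stained, 1))
        jit = rng.normal(scale=1.0, size=(n_stained, 3))
        img[stain_mask] = s_mean + t * s_sd + jit

    img[nucleus_mask] = np.asarray(NUCLEUS_COLOR) + rng.normal(
        scale=3.0, size=(int(nucleus_mask.sum()), 3)
    )

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return HistoImage(
        pixels=pixels,
        pixel_size_um=float(pixel_size_um),
        truth_stained_fraction=n_stained / n_px,
        truth_cell_density=len(centers) * 100.0 / area_um2,
        truth_stain_mask=stain_mask,
        truth_nucleus_centers=centers,
        nucleus_radius_um=float(nucleus_radius_um),
    )
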