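"""Time-harmonic shear-wave forward simulation and phase encoding.

Fields follow the u(t) = Re{U exp(i w t)} convention. A plane shear wave
propagating along n with complex wavenumber k = w sqrt(rho / G*) is
U(r) = a p exp(-i k r.n); the principal square root puts Im(k) <= 0 for
a lossy medium, so the wave decays along its propagation direction.

Heterogeneous fields come from a per-component finite-difference solve of
div(G* grad u) + rho w^2 u = 0 with a prescribed source face, absorbing
(loss-ramp) layers on the remaining in-plane faces and zero-gradient
boundaries through-slice (stacks are typically only nine slices thick).

The scanner side is emulated by `encode_wave_phases`: the motion-encoded MR
phase is sampled at four vibration phases 0, pi/2, pi, 3pi/2 per encoding
direction, optionally wrapped into (-pi, pi] and corrupted with noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import PropertyPhantom

__all__ = [
    "ComplexWaveField",
    "WaveAcquisition",
    "shear_wavenumber",
    "plane_wave_field",
    "solve_heterogeneous_helmholtz",
    "add_compressional_component",
    "encode_wave_phases",
]

WAVE_PHASE_OFFSETS = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])


@dataclass
class ComplexWaveField:
    """Complex displacement amplitude per voxel, meters."""

    displacement: np.ndarray  # (nx, ny, nz, 3) complex
    frequency: float  # Hz
    spacing_mm: tuple[float, float, float]
    interior: np.ndarray | None = None  # mask excluding source/absorbing layers

    def __post_init__(self) -> None:
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")


@dataclass
class WaveAcquisition:
    """Motion-encoded phase images, (nx, ny, nz, 3 directions, 4 phases)."""

    phase_images: np.ndarray  # radians
    scale: float  # radians of MR phase per meter of displacement
    frequency: float
    spacing_mm: tuple[float, float, float]
    wrap_applied: bool
    phase_offsets: np.ndarray = field(default_factory=lambda: WAVE_PHASE_OFFSETS.copy())

    def __post_init__(self) -> None:
        if self.phase_images.ndim != 5 or self.phase_images.shape[3:] != (3, 4):
            raise ValueError("phase_images must have shape (nx, ny, nz, 3, 4)")
        if self.wrap_applied:
            p = self.phase_images
            if p.max() > np.pi or p.min() <= -np.pi:
                raise ValueError("wrapped phases must lie in (-pi, pi]")


def shear_wavenumber(gstar_pa: complex, density: float, frequency: float) -> complex:
    """Complex k = w sqrt(rho/G*), branch with Im(k) <= 0 (decaying wave)."""
    w = 2 * np.pi * frequency
    k = w * np.sqrt(density / gstar_pa + 0j)
    if k.imag > 0:
        k = -k
    return k


def plane_wave_field(
    phantom: PropertyPhantom,
    propagation_dir: np.ndarray,
    polarization: np.ndarray,
    amplitude: float = 10e-6,
    frequency: float = 900.0,
) -> ComplexWaveField:
    """Analytic plane shear wave in a homogeneous phantom."""
    if not phantom.is_homogeneous():
        raise ValueError("plane_wave_field requires a homogeneous phantom; "
                         "use solve_heterogeneous_helmholtz")
    n = np.asarray(propagation_dir, float)
    p = np.asarray(polarization, float)
    n = n / np.linalg.norm(n)
    p = p / np.linalg.norm(p)
    if abs(n @ p) > 1e-9:
        raise ValueError("polarization must be orthogonal to propagation (shear wave)")

    g = complex(phantom.storage_modulus.flat[0], phantom.loss_modulus.flat[0])
    rho = float(phantom.density.flat[0])
    k = shear_wavenumber(g, rho, frequency)

    x, y, z = phantom.voxel_coords_mm()
    proj_m = (x * n[0] + y * n[1] + z * n[2]) * 1e-3
    u_scalar = amplitude * np.exp(-1j * k * proj_m)
    u = u_scalar[..., None] * p
    return ComplexWaveField(u, frequency, phantom.spacing_mm)


def _ramp_profile(depth: np.ndarray, width: int) -> np.ndarray:
    """Cubic 0->1 ramp over `width` voxels from the domain edge."""
    t = np.clip((width - depth) / width, 0.0, 1.0)
    return t**3


def solve_heterogeneous_helmholtz(
    phantom: PropertyPhantom,
    source_face: str = "x0",
    source_displacement: np.ndarray | complex = 1e-5,
    polarization: np.ndarray = (0.0, 0.0, 1.0),
    frequency: float = 900.0,
    absorber_width: int = 12,
    absorber_strength: float = 3.0,
    absorb_faces: tuple[str, ...] | None = None,
    z_boundary: str = "neumann",
) -> ComplexWaveField:
    """Per-component scalar Helmholtz solve on the phantom grid.

    The displacement prescribed on the source face (constant or an array
    over that face) is polarized along ``polarization``; each nonzero
    component is solved independently with the flux-form 7-point stencil of
    div(G grad u) + rho w^2 u = 0. The face opposite the source carries an
    absorbing layer — a cubic ramp of added loss modulus
    (absorber_strength * |G|) — so the launched wave is not reflected back;
    the remaining faces are zero-gradient. Lateral absorbers are
    deliberately not the default: they attenuate grazing waves and diffract
    into the interior, which is worse than the weak lateral reflections
    they would remove (override with ``absorb_faces``). Thin stacks leave
    no room for a through-slice absorber, hence zero-gradient z faces
    (set ``z_boundary="absorbing"`` for thick grids).

    The returned field's ``interior`` mask excludes the source face and all
    absorbing layers; within it the discrete residual is checked to be
    < 1e-8 in the backward-error sense.
    """
    if source_face not in ("x0", "x1", "y0", "y1"):
        raise ValueError("source_face must be one of x0, x1, y0, y1")
    nx, ny, nz = phantom.grid_shape
    hx, hy, hz = (s * 1e-3 for s in phantom.spacing_mm)
    w = 2 * np.pi * frequency
    rho = phantom.density
    g = phantom.complex_modulus().astype(complex)
    if np.any(g.real <= 0):
        raise ValueError("storage modulus must be positive throughout the domain")

    # absorbing loss ramp, by default only on the face opposite the source
    opposite = {"x0": "x1", "x1": "x0", "y0": "y1", "y1": "y0"}
    if absorb_faces is None:
        absorb_faces = (opposite[source_face],)
    if source_face in absorb_faces:
        raise ValueError("the source face cannot also absorb")
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ramp = np.zeros(phantom.grid_shape)
    face_depth = {
        "x0": ii, "x1": nx - 1 - ii, "y0": jj, "y1": ny - 1 - jj,
    }
    for f in absorb_faces:
        ramp = np.maximum(ramp, _ramp_profile(face_depth[f], absorber_width))
    if z_boundary == "absorbing":
        ramp = np.maximum(ramp, _ramp_profile(kk, absorber_width))
        ramp = np.maximum(ramp, _ramp_profile(nz - 1 - kk, absorber_width))
    elif z_boundary != "neumann":
        raise ValueError("z_boundary must be 'neumann' or 'absorbing'")
    g_eff = g + 1j * absorber_strength * np.abs(g) * ramp

    axis = {"x": 0, "y": 1}[source_face[0]]
    side = int(source_face[1])
    src_index = 0 if side == 0 else phantom.grid_shape[axis] - 1

    pol = np.asarray(polarization, float)
    pol = pol / np.linalg.norm(pol)
    face_shape = tuple(s for a, s in enumerate(phantom.grid_shape) if a != axis)
    if np.isscalar(source_displacement) or np.asarray(source_displacement).ndim == 0:
        face_vals = np.full(face_shape, complex(source_displacement))
    else:
        face_vals = np.asarray(source_displacement, complex)
        if face_vals.shape != face_shape:
            raise ValueError(f"source_displacement must have face shape {face_shape}")

    dirichlet = np.zeros(phantom.grid_shape, bool)
    dirichlet[(slice(None),) * axis + (src_index,)] = True

    n_vox = nx * ny * nz
    idx = np.arange(n_vox).reshape(nx, ny, nz)
    h = (hx, hy, hz)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = (rho * w**2).astype(complex).copy()

    for ax in range(3):
        n_ax = phantom.grid_shape[ax]
        for sgn in (+1, -1):
            sl_c = [slice(None)] * 3
            sl_n = [slice(None)] * 3
            if sgn == +1:
                sl_c[ax] = slice(0, n_ax - 1)
                sl_n[ax] = slice(1, n_ax)
            else:
                sl_c[ax] = slice(1, n_ax)
                sl_n[ax] = slice(0, n_ax - 1)
            g_face = 0.5 * (g_eff[tuple(sl_c)] + g_eff[tuple(sl_n)]) / h[ax] ** 2
            diag[tuple(sl_c)] -= g_face
            rows.append(idx[tuple(sl_c)].ravel())
            cols.append(idx[tuple(sl_n)].ravel())
            vals.append(g_face.ravel())
            # boundary voxels simply lack the outward face term, i.e. the
            # outward flux vanishes: natural zero-gradient closure (hidden
            # behind the absorber on x/y faces, the actual boundary on z).

    # first-order outgoing-wave (Robin) closure on absorbing faces:
    # du/dn = -i k u with the local wavenumber, so the ramp only has to
    # absorb what this radiation condition misses
    w_ang = w
    for f in absorb_faces:
        ax = {"x": 0, "y": 1}[f[0]]
        edge = 0 if f[1] == "0" else phantom.grid_shape[ax] - 1
        sl = [slice(None)] * 3
        sl[ax] = edge
        g_b = g_eff[tuple(sl)]
        k_b = w_ang * np.sqrt(rho[tuple(sl)] / g_b)
        k_b = np.where(k_b.imag > 0, -k_b, k_b)
        diag[tuple(sl)] += -1j * k_b * g_b / h[ax]

    a = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_vox, n_vox),
    ).tocsr()
    a = a + sp.diags(diag.ravel())

    # eliminate the Dirichlet unknowns (keeps the reduced pattern symmetric,
    # which the fill-reducing ordering needs to stay cheap)
    d_flat = np.flatnonzero(dirichlet.ravel())
    free = np.ones(n_vox, bool)
    free[d_flat] = False
    f_flat = np.flatnonzero(free)
    a_ff = a[f_flat][:, f_flat].tocsc()
    a_fd = a[f_flat][:, d_flat].tocsr()

    u = np.zeros(phantom.grid_shape + (3,), complex)
    interior = ~dirichlet & (ramp == 0)
    face_flat = face_vals.ravel()

    lu = None
    a_norm = None
    for comp in range(3):
        if pol[comp] == 0:
            continue
        u_d = pol[comp] * face_flat
        b = -(a_fd @ u_d)
        if lu is None:
            lu = spla.splu(a_ff, permc_spec="MMD_AT_PLUS_A")
            a_norm = np.abs(a_ff).sum(axis=1).max()
        sol = lu.solve(b)
        res = a_ff @ sol - b
        # backward-error style scaling: ||r|| / (||A||_inf ||x|| + ||b||)
        rel = np.linalg.norm(res) / (
            a_norm * np.linalg.norm(sol) + np.linalg.norm(b) + 1e-300
        )
        if not np.all(np.isfinite(sol)) or rel > 1e-8:
            raise RuntimeError(
                f"Helmholtz system ill-conditioned: relative residual {rel:.2e}"
            )
        full = np.zeros(n_vox, complex)
        full[f_flat] = sol
        full[d_flat] = u_d
        u[..., comp] = full.reshape(nx, ny, nz)

    return ComplexWaveField(u, frequency, phantom.spacing_mm, interior=interior)


def add_compressional_component(
    field: ComplexWaveField,
    amplitude: float,
    wavelength_mm: float = 50.0,
    direction: np.ndarray = (2.0, 1.0, 0.5),
) -> ComplexWaveField:
    """Superimpose a curl-free (gradient) long-wavelength displacement.

    The added field is U_c = grad(phi) with phi a scalar plane wave of the
    given wavelength, normalized so max |U_c| equals ``amplitude``. Being a
    gradient it is annihilated by the curl operator; it models the residual
    compressional motion the curl step is there to remove.
    """
    if amplitude == 0:
        return field
    n = np.asarray(direction, float)
    n = n / np.linalg.norm(n)
    kc = 2 * np.pi / (wavelength_mm * 1e-3)  # rad/m

    nx, ny, nz = field.displacement.shape[:3]
    axes = [(np.arange(m) + 0.5) * s * 1e-3
            for m, s in zip((nx, ny, nz), field.spacing_mm)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    proj = x * n[0] + y * n[1] + z * n[2]
    # phi = (amplitude/kc) exp(-i kc proj)  =>  grad phi = -i amplitude n exp(...)
    grad = (-1j * amplitude * np.exp(-1j * kc * proj))[..., None] * n
    return ComplexWaveField(
        field.displacement + grad, field.frequency, field.spacing_mm,
        interior=field.interior,
    )


def encode_wave_phases(
    field: ComplexWaveField,
    scale: float,
    noise_sd_rad: float = 0.0,
    wrap: bool = True,
    seed: int | np.random.Generator = 0,
) -> WaveAcquisition:
    """Sample the motion-encoded MR phase at four vibration phases.

    For wave phase theta_n = 2 pi n / 4 and encoding direction d the clean
    sample is scale * Re{U_d exp(i theta_n)}; Gaussian phase noise is added
    before optional wrapping into (-pi, pi].
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    u = field.displacement  # (nx, ny, nz, 3)
    phases = scale * np.real(
        u[..., None] * np.exp(1j * WAVE_PHASE_OFFSETS)
    )  # (nx, ny, nz, 3, 4)
    if noise_sd_rad > 0:
        phases = phases + rng.normal(0.0, noise_sd_rad, size=phases.shape)
    if wrap:
        phases = np.angle(np.exp(1j * phases))
        # np.angle returns [-pi, pi]; fold the closed lower edge
        phases[phases == -np.pi] = np.pi
    return WaveAcquisition(
        phase_images=phases,
        scale=scale,
        frequency=field.frequency,
        spacing_mm=field.spacing_mm,
        wrap_applied=wrap,
    )
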