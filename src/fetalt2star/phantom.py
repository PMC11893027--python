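"""Gestational-age-parameterized digital fetal-brain phantom.

The phantom is a set of nested and offset ellipsoids on an isotropic grid,
one ellipsoid compartment per merged anatomical category: an outer shell of
external CSF, a cortical gray-matter ribbon, interior white matter, a
central deep-gray nucleus, paired lateral ventricles, a posterior-inferior
cerebellum and an inferior brainstem. The geometry is deliberately not
anatomically realistic — regional quantification depends only on the label
bookkeeping — but every compartment scales with gestational age so that
total and regional volumes grow monotonically over the 20-40 week range.

Forward signal simulation follows the mono-exponential gradient-echo decay
model S(TE) = S0 * exp(-TE / T2*), with per-region T2* drawn from the
normative reference table and per-region proton-density-like S0. Motion
corruption is simulated by drawing one rigid transform per (slice, dynamic)
excitation and sampling the moved phantom through a separable Gaussian
point-spread function; the three echoes of one excitation share the
transform, which is the premise of multichannel slice-to-volume
reconstruction. Magnitude noise is Rician.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.ndimage import map_coordinates

from .reference import (
    DEFAULT_S0,
    REGION_LABELS,
    REGIONS,
    lookup_reference_t2star,
)
from .transforms import RigidTransform

__all__ = [
    "AcquisitionSpec",
    "PhantomSpec",
    "TissueParams",
    "LabelVolume",
    "MultiEchoVolume",
    "SliceStack",
    "build_label_volume",
    "simulate_signal",
    "add_rician_noise",
    "add_gaussian_noise",
    "render_multiecho",
    "sample_slice_stack",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and timing of the dynamic multi-echo gradient-echo acquisition.

    Defaults follow the low-field fetal protocol: three echoes at
    TE = 42/107/172 ms, 3 mm isotropic acquisition, 15 dynamics.
    ``repetition_time`` is carried as metadata only.
    """

    echo_times: tuple = (42.0, 107.0, 172.0)
    in_plane_resolution: float = 3.0
    slice_thickness: float = 3.0
    n_dynamics: int = 15
    field_of_view: float | None = None
    repetition_time: float = 10420.0

    def __post_init__(self):
        te = np.asarray(self.echo_times, dtype=float)
        if te.ndim != 1 or len(te) < 1:
            raise ValueError("echo_times must be a non-empty 1-D sequence")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be strictly increasing and positive")
        if self.in_plane_resolution <= 0 or self.slice_thickness <= 0:
            raise ValueError("resolutions must be positive")
        if self.n_dynamics < 1:
            raise ValueError("n_dynamics must be >= 1")
        object.__setattr__(self, "echo_times", tuple(float(t) for t in te))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic scan.

    ``gestational_age`` (weeks) controls brain size and reference T2*;
    ``voxel_size`` is the ground-truth grid resolution (default 1.2 mm to
    match the reconstruction target); ``motion_amplitude`` is the half-range
    of the uniform per-slice rigid motion draws in (degrees, mm);
    ``noise_sigma`` the Rician noise level in signal units. ``seed`` fixes
    every stochastic output derived from the spec.
    """

    gestational_age: float = 30.0
    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 1.2
    noise_sigma: float = 0.0
    motion_amplitude: tuple = (0.0, 0.0)
    seed: int = 0
    smooth_gradient: float = 0.0

    def __post_init__(self):
        if not (20.0 <= self.gestational_age <= 40.0):
            raise ValueError("gestational_age must lie in [20, 40] weeks for reference lookup")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.grid_shape) < 8:
            raise ValueError("grid_shape too small")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


@dataclass
class TissueParams:
    """Per-region T2* (ms) and signal amplitude S0 (arbitrary units)."""

    t2star: dict
    s0: dict

    def __post_init__(self):
        for name, v in self.t2star.items():
            if v <= 0:
                raise ValueError(f"T2* must be positive for region {name!r}")
        for name, v in self.s0.items():
            if v <= 0:
                raise ValueError(f"S0 must be positive for region {name!r}")

    @classmethod
    def from_reference(cls, ga: float) -> "TissueParams":
        """Tissue parameters at gestational age ``ga`` from the normative table."""
        t2 = {r: lookup_reference_t2star(r, ga) for r in REGIONS}
        return cls(t2star=t2, s0=dict(DEFAULT_S0))


@dataclass
class LabelVolume:
    """Integer parcellation on a 3-D grid with a voxel-to-world affine."""

    labels: np.ndarray
    affine: np.ndarray
    label_names: dict

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def region_mask(self, region: str) -> np.ndarray:
        value = {v: k for k, v in self.label_names.items()}[region]
        return self.labels == value


@dataclass
class MultiEchoVolume:
    """4-D signal grid (x, y, z, echo) with echo times in ms."""

    data: np.ndarray
    echo_times: tuple
    affine: np.ndarray
    voxel_size: float
    validity: np.ndarray | None = None

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("MultiEchoVolume data must be 4-D (x, y, z, echo)")
        if self.data.shape[3] != len(self.echo_times):
            raise ValueError("echo axis length must equal the number of echo times")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class SliceStack:
    """All acquired 2-D slices of one echo across dynamics.

    ``data`` has shape (n_dynamics, n_slices, ny, nx); ``transforms`` holds
    one rigid motion per (dynamic, slice) excitation — identical across the
    per-echo stacks of one acquisition because the echoes of an excitation
    share the fetal position.
    """

    data: np.ndarray
    transforms: np.ndarray  # (n_dynamics, n_slices, 6): rotations deg, translations mm
    echo_index: int
    echo_time: float
    slice_z: np.ndarray  # world z of each slice center, mm
    pixel_x: np.ndarray  # world x of in-plane columns, mm
    pixel_y: np.ndarray  # world y of in-plane rows, mm
    thickness: float
    in_plane_resolution: float

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def transform(self, dynamic: int, slc: int) -> RigidTransform:
        return RigidTransform.from_params(self.transforms[dynamic, slc])


# ---------------------------------------------------------------------------
# label-volume construction


def centered_affine(shape: Sequence[int], voxel_size: float) -> np.ndarray:
    """Voxel-to-world affine placing the grid center at the world origin."""
    shape = np.asarray(shape)
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size
    affine[:3, 3] = -voxel_size * (shape - 1) / 2.0
    return affine


def _growth_factor(ga: float) -> float:
    # linear size growth; normalized so GA 40 fills the reference envelope
    return (0.55 + 0.0225 * ga) / (0.55 + 0.0225 * 40.0)


# compartment geometry in brain-normalized coordinates (unit outer
# ellipsoid); values are (center, semi-axes) triples. Cerebellum and
# brainstem sit posterior-inferior / inferior, largely outside the
# cerebral ellipsoid (bordered mostly by air, as their real counterparts
# border CSF), which keeps their regional T2* quantification free of
# partial-volume mixing with unrelated tissue.
_DEEP_GM = ((0.0, 0.02, -0.55), (0.34, 0.37, 0.62))
_VENTRICLE_L = ((-0.34, 0.08, 0.78), (0.27, 0.36, 0.50))
_VENTRICLE_R = ((0.34, 0.08, 0.78), (0.27, 0.36, 0.50))
_CEREBELLUM = ((0.0, -0.80, -0.55), (0.44, 0.32, 0.30))
_BRAINSTEM = ((0.0, 0.0, -1.15), (0.20, 0.22, 0.45))

_CSF_INNER = 0.72  # normalized radius of the eCSF / gray-matter interface
_CSF_ZMIN = 0.10  # the eCSF pool covers the dorsal cap z/|semi_z| > this
_GM_INNER = 0.54  # normalized radius of the gray / white interface


def build_label_volume(spec: PhantomSpec) -> LabelVolume:
    """Construct the 7-region parcellation for one phantom.

    The outer brain ellipsoid has semi-axes (a, 0.85a, 0.8a) with ``a``
    scaled to the grid and growing linearly with gestational age, so the
    total segmented volume is strictly increasing in GA on a fixed grid.

    Raises ``ValueError`` naming the first empty region if the grid is too
    small to host all seven compartments (>= 48 voxels per axis at 1.2 mm
    is always sufficient).
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    affine = centered_affine(shape, spec.voxel_size)

    half_extent = min((s - 1) / 2.0 * spec.voxel_size for s in shape)
    a = 0.82 * half_extent * _growth_factor(spec.gestational_age)
    semi = np.array([a, 0.85 * a, 0.80 * a])
    # cerebrum sits dorsally in the grid, leaving room for the inferior
    # brainstem column below
    brain_center = np.array([0.0, 0.0, 0.08 * half_extent])

    coords = np.meshgrid(
        *[(np.arange(s) - (s - 1) / 2.0) * spec.voxel_size for s in shape], indexing="ij"
    )
    world = np.stack(coords, axis=-1)  # (X, Y, Z, 3)
    u = (world - brain_center) / semi  # brain-normalized coordinates
    r = np.linalg.norm(u, axis=-1)

    brain = r <= 1.0
    labels = np.zeros(shape, dtype=np.int16)
    # cortical ribbon over the whole surface; the external-CSF pool is a
    # dorsal cap (real fetal eCSF is distributed unevenly, and air borders
    # are neutral for T2* quantification)
    labels[(r > _GM_INNER) & brain] = REGION_LABELS["gray_matter"]
    labels[(r > _CSF_INNER) & brain & (u[..., 2] > _CSF_ZMIN)] = REGION_LABELS["eCSF"]
    labels[r <= _GM_INNER] = REGION_LABELS["white_matter"]

    def ellipsoid(center, semi_axes, clip=True):
        d = (u - np.asarray(center)) / np.asarray(semi_axes)
        inside = np.linalg.norm(d, axis=-1) <= 1.0
        return (inside & brain) if clip else inside

    # paint order sets precedence; later structures carve out earlier ones;
    # the infratentorial structures may extend below the cerebral ellipsoid
    labels[ellipsoid(*_DEEP_GM)] = REGION_LABELS["deep_gray_matter"]
    labels[ellipsoid(*_VENTRICLE_L)] = REGION_LABELS["ventricles"]
    labels[ellipsoid(*_VENTRICLE_R)] = REGION_LABELS["ventricles"]
    labels[ellipsoid(*_CEREBELLUM, clip=False)] = REGION_LABELS["cerebellum"]
    labels[ellipsoid(*_BRAINSTEM, clip=False)] = REGION_LABELS["brainstem"]

    for region, value in REGION_LABELS.items():
        if not np.any(labels == value):
            raise ValueError(
                f"grid {shape} too small to host region {region!r}; "
                "use >= 48 voxels per axis at 1.2 mm"
            )

    names = {v: k for k, v in REGION_LABELS.items()}
    names[0] = "background"
    return LabelVolume(labels=labels, affine=affine, label_names=names)


# ---------------------------------------------------------------------------
# signal model


def simulate_signal(s0: float, t2star: float, echo_times) -> np.ndarray:
    """Noise-free mono-exponential decay S(TE) = S0 * exp(-TE / T2*)."""
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    if t2star <= 0:
        raise ValueError("t2star must be > 0")
    te = np.asarray(echo_times, dtype=float)
    return s0 * np.exp(-te / t2star)


def add_rician_noise(signal, sigma: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise of scale ``sigma``.

    Each value v is replaced by sqrt((v + n1)^2 + n2^2) with n1, n2
    independent N(0, sigma). ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    arr = np.asarray(signal, dtype=float)
    if sigma == 0:
        return arr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=arr.shape)
    n2 = rng.normal(0.0, sigma, size=arr.shape)
    return np.sqrt((arr + n1) ** 2 + n2**2)


def add_gaussian_noise(signal, sigma: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Additive zero-mean Gaussian noise (estimator-comparison alternative)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    arr = np.asarray(signal, dtype=float)
    if sigma == 0:
        return arr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return arr + rng.normal(0.0, sigma, size=arr.shape)


def render_multiecho(
    labels: LabelVolume,
    tissue: TissueParams,
    acq: AcquisitionSpec,
    smooth_gradient: float = 0.0,
) -> MultiEchoVolume:
    """Forward-simulate the noise-free multi-echo volume from a parcellation.

    Every voxel of a region carries the region's (S0, T2*); background is
    zero at all echoes. ``smooth_gradient`` optionally modulates T2* by a
    linear factor (1 + g * z/z_max) along the slice axis to emulate smooth
    within-region heterogeneity.
    """
    te = np.asarray(acq.echo_times, dtype=float)
    shape = labels.labels.shape
    data = np.zeros(shape + (len(te),), dtype=float)

    if smooth_gradient != 0.0:
        nz = shape[2]
        z_norm = (np.arange(nz) - (nz - 1) / 2.0) / max((nz - 1) / 2.0, 1.0)
        modulation = 1.0 + smooth_gradient * z_norm  # (nz,)

    for value, name in labels.label_names.items():
        if value == 0:
            continue
        mask = labels.labels == value
        if name not in tissue.t2star or name not in tissue.s0:
            raise KeyError(f"tissue parameters missing for region {name!r} (label {value})")
        if smooth_gradient == 0.0:
            data[mask] = simulate_signal(tissue.s0[name], tissue.t2star[name], te)
        else:
            t2_z = tissue.t2star[name] * modulation  # (nz,)
            sig = tissue.s0[name] * np.exp(-te[None, :] / t2_z[:, None])  # (nz, n_echo)
            idx = np.nonzero(mask)
            data[idx[0], idx[1], idx[2]] = sig[idx[2]]

    voxel = float(np.abs(labels.affine[0, 0]))
    return MultiEchoVolume(
        data=data, echo_times=te_tuple(te), affine=labels.affine.copy(), voxel_size=voxel
    )


def te_tuple(te) -> tuple:
    return tuple(float(t) for t in np.asarray(te).ravel())


# ---------------------------------------------------------------------------
# slice-stack sampling


def acquisition_quadrature(
    in_plane_resolution: float,
    slice_fwhm: float,
    n_inplane: int = 3,
    n_through: int = 5,
):
    """Sampling offsets/weights of the acquisition point-spread model.

    In-plane: boxcar average over the pixel footprint (rectangle rule with
    ``n_inplane`` sub-points per axis). Through-plane: Gaussian slice
    profile of FWHM ``slice_fwhm`` integrated by Gauss-Hermite quadrature.
    The same quadrature defines both the simulator and the reconstruction
    forward model.
    """
    sz = slice_fwhm * FWHM_TO_SIGMA
    step = in_plane_resolution / n_inplane
    oxy = (np.arange(n_inplane) - (n_inplane - 1) / 2.0) * step
    wxy = np.full(n_inplane, 1.0 / n_inplane)
    h, wz = hermgauss(n_through)
    oz = np.sqrt(2.0) * sz * h
    wz = wz / wz.sum()
    off = np.stack(np.meshgrid(oxy, oxy, oz, indexing="ij"), axis=-1).reshape(-1, 3)
    wgt = (wxy[:, None, None] * wxy[None, :, None] * wz[None, None, :]).reshape(-1)
    return off, wgt / wgt.sum()


def slice_geometry(volume_shape, voxel_size: float, acq: AcquisitionSpec):
    """Nominal slice/pixel world coordinates covering the volume extent."""
    extent = np.asarray(volume_shape) * voxel_size
    fov = acq.field_of_view if acq.field_of_view is not None else float(max(extent[:2]))
    nx = max(int(np.ceil(fov / acq.in_plane_resolution)), 1)
    ny = nx
    n_slices = max(int(np.ceil(extent[2] / acq.slice_thickness)), 1)
    px = (np.arange(nx) - (nx - 1) / 2.0) * acq.in_plane_resolution
    py = (np.arange(ny) - (ny - 1) / 2.0) * acq.in_plane_resolution
    pz = (np.arange(n_slices) - (n_slices - 1) / 2.0) * acq.slice_thickness
    return px, py, pz


def sample_slice_stack(
    volume: MultiEchoVolume,
    acq: AcquisitionSpec,
    motion_amplitude=(0.0, 0.0),
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> list:
    """Simulate the dynamic 2-D acquisition of ``volume``: one SliceStack per echo.

    For each (slice, dynamic) excitation one rigid transform is drawn
    (rotations uniform in +/- amplitude degrees, translations uniform in
    +/- amplitude mm) and applied identically to all echoes. Each slice
    pixel integrates the moved phantom through a Gaussian slice profile
    (FWHM = slice thickness) and a boxcar in-plane average over the pixel
    footprint. Rician noise of scale ``noise_sigma`` is added
    independently per echo.
    """
    amp_deg, amp_mm = float(motion_amplitude[0]), float(motion_amplitude[1])
    if amp_deg < 0 or amp_mm < 0:
        raise ValueError("motion amplitudes must be >= 0")
    if acq.in_plane_resolution < volume.voxel_size - 1e-9:
        raise ValueError("acquisition resolution must be coarser than or equal to the phantom grid")

    rng = np.random.default_rng(seed)
    px, py, pz = slice_geometry(volume.shape, volume.voxel_size, acq)
    nx, ny, n_slices = len(px), len(py), len(pz)
    n_dyn = acq.n_dynamics
    n_echo = len(acq.echo_times)

    transforms = np.zeros((n_dyn, n_slices, 6))
    if amp_deg > 0:
        transforms[..., :3] = rng.uniform(-amp_deg, amp_deg, size=(n_dyn, n_slices, 3))
    if amp_mm > 0:
        transforms[..., 3:] = rng.uniform(-amp_mm, amp_mm, size=(n_dyn, n_slices, 3))

    offsets, weights = acquisition_quadrature(acq.in_plane_resolution, acq.slice_thickness)
    n_q = len(weights)

    # nominal in-plane pixel grid for one slice, (ny*nx, 3) with z filled later
    gx, gy = np.meshgrid(px, py, indexing="xy")  # (ny, nx)
    plane = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=-1)

    inv_affine = np.linalg.inv(volume.affine)
    data = np.zeros((n_echo, n_dyn, n_slices, ny, nx))

    for d in range(n_dyn):
        for k in range(n_slices):
            t = RigidTransform.from_params(transforms[d, k])
            pts = plane.copy()
            pts[:, 2] = pz[k]
            # PSF offsets are fixed to the slice frame, then the excitation moves
            sample = t.apply(pts[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
            vox = (sample @ inv_affine[:3, :3].T) + inv_affine[:3, 3]
            coords = vox.T  # (3, ny*nx*n_q)
            for e in range(n_echo):
                vals = map_coordinates(
                    volume.data[..., e], coords, order=1, mode="constant", cval=0.0
                )
                data[e, d, k] = (vals.reshape(-1, n_q) @ weights).reshape(ny, nx)

    stacks = []
    for e in range(n_echo):
        echo_data = data[e]
        if noise_sigma > 0:
            echo_data = add_rician_noise(echo_data, noise_sigma, rng)
        stacks.append(
            SliceStack(
                data=echo_data,
                transforms=transforms.copy(),
                echo_index=e,
                echo_time=float(acq.echo_times[e]),
                slice_z=pz.copy(),
                pixel_x=px.copy(),
                pixel_y=py.copy(),
                thickness=acq.slice_thickness,
                in_plane_resolution=acq.in_plane_resolution,
            )
        )
    return stacks


def simulate_scan(
    spec: PhantomSpec, acq: AcquisitionSpec | None = None
):
    """Convenience wrapper: phantom -> labels, ground-truth volume, slice stacks."""
    acq = acq or AcquisitionSpec()
    labels = build_label_volume(spec)
    tissue = TissueParams.from_reference(spec.gestational_age)
    volume = render_multiecho(labels, tissue, acq, smooth_gradient=spec.smooth_gradient)
    stacks = sample_slice_stack(
        volume,
        acq,
        motion_amplitude=spec.motion_amplitude,
        seed=spec.seed,
        noise_sigma=spec.noise_sigma,
    )
    return labels, tissue, volume, stacks
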