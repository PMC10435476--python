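"""Forward simulation of co-registered AR/OR photoacoustic volumes.

Real paired AR/OR scans require a dual-mode microscope, so training and
evaluation here run on a phantom simulator with known ground truth.  The
forward model is deliberately simple but captures the features the
translation networks must learn to invert:

* geometry — tilted hair cylinders (the classic resolution phantom: long
  absorbers descending linearly from the surface to depth) or random
  branching vessel trees;
* resolution — a separable Gaussian point-spread function, isotropic 2D
  lateral x axial 1D, with the lateral width growing linearly outside the
  depth of focus (shift-variant blur applied slice by slice in depth);
* sensitivity — exponential amplitude decay with depth and a hard
  visibility cutoff (optical focusing dies at ~1 mm; acoustic focusing
  reaches ~1.9 mm, the asymmetry the enhancement must respect);
* noise — additive Gaussian background noise, plus salt-and-pepper
  corruption for the optical-resolution channel.

Every stochastic operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_volumes import Modality, PamVolume, ValueScale

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Pitches:
    """Voxel pitches in micrometres (defaults: 5 um lateral, 10 um depth)."""

    dx: float = 5.0
    dy: float = 5.0
    dz: float = 10.0


@dataclass(frozen=True)
class PhantomSpec:
    """Absorber geometry of a simulated sample.

    ``hairs``: ``n_hairs`` straight cylinders running along ``hair_axis``
    (x = fast scan, so the hair lies inside each b-scan; y = slow scan, so
    each b-scan cuts a circular cross-section), spread across the other
    lateral axis, with centerline depth increasing linearly along the hair
    from ``hair_depth_range[0]`` to ``hair_depth_range[1]``.
    ``vessels``: seeded random branching tubes with smoothly meandering
    centerlines and diameters drawn from ``vessel_diameter_range_um``.
    """

    kind: str = "hairs"                     # {"hairs", "vessels"}
    extent: tuple[float, float, float] = (1500.0, 1500.0, 2500.0)  # (X, Y, Z) um
    n_hairs: int = 3
    hair_diameter_um: float = 150.0
    hair_depth_range: tuple[float, float] = (100.0, 2000.0)
    hair_axis: str = "x"
    n_seeds: int = 4                        # vessel trees
    branch_prob: float = 0.03               # per-step branching probability
    vessel_diameter_range_um: tuple[float, float] = (40.0, 120.0)
    tortuosity: float = 0.25                # direction jitter per step (radians scale)
    absorption: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("hairs", "vessels"):
            raise GeometryError(f"unknown phantom kind {self.kind!r}")
        if self.hair_axis not in ("x", "y"):
            raise GeometryError(f"hair_axis must be 'x' or 'y', got {self.hair_axis!r}")
        if not (0 < self.absorption <= 1):
            raise GeometryError("absorption must lie in (0, 1]")
        if min(self.extent) <= 0:
            raise GeometryError("extent must be positive")


@dataclass(frozen=True)
class PsfModel:
    """Separable Gaussian PSF with depth-of-focus behaviour.

    ``lateral_fwhm_focus_um`` is the in-focus lateral resolution; outside
    the depth of focus the lateral FWHM grows linearly:
    ``FWHM(z) = FWHM_focus * max(1, 1 + growth * max(0, |z - focal| - DOF/2))``.
    Amplitude decays as ``exp(-z / attenuation_length_um)`` and is zeroed
    beyond ``max_visible_depth_um``.
    """

    lateral_fwhm_focus_um: float
    axial_fwhm_um: float
    focal_depth_um: float = 500.0
    depth_of_focus_um: float = 400.0
    out_of_focus_growth: float = 0.0        # FWHM multiplier increase per um beyond DOF
    attenuation_length_um: float = 1500.0   # 1/e depth-decay constant (free parameter)
    max_visible_depth_um: float = np.inf

    def __post_init__(self) -> None:
        for name in ("lateral_fwhm_focus_um", "axial_fwhm_um", "focal_depth_um",
                     "depth_of_focus_um", "attenuation_length_um", "max_visible_depth_um"):
            if not (getattr(self, name) > 0):
                raise GeometryError(f"{name} must be positive")
        if self.out_of_focus_growth < 0:
            raise GeometryError("out_of_focus_growth must be >= 0")

    def lateral_fwhm_at(self, z_um: float | np.ndarray) -> np.ndarray:
        """Depth-dependent lateral FWHM in micrometres."""
        beyond = np.maximum(0.0, np.abs(np.asarray(z_um) - self.focal_depth_um)
                            - self.depth_of_focus_um / 2.0)
        return self.lateral_fwhm_focus_um * np.maximum(1.0, 1.0 + self.out_of_focus_growth * beyond)


# System presets from the measured resolutions of the dual AR/OR and deep-AR
# systems (12 / 85 um lateral, 27 um axial shared transducer; 590 / 150 um
# for the low-frequency deep system).  OR optical focusing is visible to
# ~1 mm, acoustic focusing to ~1.9 mm, deep-AR to ~5 mm.
OR_PSF = PsfModel(
    lateral_fwhm_focus_um=12.0, axial_fwhm_um=27.0, focal_depth_um=500.0,
    depth_of_focus_um=400.0, out_of_focus_growth=0.004, max_visible_depth_um=1000.0,
)
AR_PSF = PsfModel(
    lateral_fwhm_focus_um=85.0, axial_fwhm_um=27.0, focal_depth_um=500.0,
    depth_of_focus_um=1500.0, out_of_focus_growth=0.001, max_visible_depth_um=1900.0,
)
DEEP_AR_PSF = PsfModel(
    lateral_fwhm_focus_um=590.0, axial_fwhm_um=150.0, focal_depth_um=1500.0,
    depth_of_focus_um=3000.0, out_of_focus_growth=0.0, max_visible_depth_um=5000.0,
)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian background noise plus salt-and-pepper corruption.

    ``gaussian_sigma`` is a fraction of full scale; ``salt_pepper_density``
    the fraction of corrupted pixels (half set to 0, half to 1).  Salt and
    pepper is characteristic of the optical-resolution channel.
    """

    gaussian_sigma: float = 0.01
    salt_pepper_density: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise GeometryError("gaussian_sigma must be >= 0")
        if not (0 <= self.salt_pepper_density < 1):
            raise GeometryError("salt_pepper_density must lie in [0, 1)")


AR_NOISE = NoiseModel(gaussian_sigma=0.01)
OR_NOISE = NoiseModel(gaussian_sigma=0.01, salt_pepper_density=0.005)


def _grid_shape(spec: PhantomSpec, pitches: Pitches) -> tuple[int, int, int]:
    X, Y, Z = spec.extent
    shape = (int(round(Y / pitches.dy)), int(round(X / pitches.dx)), int(round(Z / pitches.dz)))
    if min(shape) < 32:
        raise GeometryError(
            f"extent/pitches give grid {shape}; need >= 32 voxels per axis"
        )
    return shape


def _centers(n: int, pitch: float) -> np.ndarray:
    """Cell-centered physical coordinates of voxel centres."""
    return (np.arange(n) + 0.5) * pitch


def make_truth_volume(
    spec: PhantomSpec, pitches: Pitches = Pitches(), seed: int = 0
) -> PamVolume:
    """Rasterize the phantom geometry into a binary-times-absorption volume."""
    n_y, n_x, n_z = _grid_shape(spec, pitches)
    data = np.zeros((n_y, n_x, n_z), dtype=np.float64)
    if spec.kind == "hairs":
        _raster_hairs(data, spec, pitches)
    else:
        _raster_vessels(data, spec, pitches, seed)
    if not data.any():
        raise GeometryError("phantom structures do not intersect the grid")
    return PamVolume(
        data=data, dx=pitches.dx, dy=pitches.dy, dz=pitches.dz,
        modality=Modality.TRUTH, value_scale=ValueScale.FLOAT_UNIT,
    )


def hair_centerline(spec: PhantomSpec, k: int) -> tuple[float, float, float]:
    """(cross_um, z_start_um, z_end_um) of hair ``k``'s straight centerline.

    ``cross_um`` is the position on the lateral axis perpendicular to the
    hair (y when hairs run along x, x when they run along y).
    """
    X, Y, Z = spec.extent
    cross_extent = Y if spec.hair_axis == "x" else X
    cross_um = cross_extent * (k + 1) / (spec.n_hairs + 1)
    return cross_um, spec.hair_depth_range[0], spec.hair_depth_range[1]


def _raster_hairs(data: np.ndarray, spec: PhantomSpec, pitches: Pitches) -> None:
    n_y, n_x, n_z = data.shape
    y_um = _centers(n_y, pitches.dy)
    x_um = _centers(n_x, pitches.dx)
    z_um = _centers(n_z, pitches.dz)
    r = spec.hair_diameter_um / 2.0
    z0, z1 = spec.hair_depth_range
    if z1 > spec.extent[2] or z0 < 0:
        raise GeometryError("hair depth range exceeds phantom extent")
    along_um, cross_um = (x_um, y_um) if spec.hair_axis == "x" else (y_um, x_um)
    along_extent = spec.extent[0] if spec.hair_axis == "x" else spec.extent[1]
    for k in range(spec.n_hairs):
        cc, _, _ = hair_centerline(spec, k)
        # centerline depth rises linearly along the hair's own axis
        zc = z0 + (z1 - z0) * along_um / along_extent            # (n_along,)
        dc2 = (cross_um - cc) ** 2                               # (n_cross,)
        dz2 = (z_um[None, :] - zc[:, None]) ** 2                 # (n_along, n_z)
        inside = dc2[:, None, None] + dz2[None, :, :] < r * r    # (cross, along, z)
        if spec.hair_axis == "x":
            data[inside] = spec.absorption                        # (y, x, z)
        else:
            data[np.transpose(inside, (1, 0, 2))] = spec.absorption


def _raster_vessels(
    data: np.ndarray, spec: PhantomSpec, pitches: Pitches, seed: int
) -> None:
    """Seeded random branching tubes meandering mostly laterally."""
    rng = np.random.default_rng([seed, 0x7E55])
    n_y, n_x, n_z = data.shape
    X, Y, Z = spec.extent
    d_lo, d_hi = spec.vessel_diameter_range_um
    step = min(pitches.dx, pitches.dy)
    stack: list[tuple[np.ndarray, np.ndarray, float]] = []
    for _ in range(spec.n_seeds):
        pos = np.array([rng.uniform(0.1 * X, 0.9 * X),
                        rng.uniform(0.1 * Y, 0.9 * Y),
                        rng.uniform(0.15 * Z, 0.6 * Z)])
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta), 0.0])
        stack.append((pos, direction, rng.uniform(d_lo, d_hi)))
    n_steps = int(1.2 * max(n_x, n_y))
    while stack:
        pos, direction, diam = stack.pop()
        for _ in range(n_steps):
            _stamp_ball(data, spec, pitches, pos, diam / 2.0)
            # smooth meander: jitter the heading, damp vertical drift
            jitter = rng.normal(0.0, spec.tortuosity, size=3)
            jitter[2] *= 0.3
            direction = direction + jitter
            direction[2] *= 0.9
            direction /= np.linalg.norm(direction) + 1e-12
            pos = pos + direction * step
            if not (0 <= pos[0] < X and 0 <= pos[1] < Y and 0 <= pos[2] < Z):
                break
            if rng.random() < spec.branch_prob and len(stack) < 32:
                theta = rng.normal(0.0, 0.8)
                rot = np.array([
                    [np.cos(theta), -np.sin(theta), 0.0],
                    [np.sin(theta), np.cos(theta), 0.0],
                    [0.0, 0.0, 1.0],
                ])
                child = rot @ direction
                stack.append((pos.copy(), child, max(d_lo, diam * rng.uniform(0.5, 0.8))))
            diam = max(d_lo, diam * 0.999)


def _stamp_ball(
    data: np.ndarray, spec: PhantomSpec, pitches: Pitches,
    pos_um: np.ndarray, r_um: float,
) -> None:
    x, y, z = pos_um
    iy = int(y / pitches.dy)
    ix = int(x / pitches.dx)
    iz = int(z / pitches.dz)
    ry = int(np.ceil(r_um / pitches.dy)) + 1
    rx = int(np.ceil(r_um / pitches.dx)) + 1
    rz = int(np.ceil(r_um / pitches.dz)) + 1
    sy = slice(max(0, iy - ry), min(data.shape[0], iy + ry + 1))
    sx = slice(max(0, ix - rx), min(data.shape[1], ix + rx + 1))
    sz = slice(max(0, iz - rz), min(data.shape[2], iz + rz + 1))
    yy = _centers(data.shape[0], pitches.dy)[sy] - y
    xx = _centers(data.shape[1], pitches.dx)[sx] - x
    zz = _centers(data.shape[2], pitches.dz)[sz] - z
    dist2 = (yy[:, None, None] ** 2 + xx[None, :, None] ** 2 + zz[None, None, :] ** 2)
    region = data[sy, sx, sz]
    region[dist2 < r_um * r_um] = spec.absorption


def simulate_scan(
    truth: PamVolume,
    psf: PsfModel,
    noise: NoiseModel = NoiseModel(gaussian_sigma=0.0),
    seed: int | None = None,
) -> PamVolume:
    """Image a ground-truth volume through a PSF and noise model.

    Per depth slice: isotropic 2D lateral Gaussian blur with the
    depth-dependent FWHM; then a 1D axial Gaussian blur; then depth
    attenuation and the hard visibility cutoff; then Gaussian noise
    followed by salt-and-pepper; finally clipped to [0, 1].  Lateral blur
    sigmas below 0.05 px are treated as identity (delta-kernel limit).
    """
    if truth.modality is not Modality.TRUTH:
        raise GeometryError("simulate_scan expects a TRUTH volume")
    if seed is None:
        seed = noise.seed if noise.seed is not None else 0
    n_y, n_x, n_z = truth.shape
    z_um = _centers(n_z, truth.dz)
    out = np.empty_like(truth.data, dtype=np.float64)
    fwhms = psf.lateral_fwhm_at(z_um)
    min_lat = np.min([n_y * truth.dy, n_x * truth.dx])
    if np.max(fwhms) / FWHM_PER_SIGMA > min_lat:
        raise GeometryError("lateral PSF kernel larger than the grid")
    for iz in range(n_z):
        sigma_um = fwhms[iz] / FWHM_PER_SIGMA
        sig = (sigma_um / truth.dy, sigma_um / truth.dx)
        plane = truth.data[:, :, iz]
        if max(sig) < 0.05:
            out[:, :, iz] = plane
        else:
            out[:, :, iz] = ndimage.gaussian_filter(plane, sig, mode="constant")
    sigma_z = psf.axial_fwhm_um / FWHM_PER_SIGMA / truth.dz
    if sigma_z >= 0.05:
        out = ndimage.gaussian_filter1d(out, sigma_z, axis=2, mode="constant")
    out *= np.exp(-z_um / psf.attenuation_length_um)[None, None, :]
    out[:, :, z_um > psf.max_visible_depth_um] = 0.0
    rng = np.random.default_rng([int(seed), 0x5CA7])
    if noise.gaussian_sigma > 0:
        out = out + rng.normal(0.0, noise.gaussian_sigma, size=out.shape)
    if noise.salt_pepper_density > 0:
        mask = rng.random(out.shape) < noise.salt_pepper_density
        salt = rng.random(out.shape) < 0.5
        out[mask & salt] = 1.0
        out[mask & ~salt] = 0.0
    out = np.clip(out, 0.0, 1.0)
    modality = Modality.OR if psf is OR_PSF else Modality.AR
    return truth.with_data(out, modality=modality)


@dataclass
class ScanPair:
    """One phantom imaged through both PSFs (intrinsically co-registered)."""

    truth: PamVolume
    ar: PamVolume
    or_: PamVolume


def make_dataset(
    spec: PhantomSpec,
    psf_ar: PsfModel = AR_PSF,
    psf_or: PsfModel = OR_PSF,
    noise_ar: NoiseModel = AR_NOISE,
    noise_or: NoiseModel = OR_NOISE,
    n_volumes: int = 1,
    pitches: Pitches = Pitches(),
    seed: int = 0,
) -> tuple[list[ScanPair], dict]:
    """Simulate ``n_volumes`` phantoms, each scanned with both PSFs.

    Returns the co-registered pairs and a provenance record of every
    parameter and derived seed, sufficient to regenerate the dataset.
    """
    if n_volumes < 1:
        raise GeometryError("n_volumes must be >= 1")
    pairs: list[ScanPair] = []
    vol_seeds = []
    for i in range(n_volumes):
        s = int(np.random.default_rng([seed, i]).integers(0, 2**31 - 1))
        vol_seeds.append(s)
        truth = make_truth_volume(spec, pitches, seed=s)
        ar = simulate_scan(truth, psf_ar, noise_ar, seed=s + 1)
        ar = ar.with_data(ar.data, modality=Modality.AR)
        or_ = simulate_scan(truth, psf_or, noise_or, seed=s + 2)
        or_ = or_.with_data(or_.data, modality=Modality.OR)
        pairs.append(ScanPair(truth=truth, ar=ar, or_=or_))
    provenance = {
        "phantom": dataclasses.asdict(spec),
        "psf_ar": dataclasses.asdict(psf_ar),
        "psf_or": dataclasses.asdict(psf_or),
        "noise_ar": dataclasses.asdict(noise_ar),
        "noise_or": dataclasses.asdict(noise_or),
        "pitches": dataclasses.asdict(pitches),
        "n_volumes": n_volumes,
        "seed": seed,
        "volume_seeds": vol_seeds,
    }
    return pairs, provenance
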