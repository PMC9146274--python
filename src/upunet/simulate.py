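"""Synthetic fluorescence-microscopy frame simulator.

Generates confocal-like frames of fluorescent calibration beads on a
spatially varying background-emission field, following the forward model

    g_n = P( H(x* + b) + eta )

where ``x*`` is the rasterized bead slice, ``b`` the background emission
(modelled by multi-octave Perlin gradient noise), ``H`` a Gaussian PSF,
``eta`` read noise calibrated in relative Frobenius norm, and ``P`` photon
(Poisson) noise.  Each rendered item is a :class:`FramePair`: the noisy
input frame (with background) and the background-free target produced by
the identical pipeline with the background amplitude set to zero and the
same statistical-noise seeds, so the network learns to remove only the
background emission while the statistical noise is retained in the target.

All intensities live on a [0, 255] float scale; beads are rasterized at
90% of the 8-bit maximum (229.5).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

logger = logging.getLogger("upunet")

#: Bead rasterization intensity: 90% of the 8-bit maximum 255.
BEAD_VALUE = 229.5

#: Minimum analytic profile radius (px) for a particle to count as present
#: in a slice's ground truth; sub-half-pixel intersections are unobservable.
MIN_TRUTH_RADIUS_PX = 0.5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeSpec:
    """Physical imaging volume and its voxel discretization.

    ``Dx, Dy, Dz`` are the physical extents in micrometers; ``n`` the lateral
    voxel count per axis (frames are square) and ``nz`` the axial count, so a
    voxel covers ``dx x dy x dz`` with ``dx = Dx / n`` etc.
    """

    Dx: float = 76.0
    Dy: float = 76.0
    Dz: float = 5.0
    n: int = 128
    nz: int = 20

    def __post_init__(self) -> None:
        if not (self.Dx > 0 and self.Dy > 0 and self.Dz > 0):
            raise ValueError("physical extents must be positive")
        if self.n < 1 or self.nz < 1:
            raise ValueError("voxel counts must be >= 1")

    @property
    def dx(self) -> float:
        return self.Dx / self.n

    @property
    def dy(self) -> float:
        return self.Dy / self.n

    @property
    def dz(self) -> float:
        return self.Dz / self.nz


@dataclass(frozen=True)
class ParticleField:
    """Non-overlapping spherical beads in a continuous volume (micrometers)."""

    centers: np.ndarray  # (p, 3) x, y, z in um
    radii: np.ndarray    # (p,) in um

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if centers.size == 0:
            centers = centers.reshape(0, 3)
        radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if centers.shape[0] != radii.shape[0]:
            raise ValueError("centers and radii length mismatch")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)

    @property
    def count(self) -> int:
        return int(self.radii.shape[0])


@dataclass(frozen=True)
class BackgroundParams:
    """Multi-octave Perlin background-emission field.

    Octave ``k`` (1-based) uses frequency ``base_frequency * 2**(k-1)`` and
    amplitude ``base_amplitude * persistence**(k-1)``.  ``amplitude`` (beta)
    is the peak background intensity on the [0, 255] scale applied after
    per-frame min-max normalization of the raw field.
    """

    octaves: int = 8
    base_frequency: float = 1.0
    base_amplitude: float = 1.0
    persistence: float = 0.5
    amplitude: float = 0.8 * 255.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if not (0.0 < self.persistence <= 1.0):
            raise ValueError("persistence must be in (0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Blur and statistical-noise configuration.

    ``psf_sigma`` is the Gaussian PSF standard deviation in pixels;
    ``gaussian_level`` the relative Frobenius read-noise level sigma_n;
    ``poisson_gamma`` the photon count per intensity unit (``inf`` disables
    Poisson noise).  ``noise_order`` selects whether Gaussian read noise is
    applied before or after the Poisson step.
    """

    psf_sigma: float = 2.0
    gaussian_level: float = 0.03
    poisson_gamma: float = 1.0
    noise_order: str = "gaussian_then_poisson"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.gaussian_level < 0:
            raise ValueError("gaussian_level must be >= 0")
        if not self.poisson_gamma > 0:
            raise ValueError("poisson_gamma must be > 0")
        if self.noise_order not in ("gaussian_then_poisson", "poisson_then_gaussian"):
            raise ValueError(f"unknown noise_order: {self.noise_order!r}")


@dataclass(frozen=True)
class TruthDisc:
    """Ground-truth circular profile of one bead in one slice (pixel units)."""

    particle_id: int
    cx_px: float
    cy_px: float
    radius_px: float
    z_um: float


@dataclass(frozen=True)
class FramePair:
    """One training item: noisy input frame plus background-free target."""

    input_frame: np.ndarray
    target_frame: np.ndarray
    truth: tuple[TruthDisc, ...]
    slice_index: int
    seeds: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class DatasetSpec:
    """Full description of a synthetic dataset (sizes, physics, seeds)."""

    n_images: int = 500
    split: tuple[float, float, float] = (0.90, 0.05, 0.05)
    count_range: tuple[int, int] = (10, 15)
    radius: float | tuple[float, float] = 2.0
    bead_value: float = BEAD_VALUE
    volume: VolumeSpec = dc_field(default_factory=VolumeSpec)
    background: BackgroundParams = dc_field(default_factory=BackgroundParams)
    noise: NoiseParams = dc_field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0.0 < self.bead_value <= 255.0):
            raise ValueError("bead_value must be in (0, 255]")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


@dataclass
class Dataset:
    """Generated dataset with train/validation/test splits."""

    train: list[FramePair]
    val: list[FramePair]
    test: list[FramePair]
    spec: DatasetSpec

    def __iter__(self):
        return iter(self.train + self.val + self.test)


# ---------------------------------------------------------------------------
# Particle placement and rasterization
# ---------------------------------------------------------------------------

class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot fit another particle."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def place_particles(
    vol: VolumeSpec,
    count_range: tuple[int, int],
    radius_spec: float | tuple[float, float],
    seed=None,
    max_tries: int = 10_000,
) -> ParticleField:
    """Draw non-intersecting spheres uniformly inside the volume.

    The particle count is uniform over ``count_range`` (inclusive); each
    radius is either the fixed value or uniform over the ``(lo, hi)`` range.
    Rejection sampling re-draws any candidate whose center comes closer than
    the sum of radii to an accepted particle (touching is allowed); spheres
    may protrude past the volume boundary.
    """
    rng = _as_rng(seed)
    lo, hi = int(count_range[0]), int(count_range[1])
    if lo < 0 or hi < lo:
        raise ValueError("invalid count_range")
    count = int(rng.integers(lo, hi + 1))

    centers: list[np.ndarray] = []
    radii: list[float] = []
    for _ in range(count):
        for attempt in range(max_tries):
            if isinstance(radius_spec, (tuple, list)):
                r = float(rng.uniform(radius_spec[0], radius_spec[1]))
            else:
                r = float(radius_spec)
            if 2 * r > min(vol.Dx, vol.Dy):
                raise ValueError("particle radius does not fit in the volume laterally")
            c = rng.uniform([0.0, 0.0, 0.0], [vol.Dx, vol.Dy, vol.Dz])
            ok = True
            for c2, r2 in zip(centers, radii):
                if np.linalg.norm(c - c2) < r + r2:
                    ok = False
                    break
            if ok:
                centers.append(c)
                radii.append(r)
                break
        else:
            raise PlacementError(
                f"volume too crowded: could not place particle after {max_tries} tries"
            )
    return ParticleField(
        centers=np.array(centers, dtype=float).reshape(len(centers), 3),
        radii=np.array(radii, dtype=float),
    )


def rasterize_slice(
    field: ParticleField,
    vol: VolumeSpec,
    z_index: int,
    bead_value: float = BEAD_VALUE,
    min_truth_radius_px: float = MIN_TRUTH_RADIUS_PX,
) -> tuple[np.ndarray, tuple[TruthDisc, ...]]:
    """Rasterize one horizontal slice of the bead volume.

    Pixel ``(row, col)`` has center ``((col+0.5) dx, (row+0.5) dy)`` with the
    slice plane at height ``(z_index+0.5) dz``; it is set to ``bead_value``
    iff that point lies strictly within distance ``r`` of some bead center.
    The returned truth lists every bead whose analytic profile radius
    ``sqrt(r^2 - (z_c - z_slice)^2) / dx`` is at least ``min_truth_radius_px``.
    Truth centers are in 0-based pixel coordinates (pixel ``i`` center at
    coordinate ``i``), row = y, col = x.
    """
    if not (0 <= z_index < vol.nz):
        raise ValueError(f"z_index {z_index} outside [0, {vol.nz})")
    n = vol.n
    img = np.zeros((n, n), dtype=np.float64)
    z_slice = (z_index + 0.5) * vol.dz

    px_x = (np.arange(n) + 0.5) * vol.dx  # column centers
    px_y = (np.arange(n) + 0.5) * vol.dy  # row centers
    truth: list[TruthDisc] = []
    for pid in range(field.count):
        cx, cy, cz = field.centers[pid]
        r = field.radii[pid]
        dz2 = (cz - z_slice) ** 2
        if dz2 >= r * r:
            continue
        # strict inequality: voxel center within distance < r
        d2 = (px_x[None, :] - cx) ** 2 + (px_y[:, None] - cy) ** 2
        img[d2 + dz2 < r * r] = bead_value
        profile_r = math.sqrt(r * r - dz2) / vol.dx
        if profile_r >= min_truth_radius_px:
            truth.append(
                TruthDisc(
                    particle_id=pid,
                    cx_px=cx / vol.dx - 0.5,
                    cy_px=cy / vol.dy - 0.5,
                    radius_px=profile_r,
                    z_um=cz,
                )
            )
    return img, tuple(truth)


# ---------------------------------------------------------------------------
# Perlin gradient noise (improved variant: quintic fade, unit gradients)
# ---------------------------------------------------------------------------

def _fade(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep 6t^5 - 15t^4 + 10t^3 (zero 1st/2nd derivative at 0, 1)."""
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def perlin_octave(shape: tuple[int, int], frequency: float, rng) -> np.ndarray:
    """Single-octave 2D gradient noise sampled on a pixel grid.

    Pixel ``(i, j)`` samples lattice coordinate ``(i * f / H, j * f / W)``, so
    when the frequency divides the image size the lattice corners coincide
    with pixels (where the value is exactly zero).  Gradients are independent
    unit vectors hashed from the generator state, one per lattice node.
    """
    rng = _as_rng(rng)
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("shape must be positive")
    f = float(frequency)
    cells = int(math.ceil(f))
    angles = rng.uniform(0.0, 2.0 * math.pi, size=(cells + 1, cells + 1))
    grad = np.stack([np.cos(angles), np.sin(angles)], axis=-1)

    u = np.arange(h) * (f / h)  # row coordinate
    v = np.arange(w) * (f / w)  # col coordinate
    u0 = np.minimum(u.astype(int), cells - 1)
    v0 = np.minimum(v.astype(int), cells - 1)
    fu = u - u0
    fv = v - v0

    fu2 = fu[:, None]
    fv2 = fv[None, :]
    # corner gradients as (h, w, 2) arrays, then dot with corner offsets
    c00 = grad[u0[:, None], v0[None, :]]
    c10 = grad[u0[:, None] + 1, v0[None, :]]
    c01 = grad[u0[:, None], v0[None, :] + 1]
    c11 = grad[u0[:, None] + 1, v0[None, :] + 1]

    d00 = c00[..., 0] * fu2 + c00[..., 1] * fv2
    d10 = c10[..., 0] * (fu2 - 1.0) + c10[..., 1] * fv2
    d01 = c01[..., 0] * fu2 + c01[..., 1] * (fv2 - 1.0)
    d11 = c11[..., 0] * (fu2 - 1.0) + c11[..., 1] * (fv2 - 1.0)

    su = _fade(fu2)
    sv = _fade(fv2)
    a = d00 + su * (d10 - d00)
    b = d01 + su * (d11 - d01)
    return a + sv * (b - a)


def perlin_field(shape: tuple[int, int], bg: BackgroundParams, seed=None) -> np.ndarray:
    """Multi-octave Perlin field (raw, before intensity scaling).

    Octave ``k`` uses frequency ``base_frequency * 2**(k-1)`` and amplitude
    ``base_amplitude * persistence**(k-1)``; the octaves are summed.
    Deterministic given the seed (``seed`` argument overrides ``bg.seed``).
    """
    rng = _as_rng(bg.seed if seed is None else seed)
    out = np.zeros(shape, dtype=np.float64)
    freq = bg.base_frequency
    amp = bg.base_amplitude
    for _ in range(bg.octaves):
        out += amp * perlin_octave(shape, freq, rng)
        freq *= 2.0
        amp *= bg.persistence
    return out


def _normalize01(field: np.ndarray) -> np.ndarray:
    lo = field.min()
    hi = field.max()
    if hi - lo <= 0:
        return np.zeros_like(field)
    return (field - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# PSF blur and statistical noise
# ---------------------------------------------------------------------------

def gaussian_kernel(sigma: float) -> np.ndarray:
    """Unit-sum 1D discrete Gaussian, truncated at radius ceil(4 sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = int(math.ceil(4.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def apply_psf(img: np.ndarray, sigma: float) -> np.ndarray:
    """Blur with a normalized Gaussian PSF, reflective boundary handling.

    The 2D kernel is separable (outer product of unit-sum 1D kernels, hence
    itself unit-sum), truncated at radius ``ceil(4 sigma)``; the output has
    the input's shape.
    """
    from scipy.ndimage import correlate1d

    k = gaussian_kernel(sigma)
    out = correlate1d(np.asarray(img, dtype=np.float64), k, axis=0, mode="reflect")
    out = correlate1d(out, k, axis=1, mode="reflect")
    return out


def add_gaussian_noise(g: np.ndarray, sigma_n: float, seed=None, eta: np.ndarray | None = None) -> np.ndarray:
    """Add read noise at relative Frobenius level ``sigma_n``.

    Returns ``g + sigma_n * (eta / ||eta||_F) * ||g||_F`` with ``eta`` a
    standard-normal array, so ``||g_n - g||_F = sigma_n * ||g||_F`` exactly.
    The output is not clipped.  A pre-drawn ``eta`` may be supplied to share
    the noise realization between paired frames.
    """
    if sigma_n < 0:
        raise ValueError("sigma_n must be >= 0")
    g = np.asarray(g, dtype=np.float64)
    if sigma_n == 0:
        return g.copy()
    norm_g = np.linalg.norm(g)
    if norm_g == 0:
        warnings.warn("add_gaussian_noise: zero-norm input, returned unchanged", stacklevel=2)
        return g.copy()
    if eta is None:
        eta = _as_rng(seed).standard_normal(g.shape)
    return g + sigma_n * (eta / np.linalg.norm(eta)) * norm_g


def add_poisson_noise(g: np.ndarray, gamma: float, seed=None) -> np.ndarray:
    """Photon noise: ``Poisson(gamma * g) / gamma`` per pixel.

    ``gamma`` is the photon count per intensity unit; ``inf`` disables the
    step.  Negative inputs (possible after read noise) are clamped to zero.
    """
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    g = np.asarray(g, dtype=np.float64)
    if math.isinf(gamma):
        return g.copy()
    if (g < 0).any():
        logger.debug("add_poisson_noise: clamping %d negative pixels to 0", int((g < 0).sum()))
        g = np.clip(g, 0.0, None)
    rng = _as_rng(seed)
    return rng.poisson(gamma * g).astype(np.float64) / gamma


# ---------------------------------------------------------------------------
# Frame rendering and dataset generation
# ---------------------------------------------------------------------------

def render_pair(
    field: ParticleField,
    vol: VolumeSpec,
    z_index: int,
    bg: BackgroundParams,
    noise: NoiseParams,
    bead_value: float = BEAD_VALUE,
) -> FramePair:
    """Render one (input, target) frame pair from a bead scene.

    input  = noise( blur( raster + beta * normalize01(perlin) ) )
    target = the identical pipeline with beta = 0, reusing the same
             statistical-noise seeds, so the pair differs only through the
             background contribution.
    """
    raster, truth = rasterize_slice(field, vol, z_index, bead_value)
    beta = bg.amplitude
    if beta > 0:
        bg_field = beta * _normalize01(perlin_field((vol.n, vol.n), bg))
        pre_input = raster + bg_field
    else:
        pre_input = raster

    blurred_input = apply_psf(pre_input, noise.psf_sigma)
    blurred_target = apply_psf(raster, noise.psf_sigma)

    ss = np.random.SeedSequence(noise.seed)
    gauss_seed, poisson_seed = ss.spawn(2)
    eta = np.random.default_rng(gauss_seed).standard_normal(blurred_input.shape)

    def _apply_noise(g: np.ndarray) -> np.ndarray:
        if noise.noise_order == "gaussian_then_poisson":
            g = add_gaussian_noise(g, noise.gaussian_level, eta=eta)
            g = add_poisson_noise(g, noise.poisson_gamma, seed=np.random.default_rng(poisson_seed))
        else:
            g = add_poisson_noise(g, noise.poisson_gamma, seed=np.random.default_rng(poisson_seed))
            g = add_gaussian_noise(g, noise.gaussian_level, eta=eta)
            g = np.clip(g, 0.0, None)
        return g

    input_frame = _apply_noise(blurred_input)
    target_frame = _apply_noise(blurred_target)
    return FramePair(
        input_frame=input_frame,
        target_frame=target_frame,
        truth=truth,
        slice_index=z_index,
        seeds={"noise": noise.seed, "background": bg.seed},
    )


def render_scene(spec: DatasetSpec, scene_seed: int) -> FramePair:
    """Render one frame pair of a dataset from a single integer seed."""
    ss = np.random.SeedSequence(scene_seed)
    s_place, s_slice, s_bg, s_noise = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    field = place_particles(spec.volume, spec.count_range, spec.radius, seed=s_place)
    z_index = int(np.random.default_rng(s_slice).integers(0, spec.volume.nz))
    bg = replace(spec.background, seed=s_bg)
    noise = replace(spec.noise, seed=s_noise)
    return render_pair(field, spec.volume, z_index, bg, noise, spec.bead_value)


def generate_dataset(spec: DatasetSpec) -> Dataset:
    """Generate ``spec.n_images`` frame pairs and split them.

    Each pair comes from an independent seeded scene with a uniformly random
    slice index.  Split sizes are ``floor(fraction * n)`` for validation and
    test with the remainder going to train; membership is a seeded
    permutation.  The whole dataset is a pure function of the spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    scene_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(spec.n_images + 1)]
    perm_seed = scene_seeds.pop()
    pairs = [render_scene(spec, s) for s in scene_seeds]

    n = spec.n_images
    n_val = int(math.floor(spec.split[1] * n))
    n_test = int(math.floor(spec.split[2] * n))
    n_train = n - n_val - n_test
    perm = np.random.default_rng(perm_seed).permutation(n)
    train = [pairs[i] for i in perm[:n_train]]
    val = [pairs[i] for i in perm[n_train:n_train + n_val]]
    test = [pairs[i] for i in perm[n_train + n_val:]]
    logger.info("generated dataset: %d train / %d val / %d test", len(train), len(val), len(test))
    return Dataset(train=train, val=val, test=test, spec=spec)
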