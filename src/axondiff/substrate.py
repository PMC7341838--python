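"""Synthetic axon substrates with caliber variation, undulation and mitochondria.

Axons are modeled as axially symmetric tubes whose radius ``r(z)`` varies
along the nominal fiber axis ``z``.  Caliber maxima ("beads" or
varicosities) are placed as a renewal process with gamma-distributed
spacings (mean ``a_mean``, SD ``a_sd``) and superimposed on a baseline
radius as smooth unimodal bumps of characteristic width ``l_mean``.  The
tube may additionally undulate transversely along a smoothed random
skeleton.  Substrates are discretized onto an isotropic voxel grid with
integer labels (0 = exterior, 1 = axoplasm, 2 = mitochondrion) that the
random-walk engine consumes.

Units are fixed package-wide: lengths in um, times in ms, diffusivities in
um^2/ms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

__all__ = [
    "SubstrateError",
    "SubstrateTooShortError",
    "ResolutionError",
    "InvalidSpecError",
    "BeadSpec",
    "RadiusProfile",
    "Skeleton",
    "LabeledVolume",
    "CompartmentProps",
    "OrientationSet",
    "generate_restriction_positions",
    "generate_radius_profile",
    "beaded_profile",
    "normalize_volumes",
    "voxelize",
    "make_undulating_skeleton",
    "make_scenario",
    "place_mitochondria",
    "sample_watson",
    "kappa_to_theta",
    "watson_mean_cos2",
    "effective_restriction_width",
]

UNIFORM_THETA_DEG = math.degrees(math.acos(math.sqrt(1.0 / 3.0)))  # 54.7356...


class SubstrateError(ValueError):
    """Base class for substrate-generation failures."""


class SubstrateTooShortError(SubstrateError):
    """Requested substrate length cannot hold even one mean spacing."""


class ResolutionError(SubstrateError):
    """Grid spacing too coarse for the requested geometry."""


class InvalidSpecError(SubstrateError):
    """Bead / compartment specification violates its invariants."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BeadSpec:
    """Statistics of caliber restrictions along one axon.

    Parameters
    ----------
    a_mean : float
        Mean spacing between restrictions (um).
    a_sd : float
        Standard deviation of the spacing (um).  ``0`` gives a perfectly
        periodic arrangement.
    l_mean : float
        Characteristic (FWHM) width of one restriction bump (um).
    amplitude : float
        Fractional radius modulation at the center of an isolated bead.
    r0 : float
        Baseline radius (um).

    The default spacing statistics are those measured on segmented
    myelinated axons of mouse corpus callosum; the default amplitude is
    calibrated (once, through the caliber statistics alone) so the
    generated ensemble reproduces the normalized low-k spectral plateau
    ~0.25 and CV(r) ~ 0.27 characteristic of those axons.
    """

    a_mean: float = 5.70
    a_sd: float = 2.88
    l_mean: float = 5.6
    amplitude: float = 1.2
    r0: float = 0.5

    def __post_init__(self) -> None:
        if self.a_mean <= 0 or self.l_mean <= 0 or self.r0 <= 0:
            raise InvalidSpecError("a_mean, l_mean and r0 must be positive")
        if self.a_sd < 0:
            raise InvalidSpecError("a_sd must be non-negative")
        if self.amplitude < 0:
            raise InvalidSpecError("amplitude must be non-negative")


@dataclass
class RadiusProfile:
    """Discretized caliber function r(z) of one axon on a uniform grid."""

    dz: float
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.dz <= 0:
            raise SubstrateError("dz must be positive")
        if self.r.ndim != 1 or self.r.size == 0:
            raise SubstrateError("radius profile must be a non-empty 1d array")
        if not np.all(np.isfinite(self.r)) or np.any(self.r <= 0):
            raise SubstrateError("all radii must be positive and finite")

    @property
    def z(self) -> np.ndarray:
        return np.arange(self.r.size) * self.dz

    @property
    def length(self) -> float:
        return self.dz * self.r.size

    @property
    def area(self) -> np.ndarray:
        """Cross-sectional area A(z) = pi r^2(z) (um^2)."""
        return math.pi * self.r**2

    @property
    def volume(self) -> float:
        return float(np.sum(self.area) * self.dz)


@dataclass
class Skeleton:
    """Transverse centerline offsets (x(z), y(z)) on the profile grid."""

    dz: float
    x: np.ndarray
    y: np.ndarray
    sigma_s: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise SubstrateError("skeleton offsets must be matching 1d arrays")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise SubstrateError("skeleton offsets must be finite")
        if self.sigma_s < 0:
            raise SubstrateError("sigma_s must be non-negative")

    @property
    def z(self) -> np.ndarray:
        return np.arange(self.x.size) * self.dz

    def arc_length(self) -> float:
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        return float(np.sum(np.sqrt(dx**2 + dy**2 + self.dz**2)) + self.dz)


@dataclass
class LabeledVolume:
    """3d voxel substrate: 0 = exterior, 1 = axoplasm, 2 = mitochondrion.

    ``labels`` is indexed ``[ix, iy, iz]``; voxel centers sit at
    ``(i + 1/2) h`` (half-open convention, 0-based indices).
    """

    labels: np.ndarray
    h: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise SubstrateError("labels must be a 3d array")
        if self.h <= 0:
            raise SubstrateError("voxel size h must be positive")
        if not np.isin(self.labels, (0, 1, 2)).all():
            raise SubstrateError("labels must be in {0, 1, 2}")
        if not (self.labels == 1).any():
            raise SubstrateError("volume contains no axoplasm voxels")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def box(self) -> tuple[float, float, float]:
        return tuple(n * self.h for n in self.labels.shape)

    def interior_volume(self) -> float:
        """Volume of the union of axoplasm and mitochondria (um^3)."""
        return float(np.count_nonzero(self.labels) * self.h**3)

    def mito_fraction(self) -> float:
        n_in = np.count_nonzero(self.labels)
        return float(np.count_nonzero(self.labels == 2) / n_in)


@dataclass(frozen=True)
class CompartmentProps:
    """Intrinsic diffusivities and T2 of axoplasm / mitochondria."""

    D_a: float = 2.0
    D_m: float = 0.13
    T2_a: float = 80.0
    T2_m: float = 20.0
    f_m: float = 0.06

    def __post_init__(self) -> None:
        if self.D_a < 0 or self.D_m < 0:
            raise InvalidSpecError("diffusivities must be non-negative")
        if self.T2_a <= 0 or self.T2_m <= 0:
            raise InvalidSpecError("T2 values must be positive")
        if not 0 <= self.f_m < 1:
            raise InvalidSpecError("f_m must be in [0, 1)")


@dataclass
class OrientationSet:
    """Unit fiber directions drawn from an axially symmetric Watson density."""

    vectors: np.ndarray
    kappa: float
    theta_deg: float

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise SubstrateError("orientation vectors must be unit norm")


# ---------------------------------------------------------------------------
# restriction placement and radius profiles


def generate_restriction_positions(
    L: float, spec: BeadSpec, seed: int | None = None
) -> np.ndarray:
    """Place restriction centers on [0, L) as a gamma renewal process.

    Successive spacings are i.i.d. gamma with mean ``spec.a_mean`` and SD
    ``spec.a_sd`` (degenerate, i.e. exactly periodic, when ``a_sd == 0``).
    The first center carries a uniform random phase in ``[0, a_mean)`` so
    the process is statistically stationary.
    """
    if L <= spec.a_mean:
        raise SubstrateTooShortError(
            f"substrate length {L} um must exceed the mean spacing {spec.a_mean} um"
        )
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, spec.a_mean)
    # over-draw spacings, then truncate to [0, L)
    n_guess = int(3 * L / spec.a_mean) + 20
    if spec.a_sd == 0:
        spacings = np.full(n_guess, spec.a_mean)
    else:
        shape = (spec.a_mean / spec.a_sd) ** 2
        scale = spec.a_sd**2 / spec.a_mean
        spacings = rng.gamma(shape, scale, size=n_guess)
    positions = phase + np.concatenate(([0.0], np.cumsum(spacings)))
    while positions[-1] < L:  # pragma: no cover - extremely unlikely
        extra = rng.gamma(shape, scale, size=n_guess) if spec.a_sd else spacings
        positions = np.concatenate([positions, positions[-1] + np.cumsum(extra)])
    return positions[positions < L]


def _bump(u: np.ndarray) -> np.ndarray:
    """Unit-height cosine lobe with FWHM 1, truncated at |u| = 1."""
    out = np.zeros_like(u)
    m = np.abs(u) < 1.0
    out[m] = 0.5 * (1.0 + np.cos(math.pi * u[m]))
    return out


#: integrals of the bump and its square over the support (in units of l_mean)
BUMP_INTEGRAL = 1.0  # int 0.5 (1 + cos pi u) du over [-1, 1]
BUMP_SQ_INTEGRAL = 0.75  # int [0.5 (1 + cos pi u)]^2 du over [-1, 1]


def generate_radius_profile(
    positions: np.ndarray, L: float, spec: BeadSpec, dz: float = 0.1
) -> RadiusProfile:
    """Build r(z) = r0 (1 + amplitude * sum_k g((z - z_k)/l_mean)).

    ``g`` is a unit-height cosine lobe of FWHM ``l_mean`` truncated at
    ``+- l_mean``; overlapping beads superpose linearly in radius.
    """
    if dz > spec.l_mean / 5:
        raise ResolutionError(
            f"dz = {dz} um too coarse; need dz <= l_mean/5 = {spec.l_mean / 5:.3g} um"
        )
    n = int(round(L / dz))
    z = np.arange(n) * dz
    bump_sum = np.zeros(n)
    half = spec.l_mean
    for zk in np.asarray(positions, dtype=float):
        lo = max(0, int(math.ceil((zk - half) / dz)))
        hi = min(n, int(math.floor((zk + half) / dz)) + 1)
        if hi > lo:
            bump_sum[lo:hi] += _bump((z[lo:hi] - zk) / spec.l_mean)
    r = spec.r0 * (1.0 + spec.amplitude * bump_sum)
    return RadiusProfile(dz=dz, r=r)


def beaded_profile(
    L: float, spec: BeadSpec, dz: float = 0.1, seed: int | None = None
) -> RadiusProfile:
    """Convenience: restriction placement followed by profile construction."""
    positions = generate_restriction_positions(L, spec, seed)
    return generate_radius_profile(positions, L, spec, dz)


def effective_restriction_width(spec: BeadSpec, mean_area: float | None = None) -> float:
    """Effective restriction width l_eff = v0 / A_mean entering the
    low-k plateau prediction for generated substrates.

    ``v0`` is the excess cross-sectional volume of one bead,
    ``pi r0^2 l_mean (2 a I1 + a^2 I2)`` for bump amplitude ``a``; dividing
    by the mean CSA turns the bead "strength" into a length, the same
    convention by which a restriction shape function reduces to a width at
    k -> 0.  When ``mean_area`` is omitted, the stationary mean CSA of the
    renewal bead process is used.
    """
    a = spec.amplitude
    v0 = math.pi * spec.r0**2 * spec.l_mean * (2 * a * BUMP_INTEGRAL + a**2 * BUMP_SQ_INTEGRAL)
    if mean_area is None:
        # stationary mean of (1 + a G)^2 with G the bump superposition:
        # <G> = l I1 / abar; <G^2> = <G>^2 + Var(G), Var(G) ~ (l/abar) I2
        # for renewal placement (uncorrelated bead positions at high order).
        g1 = spec.l_mean * BUMP_INTEGRAL / spec.a_mean
        g2 = g1**2 + spec.l_mean * BUMP_SQ_INTEGRAL / spec.a_mean
        mean_area = math.pi * spec.r0**2 * (1 + 2 * a * g1 + a**2 * g2)
    return v0 / mean_area


def normalize_volumes(profiles: list[RadiusProfile]) -> list[RadiusProfile]:
    """Rescale every axon's radii by sqrt(Vbar / V_i) so all volumes equal
    the input mean volume; total volume is conserved."""
    if not profiles:
        raise SubstrateError("normalize_volumes needs at least one profile")
    volumes = np.array([p.volume for p in profiles])
    v_mean = volumes.mean()
    return [
        replace(p, r=p.r * math.sqrt(v_mean / v)) for p, v in zip(profiles, volumes)
    ]


# ---------------------------------------------------------------------------
# voxelization


def _interp_to_centers(values: np.ndarray, dz: float, z_centers: np.ndarray) -> np.ndarray:
    z_nodes = np.arange(values.size) * dz
    return np.interp(z_centers, z_nodes, values)


def voxelize(
    profile: RadiusProfile,
    skeleton: Skeleton | None = None,
    h: float = 0.1,
    margin: int = 2,
) -> LabeledVolume:
    """Discretize a tube of radius r(z) around a (possibly undulating)
    centerline onto an isotropic grid.

    A voxel is axoplasm iff its center lies within r(z) of the centerline
    in the plane perpendicular to z.
    """
    rmin = float(profile.r.min())
    if h > rmin / 3:
        raise ResolutionError(
            f"h = {h} um too coarse; need h <= min(r)/3 = {rmin / 3:.3g} um"
        )
    nz = int(round(profile.length / h))
    zc = (np.arange(nz) + 0.5) * h
    r = _interp_to_centers(profile.r, profile.dz, zc)
    if skeleton is not None:
        x0 = _interp_to_centers(skeleton.x, skeleton.dz, zc)
        y0 = _interp_to_centers(skeleton.y, skeleton.dz, zc)
    else:
        x0 = np.zeros(nz)
        y0 = np.zeros(nz)

    rmax = r.max()
    x_lo, x_hi = (x0 - rmax).min(), (x0 + rmax).max()
    y_lo, y_hi = (y0 - rmax).min(), (y0 + rmax).max()
    nx = int(math.ceil((x_hi - x_lo) / h)) + 2 * margin + 1
    ny = int(math.ceil((y_hi - y_lo) / h)) + 2 * margin + 1
    xc = (np.arange(nx) + 0.5) * h + (x_lo - margin * h)
    yc = (np.arange(ny) + 0.5) * h + (y_lo - margin * h)

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    dx2 = (xc[:, None] - x0[None, :]) ** 2  # (nx, nz)
    for j in range(ny):
        d2 = dx2 + (yc[j] - y0[None, :]) ** 2
        labels[:, j, :] = d2 <= r[None, :] ** 2
    return LabeledVolume(labels=labels, h=h)


def make_undulating_skeleton(
    L: float,
    dz: float,
    amplitude: float,
    sigma_s: float = 1.0,
    seed: int | None = None,
) -> Skeleton:
    """Random transverse skeleton: white Gaussian offsets smoothed by a
    Gaussian filter of SD ``sigma_s`` (um), rescaled so the RMS transverse
    displacement sqrt(<x^2 + y^2>) equals ``amplitude`` (um)."""
    n = int(round(L / dz))
    rng = np.random.default_rng(seed)
    x = gaussian_filter1d(rng.standard_normal(n), sigma_s / dz, mode="wrap")
    y = gaussian_filter1d(rng.standard_normal(n), sigma_s / dz, mode="wrap")
    if amplitude > 0:
        rms = math.sqrt(float(np.mean(x**2 + y**2)))
        x *= amplitude / rms
        y *= amplitude / rms
    else:
        x[:] = 0.0
        y[:] = 0.0
    return Skeleton(dz=dz, x=x, y=y, sigma_s=sigma_s)


def _smooth_skeleton(skeleton: Skeleton) -> Skeleton:
    if skeleton.sigma_s == 0:
        return skeleton
    s = skeleton.sigma_s / skeleton.dz
    return Skeleton(
        dz=skeleton.dz,
        x=gaussian_filter1d(skeleton.x, s, mode="nearest"),
        y=gaussian_filter1d(skeleton.y, s, mode="nearest"),
        sigma_s=skeleton.sigma_s,
    )


def _voxelize_tube_along_curve(
    skeleton: Skeleton, L: float, radius: float, h: float, margin: int = 2
) -> tuple[np.ndarray, float]:
    """Label voxels within ``radius`` of the 3d skeleton curve (circular
    cross-sections perpendicular to the skeleton).  The curve is extended
    past both ends by its mirror image, consistent with the mirrored
    z-boundary of the simulation, to avoid spherical end caps."""
    ds = h / 2
    n_s = int(round(L / ds)) + 1
    zs = np.linspace(0.0, L, n_s)
    xs = _interp_to_centers(skeleton.x, skeleton.dz, zs)
    ys = _interp_to_centers(skeleton.y, skeleton.dz, zs)
    # mirror extension by ~radius beyond each end
    n_ext = int(math.ceil(radius / ds)) + 2
    n_ext = min(n_ext, n_s - 1)
    zs_full = np.concatenate([-zs[1 : n_ext + 1][::-1], zs, 2 * L - zs[-n_ext - 1 : -1][::-1]])
    xs_full = np.concatenate([xs[1 : n_ext + 1][::-1], xs, xs[-n_ext - 1 : -1][::-1]])
    ys_full = np.concatenate([ys[1 : n_ext + 1][::-1], ys, ys[-n_ext - 1 : -1][::-1]])
    tree = cKDTree(np.column_stack([xs_full, ys_full, zs_full]))

    nz = int(round(L / h))
    x_lo, x_hi = xs.min() - radius, xs.max() + radius
    y_lo, y_hi = ys.min() - radius, ys.max() + radius
    nx = int(math.ceil((x_hi - x_lo) / h)) + 2 * margin + 1
    ny = int(math.ceil((y_hi - y_lo) / h)) + 2 * margin + 1
    xc = (np.arange(nx) + 0.5) * h + (x_lo - margin * h)
    yc = (np.arange(ny) + 0.5) * h + (y_lo - margin * h)
    zc = (np.arange(nz) + 0.5) * h
    pts = np.stack(np.meshgrid(xc, yc, zc, indexing="ij"), axis=-1).reshape(-1, 3)
    dist, _ = tree.query(pts, workers=-1)
    labels = (dist.reshape(nx, ny, nz) <= radius).astype(np.uint8)
    arc = float(np.sum(np.sqrt(np.diff(xs) ** 2 + np.diff(ys) ** 2 + np.diff(zs) ** 2)))
    return labels, arc


def make_scenario(
    scenario: str,
    profile: RadiusProfile,
    skeleton: Skeleton | None = None,
    props: CompartmentProps | None = None,
    h: float = 0.1,
    seed: int | None = None,
) -> LabeledVolume:
    """Build one of the comparison microgeometries.

    - ``"I"``   caliber variation + undulation + mitochondria (T2/D contrast
      is carried by :class:`CompartmentProps` at simulation time);
    - ``"II"``  same geometry as I without mitochondria;
    - ``"III"`` axially symmetric tube with the same A(z), straight axis;
    - ``"IV"``  constant-CSA tube following the smoothed skeleton,
      volume-preserving;
    - ``"straight"`` constant-radius straight cylinder of equal volume.
    """
    scenario = str(scenario)
    if scenario in ("I", "II"):
        vol = voxelize(profile, skeleton, h=h)
        if scenario == "I":
            if props is None:
                props = CompartmentProps()
            vol = place_mitochondria(vol, profile, props, seed=seed)
        return vol
    if scenario == "III":
        return voxelize(profile, None, h=h)
    if scenario == "IV":
        if skeleton is None:
            raise SubstrateError("scenario IV requires a skeleton")
        sk = _smooth_skeleton(skeleton)
        L = profile.length
        v_target = profile.volume
        # initial volume-equivalent radius from the skeleton arc length,
        # then fixed-point correction of the voxelized volume
        labels, arc = _voxelize_tube_along_curve(sk, L, math.sqrt(v_target / (math.pi * L)), h)
        radius = math.sqrt(v_target / (math.pi * arc))
        for _ in range(4):
            labels, _ = _voxelize_tube_along_curve(sk, L, radius, h)
            v_vox = np.count_nonzero(labels) * h**3
            err = v_vox / v_target - 1.0
            if abs(err) < 5e-4:
                break
            radius *= math.sqrt(v_target / v_vox)
        return LabeledVolume(labels=labels, h=h)
    if scenario == "straight":
        r_eq = math.sqrt(profile.volume / (math.pi * profile.length))
        flat = RadiusProfile(dz=profile.dz, r=np.full(profile.r.size, r_eq))
        return voxelize(flat, None, h=h)
    raise SubstrateError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# mitochondria


def place_mitochondria(
    vol: LabeledVolume,
    profile: RadiusProfile,
    props: CompartmentProps,
    seed: int | None = None,
    rod_radius: float | None = None,
    rod_length: tuple[float, float] = (1.0, 2.0),
) -> LabeledVolume:
    """Insert rod-shaped mitochondria into the axoplasm.

    Rods are cylinders along z of radius ``0.25 <r>`` by default, with
    lengths uniform in ``rod_length``.  Axial placement is rejection-sampled
    with acceptance proportional to the local cross-sectional area, so
    mitochondria preferentially occupy caliber maxima (larger local A(z)),
    mirroring the observed caliber-mitochondria coupling.  Placement stops
    once the achieved mitochondrial volume fraction reaches ``props.f_m``.
    """
    if props.f_m >= 0.5:
        raise InvalidSpecError("f_m must be < 0.5")
    labels = vol.labels.copy()
    if props.f_m == 0:
        return LabeledVolume(labels=labels, h=vol.h)
    h = vol.h
    rng = np.random.default_rng(seed)
    n_interior = np.count_nonzero(labels)
    target_vox = props.f_m * n_interior
    r_m = rod_radius if rod_radius is not None else 0.25 * float(np.mean(profile.r))

    nz = labels.shape[2]
    zc = (np.arange(nz) + 0.5) * h
    r_z = _interp_to_centers(profile.r, profile.dz, zc)
    area = r_z**2
    area_max = area.max()

    counts = np.count_nonzero(labels == 1, axis=(0, 1))
    # slice centroids of the axoplasm define the local axis
    ix_grid = (np.arange(labels.shape[0]) + 0.5) * h
    iy_grid = (np.arange(labels.shape[1]) + 0.5) * h
    ax_mask = labels == 1
    with np.errstate(invalid="ignore"):
        cx = np.where(counts > 0, ax_mask.sum(axis=1).T @ ix_grid / np.maximum(counts, 1), 0.0)
        cy = np.where(counts > 0, ax_mask.sum(axis=0).T @ iy_grid / np.maximum(counts, 1), 0.0)

    X = ix_grid[:, None]
    Y = iy_grid[None, :]
    n_mito = 0
    for _ in range(100000):
        if n_mito >= target_vox:
            break
        iz = rng.integers(0, nz)
        if counts[iz] == 0 or rng.uniform() > area[iz] / area_max:
            continue
        length = rng.uniform(*rod_length)
        rho = rng.uniform(0.0, max(r_z[iz] - r_m, 0.0) / 2)
        phi = rng.uniform(0.0, 2 * math.pi)
        x_c = cx[iz] + rho * math.cos(phi)
        y_c = cy[iz] + rho * math.sin(phi)
        z_lo = max(0, int((zc[iz] - length / 2) / h))
        z_hi = min(nz, int((zc[iz] + length / 2) / h) + 1)
        disk = (X - x_c) ** 2 + (Y - y_c) ** 2 <= r_m**2
        block = labels[:, :, z_lo:z_hi]
        conv = disk[:, :, None] & (block == 1)
        block[conv] = 2
        n_mito += int(conv.sum())
    return LabeledVolume(labels=labels, h=h)


# ---------------------------------------------------------------------------
# orientation dispersion


def watson_mean_cos2(kappa: float) -> float:
    """<cos^2 psi> of the axially symmetric Watson density ~ exp(kappa cos^2 psi),
    by deterministic quadrature."""
    if kappa < 0:
        raise InvalidSpecError("kappa must be non-negative")
    if math.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 1.0 / 3.0
    num = quad(lambda u: u**2 * math.exp(kappa * (u**2 - 1)), 0, 1, epsabs=1e-12)[0]
    den = quad(lambda u: math.exp(kappa * (u**2 - 1)), 0, 1, epsabs=1e-12)[0]
    return num / den


def kappa_to_theta(kappa: float) -> float:
    """Overall polar dispersion angle theta = acos(sqrt(<cos^2 psi>)) in degrees."""
    return math.degrees(math.acos(math.sqrt(watson_mean_cos2(kappa))))


def sample_watson(kappa: float, n: int, seed: int | None = None) -> OrientationSet:
    """Draw ``n`` unit vectors from the Watson density ~ exp(kappa cos^2 psi)
    about the z-axis, by rejection sampling of cos(psi)."""
    if n <= 0:
        raise InvalidSpecError("n must be positive")
    if kappa < 0:
        raise InvalidSpecError("kappa must be non-negative")
    rng = np.random.default_rng(seed)
    if math.isinf(kappa):
        vecs = np.tile([0.0, 0.0, 1.0], (n, 1))
        return OrientationSet(vectors=vecs, kappa=kappa, theta_deg=0.0)
    cos_psi = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        u = rng.uniform(-1.0, 1.0, size=m)
        accept = rng.uniform(size=m) < np.exp(kappa * (u**2 - 1.0))
        got = u[accept][: n - filled]
        cos_psi[filled : filled + got.size] = got
        filled += got.size
    phi = rng.uniform(0.0, 2 * math.pi, size=n)
    sin_psi = np.sqrt(1.0 - cos_psi**2)
    vecs = np.column_stack([sin_psi * np.cos(phi), sin_psi * np.sin(phi), cos_psi])
    return OrientationSet(vectors=vecs, kappa=kappa, theta_deg=kappa_to_theta(kappa))
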