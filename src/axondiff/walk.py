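"""Continuous-space Monte-Carlo random walk in labeled substrates.

Walkers take fixed-length steps sqrt(6 D dt) in isotropic random directions
within the compartment they occupy.  A step landing in the exterior is
rejected (elastic encounter with the membrane); a step crossing the
axoplasm-mitochondrion interface is accepted with the transit probability
for highly permeable membranes,

    P(1 -> 2) = min(1, sqrt(D2 / D1)),

which preserves volume-proportional equilibrium occupancy.  All three box
faces are handled by unfolding into mirrored copies: the compartment label
is looked up at the folded coordinate while the true (unfolded)
displacement keeps accumulating, so the finite substrate behaves as an
infinite periodic-mirror medium along z (and free space when the whole box
is axoplasm).

Displacement statistics are accumulated as weighted second- and
fourth-moment tensors at the requested sample times; the optional T2
weighting multiplies each walker by exp(-sum_steps dt / T2(label)).

Randomness is a SplitMix64 counter-based stream keyed by (seed, walker
index), so results do not depend on execution order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .substrate import CompartmentProps, LabeledVolume

__all__ = [
    "SimConfig",
    "MomentRecord",
    "M2_LABELS",
    "M4_EXPONENTS",
    "M4_MULTIPLICITY",
    "step_length",
    "permeation_probability",
    "free_substrate",
    "init_walkers",
    "run_walk",
    "log_spaced_times",
]

#: order of the six unique second-moment components
M2_LABELS = ("xx", "yy", "zz", "xy", "xz", "yz")
#: contraction multiplicities of the off-diagonal second moments
M2_MULTIPLICITY = np.array([1, 1, 1, 2, 2, 2], dtype=float)

#: exponents (i, j, k) of the 15 unique fourth-moment monomials x^i y^j z^k
M4_EXPONENTS = np.array(
    [
        (4, 0, 0), (0, 4, 0), (0, 0, 4),
        (3, 1, 0), (3, 0, 1), (1, 3, 0), (0, 3, 1), (1, 0, 3), (0, 1, 3),
        (2, 2, 0), (2, 0, 2), (0, 2, 2),
        (2, 1, 1), (1, 2, 1), (1, 1, 2),
    ],
    dtype=np.int64,
)
#: multinomial multiplicities 4!/(i! j! k!)
M4_MULTIPLICITY = np.array(
    [math.factorial(4) // (math.factorial(i) * math.factorial(j) * math.factorial(k))
     for i, j, k in M4_EXPONENTS],
    dtype=float,
)


def step_length(D: float, dt: float) -> float:
    """Step length sqrt(6 D dt) in um (D in um^2/ms, dt in ms)."""
    if D < 0:
        raise ValueError("diffusivity must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return math.sqrt(6.0 * D * dt)


def permeation_probability(D_from: float, D_to: float) -> float:
    """One-step transit probability min(1, sqrt(D_to / D_from))."""
    if D_from <= 0:
        raise ValueError("D_from must be positive")
    return min(1.0, math.sqrt(D_to / D_from))


def log_spaced_times(t_min: float = 1.0, t_max: float = 100.0, n: int = 20) -> np.ndarray:
    """Default diffusion-time sampling: n log-spaced points (ms)."""
    return np.geomspace(t_min, t_max, n)


@dataclass
class SimConfig:
    """Monte-Carlo run parameters.

    ``dt`` is the step duration (ms); the per-compartment step length
    sqrt(6 D dt) must not exceed the voxel size h (h/2 recommended).
    ``sample_times`` are snapped to the nearest step.
    """

    dt: float
    n_walkers: int
    sample_times: np.ndarray = field(default_factory=log_spaced_times)
    seed: int = 0
    t2_weighting: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_walkers < 0:
            raise ValueError("n_walkers must be non-negative")
        self.sample_times = np.atleast_1d(np.asarray(self.sample_times, dtype=float))

    def sample_steps(self) -> np.ndarray:
        steps = np.unique(np.maximum(1, np.round(self.sample_times / self.dt).astype(np.int64)))
        return steps


@dataclass
class MomentRecord:
    """Weighted displacement-moment tensors at each sampled diffusion time.

    ``m2`` and ``m4`` hold weighted *sums* of the unique monomials (order
    given by :data:`M2_LABELS` / :data:`M4_EXPONENTS`); divide by ``W`` for
    the weighted means.
    """

    t: np.ndarray
    W: np.ndarray
    m2: np.ndarray  # (n_t, 6)
    m4: np.ndarray  # (n_t, 15)
    n_walkers: int
    final_positions: np.ndarray | None = None  # folded, (n_walkers, 3)
    final_labels: np.ndarray | None = None

    def mean_m2(self) -> np.ndarray:
        return self.m2 / self.W[:, None]

    def mean_m4(self) -> np.ndarray:
        return self.m4 / self.W[:, None]


def free_substrate(box: float = 20.0, h: float = 5.0) -> LabeledVolume:
    """All-axoplasm volume: with mirrored boundaries this is exact free space."""
    n = max(2, int(round(box / h)))
    return LabeledVolume(labels=np.ones((n, n, n), dtype=np.uint8), h=h)


def init_walkers(vol: LabeledVolume, n: int, seed: int | None = None) -> np.ndarray:
    """Uniform initial positions over the union of labels {1, 2}, by
    rejection sampling of the bounding box."""
    if not (vol.labels > 0).any():
        raise ValueError("volume has no interior to seed walkers in")
    if n == 0:
        return np.empty((0, 3))
    rng = np.random.default_rng(seed)
    box = np.array(vol.box)
    out = np.empty((n, 3))
    filled = 0
    frac = max(np.count_nonzero(vol.labels) / vol.labels.size, 1e-6)
    while filled < n:
        m = int((n - filled) / frac * 1.2) + 16
        pts = rng.uniform(0.0, 1.0, size=(m, 3)) * box
        idx = np.minimum((pts / vol.h).astype(np.int64), np.array(vol.labels.shape) - 1)
        ok = vol.labels[idx[:, 0], idx[:, 1], idx[:, 2]] > 0
        got = pts[ok][: n - filled]
        out[filled : filled + got.shape[0]] = got
        filled += got.shape[0]
    return out


# ---------------------------------------------------------------------------
# numba kernel

_U1 = np.uint64(0x9E3779B97F4A7C15)
_U2 = np.uint64(0xBF58476D1CE4E5B9)
_U3 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0
#: reflection-candidate order: single axes, then pairs, then all three
_REFLECT_ORDER = np.array([1, 2, 4, 3, 5, 6, 7], dtype=np.int64)


@njit(inline="always", cache=True)
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * _U2
    z = (z ^ (z >> np.uint64(27))) * _U3
    return z ^ (z >> np.uint64(31))


@njit(inline="always", cache=True)
def _fold(q, L):
    """Triangle-wave fold of q into [0, L]; returns (folded, parity)."""
    m = np.mod(q, 2.0 * L)
    if m >= L:
        return 2.0 * L - m, -1.0
    return m, 1.0


@njit(cache=True)
def _walk_kernel(labels, h, D_label, inv_T2, use_t2, dt, sample_steps, x0, seed):
    nx, ny, nz = labels.shape
    Lx = nx * h
    Ly = ny * h
    Lz = nz * h
    n_t = sample_steps.shape[0]
    n_steps = sample_steps[n_t - 1]
    n_w = x0.shape[0]

    W = np.zeros(n_t)
    M2 = np.zeros((n_t, 6))
    M4 = np.zeros((n_t, 15))

    slen = np.sqrt(6.0 * D_label * dt)
    P = np.ones((3, 3))
    for a in range(1, 3):
        for b in range(1, 3):
            if D_label[a] > 0.0:
                P[a, b] = min(1.0, np.sqrt(D_label[b] / D_label[a]))

    final_pos = np.empty((n_w, 3))
    final_lab = np.empty(n_w, dtype=np.uint8)

    two_pi = 2.0 * math.pi
    for w in range(n_w):
        state = _mix64(np.uint64(seed) * _U2 + np.uint64(w + 1) * _U1)
        px = x0[w, 0]
        py = x0[w, 1]
        pz = x0[w, 2]
        sx = px
        sy = py
        sz = pz
        ix = min(int(px / h), nx - 1)
        iy = min(int(py / h), ny - 1)
        iz = min(int(pz / h), nz - 1)
        lab = labels[ix, iy, iz]
        logw = 0.0
        si = 0
        for step in range(1, n_steps + 1):
            state = state + _U1
            u1 = (_mix64(state) >> np.uint64(11)) * _INV53
            state = state + _U1
            u2 = (_mix64(state) >> np.uint64(11)) * _INV53
            cz = 1.0 - 2.0 * u1
            st = math.sqrt(max(0.0, 1.0 - cz * cz))
            phi = two_pi * u2
            Ls = slen[lab]
            qx = px + Ls * st * math.cos(phi)
            qy = py + Ls * st * math.sin(phi)
            qz = pz + Ls * cz
            fx, gx = _fold(qx, Lx)
            fy, gy = _fold(qy, Ly)
            fz, gz = _fold(qz, Lz)
            ix = min(int(fx / h), nx - 1)
            iy = min(int(fy / h), ny - 1)
            iz = min(int(fz / h), nz - 1)
            nl = labels[ix, iy, iz]
            if nl == lab:
                px = qx
                py = qy
                pz = qz
            else:
                permit = False
                if nl != 0:
                    pr = P[lab, nl]
                    if pr >= 1.0:
                        permit = True
                    else:
                        state = state + _U1
                        u3 = (_mix64(state) >> np.uint64(11)) * _INV53
                        permit = u3 < pr
                if permit:
                    px = qx
                    py = qy
                    pz = qz
                    lab = nl
                else:
                    # elastic (specular) reflection off the voxel face(s)
                    # crossed; axis-aligned faces preserve the tangential
                    # displacement components exactly.
                    cfx, _ = _fold(px, Lx)
                    cfy, _ = _fold(py, Ly)
                    cfz, _ = _fold(pz, Lz)
                    jx = min(int(cfx / h), nx - 1)
                    jy = min(int(cfy / h), ny - 1)
                    jz = min(int(cfz / h), nz - 1)
                    rfx = fx
                    rfy = fy
                    rfz = fz
                    if ix != jx:
                        rfx = 2.0 * h * max(ix, jx) - fx
                    if iy != jy:
                        rfy = 2.0 * h * max(iy, jy) - fy
                    if iz != jz:
                        rfz = 2.0 * h * max(iz, jz) - fz
                    # try single-axis reflections first, then pairs, then all
                    done = False
                    for mi in range(7):
                        mask = _REFLECT_ORDER[mi]
                        tx = rfx if (mask & 1) and ix != jx else fx
                        ty = rfy if (mask & 2) and iy != jy else fy
                        tz = rfz if (mask & 4) and iz != jz else fz
                        if tx == fx and ty == fy and tz == fz:
                            continue
                        kx = min(max(int(tx / h), 0), nx - 1)
                        ky = min(max(int(ty / h), 0), ny - 1)
                        kz = min(max(int(tz / h), 0), nz - 1)
                        cl = labels[kx, ky, kz]
                        ok = False
                        if cl == lab:
                            ok = True
                        elif cl != 0:
                            # reflected into the other permeable compartment
                            pr2 = P[lab, cl]
                            if pr2 >= 1.0:
                                ok = True
                            else:
                                state = state + _U1
                                u4 = (_mix64(state) >> np.uint64(11)) * _INV53
                                ok = u4 < pr2
                        if ok:
                            # map the reflected local endpoint back to the
                            # unfolded frame via the fold parity
                            px = qx + gx * (tx - fx)
                            py = qy + gy * (ty - fy)
                            pz = qz + gz * (tz - fz)
                            lab = cl
                            done = True
                            break
                    # if no reflected image stays in the compartment the
                    # walker waits out the step (rare corner geometry)
                    if not done:
                        pass
            if use_t2:
                logw -= dt * inv_T2[lab]
            if si < n_t and step == sample_steps[si]:
                wt = math.exp(logw) if use_t2 else 1.0
                dx = px - sx
                dy = py - sy
                dz_ = pz - sz
                x2 = dx * dx
                y2 = dy * dy
                z2 = dz_ * dz_
                W[si] += wt
                M2[si, 0] += wt * x2
                M2[si, 1] += wt * y2
                M2[si, 2] += wt * z2
                M2[si, 3] += wt * dx * dy
                M2[si, 4] += wt * dx * dz_
                M2[si, 5] += wt * dy * dz_
                M4[si, 0] += wt * x2 * x2
                M4[si, 1] += wt * y2 * y2
                M4[si, 2] += wt * z2 * z2
                M4[si, 3] += wt * x2 * dx * dy
                M4[si, 4] += wt * x2 * dx * dz_
                M4[si, 5] += wt * dx * y2 * dy
                M4[si, 6] += wt * y2 * dy * dz_
                M4[si, 7] += wt * dx * z2 * dz_
                M4[si, 8] += wt * dy * z2 * dz_
                M4[si, 9] += wt * x2 * y2
                M4[si, 10] += wt * x2 * z2
                M4[si, 11] += wt * y2 * z2
                M4[si, 12] += wt * x2 * dy * dz_
                M4[si, 13] += wt * dx * y2 * dz_
                M4[si, 14] += wt * dx * dy * z2
                si += 1
        ffx, _ = _fold(px, Lx)
        ffy, _ = _fold(py, Ly)
        ffz, _ = _fold(pz, Lz)
        final_pos[w, 0] = ffx
        final_pos[w, 1] = ffy
        final_pos[w, 2] = ffz
        final_lab[w] = lab
    return W, M2, M4, final_pos, final_lab


def run_walk(
    vol: LabeledVolume, props: CompartmentProps, cfg: SimConfig
) -> MomentRecord:
    """Run the random walk and return weighted displacement moments.

    Raises ``ValueError`` if the step length in any occupied compartment
    exceeds the voxel size (the walker could then tunnel through a
    membrane voxel undetected).
    """
    D_label = np.array([0.0, props.D_a, props.D_m])
    present = np.unique(vol.labels)
    max_step = max(step_length(D_label[l], cfg.dt) for l in present if l > 0)
    if max_step > vol.h * (1 + 1e-12):
        raise ValueError(
            f"step length {max_step:.4g} um exceeds voxel size {vol.h} um; reduce dt"
        )
    inv_T2 = np.array([0.0, 1.0 / props.T2_a, 1.0 / props.T2_m])
    steps = cfg.sample_steps()
    x0 = init_walkers(vol, cfg.n_walkers, seed=(cfg.seed * 2654435761 + 7) % 2**31)
    W, M2, M4, fpos, flab = _walk_kernel(
        vol.labels,
        float(vol.h),
        D_label,
        inv_T2,
        cfg.t2_weighting,
        float(cfg.dt),
        steps,
        x0,
        np.uint64(cfg.seed % (2**63)),
    )
    return MomentRecord(
        t=steps * cfg.dt, W=W, m2=M2, m4=M4, n_walkers=cfg.n_walkers,
        final_positions=fpos, final_labels=flab,
    )
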