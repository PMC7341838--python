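"""Per-axon and ensemble diffusion cumulants D(t), K(t) and signal synthesis.

The apparent diffusivity and kurtosis along a direction n are tensor
contractions of the weighted displacement moments,

    D(t, n) = <s^2> / (2 t),      K(t, n) = <s^4> / <s^2>^2 - 3,

with s the displacement projected on n.  Ensemble quantities follow from
the O(b) and O(b^2) coefficients of the log of the multi-compartment
cumulant signal

    S(b, t) = sum_i f_i exp(-b D_i + (1/6) b^2 D_i^2 K_i),

giving D = <D_i> and K = (1/D^2) sum_i [3 f_i (D_i - D)^2 + f_i D_i^2 K_i]
(inter- plus intra-compartment parts).  Orientation dispersion of a bundle
is applied analytically: an axon oriented along n' contributes, measured
along z, exactly its own-frame cumulants along the reflected direction
n = 2 (n'.z) z - n'.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .walk import M2_MULTIPLICITY, M4_EXPONENTS, M4_MULTIPLICITY, MomentRecord

__all__ = [
    "AxonCumulants",
    "SignalSet",
    "second_moment",
    "fourth_moment",
    "apparent_D",
    "apparent_K",
    "apparent_D_se",
    "apparent_K_se",
    "cumulant_series",
    "reflect_direction",
    "ensemble_D",
    "ensemble_K",
    "synthesize_signal",
    "fit_dki_wlls",
    "dispersed_ensemble",
]


@dataclass
class AxonCumulants:
    """Time-resolved diffusivity and kurtosis of one axon along one direction."""

    t: np.ndarray
    D: np.ndarray
    K: np.ndarray
    f: float = 1.0
    axon_id: int | None = None
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.f <= 0:
            raise ValueError("volume fraction must be positive")


@dataclass
class SignalSet:
    """Synthesized dMRI signals S(b, t), normalized to S(0, t) = 1."""

    b: np.ndarray  # (n_b,), ms/um^2
    t: np.ndarray  # (n_t,), ms
    S: np.ndarray  # (n_b, n_t)


def _check_unit(n: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    return n


def _t_index(rec: MomentRecord, t: float) -> int:
    i = int(np.argmin(np.abs(rec.t - t)))
    if abs(rec.t[i] - t) > 1e-9 * max(1.0, t):
        raise ValueError(f"t = {t} ms was not sampled")
    return i


def second_moment(rec: MomentRecord, n: np.ndarray, t: float) -> float:
    """<s^2> = n_a n_b <x_a x_b> from the six unique weighted components."""
    n = _check_unit(n)
    i = _t_index(rec, t)
    m2 = rec.m2[i] / rec.W[i]
    prods = np.array([n[0] ** 2, n[1] ** 2, n[2] ** 2, n[0] * n[1], n[0] * n[2], n[1] * n[2]])
    return float(np.sum(M2_MULTIPLICITY * prods * m2))


def fourth_moment(rec: MomentRecord, n: np.ndarray, t: float) -> float:
    """<s^4>: full fourth-moment contraction with multinomial multiplicities."""
    n = _check_unit(n)
    i = _t_index(rec, t)
    m4 = rec.m4[i] / rec.W[i]
    e = M4_EXPONENTS
    prods = n[0] ** e[:, 0] * n[1] ** e[:, 1] * n[2] ** e[:, 2]
    return float(np.sum(M4_MULTIPLICITY * prods * m4))


def apparent_D(rec: MomentRecord, n: np.ndarray, t: float) -> float:
    """Apparent diffusivity <s^2> / (2 t) along n (um^2/ms)."""
    return second_moment(rec, n, t) / (2.0 * t)


def apparent_K(rec: MomentRecord, n: np.ndarray, t: float) -> float:
    """Apparent excess kurtosis <s^4>/<s^2>^2 - 3 along n."""
    s2 = second_moment(rec, n, t)
    if s2 == 0:
        raise ValueError("second moment vanishes; kurtosis undefined")
    return fourth_moment(rec, n, t) / s2**2 - 3.0


def apparent_D_se(rec: MomentRecord, n: np.ndarray, t: float) -> float:
    """Monte-Carlo standard error of the apparent diffusivity.

    Var(s^2) per walker = (K + 2) <s^2>^2; the weight spread is ignored,
    which is adequate when T2 weights are near-uniform.
    """
    s2 = second_moment(rec, n, t)
    K = apparent_K(rec, n, t)
    return np.sqrt(max(K + 2.0, 0.0) / rec.n_walkers) * s2 / (2.0 * t)


def apparent_K_se(rec: MomentRecord, n: np.ndarray, t: float) -> float:
    """Asymptotic standard error of the excess-kurtosis estimate near
    Gaussianity, sqrt(24 / n)."""
    return float(np.sqrt(24.0 / rec.n_walkers))


def cumulant_series(
    rec: MomentRecord, n: np.ndarray, f: float = 1.0, axon_id: int | None = None
) -> AxonCumulants:
    """D(t), K(t) along n at every sampled time of a moment record."""
    D = np.array([apparent_D(rec, n, t) for t in rec.t])
    K = np.array([apparent_K(rec, n, t) for t in rec.t])
    return AxonCumulants(t=rec.t.copy(), D=D, K=K, f=f, axon_id=axon_id, direction=np.asarray(n, float))


def reflect_direction(n_prime: np.ndarray) -> np.ndarray:
    """Reflect n' about the z-axis: n = 2 (n'.z) z - n'.

    Measuring along z in the lab frame of an axon tilted along n' equals
    measuring along n in the axon's own frame; the polar angle is
    preserved (n.z = n'.z).
    """
    n_prime = _check_unit(n_prime)
    z = np.array([0.0, 0.0, 1.0])
    return 2.0 * float(n_prime @ z) * z - n_prime


def _fractions(axons: list[AxonCumulants]) -> np.ndarray:
    f = np.array([a.f for a in axons])
    if abs(f.sum() - 1.0) > 1e-8:
        raise ValueError(f"volume fractions must sum to 1 (got {f.sum():.10g})")
    return f


def ensemble_D(axons: list[AxonCumulants]) -> np.ndarray:
    """Volume-fraction-weighted mean diffusivity D(t) = sum_i f_i D_i(t)."""
    f = _fractions(axons)
    D = np.stack([a.D for a in axons])
    return f @ D


def ensemble_K(axons: list[AxonCumulants]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble kurtosis and its inter-/intra-compartment split.

    Returns ``(K, K_inter, K_intra)`` with
    K = (1/D^2) sum_i [3 f_i (D_i - D)^2 + f_i D_i^2 K_i].
    """
    f = _fractions(axons)
    D_i = np.stack([a.D for a in axons])
    K_i = np.stack([a.K for a in axons])
    D = f @ D_i
    if np.any(D == 0):
        raise ValueError("ensemble diffusivity vanishes; kurtosis undefined")
    K_inter = 3.0 * (f @ (D_i - D[None, :]) ** 2) / D**2
    K_intra = (f @ (D_i**2 * K_i)) / D**2
    return K_inter + K_intra, K_inter, K_intra


def synthesize_signal(axons: list[AxonCumulants], b: np.ndarray) -> SignalSet:
    """Multi-compartment cumulant signal S(b, t) = sum_i f_i
    exp(-b D_i + b^2 D_i^2 K_i / 6); warns when b exceeds the
    monotonicity bound 3 / (D_i K_i) of any compartment."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    f = _fractions(axons)
    D_i = np.stack([a.D for a in axons])  # (n_axon, n_t)
    K_i = np.stack([a.K for a in axons])
    with np.errstate(divide="ignore"):
        b_limit = np.where(D_i * K_i > 0, 3.0 / (D_i * K_i), np.inf)
    if np.any(b.max() > b_limit):
        warnings.warn(
            "b exceeds the cumulant-expansion monotonicity bound 3/(D K) "
            "for at least one compartment", stacklevel=2,
        )
    expo = -b[:, None, None] * D_i[None] + (b[:, None, None] ** 2) * D_i[None] ** 2 * K_i[None] / 6.0
    S = np.einsum("i,bit->bt", f, np.exp(expo))
    t = axons[0].t
    return SignalSet(b=b, t=t.copy(), S=S)


def fit_dki_wlls(signals: SignalSet) -> tuple[np.ndarray, np.ndarray]:
    """Weighted linear least-squares DKI fit per diffusion time.

    Solves ln S = -b D + (1/6) b^2 D^2 K in the coefficients
    (D, D^2 K) with weights S^2 (the standard weighting that undoes the
    noise distortion of the log transform).  Requires >= 3 distinct
    b-values including b = 0.
    """
    b = signals.b
    if b.size < 3 or np.unique(b).size < 3 or 0.0 not in b:
        raise ValueError("need >= 3 distinct b-values including b = 0")
    if np.any(signals.S <= 0):
        raise ValueError("signals must be positive")
    X = np.column_stack([-b, b**2 / 6.0])
    D_out = np.empty(signals.t.size)
    K_out = np.empty(signals.t.size)
    for j in range(signals.t.size):
        y = np.log(signals.S[:, j])
        w = signals.S[:, j] ** 2
        A = X.T @ (X * w[:, None])
        if np.linalg.matrix_rank(A) < 2:
            raise ValueError("rank-deficient design (degenerate b-values)")
        c1, c2 = np.linalg.solve(A, X.T @ (w * y))
        D_out[j] = c1
        K_out[j] = c2 / c1**2 if c1 != 0 else np.nan
    return D_out, K_out


def dispersed_ensemble(
    records: list[MomentRecord],
    fractions: np.ndarray,
    kappa: float,
    n_draws: int,
    seed: int | None = None,
) -> list[AxonCumulants]:
    """Cumulants of a Watson-dispersed bundle measured along z.

    Each (record, Watson draw) pair becomes one pseudo-axon whose own-frame
    cumulants are evaluated along the reflected direction; volume fractions
    are split evenly over the draws.
    """
    from .substrate import sample_watson

    fractions = np.asarray(fractions, dtype=float)
    dirs = sample_watson(kappa, n_draws, seed=seed).vectors
    axons: list[AxonCumulants] = []
    for rec, f in zip(records, fractions):
        for d in dirs:
            n = reflect_direction(d)
            axons.append(cumulant_series(rec, n, f=f / n_draws))
    return axons
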