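"""Structural analysis of caliber profiles and labeled volumes.

Implements the 1d power-spectrum analysis that classifies the placement of
restrictions along axons: a low-k plateau of the cross-sectional-area
fluctuation spectrum (structural exponent p = 0) is the fingerprint of
short-range disorder, which in turn dictates the t^(-1/2) tail of the
time-dependent axial diffusivity.  Also provides restriction statistics
(spacing mean/SD from detected caliber maxima), caliber statistics (CV of
radius), and the closed-form plateau relation linking the two:

    Gamma_1d / abar = (sigma_a^2 / abar^2) * (lbar^2 / abar^2)

so the average restriction width lbar can be read off a measured plateau.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .substrate import LabeledVolume, RadiusProfile, SubstrateError

__all__ = [
    "PowerSpectrum1d",
    "RestrictionStats",
    "CaliberStats",
    "cross_section_series",
    "caliber_stats",
    "concatenate_profiles",
    "power_spectrum_density",
    "position_spectrum",
    "estimate_plateau_and_p",
    "plateau_eq7",
    "l_from_plateau",
    "find_restrictions",
]


@dataclass
class PowerSpectrum1d:
    """One-sided 1d power spectrum on a uniform k grid (rad/um)."""

    k: np.ndarray
    gamma: np.ndarray
    mean_area: float
    kind: str  # "density" | "positions"

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.k.shape != self.gamma.shape:
            raise ValueError("k and gamma must have matching shapes")


@dataclass
class RestrictionStats:
    """Spacing statistics of detected caliber maxima."""

    positions: np.ndarray
    a_mean: float
    a_sd: float
    l_est: float | None = None


@dataclass
class CaliberStats:
    """Radius / cross-sectional-area statistics of one axon."""

    mean_r: float
    sd_r: float
    cv: float
    area: np.ndarray
    centroid: np.ndarray | None = None
    gaps: np.ndarray | None = None

    @property
    def cv2(self) -> float:
        return self.cv**2


def caliber_stats(profile: RadiusProfile) -> CaliberStats:
    r = profile.r
    mean_r = float(r.mean())
    sd_r = float(r.std())
    return CaliberStats(mean_r=mean_r, sd_r=sd_r, cv=sd_r / mean_r, area=profile.area)


def cross_section_series(vol: LabeledVolume) -> CaliberStats:
    """Per-slice cross-sectional area, centroid track and equivalent radius
    from a labeled volume (labels 1 and 2 both count as intra-axonal)."""
    inside = vol.labels > 0
    counts = inside.sum(axis=(0, 1))
    h = vol.h
    area = counts * h**2
    gaps = counts == 0
    xg = (np.arange(vol.labels.shape[0]) + 0.5) * h
    yg = (np.arange(vol.labels.shape[1]) + 0.5) * h
    denom = np.maximum(counts, 1)
    cx = inside.sum(axis=1).T @ xg / denom
    cy = inside.sum(axis=0).T @ yg / denom
    r_eq = np.sqrt(area / math.pi)
    valid = r_eq[~gaps]
    mean_r = float(valid.mean())
    sd_r = float(valid.std())
    return CaliberStats(
        mean_r=mean_r,
        sd_r=sd_r,
        cv=sd_r / mean_r,
        area=area,
        centroid=np.column_stack([cx, cy]),
        gaps=gaps,
    )


def concatenate_profiles(
    profiles: list[RadiusProfile], seed: int | None = None
) -> RadiusProfile:
    """Concatenate volume-normalized profiles along z in a seeded random order."""
    if not profiles:
        raise SubstrateError("no profiles to concatenate")
    dz = profiles[0].dz
    if any(abs(p.dz - dz) > 1e-12 for p in profiles):
        raise SubstrateError("profiles must share a common dz")
    order = np.random.default_rng(seed).permutation(len(profiles))
    r = np.concatenate([profiles[i].r for i in order])
    return RadiusProfile(dz=dz, r=r)


# ---------------------------------------------------------------------------
# power spectra


def power_spectrum_density(
    profile: RadiusProfile, subtract_mean: bool = True
) -> PowerSpectrum1d:
    """1d reduction of the axially symmetric density's power spectrum,

        Gamma_1d(k_z) = |dA(k_z)|^2 / (V * Abar),

    with ``dA`` the discrete Fourier transform of the CSA fluctuations
    A(z) - Abar (rectangular-window periodogram).  ``subtract_mean=False``
    keeps the raw density as printed in the defining relation; the mean is
    subtracted by default because its spectral leakage at finite length
    otherwise swamps the low-k plateau of interest.  Units of Gamma are um.
    """
    area = profile.area
    n = area.size
    dz = profile.dz
    L = n * dz
    a_bar = float(area.mean())
    v = float(area.sum() * dz)
    signal = area - a_bar if subtract_mean else area
    ft = np.fft.rfft(signal) * dz
    gamma = np.abs(ft) ** 2 / (v * a_bar)
    k = 2 * math.pi * np.arange(ft.size) / L
    return PowerSpectrum1d(k=k[1:], gamma=gamma[1:], mean_area=a_bar, kind="density")


def position_spectrum(positions: np.ndarray, L: float | None = None) -> PowerSpectrum1d:
    """Power spectrum of the restriction positions (sum of delta functions),
    normalized so the low-k plateau tends to sigma_a^2 / abar^2 for renewal
    placement:  Gamma_pos(k) = |sum_j e^{-i k z_j}|^2 / N  at k = 2 pi m / L.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.size
    if n < 10:
        raise ValueError("need at least 10 positions")
    if L is None:
        L = float(positions.max())
    m_max = n // 2
    m = np.arange(1, m_max + 1)
    k = 2 * math.pi * m / L
    phases = np.exp(-1j * np.outer(k, positions))
    gamma = np.abs(phases.sum(axis=1)) ** 2 / n
    return PowerSpectrum1d(k=k, gamma=gamma, mean_area=float("nan"), kind="positions")


def estimate_plateau_and_p(
    spectrum: PowerSpectrum1d,
    k_max: float,
    k_min: float | None = None,
) -> tuple[float, float]:
    """Low-k plateau level and structural exponent p.

    The plateau is the mean of Gamma over (k_min, k_max]; p is the slope of
    log Gamma vs log k over the same window.  |p| < 0.3 is read as
    short-range disorder (p = 0 class).
    """
    mask = spectrum.k <= k_max
    if k_min is not None:
        mask &= spectrum.k > k_min
    if mask.sum() < 5:
        raise ValueError("fit window must contain at least 5 spectral points")
    k = spectrum.k[mask]
    g = spectrum.gamma[mask]
    plateau = float(g.mean())
    pos = g > 0
    if pos.sum() < 5:
        raise ValueError("too few positive spectral points for a log-log slope")
    p = float(np.polyfit(np.log(k[pos]), np.log(g[pos]), 1)[0])
    return plateau, p


def plateau_eq7(a_mean: float, a_sd: float, l_mean: float) -> float:
    """Normalized low-k plateau Gamma_1d/abar for short-range disorder:
    (sigma_a^2/abar^2) * (lbar^2/abar^2)."""
    if a_mean <= 0 or l_mean <= 0 or a_sd < 0:
        raise ValueError("arguments must be positive (a_sd non-negative)")
    return (a_sd**2 / a_mean**2) * (l_mean**2 / a_mean**2)


def l_from_plateau(plateau: float, a_mean: float, a_sd: float) -> float:
    """Invert the plateau relation for the average restriction width:
    lbar = (abar^2 / sigma_a) * sqrt(Gamma/abar)."""
    if a_sd == 0:
        raise ValueError("width is undefined for a periodic arrangement (sigma_a = 0)")
    if plateau < 0:
        raise ValueError("plateau must be non-negative")
    return (a_mean**2 / a_sd) * math.sqrt(plateau)


# ---------------------------------------------------------------------------
# restriction detection


def find_restrictions(
    profile: RadiusProfile,
    smoothing: float = 1.0,
    estimate_width: bool = False,
) -> RestrictionStats:
    """Locate local caliber maxima of the smoothed profile and summarize
    their spacings.  ``smoothing`` is the Gaussian detection scale in um;
    plateau-equal maxima resolve to the leftmost point.
    """
    r = profile.r
    if smoothing > 0:
        r = gaussian_filter1d(r, smoothing / profile.dz, mode="nearest")
    rising = r[1:-1] > r[:-2]
    falling = r[1:-1] >= r[2:]
    idx = np.nonzero(rising & falling)[0] + 1
    positions = idx * profile.dz
    # drop maxima within the smoothing support of the profile ends, where
    # the boundary padding of the filter distorts peak locations
    edge = 2.0 * smoothing
    positions = positions[(positions >= edge) & (positions <= profile.length - edge)]
    if positions.size == 0:
        raise SubstrateError("no interior caliber maxima found")
    if positions.size < 2:
        return RestrictionStats(positions=positions, a_mean=float("nan"), a_sd=float("nan"))
    spacings = np.diff(positions)
    a_mean = float(spacings.mean())
    a_sd = float(spacings.std())
    l_est = None
    if estimate_width and a_sd > 0:
        spec = power_spectrum_density(profile)
        plateau, _ = estimate_plateau_and_p(spec, k_max=0.5 / a_mean)
        l_est = l_from_plateau(plateau / a_mean, a_mean, a_sd)
    return RestrictionStats(positions=positions, a_mean=a_mean, a_sd=a_sd, l_est=l_est)
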