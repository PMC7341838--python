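"""Shared fixtures.

The expensive Monte-Carlo runs are session-scoped and shared between the
unit/property tests and the acceptance tests, so each substrate is
simulated exactly once per session.  Problem sizes are desk-scale
(20 um-long tubes, 1e4-2e4 walkers, step = h/2); see docs/methods.md.
"""
from __future__ import annotations

import numpy as np
import pytest

from axondiff import cumulants as cm
from axondiff import morphometry as mm
from axondiff import substrate as sb
from axondiff import walk as wk

#: diffusion-time grid used by the simulation fixtures (ms)
SIM_TIMES = np.array([5.0, 10, 15, 20, 25, 30, 36, 42, 50, 58, 66, 73, 80])

#: step length is half the voxel size; dt = step^2 / (6 D_a)
def dt_for(h: float, D: float = 2.0, frac: float = 0.5) -> float:
    return (frac * h) ** 2 / (6.0 * D)


@pytest.fixture(scope="session")
def study_spec() -> sb.BeadSpec:
    """Calibrated bead statistics of the study substrate."""
    return sb.BeadSpec()


@pytest.fixture(scope="session")
def beaded_profile_60(study_spec) -> sb.RadiusProfile:
    return sb.beaded_profile(60.0, study_spec, dz=0.1, seed=11)


@pytest.fixture(scope="session")
def beaded_sim(beaded_profile_60):
    """Monte-Carlo moments in the calibrated beaded substrate (h = 0.15 um,
    2e4 walkers, t up to 80 ms)."""
    vol = sb.voxelize(beaded_profile_60, None, h=0.15)
    props = sb.CompartmentProps()
    cfg = wk.SimConfig(
        dt=dt_for(0.15), n_walkers=20000, sample_times=SIM_TIMES, seed=4
    )
    rec = wk.run_walk(vol, props, cfg)
    return {"profile": beaded_profile_60, "vol": vol, "props": props, "rec": rec}


@pytest.fixture(scope="session")
def cylinder_sim():
    """Straight cylinder of radius 1 um (free axial diffusion, restricted
    transverse)."""
    prof = sb.RadiusProfile(dz=0.1, r=np.full(600, 1.0))
    vol = sb.voxelize(prof, None, h=0.2)
    props = sb.CompartmentProps()
    cfg = wk.SimConfig(
        dt=dt_for(0.2), n_walkers=10000, sample_times=SIM_TIMES, seed=3
    )
    rec = wk.run_walk(vol, props, cfg)
    return {"profile": prof, "vol": vol, "props": props, "rec": rec}


@pytest.fixture(scope="session")
def free_sim():
    """Unbounded diffusion at D = 2 um^2/ms (mirrored all-axoplasm box).

    Sampled times start at 1000 steps: a fixed-step-length walk carries a
    known O(1/n_steps) negative kurtosis that must be below the Monte-Carlo
    noise floor before Gaussianity can be asserted.
    """
    vol = wk.free_substrate()
    props = sb.CompartmentProps(D_a=2.0, D_m=2.0)
    times = np.geomspace(20.0, 100.0, 8)
    cfg = wk.SimConfig(dt=0.02, n_walkers=100000, sample_times=times, seed=5)
    rec = wk.run_walk(vol, props, cfg)
    return {"vol": vol, "props": props, "rec": rec}


AMPLITUDE_SWEEP = (0.05, 0.6, 1.2)

#: denser in-window grid for the sweep arms (sharper power-law fits)
SWEEP_TIMES = np.concatenate([np.array([5.0, 10, 15]), np.linspace(20, 80, 21)])


@pytest.fixture(scope="session")
def amplitude_sweep_sims(study_spec, beaded_sim):
    """Beaded substrates at increasing bead amplitude sharing the study
    substrate's seeds (common random numbers); the calibrated study run
    itself serves as the strongest-amplitude arm.  Used for the zeta-CV^2
    relation and the c-vs-amplitude ordering."""
    out = []
    z = np.array([0.0, 0.0, 1.0])
    for amp in AMPLITUDE_SWEEP[:-1]:
        spec = sb.BeadSpec(
            a_mean=study_spec.a_mean, a_sd=study_spec.a_sd,
            l_mean=study_spec.l_mean, amplitude=amp, r0=study_spec.r0,
        )
        prof = sb.beaded_profile(60.0, spec, dz=0.1, seed=11)
        vol = sb.voxelize(prof, None, h=0.15)
        cfg = wk.SimConfig(
            dt=dt_for(0.15), n_walkers=12000, sample_times=SWEEP_TIMES, seed=4
        )
        rec = wk.run_walk(vol, sb.CompartmentProps(), cfg)
        out.append({
            "amplitude": amp,
            "cv": mm.caliber_stats(prof).cv,
            "rec": rec,
            "series": cm.cumulant_series(rec, z),
        })
    out.append({
        "amplitude": AMPLITUDE_SWEEP[-1],
        "cv": mm.caliber_stats(beaded_sim["profile"]).cv,
        "rec": beaded_sim["rec"],
        "series": cm.cumulant_series(beaded_sim["rec"], z),
    })
    return out
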