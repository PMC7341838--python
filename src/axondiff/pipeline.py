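"""End-to-end pipeline: substrate -> morphometry -> simulation -> cumulants -> fit.

Each stage writes its outputs to the run directory and can be skipped or
resumed; a JSON manifest records the configuration, seed and output hashes
so every stochastic result is traceable.
"""
from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import cumulants as cm
from . import io as aio
from . import morphometry as mm
from . import substrate as sb
from . import timedep as td
from . import walk as wk

__all__ = ["ALL_STAGES", "run_pipeline"]

ALL_STAGES = ("substrate", "morphometry", "simulate", "cumulants", "fit")


def _build_substrate(cfg: dict[str, Any], seed: int, outdir: Path):
    s = cfg["substrate"]
    spec = sb.BeadSpec(
        a_mean=s["a_mean"], a_sd=s["a_sd"], l_mean=s["l_mean"],
        amplitude=s["amplitude"], r0=s["r0"],
    )
    scenario = s["scenario"]
    if scenario == "straight":
        profile = sb.RadiusProfile(
            dz=s["dz"], r=np.full(int(round(s["L"] / s["dz"])), s["r0"])
        )
    else:
        profile = sb.beaded_profile(s["L"], spec, dz=s["dz"], seed=seed)
    skeleton = None
    if s["undulation"] > 0 and scenario in ("I", "II", "IV"):
        skeleton = sb.make_undulating_skeleton(
            s["L"], s["dz"], s["undulation"], s["sigma_s"], seed=seed + 1
        )
    c = cfg["compartments"]
    props = sb.CompartmentProps(
        D_a=c["D_a"], D_m=c["D_m"], T2_a=c["T2_a"], T2_m=c["T2_m"], f_m=c["f_m"]
    )
    if scenario in ("I", "II", "III", "IV"):
        vol = sb.make_scenario(scenario, profile, skeleton=skeleton, props=props,
                               h=s["h"], seed=seed + 2)
    elif scenario == "straight":
        vol = sb.make_scenario("straight", profile, h=s["h"])
    else:
        vol = sb.voxelize(profile, skeleton, h=s["h"])
    aio.save_profile(profile, outdir / "profile.csv", skeleton)
    aio.save_labeled_volume(vol, outdir / "substrate.nii")
    return profile, vol, props


def run_pipeline(
    config: dict[str, Any] | str | Path,
    seed: int,
    outdir: str | Path,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict[str, Any]:
    """Drive the full chain on one substrate and return the fit summary.

    ``stages`` selects which stages run; earlier outputs are re-loaded from
    ``outdir`` when a stage is skipped (resume semantics).
    """
    if not isinstance(config, dict):
        config = aio.load_config(config)
    else:
        config = aio.validate_config(config)
    for st in stages:
        if st not in ALL_STAGES:
            raise ValueError(f"unknown stage {st!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict[str, Any] = {}

    s = cfg_sub = config["substrate"]
    c = config["compartments"]
    props = sb.CompartmentProps(
        D_a=c["D_a"], D_m=c["D_m"], T2_a=c["T2_a"], T2_m=c["T2_m"], f_m=c["f_m"]
    )

    profile = vol = None
    t0 = time.perf_counter()
    if "substrate" in stages:
        profile, vol, props = _build_substrate(config, seed, outdir)
        timings["substrate"] = time.perf_counter() - t0
    elif {"morphometry", "simulate"} & set(stages):
        profile, _ = aio.load_profile(outdir / "profile.csv")
        vol = aio.load_labeled_volume(outdir / "substrate.nii")

    if "morphometry" in stages:
        t0 = time.perf_counter()
        stats = mm.caliber_stats(profile)
        spec1d = mm.power_spectrum_density(profile)
        pd.DataFrame({"k": spec1d.k, "gamma": spec1d.gamma}).to_csv(
            outdir / "spectrum.csv", index=False, float_format=aio.FLOAT_FMT
        )
        morpho = {"mean_r": stats.mean_r, "sd_r": stats.sd_r, "cv_r": stats.cv}
        if cfg_sub["scenario"] != "straight":
            try:
                rest = mm.find_restrictions(profile)
                morpho.update(a_mean=rest.a_mean, a_sd=rest.a_sd)
            except sb.SubstrateError:
                pass
        with open(outdir / "morphometry.json", "w") as fh:
            json.dump(morpho, fh, indent=2)
        results["morphometry"] = morpho
        timings["morphometry"] = time.perf_counter() - t0

    sim = config["simulation"]
    if "simulate" in stages:
        t0 = time.perf_counter()
        step = sim["step_fraction"] * s["h"]
        dt = step**2 / (6.0 * max(props.D_a, props.D_m))
        cfg_run = wk.SimConfig(
            dt=dt,
            n_walkers=sim["n_walkers"],
            sample_times=wk.log_spaced_times(sim["t_min"], sim["t_max"], sim["n_times"]),
            seed=seed,
            t2_weighting=sim["t2_weighting"],
        )
        rec = wk.run_walk(vol, props, cfg_run)
        aio.save_moments(rec, outdir / "moments.csv")
        timings["simulate"] = time.perf_counter() - t0
    elif "cumulants" in stages:
        rec = aio.load_moments(outdir / "moments.csv")

    if "cumulants" in stages:
        t0 = time.perf_counter()
        series = cm.cumulant_series(rec, np.array([0.0, 0.0, 1.0]))
        pd.DataFrame({"t": series.t, "D": series.D, "K": series.K}).to_csv(
            outdir / "cumulants.csv", index=False, float_format=aio.FLOAT_FMT
        )
        timings["cumulants"] = time.perf_counter() - t0
    elif "fit" in stages:
        df = pd.read_csv(outdir / "cumulants.csv", float_precision="round_trip")
        series = cm.AxonCumulants(t=df["t"].to_numpy(), D=df["D"].to_numpy(),
                                  K=df["K"].to_numpy())

    if "fit" in stages:
        t0 = time.perf_counter()
        window = tuple(config["fit"]["window"])
        fit = td.fit_power_law(series.t, series.D, window=window)
        fit_out = {
            "D_inf": fit.D_inf, "c": fit.c,
            "D_inf_se": fit.D_inf_se, "c_se": fit.c_se,
            "p_value": fit.p_value, "window": list(fit.window),
        }
        with open(outdir / "fit.json", "w") as fh:
            json.dump(fit_out, fh, indent=2)
        results["fit"] = fit_out
        timings["fit"] = time.perf_counter() - t0

    files = {name: outdir / fname for name, fname in [
        ("profile", "profile.csv"), ("substrate", "substrate.nii"),
        ("spectrum", "spectrum.csv"), ("moments", "moments.csv"),
        ("cumulants", "cumulants.csv"), ("fit", "fit.json"),
    ]}
    manifest = aio.build_manifest(config, seed, files, timings)
    aio.write_manifest(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results
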