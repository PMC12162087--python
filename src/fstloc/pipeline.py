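"""End-to-end stages tying the modules together.

Each stage reads/writes plain files in an output directory so stages can be
re-run or inspected independently:

* :func:`cmd_simulate` — ground-truth hemisphere, schedules, all runs' time
  series (the synthetic stand-in for a scanning session);
* :func:`cmd_localize` — GLM, contrasts, ROI delineation, overlap metrics;
* :func:`cmd_prf_fit` — pRF and stimulus-contrast model fits per vertex;
* :func:`cmd_biassim` — the size/eccentricity estimation-bias simulation;
* :func:`cmd_report` — group-level statistics over a synthetic cohort.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm, io, roi, stats, stimuli, synth
from .config import RunConfig

__all__ = ["cmd_simulate", "cmd_localize", "cmd_prf_fit", "cmd_biassim", "cmd_report"]


def _log(out_dir: Path, stage: str, **info) -> None:
    with (out_dir / "pipeline_log.jsonl").open("a") as fh:
        fh.write(json.dumps({"stage": stage, **info}) + "\n")


def _build_schedules(cfg: RunConfig) -> dict[str, stimuli.BlockSchedule]:
    s = cfg["schedules"]
    return {
        "motion2d": stimuli.build_2d_schedule(
            block_s=s["motion2d"]["block_s"],
            reps_per_direction=s["motion2d"]["reps_per_direction"],
        ),
        "motion3d": stimuli.build_3d_schedule(
            block_s=s["motion3d"]["block_s"], reps=s["motion3d"]["reps"]
        ),
        "opponent": stimuli.build_opponent_schedule(
            block_s=s["opponent"]["block_s"], n_blocks=s["opponent"]["n_blocks"]
        ),
    }


def _build_apertures(cfg: RunConfig) -> dict[str, stimuli.ApertureMovie]:
    a = cfg["aperture"]
    common = dict(
        radius=a["radius"], grid_size=a["grid_size"], n_steps=a["n_steps"],
        tr=a["tr"], step_trs=a["step_trs"],
    )
    return {
        "bar": stimuli.gen_prf_apertures("bar", **common),
        "wedge": stimuli.gen_prf_apertures("wedge", **common),
        "ring": stimuli.gen_prf_apertures("ring", **common),
    }


def prf_run_plan(cfg: RunConfig) -> list[tuple[str, str]]:
    """(run name, aperture kind) for the retinotopy protocol.

    Half the scans use the static-carrier stimulus and half the moving
    version; both halves alternate bar and wedge/ring apertures. Defaults
    give 12 scans in total.
    """
    n_bar = int(cfg["prf_runs"]["n_bar"])
    n_wr = int(cfg["prf_runs"]["n_wedge_ring"])
    plan = [(f"prf_bar{i:02d}", "bar") for i in range(n_bar)]
    for i in range(n_wr):
        plan.append((f"prf_wr{i:02d}", "wedge" if i % 2 == 0 else "ring"))
    return plan


def cmd_simulate(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write ground truth, schedules and every run's simulated time series."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hemi = synth.make_hemisphere(cfg.hemisphere_config(), seed=cfg.stage_seed("hemisphere"))
    io.write_hemisphere(hemi, out / "hemisphere.csv")

    schedules = _build_schedules(cfg)
    for name, sched in schedules.items():
        io.write_events(sched, out / f"events_{name}.tsv")

    noise_sd = cfg.noise_sd
    drift = float(cfg.data.get("drift_slope", 0.0))
    for name, sched in schedules.items():
        n_runs = int(cfg["schedules"][name]["n_runs"])
        for run in range(n_runs):
            seed = cfg.stage_seed(f"{name}_run{run}")
            ts = synth.simulate_run(hemi, sched, noise_sd, seed, drift_slope=drift)
            io.write_timeseries(
                ts, out / f"{name}_run{run:02d}.npy", experiment=name, seed=seed
            )
            _log(out, "simulate", run=f"{name}_run{run:02d}", seed=seed)

    apertures = _build_apertures(cfg)
    for kind, ap in apertures.items():
        io.write_apertures(ap, out / f"apertures_{kind}.npy")
    for run_name, kind in prf_run_plan(cfg):
        seed = cfg.stage_seed(run_name)
        ts = synth.simulate_run(hemi, apertures[kind], noise_sd, seed, drift_slope=drift)
        io.write_timeseries(
            ts, out / f"{run_name}.npy", experiment="prf", aperture=kind, seed=seed
        )
        _log(out, "simulate", run=run_name, seed=seed, aperture=kind)
    return out


def _contrast_maps(cfg: RunConfig, data_dir: Path) -> dict[str, glm.ContrastMap]:
    maps = {}
    for name in ("motion2d", "motion3d", "opponent"):
        sched = io.read_events(data_dir / f"events_{name}.tsv")
        design = glm.build_design(sched)
        run_files = sorted(data_dir.glob(f"{name}_run*.npy"))
        if not run_files:
            raise FileNotFoundError(
                f"no simulated runs for {name!r} in {data_dir}; run simulate first"
            )
        betas = glm.average_runs(
            [glm.fit_glm(glm.to_psc(io.read_timeseries(f)), design) for f in run_files]
        )
        cname = "opponency" if name == "opponent" else name
        pos, neg = glm.CONTRASTS[cname]
        maps[cname] = glm.contrast(betas, design.labels, pos, neg, name=cname)
    return maps


def cmd_localize(cfg: RunConfig, data_dir: str | Path, out_dir: str | Path | None = None) -> pd.DataFrame:
    """GLM -> contrasts -> delineation -> overlap metrics."""
    data_dir = Path(data_dir)
    out = Path(out_dir) if out_dir is not None else data_dir
    out.mkdir(parents=True, exist_ok=True)

    truth = pd.read_csv(data_dir / "hemisphere.csv")
    shape = (int(truth["row"].max()) + 1, int(truth["col"].max()) + 1)
    maps = _contrast_maps(cfg, data_dir)
    for cname, cmap in maps.items():
        np.savetxt(out / f"contrast_{cname}.csv", cmap.values, delimiter=",")

    r = cfg["roi"]
    rois = roi.delineate(
        maps["motion2d"], maps["motion3d"], shape,
        q_start=float(r["q_start"]), q_min=float(r["q_min"]),
        q_step=float(r["q_step"]), adjacency_dist=int(r["adjacency_dist"]),
    )
    pd.DataFrame(
        {"vertex": np.arange(rois.labels.size), "roi_label": rois.labels.ravel()}
    ).to_csv(out / "roi_labels.csv", index=False)

    region_codes = {"background": 0, "V1like": 1, "hMTMST": 2, "pFST": 3}
    true_label = truth["region"].map(region_codes).to_numpy().reshape(shape)
    atlas_label = truth["atlas_label"].to_numpy().reshape(shape)

    rows = []
    for name, code in (("hMTMST", 2), ("pFST", 3)):
        est = rois.mask(name)
        tru = true_label == code
        atl = atlas_label == code
        row = {
            "roi": name,
            "scenario": rois.scenario,
            "threshold_2d": rois.threshold_used_2d,
            "threshold_3d": rois.threshold_used_3d,
            "n_vertices": int(est.sum()),
            "dice_truth": roi.dice(est, tru),
            "dice_atlas": roi.dice(est, atl),
            "surface_area": roi.surface_area(est),
        }
        row["centroid_dist_truth"] = (
            roi.centroid_distance(est, tru) if est.any() and tru.any() else np.nan
        )
        row["centroid_dist_atlas"] = (
            roi.centroid_distance(est, atl) if est.any() and atl.any() else np.nan
        )
        rows.append(row)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "roi_metrics.csv", index=False)
    _log(out, "localize", scenario=rois.scenario, q=rois.threshold_used_2d)
    return metrics


def cmd_prf_fit(cfg: RunConfig, data_dir: str | Path, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Fit the pRF and stimulus-contrast models to the averaged bar runs."""
    from .prf import PRFFitter, fit_contrast

    data_dir = Path(data_dir)
    out = Path(out_dir) if out_dir is not None else data_dir
    out.mkdir(parents=True, exist_ok=True)

    apertures = io.read_apertures(data_dir / "apertures_bar.npy")
    bar_files = sorted(data_dir.glob("prf_bar*.npy"))
    if not bar_files:
        raise FileNotFoundError(f"no bar-aperture pRF runs in {data_dir}")
    runs = [glm.to_psc(io.read_timeseries(f)).values for f in bar_files]
    mean_ts = np.mean(runs, axis=0)

    fitter = PRFFitter(apertures, cfg.grid_spec())
    tol = float(cfg["fit"].get("refine_tol", 1e-4))
    rows = []
    for v in range(mean_ts.shape[0]):
        for fit in (fitter.fit(mean_ts[v], refine_tol=tol), fit_contrast(mean_ts[v], apertures)):
            rows.append({"vertex": v, **fit.as_dict()})
    fits = pd.DataFrame(rows)
    fits.to_csv(out / "prf_fits.csv", index=False)
    _log(out, "prf_fit", n_vertices=mean_ts.shape[0], n_runs=len(runs))
    return fits


def cmd_biassim(cfg: RunConfig, out_dir: str | Path, make_plots: bool = True) -> pd.DataFrame:
    """Run the estimation-bias simulation; write CSV and summary figures."""
    from .biassim import run_bias_sim

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b = cfg["biassim"]
    a = cfg["aperture"]
    apertures = stimuli.gen_prf_apertures(
        "bar", radius=a["radius"], grid_size=a["grid_size"],
        n_steps=a["n_steps"], tr=a["tr"], step_trs=a["step_trs"],
    )
    result = run_bias_sim(
        apertures,
        sizes=b["sizes"], eccs=b["eccs"], noise_levels=b["noise_levels"],
        n_voxels=int(b["n_voxels"]), seed=cfg.stage_seed("biassim"),
        n_boot=int(b["n_boot"]), grid_spec=cfg.grid_spec(),
        signal_peak=float(b.get("signal_peak", 1.0)),
    )
    result.to_csv(out / "bias_simulation.csv")
    if make_plots:
        _plot_bias(result.table, out)
    _log(out, "biassim", n_cells=len(result.table), seed=result.seed)
    return result.table


def _plot_bias(table: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for noise, grp in table.groupby("noise_sd"):
        g = grp.groupby("true_sigma")["mean_sigma_hat"].mean()
        axes[0].errorbar(g.index, g.values, label=f"noise {noise:g}", marker="o")
    axes[0].plot(table["true_sigma"].unique(), table["true_sigma"].unique(), "k--", lw=1)
    axes[0].set(xlabel="true pRF size (deg)", ylabel="estimated size (deg)")
    axes[0].legend()
    for sigma, grp in table.groupby("true_sigma"):
        g = grp.groupby("true_ecc")["mean_ecc_hat"].mean()
        axes[1].plot(g.index, g.values, marker="o", label=f"size {sigma:g}")
    axes[1].plot(table["true_ecc"].unique(), table["true_ecc"].unique(), "k--", lw=1)
    axes[1].set(xlabel="true eccentricity (deg)", ylabel="estimated eccentricity (deg)")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "bias_simulation.png", dpi=120)
    plt.close(fig)


def cmd_report(cfg: RunConfig, out_dir: str | Path, null: bool = False) -> pd.DataFrame:
    """Group-level validation statistics over a synthetic cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c = cfg.data.get("cohort", {})
    cohort = synth.cohort_measures(
        n_subjects=int(c.get("n_subjects", 9)),
        seed=cfg.stage_seed("cohort"),
        config=cfg.hemisphere_config(),
        vertex_sd=float(c.get("vertex_sd", 0.3)),
        r1_vertex_sd=float(c.get("r1_vertex_sd", 0.02)),
        hemisphere_sd=float(c.get("hemisphere_sd", 0.1)),
        r1_hemisphere_sd=float(c.get("r1_hemisphere_sd", 0.01)),
        null=null,
    )
    report = stats.group_report(cohort)
    report.to_csv(out / "group_report.csv", index=False)

    deciles = []
    for m in ("motion2d", "motion3d", "opponency", "r1"):
        pooled_mt = np.concatenate([h["measures"][m]["hMTMST"] for h in cohort])
        pooled_fst = np.concatenate([h["measures"][m]["pFST"] for h in cohort])
        d = stats.decile_profile(pooled_mt, pooled_fst)
        d.insert(0, "measure", m)
        deciles.append(d)
    pd.concat(deciles).to_csv(out / "decile_profiles.csv", index=False)
    _log(out, "report", n_hemispheres=len(cohort), null=null)
    return report
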