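"""End-to-end workflows reproducing the three experiments.

Each workflow either simulates its raw inputs (synthetic stacks / event
tables with known ground truth) or reads user data, runs the corresponding
analysis chain, and writes CSV tables, plots and a machine-readable
``summary.json`` stamped with the config hash and seed so reruns with
identical config and seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import bead as beadmod
from . import facs as facsmod
from . import flowcell as fcmod
from . import synth
from .config import config_hash
from .imagecore import (
    CHANNEL_CARRIER,
    CHANNEL_FREE,
    read_stack,
    segment_channel,
)

__all__ = ["run_flowcell", "run_bead", "run_facs", "run_all"]

FLOAT_FMT = "%.10g"


def _child_seed(seed: int, *tags) -> int:
    """Deterministic sub-seed below 2**31 derived from the run seed.

    Uses a stable (process-independent) hash of the tag strings.
    """
    import zlib

    digest = [zlib.crc32(str(t).encode()) for t in tags]
    h = np.random.SeedSequence([int(seed)] + digest)
    return int(h.generate_state(1)[0] % (2 ** 31))


def _write_summary(outdir: Path, cfg: dict, seed, payload: dict) -> dict:
    summary = {"config_hash": config_hash(cfg), "seed": seed, **payload}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# flow-cell workflow
# ---------------------------------------------------------------------------

def _segment_pair(img, threshold_cfg, smooth):
    free = segment_channel(img, CHANNEL_FREE,
                           method=threshold_cfg["green"], smooth=smooth)
    carrier = segment_channel(img, CHANNEL_CARRIER,
                              method=threshold_cfg["red"], smooth=smooth)
    return free, carrier


def _simulate_flowcell_images(cfg: dict, seed: int):
    """Yield (plasmid, replicate, image_id, VoxelImage, truth_df)."""
    sim = cfg["flowcell"]["sim"]
    profile = synth.step_profile(sim["p_loss_bottom"], sim["p_loss_top"],
                                 sim["n_layers"])
    for plasmid in sim["plasmids"]:
        for rep in range(sim["n_replicates"]):
            for im in range(sim["images_per_replicate"]):
                truth = synth.FlowcellTruth(
                    n_layers=sim["n_layers"],
                    shape_yx=tuple(sim["shape_yx"]),
                    loss_profile=profile,
                    biomass_profile=float(sim["biomass_per_layer"]),
                    voxel_size=tuple(cfg["flowcell"]["voxel_size_um"]),
                    noise_mean=sim["noise_mean"],
                    noise_sd=sim["noise_sd"],
                    fg_intensity=sim.get("fg_intensity", 1000.0),
                    seed=_child_seed(seed, "flowcell", plasmid, rep, im),
                )
                img, truth_df = synth.generate_flowcell_stack(truth)
                yield plasmid, rep, im, img, truth_df


def _load_flowcell_images(stacks_dir, cfg):
    """Read stacks from a directory; file stem convention
    ``<plasmid>_rep<k>_im<j>.tif`` (fallback: one replicate per file)."""
    paths = sorted(Path(stacks_dir).glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no .tif stacks in {stacks_dir}")
    for i, p in enumerate(paths):
        parts = p.stem.split("_")
        plasmid = parts[0] if len(parts) >= 3 else "plasmid"
        rep = parts[1] if len(parts) >= 3 else f"rep{i}"
        im = parts[2] if len(parts) >= 3 else "im0"
        img = read_stack(p, voxel_size=tuple(cfg["flowcell"]["voxel_size_um"]))
        yield plasmid, rep, im, img, None


def run_flowcell(cfg: dict, seed: int, outdir, stacks_dir=None,
                 span: float | None = None) -> dict:
    """Flow-cell chain: segment, profile, recenter, average, LOESS,
    stratify, two-way ANOVA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    span = span if span is not None else cfg["flowcell"]["loess_span"]
    degree = cfg["flowcell"]["loess_degree"]
    source = (_load_flowcell_images(stacks_dir, cfg) if stacks_dir
              else _simulate_flowcell_images(cfg, seed))

    profiles_by_rep: dict = {}
    ratios = {}
    truth_rows = []
    for plasmid, rep, im, img, truth_df in source:
        free, carrier = _segment_pair(img, cfg["flowcell"]["threshold"],
                                      cfg["flowcell"]["smooth"])
        prof = fcmod.recenter_z(fcmod.layer_profile(free, carrier))
        profiles_by_rep.setdefault((plasmid, rep), []).append(prof)
        ratios[(f"{plasmid}_rep{rep}_im{im}", plasmid)] = \
            fcmod.split_top_bottom(prof)
        if truth_df is not None:
            truth_df = truth_df.assign(plasmid=plasmid, replicate=rep,
                                       image=im)
            truth_rows.append(truth_df)

    profile_rows = []
    curve_rows = []
    curves = []
    avg_profiles = []
    for (plasmid, rep), profs in sorted(profiles_by_rep.items(),
                                        key=lambda kv: str(kv[0])):
        avg = fcmod.average_replicates(profs)
        avg_profiles.append(avg)
        df = avg.to_frame().assign(plasmid=plasmid, replicate=rep)
        profile_rows.append(df)
        curve = fcmod.weighted_loess(avg, span=span, degree=degree,
                                     replicate=f"{plasmid}_rep{rep}")
        curves.append(curve)
        curve_rows.append(pd.DataFrame({
            "plasmid": plasmid, "replicate": rep, "z_corrected": curve.x,
            "loess_fit": curve.fitted, "span": span}))

    _write_csv(pd.concat(profile_rows, ignore_index=True),
               outdir / "profiles.csv")
    _write_csv(pd.concat(curve_rows, ignore_index=True),
               outdir / "loess.csv")
    strata = fcmod.strata_table(ratios)
    _write_csv(strata, outdir / "strata.csv")
    anova = fcmod.compare_strata(strata)
    _write_csv(anova, outdir / "anova.csv")
    if truth_rows:
        _write_csv(pd.concat(truth_rows, ignore_index=True),
                   outdir / "truth_counts.csv")

    if cfg.get("plots", True):
        from .plotting import plot_loss_depth

        plot_loss_depth(avg_profiles, curves, outdir / "loss_vs_depth.png")

    finite = strata["ratio"].replace([np.inf, -np.inf], np.nan).dropna()
    top = strata.loc[strata["stratum"] == "top", "ratio"]
    bot = strata.loc[strata["stratum"] == "bottom", "ratio"]
    payload = {
        "experiment": "flowcell",
        "n_images": len(ratios),
        "loess_span": span,
        "mean_top_ratio": float(top.replace([np.inf], np.nan).mean()),
        "mean_bottom_ratio": float(bot.replace([np.inf], np.nan).mean()),
        "anova": {row["factor"]: {"F": row["F"], "p": row["p"]}
                  for _, row in anova.iterrows()
                  if row["factor"] != "residual"},
        "n_finite_ratios": int(finite.size),
    }
    return _write_summary(outdir, cfg, seed, payload)


# ---------------------------------------------------------------------------
# bead workflow
# ---------------------------------------------------------------------------

def _simulate_bead_stacks(cfg: dict, seed: int):
    sim = cfg["bead"]["sim"]
    rng = np.random.default_rng(_child_seed(seed, "bead", "intercepts"))
    for strain in sim["strains"]:
        for b in range(sim["beads_per_strain"]):
            shift = rng.normal(0.0, sim["bead_intercept_sd"])
            model = {status: (icpt + shift, slope)
                     for status, (icpt, slope) in sim["size_model"].items()}
            truth = synth.BeadTruth(
                shape=tuple(sim["shape"]),
                radius_um=sim["radius_um"],
                n_aggregates=sim["n_aggregates"],
                size_model=model,
                size_sd=sim["size_sd"],
                free_fraction=sim["free_fraction"],
                voxel_size=tuple(cfg["bead"]["voxel_size_um"]),
                seed=_child_seed(seed, "bead", strain, b),
            )
            img, truth_df = synth.generate_bead_stack(truth)
            yield strain, f"{strain}_bead{b}", img, truth_df


def _load_bead_stacks(stacks_dir, cfg):
    paths = sorted(Path(stacks_dir).glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no .tif stacks in {stacks_dir}")
    for p in paths:
        strain = p.stem.split("_")[0]
        img = read_stack(p, voxel_size=tuple(cfg["bead"]["voxel_size_um"]))
        yield strain, p.stem, img, None


def run_bead(cfg: dict, seed: int, outdir, stacks_dir=None,
             min_volume: float | None = None) -> dict:
    """Bead chain: segment, centre, detect, filter, normalize, ratios,
    size-distance OLS, status LMM, Welch t between strains."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bcfg = cfg["bead"]
    min_volume = (min_volume if min_volume is not None
                  else bcfg["min_volume_um3"])
    source = (_load_bead_stacks(stacks_dir, cfg) if stacks_dir
              else _simulate_bead_stacks(cfg, seed))

    tables = []
    strain_of = {}
    for strain, bead_id, img, truth_df in source:
        free, carrier = _segment_pair(img, bcfg["threshold"], bcfg["smooth"])
        center = beadmod.bead_center(free, carrier, img.voxel_size)
        table = beadmod.detect_aggregates(free, carrier, img.voxel_size,
                                          center, bead_id=bead_id)
        tables.append(table)
        strain_of[bead_id] = strain
    table = pd.concat(tables, ignore_index=True)
    table = beadmod.filter_aggregates(
        table, min_volume=min_volume,
        exclusion_factor=bcfg["exclusion_factor"],
        radius_quantile=bcfg["radius_quantile"])
    table = beadmod.normalize_distances(table)
    table["strain"] = table["bead_id"].map(strain_of)
    _write_csv(table, outdir / "aggregates.csv")

    ratios = beadmod.loss_ratio(table)
    ratios["strain"] = ratios["bead_id"].map(
        lambda b: strain_of.get(b, "pooled"))
    _write_csv(ratios, outdir / "bead_ratios.csv")

    reg = beadmod.size_distance_regression(table)
    lmm = beadmod.size_by_status_lmm(table)
    report = pd.DataFrame([
        {"model": "size_distance_ols", "term": "slope",
         "estimate": reg["slope"], "se": reg["slope_se"], "p": reg["p"]},
        {"model": "size_distance_ols", "term": "intercept",
         "estimate": reg["intercept"], "se": reg["intercept_se"],
         "p": np.nan},
        {"model": "size_status_lmm", "term": "status_free",
         "estimate": lmm["status_effect"], "se": lmm["status_se"],
         "p": lmm["p"]},
    ])
    _write_csv(report, outdir / "models.csv")

    strains = sorted(set(strain_of.values()))
    welch = None
    per_bead = ratios[ratios["bead_id"] != "pooled"]
    if len(strains) == 2:
        a = per_bead.loc[per_bead["strain"] == strains[0], "ratio"]
        b = per_bead.loc[per_bead["strain"] == strains[1], "ratio"]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) >= 2 and len(b) >= 2:
            welch = facsmod.welch_t(a, b)

    if cfg.get("plots", True):
        from .plotting import plot_ratio_box, plot_size_distance

        plot_ratio_box(per_bead, outdir / "loss_ratio_box.png")
        plot_size_distance(table, reg, outdir / "size_vs_distance.png")

    pooled = ratios.loc[ratios["bead_id"] == "pooled", "ratio"].iloc[-1]
    payload = {
        "experiment": "bead",
        "n_beads": int(per_bead["bead_id"].nunique()),
        "n_aggregates_retained": int(table["retained"].sum()),
        "pooled_loss_ratio": float(pooled),
        "size_distance_slope": reg["slope"],
        "size_distance_slope_se": reg["slope_se"],
        "lmm_status_effect": lmm["status_effect"],
        "lmm_status_se": lmm["status_se"],
        "lmm_p": lmm["p"],
        "welch_strains": welch,
    }
    return _write_summary(outdir, cfg, seed, payload)


# ---------------------------------------------------------------------------
# FACS workflow
# ---------------------------------------------------------------------------

def simulate_event_tables(cfg: dict, seed: int
                          ) -> tuple[pd.DataFrame, pd.DataFrame,
                                     pd.DataFrame]:
    """Simulated controls and experiment events.

    Returns ``(carrier_control, free_control, events)``; events carry
    sample metadata and per-day true free fractions from the
    segregational-loss recursion per strain.
    """
    sim = cfg["facs"]["sim"]
    carrier_control = synth.generate_facs_events(synth.FacsTruth(
        n_events=sim["control_events"], free_fraction=0.0,
        debris_fraction=0.0, seed=_child_seed(seed, "facs", "ctrl_carrier")))
    free_control = synth.generate_facs_events(synth.FacsTruth(
        n_events=sim["control_events"], free_fraction=1.0,
        debris_fraction=0.0, seed=_child_seed(seed, "facs", "ctrl_free")))

    frames = []
    for strain, pars in sim["strains"].items():
        traj = synth.TrajectoryTruth(
            lambda_seg=pars["lambda_seg"], s_cost=pars["s_cost"],
            generations_per_day=sim["generations_per_day"],
            days=sim["days"], f0=0.0)
        expected = synth.expected_loss_fractions(traj)
        for plasmid in sim["plasmids"]:
            for bio in range(sim["n_bio_reps"]):
                for tech in range(sim["n_tech_reps"]):
                    for day in range(sim["days"] + 1):
                        truth = synth.FacsTruth(
                            n_events=sim["events_per_sample"],
                            free_fraction=float(expected[day]),
                            debris_fraction=sim["debris_fraction"],
                            seed=_child_seed(seed, "facs", strain, plasmid,
                                             bio, tech, day))
                        ev = synth.generate_facs_events(
                            truth,
                            metadata={"strain": strain, "plasmid": plasmid,
                                      "day": day, "bio_rep": bio,
                                      "tech_rep": tech})
                        frames.append(ev)
    return carrier_control, free_control, pd.concat(frames,
                                                    ignore_index=True)


def run_facs(cfg: dict, seed: int, outdir, events: pd.DataFrame = None,
             controls: tuple = None) -> dict:
    """FACS chain: gates from controls, per-sample loss fractions,
    trajectory aggregation, trend comparison, competition fitness."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fcfg = cfg["facs"]
    sim = fcfg["sim"]
    simulated = events is None
    if simulated:
        carrier_control, free_control, events = simulate_event_tables(cfg,
                                                                      seed)
    else:
        if controls is None:
            if "control" not in events.columns:
                raise ValueError(
                    "user event tables need a 'control' column "
                    "('carrier'/'free') or explicit control frames")
            carrier_control = events[events["control"] == "carrier"]
            free_control = events[events["control"] == "free"]
            events = events[~events["control"].isin(["carrier", "free"])]
        else:
            carrier_control, free_control = controls

    gates = facsmod.build_gates(carrier_control, free_control,
                                n_sd=fcfg["gate_n_sd"],
                                min_separation_sd=fcfg["min_separation_sd"])

    keys = ["strain", "plasmid", "bio_rep", "tech_rep", "day"]
    rows = []
    for vals, sub in events.groupby(keys):
        lf = facsmod.loss_fraction(sub, gates)
        rows.append(dict(zip(keys, vals)) | {
            "fraction": lf["fraction"], "ci_low": lf["ci"][0],
            "ci_high": lf["ci"][1], "n_gated": lf["n_gated"]})
    fractions = pd.DataFrame(rows)
    traj, summary_tbl = facsmod.aggregate_trajectory(fractions)
    _write_csv(fractions, outdir / "fractions.csv")
    _write_csv(traj, outdir / "trajectory.csv")
    _write_csv(summary_tbl, outdir / "trajectory_summary.csv")

    trend_rows = []
    for plasmid, sub in traj.groupby("plasmid"):
        if sub["strain"].nunique() == 2:
            res = facsmod.compare_trends(sub)
            trend_rows.append({
                "plasmid": plasmid, "groups": "|".join(res["groups"]),
                "interaction": res["interaction"],
                "se": res["interaction_se"], "t": res["t"], "p": res["p"]})
    trends = pd.DataFrame(trend_rows)
    if not trends.empty:
        _write_csv(trends, outdir / "trends.csv")

    fitness = None
    if simulated:
        # competition assay: both competitors grow exponentially, the
        # plasmid-free one with a (1 + s) per-generation advantage
        rng = np.random.default_rng(_child_seed(seed, "facs", "competition"))
        g = sim["competition_growth_per_gen"]
        G = sim["competition_generations"]
        s = list(sim["strains"].values())[0]["s_cost"]
        n0 = sim["competition_inoculum"]
        free_final = rng.poisson(n0 * (g * (1 + s)) ** G)
        car_final = rng.poisson(n0 * g ** G)
        fit = facsmod.relative_fitness(n0, free_final, n0, car_final)
        fitness = {"w": fit.w, "free_initial": n0,
                   "free_final": int(free_final), "carrier_initial": n0,
                   "carrier_final": int(car_final),
                   "s_cost_true": s, "flags": fit.flags}
        with open(outdir / "fitness.json", "w") as fh:
            json.dump(fitness, fh, indent=2, sort_keys=True)
            fh.write("\n")

    if cfg.get("plots", True):
        from .plotting import plot_trajectory

        plot_trajectory(summary_tbl, outdir / "trajectory.png")

    payload = {
        "experiment": "facs",
        "gates": {"green_cut": gates.green_cut, "red_cut": gates.red_cut},
        "n_samples": len(fractions),
        "final_day_fractions": {
            f"{r.strain}/{r.plasmid}": float(r.mean)
            for r in summary_tbl[summary_tbl["day"]
                                 == summary_tbl["day"].max()].itertuples()},
        "trends": trend_rows,
        "fitness": fitness,
    }
    return _write_summary(outdir, cfg, seed, payload)


def run_all(cfg: dict, seed: int, outdir) -> dict:
    """All three experiment chains on simulated inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {
        "flowcell": run_flowcell(cfg, seed, outdir / "flowcell"),
        "bead": run_bead(cfg, seed, outdir / "bead"),
        "facs": run_facs(cfg, seed, outdir / "facs"),
    }
    payload = {"experiment": "all",
               "bundles": {k: v["experiment"] for k, v in results.items()}}
    return _write_summary(outdir, cfg, seed, payload)
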