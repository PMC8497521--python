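"""Flow-cytometry gating, loss trajectories, trend tests and fitness.

Event tables carry one row per event with linear-scale green (GFP,
plasmid-free) and red (mCherry, plasmid-carrying) fluorescence intensities
plus sample metadata. Gates are rectangles in (log10 green, log10 red)
space constructed from single-population control samples: the per-channel
cut sits at the midpoint between the control population means and each
population rectangle extends to mean +/- 3 sd on its own side of the cuts;
events below both cuts are treated as debris, events in neither population
rectangle are left ungated.

Downstream: plasmid-free fractions with Wilson intervals, technical/
biological replicate averaging into day-resolved loss trajectories, a
linear-model comparison of loss trends between strains (the day x strain
interaction), Welch's t test, and relative fitness from competition counts
(ratio of realized Malthusian parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats

__all__ = [
    "GateSet",
    "FitnessResult",
    "build_gates",
    "classify_events",
    "loss_fraction",
    "aggregate_trajectory",
    "compare_trends",
    "welch_t",
    "relative_fitness",
    "REQUIRED_EVENT_COLUMNS",
]

REQUIRED_EVENT_COLUMNS = ("green", "red", "strain", "plasmid", "day",
                          "bio_rep", "tech_rep")


@dataclass
class GateSet:
    """Rectangular gates in (log10 green, log10 red) space.

    ``green_cut`` / ``red_cut`` are the midpoints between the control
    population means; each population rectangle is bounded by its cut on
    the side facing the other population and by mean +/- 3 sd elsewhere,
    so the carrier and free regions are disjoint by construction.
    """

    green_cut: float
    red_cut: float
    carrier_green: tuple[float, float]
    carrier_red: tuple[float, float]
    free_green: tuple[float, float]
    free_red: tuple[float, float]
    n_sd: float = 3.0

    def classify(self, green, red) -> np.ndarray:
        """Assign each event to carrier / free / debris / ungated."""
        lg = np.log10(np.maximum(np.asarray(green, dtype=float), 1e-12))
        lr = np.log10(np.maximum(np.asarray(red, dtype=float), 1e-12))
        out = np.full(lg.shape, "ungated", dtype=object)
        car = ((self.carrier_green[0] <= lg) & (lg <= self.carrier_green[1])
               & (self.carrier_red[0] <= lr) & (lr <= self.carrier_red[1]))
        fre = ((self.free_green[0] <= lg) & (lg <= self.free_green[1])
               & (self.free_red[0] <= lr) & (lr <= self.free_red[1]))
        deb = (lg < self.green_cut) & (lr < self.red_cut) & ~car & ~fre
        out[car] = "carrier"
        out[fre] = "free"
        out[deb] = "debris"
        return out


@dataclass
class FitnessResult:
    """Relative fitness of the plasmid-free vs plasmid-carrying competitor.

    w is the ratio of realized Malthusian parameters over the competition
    interval; w > 1 means the plasmid-free competitor outcompetes.
    """

    w: float
    free_initial: float
    free_final: float
    carrier_initial: float
    carrier_final: float
    flags: list[str]


def _log_stats(values) -> tuple[float, float]:
    lv = np.log10(np.maximum(np.asarray(values, dtype=float), 1e-12))
    return float(lv.mean()), float(lv.std(ddof=1))


def build_gates(carrier_control: pd.DataFrame, free_control: pd.DataFrame,
                n_sd: float = 3.0, min_separation_sd: float = 2.0) -> GateSet:
    """Place gates from pure carrier and pure plasmid-free controls.

    Each channel's cut is the midpoint between the two control means in
    log10 space. Controls whose means are closer than
    ``min_separation_sd`` pooled sds in either channel are rejected as not
    separable.
    """
    cg_m, cg_s = _log_stats(carrier_control["green"])
    cr_m, cr_s = _log_stats(carrier_control["red"])
    fg_m, fg_s = _log_stats(free_control["green"])
    fr_m, fr_s = _log_stats(free_control["red"])

    for name, (m1, s1, m2, s2) in {
        "green": (cg_m, cg_s, fg_m, fg_s),
        "red": (cr_m, cr_s, fr_m, fr_s),
    }.items():
        pooled = math.sqrt(0.5 * (s1 ** 2 + s2 ** 2))
        if abs(m1 - m2) < min_separation_sd * pooled:
            raise ValueError(
                f"populations not separable in the {name} channel "
                f"(means {abs(m1 - m2):.3f} apart, "
                f"< {min_separation_sd} sd = {min_separation_sd * pooled:.3f})")

    green_cut = 0.5 * (cg_m + fg_m)
    red_cut = 0.5 * (cr_m + fr_m)
    # carrier: green low / red high; free: green high / red low
    return GateSet(
        green_cut=green_cut,
        red_cut=red_cut,
        carrier_green=(cg_m - n_sd * cg_s, min(green_cut, cg_m + n_sd * cg_s)),
        carrier_red=(max(red_cut, cr_m - n_sd * cr_s), cr_m + n_sd * cr_s),
        free_green=(max(green_cut, fg_m - n_sd * fg_s), fg_m + n_sd * fg_s),
        free_red=(fr_m - n_sd * fr_s, min(red_cut, fr_m + n_sd * fr_s)),
        n_sd=n_sd,
    )


def classify_events(events: pd.DataFrame, gates: GateSet) -> pd.DataFrame:
    """Events with an added ``gate`` column."""
    out = events.copy()
    out["gate"] = gates.classify(out["green"].to_numpy(),
                                 out["red"].to_numpy())
    return out


def loss_fraction(events: pd.DataFrame, gates: GateSet,
                  level: float = 0.95) -> dict:
    """Plasmid-free fraction among gated cells, with a Wilson interval.

    Debris and ungated events are excluded: fraction =
    n_free / (n_free + n_carrier).
    """
    gate = gates.classify(events["green"].to_numpy(),
                          events["red"].to_numpy())
    n_free = int((gate == "free").sum())
    n_car = int((gate == "carrier").sum())
    n = n_free + n_car
    if n == 0:
        raise ValueError("no events in the carrier or free gates")
    frac = n_free / n
    lo, hi = stats.wilson_interval(n_free, n, level)
    return {"fraction": frac, "ci": (lo, hi), "n_free": n_free,
            "n_carrier": n_car, "n_gated": n}


def aggregate_trajectory(fractions: pd.DataFrame) -> tuple[pd.DataFrame,
                                                           pd.DataFrame]:
    """Average technical replicates; summarize biological replicates.

    ``fractions`` needs columns strain, plasmid, day, bio_rep, tech_rep,
    fraction. Returns ``(trajectory, summary)``: the trajectory holds one
    row per (strain, plasmid, bio_rep, day) with technical replicates
    averaged; the summary holds the per-day mean and standard error of the
    mean across biological replicates (the error bars of a trajectory
    plot).
    """
    needed = {"strain", "plasmid", "day", "bio_rep", "fraction"}
    missing = needed - set(fractions.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    keys = ["strain", "plasmid", "bio_rep", "day"]
    traj = (fractions.groupby(keys, as_index=False)["fraction"].mean()
            .sort_values(keys).reset_index(drop=True))
    summ = (traj.groupby(["strain", "plasmid", "day"])["fraction"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index())
    summ["sem"] = summ["sd"] / np.sqrt(summ["n"])
    return traj, summ


def compare_trends(trajectory: pd.DataFrame, group_col: str = "strain",
                   logit: bool = False) -> dict:
    """Compare loss trends between two groups by a linear model.

    Fits fraction ~ day * group on biological-replicate-level fractions
    (technical replicates pre-averaged); the day:group interaction
    coefficient is the difference in loss rate per day, tested by a t test.
    Fractions enter untransformed by default; ``logit=True`` applies an
    empirical logit for sensitivity analysis.
    """
    groups = np.unique(trajectory[group_col])
    if groups.size != 2:
        raise ValueError(f"need exactly 2 groups in {group_col!r}, "
                         f"got {list(groups)}")
    if trajectory.groupby(group_col)["day"].nunique().min() < 2:
        raise ValueError("need >= 2 days per group")
    y = trajectory["fraction"].to_numpy(dtype=float)
    if logit:
        eps = 0.5 / max(len(y), 1)
        yc = np.clip(y, eps, 1 - eps)
        y = np.log(yc / (1 - yc))
    day = trajectory["day"].to_numpy(dtype=float)
    g = (trajectory[group_col] == groups[1]).to_numpy().astype(float)
    X = np.column_stack([np.ones_like(day), day, g, day * g])
    names = ["intercept", "day", f"{group_col}[{groups[1]}]",
             f"day:{group_col}[{groups[1]}]"]
    fit = stats.ols(y, X, names=names)
    t, p = fit.t_test(3)
    return {"interaction": float(fit.coef[3]),
            "interaction_se": float(fit.se[3]),
            "t": t, "p": p, "df": fit.df_resid,
            "groups": (str(groups[0]), str(groups[1])), "fit": fit}


def welch_t(x, y) -> dict:
    """Two-tailed Welch's t test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean():
        # identical degenerate samples: no evidence of a difference
        return {"t": 0.0, "df": float(x.size + y.size - 2), "p": 1.0}
    res = sps.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue)}


def relative_fitness(free_initial: float, free_final: float,
                     carrier_initial: float, carrier_final: float
                     ) -> FitnessResult:
    """Relative fitness w of the plasmid-free competitor.

    w = ln(N_free_final / N_free_initial) / ln(N_carrier_final /
    N_carrier_initial): the ratio of realized Malthusian parameters over
    the competition interval. A competitor that did not grow makes the
    denominator non-positive; the result is flagged.
    """
    counts = {"free_initial": free_initial, "free_final": free_final,
              "carrier_initial": carrier_initial,
              "carrier_final": carrier_final}
    for name, v in counts.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    flags = []
    num = math.log(free_final / free_initial)
    den = math.log(carrier_final / carrier_initial)
    if den <= 0:
        flags.append("carrier competitor did not grow; w undefined")
        w = math.nan
    else:
        w = num / den
        if num <= 0:
            flags.append("free competitor did not grow")
    return FitnessResult(w=w, free_initial=free_initial,
                         free_final=free_final,
                         carrier_initial=carrier_initial,
                         carrier_final=carrier_final, flags=flags)


def read_events_csv(path) -> pd.DataFrame:
    """Read an event-table CSV, checking the documented column contract."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns "
                         f"{sorted(missing)}")
    return df
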