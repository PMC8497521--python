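"""Aggregate quantification in alginate-bead stacks.

In alginate beads every encapsulated founder cell grows into a discrete,
immobile microcolony ("aggregate"). From segmented two-channel stacks this
module detects aggregates per channel by 26-connected labeling, computes
physical volumes and centroid distances to the bead centre (the
coordinate-wise median of all foreground voxels), filters small or
out-of-bead aggregates, normalizes distances per bead by the maximum
retained distance, and fits the two summary models: an OLS regression of
log10 aggregate volume on normalized distance and a random-intercept mixed
model of log10 volume on plasmid status (random intercept per bead).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .imagecore import (
    CHANNEL_CARRIER,
    CHANNEL_FREE,
    BinaryMask,
    label_components,
)

__all__ = [
    "BeadCenter",
    "bead_center",
    "detect_aggregates",
    "filter_aggregates",
    "normalize_distances",
    "loss_ratio",
    "size_distance_regression",
    "size_by_status_lmm",
    "MIN_VOLUME_UM3",
]

#: default minimum aggregate volume retained, in um^3
MIN_VOLUME_UM3 = 50.0



def _retained(table: pd.DataFrame) -> pd.DataFrame:
    """Rows flagged retained; tables without the flag count fully."""
    if "retained" in table.columns:
        return table[table["retained"]]
    return table


@dataclass
class BeadCenter:
    """Bead centre: coordinate-wise median of all foreground voxels, in um."""

    z_um: float
    y_um: float
    x_um: float
    n_voxels: int

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.z_um, self.y_um, self.x_um])


def bead_center(free_mask: BinaryMask, carrier_mask: BinaryMask,
                voxel_size) -> BeadCenter:
    """Median position of all foreground voxels (union of both channels).

    The median is robust: a handful of stray voxels far from the bead do
    not move the centre, unlike a mean.
    """
    union = free_mask.foreground | carrier_mask.foreground
    idx = np.nonzero(union)
    n = idx[0].size
    if n == 0:
        raise ValueError("no foreground voxels; cannot locate bead centre")
    dz, dy, dx = voxel_size
    med = [float(np.median(ax)) for ax in idx]
    return BeadCenter(z_um=med[0] * dz, y_um=med[1] * dy, x_um=med[2] * dx,
                      n_voxels=int(n))


def _channel_aggregates(mask: BinaryMask, voxel_size, center: BeadCenter,
                        channel: str, connectivity: int) -> list[dict]:
    from scipy import ndimage as ndi

    lm = label_components(mask, connectivity=connectivity)
    if lm.n_components == 0:
        return []
    dz, dy, dx = voxel_size
    vol_vox = dz * dy * dx
    ids = np.arange(1, lm.n_components + 1)
    counts = ndi.sum_labels(np.ones_like(lm.labels), lm.labels, ids)
    centroids = ndi.center_of_mass(np.ones_like(lm.labels), lm.labels, ids)
    rows = []
    for lab, n_vox, (cz, cy, cx) in zip(ids, counts, centroids):
        c_um = np.array([cz * dz, cy * dy, cx * dx])
        rows.append({
            "label": int(lab),
            "channel": channel,
            "n_voxels": int(n_vox),
            "volume_um3": float(n_vox * vol_vox),
            "centroid_z_um": c_um[0],
            "centroid_y_um": c_um[1],
            "centroid_x_um": c_um[2],
            "distance_um": float(np.linalg.norm(c_um - center.coords)),
        })
    return rows


def detect_aggregates(free_mask: BinaryMask, carrier_mask: BinaryMask,
                      voxel_size, center: BeadCenter, bead_id=0,
                      connectivity: int = 26) -> pd.DataFrame:
    """Detect aggregates per channel by grouping adjacent voxels
    (diagonals included) and measure volume and distance to the centre.

    The two channels are labelled independently. Volume is voxel count
    times physical voxel volume; the centroid is the unweighted mean of
    voxel positions in um.
    """
    if free_mask.foreground.shape != carrier_mask.foreground.shape:
        raise ValueError("mask shapes differ")
    rows = (_channel_aggregates(free_mask, voxel_size, center,
                                CHANNEL_FREE, connectivity)
            + _channel_aggregates(carrier_mask, voxel_size, center,
                                  CHANNEL_CARRIER, connectivity))
    cols = ["bead_id", "label", "channel", "n_voxels", "volume_um3",
            "centroid_z_um", "centroid_y_um", "centroid_x_um", "distance_um"]
    df = pd.DataFrame.from_records(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    df.insert(0, "bead_id", bead_id)
    return df[cols]


def filter_aggregates(table: pd.DataFrame,
                      min_volume: float = MIN_VOLUME_UM3,
                      exclusion_factor: float = 1.1,
                      radius_quantile: float = 0.99,
                      bead_radius_um: float | None = None) -> pd.DataFrame:
    """Flag aggregates for retention.

    Discards aggregates *smaller than* ``min_volume`` (an aggregate of
    exactly ``min_volume`` is kept) and aggregates lying outside the bead.
    The bead radius, unless given, is estimated per bead as the
    ``radius_quantile`` quantile of the distances of size-retained
    aggregates (robust to stragglers); anything beyond
    ``exclusion_factor`` x radius is removed as outside. Removals keep their
    rows with a ``removal_reason``.
    """
    t = table.copy()
    if t.empty:
        t["retained"] = pd.Series(dtype=bool)
        t["removal_reason"] = pd.Series(dtype=object)
        return t
    big = t["volume_um3"] >= min_volume
    reasons = np.where(big, "", f"volume < {min_volume:g} um3")
    inside = np.ones(len(t), dtype=bool)
    for bead, sub in t.groupby("bead_id"):
        sel = t["bead_id"] == bead
        d = sub.loc[sub["volume_um3"] >= min_volume, "distance_um"]
        if bead_radius_um is not None:
            radius = bead_radius_um
        elif len(d):
            radius = float(np.quantile(d.to_numpy(), radius_quantile))
        else:
            continue
        limit = exclusion_factor * radius
        out = sel.to_numpy() & (t["distance_um"].to_numpy() > limit)
        inside &= ~out
        reasons = np.where(out & big.to_numpy(),
                           f"outside bead (> {limit:.1f} um)", reasons)
    t["retained"] = big.to_numpy() & inside
    t["removal_reason"] = reasons
    return t


def normalize_distances(table: pd.DataFrame) -> pd.DataFrame:
    """Per bead, divide retained distances by the maximum retained distance.

    The farthest retained aggregate of each bead maps to exactly 1. A bead
    with a single retained aggregate gets 1.0 with a flag in
    ``normalization_flag``.
    """
    t = table.copy()
    t["normalized_distance"] = np.nan
    t["normalization_flag"] = ""
    for bead, sub in _retained(t).groupby("bead_id"):
        if sub.empty:
            continue
        dmax = float(sub["distance_um"].max())
        if dmax <= 0:
            t.loc[sub.index, "normalized_distance"] = 1.0
            t.loc[sub.index, "normalization_flag"] = "all at centre"
            continue
        t.loc[sub.index, "normalized_distance"] = \
            sub["distance_um"].to_numpy() / dmax
        if len(sub) == 1:
            t.loc[sub.index, "normalization_flag"] = "single aggregate"
    return t


def loss_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Ratio of plasmid-free to plasmid-carrying aggregate counts.

    Returns one row per bead plus a pooled row; beads with zero carrier
    aggregates get an infinite ratio with a flag.
    """
    t = _retained(table)
    rows = []

    def _one(sub, bead):
        n_free = int((sub["channel"] == CHANNEL_FREE).sum())
        n_car = int((sub["channel"] == CHANNEL_CARRIER).sum())
        if n_car == 0:
            ratio, flag = (math.inf if n_free else math.nan), "no carrier"
        else:
            ratio, flag = n_free / n_car, ""
        rows.append({"bead_id": bead, "n_free": n_free, "n_carrier": n_car,
                     "ratio": ratio, "flag": flag})

    for bead, sub in t.groupby("bead_id"):
        _one(sub, bead)
    _one(t, "pooled")
    return pd.DataFrame(rows)


def size_distance_regression(table: pd.DataFrame,
                             level: float = 0.95) -> dict:
    """OLS of log10(volume um^3) on normalized distance, retained aggregates.

    Returns slope/intercept with standard errors and the confidence
    interval of the slope.
    """
    t = _retained(table)
    if len(t) < 3:
        raise ValueError("need at least 3 retained aggregates")
    d = t["normalized_distance"].to_numpy(dtype=float)
    if np.ptp(d) <= 0:
        raise ValueError("zero variance in normalized distance")
    y = np.log10(t["volume_um3"].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(d), d])
    fit = stats.ols(y, X, names=["intercept", "distance"])
    lo, hi = fit.conf_int(1, level)
    tstat, p = fit.t_test(1)
    return {"intercept": float(fit.coef[0]), "slope": float(fit.coef[1]),
            "intercept_se": float(fit.se[0]), "slope_se": float(fit.se[1]),
            "slope_ci": (lo, hi), "t": tstat, "p": p, "n": len(t),
            "fit": fit}


def size_by_status_lmm(table: pd.DataFrame) -> dict:
    """Plasmid-status effect on log10 volume, random intercept per bead.

    Fits log10(volume) ~ status + (1 | bead) by profile REML. The reported
    p-value is a normal approximation on estimate/SE (no small-sample df
    correction). With a single bead the fit falls back to OLS with a
    warning.
    """
    t = _retained(table)
    channels = set(t["channel"])
    if not {CHANNEL_FREE, CHANNEL_CARRIER} <= channels:
        raise ValueError("both plasmid statuses must be present")
    y = np.log10(t["volume_um3"].to_numpy(dtype=float))
    is_free = (t["channel"] == CHANNEL_FREE).to_numpy().astype(float)
    X = np.column_stack([np.ones_like(is_free), is_free])
    groups = t["bead_id"].to_numpy()
    if np.unique(groups).size < 2:
        warnings.warn("single bead: falling back to OLS", stacklevel=2)
    fit = stats.reml_random_intercept(y, X, groups,
                                      names=["intercept", "status_free"])
    z, p = fit.z_test(1)
    return {"status_effect": float(fit.coef[1]),
            "status_se": float(fit.se[1]),
            "z": z, "p": p,
            "sigma_b2": fit.sigma_b2, "sigma_e2": fit.sigma_e2,
            "n_beads": fit.n_groups, "n": fit.n_obs,
            "method": fit.method, "fit": fit}
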