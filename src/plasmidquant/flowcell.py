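"""Depth-resolved plasmid loss in flow-cell biofilms.

Segmented two-channel stacks are reduced to per-layer voxel counts of
plasmid-free (green) and plasmid-carrying (red) cells. Layer positions are
recentred by subtracting the biomass-weighted mean z so that corrected
position 0 marks the biomass centre and different images become comparable.
From the recentred profiles the module produces:

* per-layer loss proportions p(z) = n_free / (n_free + n_carrier),
* biomass-weighted LOESS loss curves (one per biological replicate),
* the top/bottom stratification statistic — free:carrier ratios aggregated
  over the strata above and below corrected z = 0, each holding half the
  biomass — and a two-way ANOVA over stratum and plasmid variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .imagecore import BinaryMask

__all__ = [
    "ZProfile",
    "LossCurve",
    "StratifiedRatios",
    "layer_profile",
    "recenter_z",
    "average_replicates",
    "loss_proportion",
    "weighted_loess",
    "split_top_bottom",
    "compare_strata",
]


@dataclass
class ZProfile:
    """Per-layer voxel counts along the vertical axis of one stack.

    ``z`` is the layer index in image order; ``z_corrected`` (set by
    :func:`recenter_z`) is the biomass-weighted recentred position.
    Counts may be fractional after replicate averaging.
    """

    z: np.ndarray
    n_free: np.ndarray
    n_carrier: np.ndarray
    z_corrected: np.ndarray | None = None
    mode_z_corrected: float | None = None  # diagnostic: modal layer position

    def __post_init__(self):
        self.z = np.asarray(self.z)
        self.n_free = np.asarray(self.n_free, dtype=float)
        self.n_carrier = np.asarray(self.n_carrier, dtype=float)
        if not (self.z.shape == self.n_free.shape == self.n_carrier.shape):
            raise ValueError("profile arrays must share shape")
        if np.any(self.n_free < 0) or np.any(self.n_carrier < 0):
            raise ValueError("counts must be non-negative")
        if self.z_corrected is not None:
            self.z_corrected = np.asarray(self.z_corrected, dtype=float)

    @property
    def biomass(self) -> np.ndarray:
        return self.n_free + self.n_carrier

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"z": self.z, "n_free": self.n_free,
                           "n_carrier": self.n_carrier,
                           "biomass": self.biomass})
        if self.z_corrected is not None:
            df["z_corrected"] = self.z_corrected
        df["p_free"] = loss_proportion(self)
        return df


@dataclass
class LossCurve:
    """Biomass-weighted LOESS fit of the loss proportion against corrected z."""

    x: np.ndarray
    fitted_raw: np.ndarray
    span: float
    replicate: str = ""

    @property
    def fitted(self) -> np.ndarray:
        """Fitted proportions clipped to [0, 1] for reporting."""
        return np.clip(self.fitted_raw, 0.0, 1.0)


@dataclass
class StratifiedRatios:
    """Free:carrier voxel ratios aggregated over the top and bottom strata.

    ``boundary``: "bottom = z_corrected < 0, top = z_corrected >= 0"; the
    layer at exactly 0 goes to the top. Infinite ratios (no carrier voxels
    in a stratum) are flagged.
    """

    top_ratio: float
    bottom_ratio: float
    top_biomass: float
    bottom_biomass: float
    top_free: float
    top_carrier: float
    bottom_free: float
    bottom_carrier: float
    boundary_biomass: float
    flags: list[str] = field(default_factory=list)


def layer_profile(free_mask: BinaryMask, carrier_mask: BinaryMask) -> ZProfile:
    """Count foreground voxels per layer for each channel."""
    f = free_mask.foreground
    c = carrier_mask.foreground
    if f.shape != c.shape:
        raise ValueError(f"mask shapes differ: {f.shape} vs {c.shape}")
    return ZProfile(
        z=np.arange(f.shape[0]),
        n_free=f.sum(axis=(1, 2)).astype(float),
        n_carrier=c.sum(axis=(1, 2)).astype(float),
    )


def recenter_z(profile: ZProfile) -> ZProfile:
    """Shift layer positions by the biomass-weighted mean z.

    After the shift the biomass-weighted mean of ``z_corrected`` is zero, so
    corrected position 0 marks the biomass centre. (The modal layer — the
    single layer with the most biomass — need not land at 0; its corrected
    position is kept as a diagnostic.)
    """
    b = profile.biomass
    total = b.sum()
    if total <= 0:
        raise ValueError("zero total biomass; cannot recenter")
    z = profile.z.astype(float)
    shift = float((z * b).sum() / total)
    zc = z - shift
    mode = float(zc[int(np.argmax(b))])
    return ZProfile(z=profile.z, n_free=profile.n_free,
                    n_carrier=profile.n_carrier, z_corrected=zc,
                    mode_z_corrected=mode)


def average_replicates(profiles: list[ZProfile]) -> ZProfile:
    """Average per-layer counts across the images of one biological replicate.

    Profiles are aligned on corrected z by binning to unit-layer bins
    centred on integers; a bin absent from an image contributes zero counts
    for that image.
    """
    if not profiles:
        raise ValueError("empty replicate group")
    for p in profiles:
        if p.z_corrected is None:
            raise ValueError("profiles must be recentred before averaging")
    # half-up rounding (not banker's) so half-integer corrected positions
    # map to distinct adjacent bins
    bins = [np.floor(p.z_corrected + 0.5).astype(int) for p in profiles]
    lo = min(b.min() for b in bins)
    hi = max(b.max() for b in bins)
    grid = np.arange(lo, hi + 1)
    free = np.zeros(grid.size)
    carrier = np.zeros(grid.size)
    for p, b in zip(profiles, bins):
        free += np.bincount(b - lo, weights=p.n_free, minlength=grid.size)
        carrier += np.bincount(b - lo, weights=p.n_carrier,
                               minlength=grid.size)
    m = len(profiles)
    return ZProfile(z=grid, n_free=free / m, n_carrier=carrier / m,
                    z_corrected=grid.astype(float))


def loss_proportion(profile: ZProfile) -> np.ndarray:
    """Per-layer plasmid-free proportion; NaN where the layer is empty."""
    b = profile.biomass
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(b > 0, profile.n_free / np.where(b > 0, b, 1.0), np.nan)
    return p


def weighted_loess(profile: ZProfile, span: float = 0.75, degree: int = 2,
                   xout=None, replicate: str = "") -> LossCurve:
    """Biomass-weighted LOESS of the loss proportion against corrected z."""
    if profile.z_corrected is None:
        raise ValueError("profile must be recentred before smoothing")
    p = loss_proportion(profile)
    keep = np.isfinite(p)
    x = profile.z_corrected[keep]
    if xout is None:
        xout = x
    fitted = stats.loess(x, p[keep], weights=profile.biomass[keep],
                         span=span, degree=degree, xout=xout)
    return LossCurve(x=np.asarray(xout, dtype=float), fitted_raw=fitted,
                     span=span, replicate=replicate)


def _ratio(free: float, carrier: float, name: str, flags: list[str]) -> float:
    if carrier <= 0:
        if free > 0:
            flags.append(f"{name}: no carrier voxels; ratio infinite")
            return math.inf
        flags.append(f"{name}: empty stratum")
        return math.nan
    return free / carrier


def split_top_bottom(profile: ZProfile) -> StratifiedRatios:
    """Free:carrier ratios aggregated over the strata above/below corrected 0.

    Counts are summed within each stratum before forming the ratio, which is
    equivalent to biomass-weighting the per-layer ratios. The two stratum
    biomasses can differ by at most the boundary layer's biomass (the
    discretization limit of the half-biomass split).
    """
    if profile.z_corrected is None:
        raise ValueError("profile must be recentred before stratifying")
    zc = profile.z_corrected
    top = zc >= 0
    bottom = ~top
    flags: list[str] = []
    b = profile.biomass
    # boundary layer: first layer at or above 0 (ties go to top)
    above = np.where(top & (b > 0))[0]
    boundary_biomass = float(b[above[np.argmin(zc[above])]]) if above.size \
        else 0.0
    top_free = float(profile.n_free[top].sum())
    top_car = float(profile.n_carrier[top].sum())
    bot_free = float(profile.n_free[bottom].sum())
    bot_car = float(profile.n_carrier[bottom].sum())
    return StratifiedRatios(
        top_ratio=_ratio(top_free, top_car, "top", flags),
        bottom_ratio=_ratio(bot_free, bot_car, "bottom", flags),
        top_biomass=top_free + top_car,
        bottom_biomass=bot_free + bot_car,
        top_free=top_free, top_carrier=top_car,
        bottom_free=bot_free, bottom_carrier=bot_car,
        boundary_biomass=boundary_biomass,
        flags=flags,
    )


def strata_table(ratios_by_image: dict) -> pd.DataFrame:
    """Long-format table of stratum ratios for the ANOVA.

    ``ratios_by_image`` maps ``(image_id, plasmid)`` to
    :class:`StratifiedRatios`.
    """
    rows = []
    for (image_id, plasmid), r in ratios_by_image.items():
        rows.append({"image": image_id, "plasmid": plasmid,
                     "stratum": "top", "ratio": r.top_ratio})
        rows.append({"image": image_id, "plasmid": plasmid,
                     "stratum": "bottom", "ratio": r.bottom_ratio})
    return pd.DataFrame(rows)


def compare_strata(table: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of stratum ratios (no interaction).

    ``table`` needs columns ``ratio``, ``stratum``, ``plasmid``. Main-effect
    F statistics and p-values for stratum (top vs bottom) and plasmid
    variant are returned; non-finite ratios are dropped with a flag row.
    """
    t = table.copy()
    finite = np.isfinite(t["ratio"].to_numpy(dtype=float))
    t = t[finite]
    n_per = t.groupby(["stratum", "plasmid"]).size()
    if (n_per < 2).any():
        import warnings

        warnings.warn("fewer than 2 observations in some design cells",
                      stacklevel=2)
    return stats.two_way_anova(t["ratio"].to_numpy(dtype=float),
                               t["stratum"].to_numpy(),
                               t["plasmid"].to_numpy(),
                               names=("stratum", "plasmid"))
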