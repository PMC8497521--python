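"""Synthetic-data generators with known ground truth.

The real experiments image dual-labelled *Pseudomonas putida*: plasmid-
carrying cells fluoresce red (plasmid-encoded mCherry) and cells that have
lost the plasmid fluoresce green (chromosomal GFP de-repressed once the
plasmid-encoded LacI^q is gone). These generators emulate the raw inputs of
the three quantification pipelines so every stage has a recoverable target:

* flow-cell biofilm z-stacks whose plasmid-free proportion varies with depth,
* alginate-bead stacks of discrete spherical aggregates whose log10 size
  grows with radial distance and differs by plasmid status,
* flow-cytometry event tables drawn from a carrier/free/debris log-normal
  mixture,
* multi-day plasmid-loss trajectories from a segregational-loss recursion.

None of these generative forms is measured by the underlying experiments;
they are modelling choices matched to the statistical structure the
analyses assume (binomial channel assignment, log-normal fluorescence,
log-linear size model). The ground truth returned alongside each dataset is
the oracle for the recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .imagecore import CHANNEL_CARRIER, CHANNEL_FREE, VoxelImage

__all__ = [
    "FlowcellTruth",
    "BeadTruth",
    "FacsTruth",
    "TrajectoryTruth",
    "generate_flowcell_stack",
    "generate_bead_stack",
    "generate_facs_events",
    "generate_loss_timecourse",
    "expected_loss_fractions",
    "step_profile",
    "DEFAULT_FACS_PARAMS",
]


def _resolve_profile(profile, n: int) -> np.ndarray:
    if callable(profile):
        return np.asarray([float(profile(z)) for z in range(n)], dtype=float)
    arr = np.asarray(profile, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"profile has shape {arr.shape}, expected ({n},)")
    return arr


def step_profile(low: float, high: float, n_layers: int) -> np.ndarray:
    """Two-plateau loss profile: ``low`` in the bottom half of the stack,
    ``high`` in the top half (image order: layer 0 = bottom)."""
    p = np.full(n_layers, low, dtype=float)
    p[n_layers // 2:] = high
    return p


# ---------------------------------------------------------------------------
# flow-cell stacks
# ---------------------------------------------------------------------------

@dataclass
class FlowcellTruth:
    """Generative parameters for a flow-cell biofilm stack.

    ``loss_profile`` maps layer index z to the true plasmid-free proportion;
    ``biomass_profile`` gives the foreground voxel count per layer. Both may
    be arrays of length ``n_layers`` or callables of z. Default voxel sizes
    are plausible for a 63x/1.4 oil objective.
    """

    n_layers: int = 40
    shape_yx: tuple[int, int] = (96, 96)
    loss_profile: np.ndarray | Callable = field(
        default_factory=lambda: step_profile(0.05, 0.30, 40))
    biomass_profile: np.ndarray | Callable = 2000.0
    voxel_size: tuple[float, float, float] = (0.5, 0.2, 0.2)
    # 12-bit-detector-like contrast: signal ~1000 counts over a dim, narrow
    # background; foreground occupies ~20% of a layer by default
    noise_mean: float = 10.0
    noise_sd: float = 2.0
    fg_intensity: float = 1000.0
    seed: int = 0

    def resolved(self) -> tuple[np.ndarray, np.ndarray]:
        p = _resolve_profile(self.loss_profile, self.n_layers)
        if np.isscalar(self.biomass_profile):
            b = np.full(self.n_layers, float(self.biomass_profile))
        else:
            b = _resolve_profile(self.biomass_profile, self.n_layers)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("loss profile must lie in [0, 1]")
        if np.any(b < 0):
            raise ValueError("biomass profile must be non-negative")
        if not np.any(b > 0):
            raise ValueError("biomass profile is identically zero")
        return p, b


def generate_flowcell_stack(truth: FlowcellTruth
                            ) -> tuple[VoxelImage, pd.DataFrame]:
    """Render a two-channel flow-cell stack plus the true per-layer counts.

    Per layer z, ``round(B(z))`` distinct voxel positions become foreground;
    each is assigned to the green (plasmid-free) channel with probability
    ``p_loss(z)`` and to the red channel otherwise. Gaussian background
    noise (clipped at zero) is added to both channels. Before noise, the
    summed true counts per layer equal the rendered foreground voxels
    exactly.
    """
    p_loss, biomass = truth.resolved()
    ny, nx = truth.shape_yx
    rng = np.random.default_rng(truth.seed)
    red = np.zeros((truth.n_layers, ny, nx))
    green = np.zeros_like(red)
    records = []
    for z in range(truth.n_layers):
        n_fg = int(round(biomass[z]))
        if n_fg > ny * nx:
            raise ValueError(f"layer {z}: biomass {n_fg} exceeds layer size")
        if n_fg > 0:
            flat = rng.choice(ny * nx, size=n_fg, replace=False)
            is_free = rng.random(n_fg) < p_loss[z]
            yy, xx = np.unravel_index(flat, (ny, nx))
            green[z, yy[is_free], xx[is_free]] = truth.fg_intensity
            red[z, yy[~is_free], xx[~is_free]] = truth.fg_intensity
            n_free = int(is_free.sum())
        else:
            n_free = 0
        records.append({"z": z, "n_free": n_free, "n_carrier": n_fg - n_free,
                        "p_loss_true": p_loss[z]})
    for arr in (red, green):
        noise = rng.normal(truth.noise_mean, truth.noise_sd, arr.shape)
        arr += np.clip(noise, 0.0, None)
    img = VoxelImage(channels={CHANNEL_CARRIER: red, CHANNEL_FREE: green},
                     voxel_size=truth.voxel_size)
    return img, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# alginate-bead stacks
# ---------------------------------------------------------------------------

@dataclass
class BeadTruth:
    """Generative parameters for one alginate-bead stack.

    Each founder cell grows into a single discrete microcolony, rendered
    here as a voxelized sphere (sphericity makes the volume ground truth
    analytic). ``size_model`` maps plasmid status to (intercept, slope) of
    log10(volume um^3) against normalized radial distance. Default voxel
    sizes are plausible for a 10x/0.30 objective.
    """

    shape: tuple[int, int, int] = (80, 192, 192)
    radius_um: float = 80.0
    n_aggregates: int = 60
    size_model: dict = field(default_factory=lambda: {
        "free": (2.9, 0.8), "carrier": (2.6, 0.8)})
    size_sd: float = 0.2          # log10 residual sd
    free_fraction: float = 0.25
    voxel_size: tuple[float, float, float] = (2.0, 1.0, 1.0)
    center_vox: tuple[float, float, float] | None = None
    noise_mean: float = 5.0
    noise_sd: float = 2.0
    fg_intensity: float = 1000.0
    min_gap_um: float | None = None   # default: 2 x largest voxel dimension
    max_tries: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if not 0.0 <= self.free_fraction <= 1.0:
            raise ValueError("free_fraction must be in [0, 1]")
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be >= 0")


def _render_sphere(channel_arr, center_vox, radius_um, voxel_size, value):
    """Set voxels whose physical center lies within ``radius_um`` of the
    sphere center; returns (voxel count, surface voxel count, centroid_vox)."""
    from scipy import ndimage as ndi

    dz, dy, dx = voxel_size
    cz, cy, cx = center_vox
    ez, ey, ex = radius_um / dz, radius_um / dy, radius_um / dx
    z0, z1 = int(math.floor(cz - ez)) - 1, int(math.ceil(cz + ez)) + 2
    y0, y1 = int(math.floor(cy - ey)) - 1, int(math.ceil(cy + ey)) + 2
    x0, x1 = int(math.floor(cx - ex)) - 1, int(math.ceil(cx + ex)) + 2
    z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
    z1 = min(z1, channel_arr.shape[0])
    y1 = min(y1, channel_arr.shape[1])
    x1 = min(x1, channel_arr.shape[2])
    zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    d2 = (((zz - cz) * dz) ** 2 + ((yy - cy) * dy) ** 2
          + ((xx - cx) * dx) ** 2)
    inside = d2 <= radius_um ** 2
    if not inside.any():
        # sphere smaller than one voxel: render the nearest voxel
        iz, iy, ix = (int(round(cz)), int(round(cy)), int(round(cx)))
        channel_arr[iz, iy, ix] = value
        return 1, 1, (float(iz), float(iy), float(ix))
    core = ndi.binary_erosion(inside)
    n_surface = int(inside.sum() - core.sum())
    channel_arr[z0:z1, y0:y1, x0:x1][inside] = value
    centroid = (float(zz[inside].mean()), float(yy[inside].mean()),
                float(xx[inside].mean()))
    return int(inside.sum()), n_surface, centroid


def generate_bead_stack(truth: BeadTruth) -> tuple[VoxelImage, pd.DataFrame]:
    """Render spherical aggregates inside a bead and return the truth table.

    Aggregates are placed by rejection sampling at uniform normalized radial
    distances with volumes from the log-linear size model; placements that
    would overlap (or leave the image) are retried up to ``max_tries`` times
    before an error.
    """
    dz, dy, dx = truth.voxel_size
    nz, ny, nx = truth.shape
    rng = np.random.default_rng(truth.seed)
    center = truth.center_vox or ((nz - 1) / 2.0, (ny - 1) / 2.0,
                                  (nx - 1) / 2.0)
    min_gap = (truth.min_gap_um if truth.min_gap_um is not None
               else 2.0 * max(truth.voxel_size))

    red = np.zeros(truth.shape)
    green = np.zeros(truth.shape)
    placed = []   # (center_um(z,y,x), radius_um)
    records = []
    center_um = np.array([center[0] * dz, center[1] * dy, center[2] * dx])

    for i in range(truth.n_aggregates):
        status = "free" if rng.random() < truth.free_fraction else "carrier"
        icpt, slope = truth.size_model[status]
        ok = False
        for _ in range(truth.max_tries):
            d = rng.random()
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos_um = center_um + d * truth.radius_um * u
            log10v = icpt + slope * d + truth.size_sd * rng.normal()
            vol = 10.0 ** log10v
            r_um = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
            pos_vox = np.array([pos_um[0] / dz, pos_um[1] / dy,
                                pos_um[2] / dx])
            ext = np.array([r_um / dz, r_um / dy, r_um / dx]) + 1.0
            if (np.any(pos_vox - ext < 0)
                    or np.any(pos_vox + ext > np.array(truth.shape) - 1)):
                continue
            if any(np.linalg.norm(pos_um - c) <= r_um + r + min_gap
                   for c, r in placed):
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place aggregate {i} without overlap after "
                f"{truth.max_tries} tries; reduce n_aggregates or sizes")
        placed.append((pos_um, r_um))
        arr = green if status == "free" else red
        n_vox, n_surf, centroid_vox = _render_sphere(
            arr, pos_vox, r_um, truth.voxel_size, truth.fg_intensity)
        records.append({
            "aggregate_id": i,
            "channel": CHANNEL_FREE if status == "free" else CHANNEL_CARRIER,
            "status": status,
            "norm_distance_true": d,
            "volume_true_um3": vol,
            "n_voxels_rendered": n_vox,
            "volume_rendered_um3": n_vox * dz * dy * dx,
            "surface_voxels": n_surf,
            "centroid_z_um": centroid_vox[0] * dz,
            "centroid_y_um": centroid_vox[1] * dy,
            "centroid_x_um": centroid_vox[2] * dx,
            "distance_um": float(d * truth.radius_um),
        })
    for arr in (red, green):
        noise = rng.normal(truth.noise_mean, truth.noise_sd, arr.shape)
        arr += np.clip(noise, 0.0, None)
    img = VoxelImage(channels={CHANNEL_CARRIER: red, CHANNEL_FREE: green},
                     voxel_size=truth.voxel_size)
    cols = ["aggregate_id", "channel", "status", "norm_distance_true",
            "volume_true_um3", "n_voxels_rendered", "volume_rendered_um3",
            "surface_voxels", "centroid_z_um", "centroid_y_um",
            "centroid_x_um", "distance_um"]
    return img, pd.DataFrame.from_records(records, columns=cols)


# ---------------------------------------------------------------------------
# FACS event tables
# ---------------------------------------------------------------------------

#: per-class (log10 green mean, green sd, log10 red mean, red sd); the
#: carrier/free separation mirrors a clean dual-label reporter readout
DEFAULT_FACS_PARAMS = {
    "carrier": (1.5, 0.15, 3.0, 0.15),
    "free": (3.0, 0.15, 1.5, 0.15),
    "debris": (0.8, 0.3, 0.8, 0.3),
}


@dataclass
class FacsTruth:
    """Generative parameters for a flow-cytometry event table."""

    n_events: int = 10_000
    free_fraction: float = 0.1
    debris_fraction: float = 0.05
    params: dict = field(default_factory=lambda: dict(DEFAULT_FACS_PARAMS))
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.free_fraction <= 1.0:
            raise ValueError("free_fraction must be in [0, 1]")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise ValueError("debris_fraction must be in [0, 1)")
        for cls, (gm, gs, rm, rs) in self.params.items():
            if gs <= 0 or rs <= 0:
                raise ValueError(f"class {cls!r}: sds must be positive")


def generate_facs_events(truth: FacsTruth, metadata: dict | None = None
                         ) -> pd.DataFrame:
    """Draw events from the carrier/free/debris log-normal mixture.

    Returns one row per event with linear-scale ``green`` and ``red``
    intensities, the drawn ``true_class`` (for validation), and any
    ``metadata`` columns broadcast over rows.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_events
    classes = np.empty(n, dtype=object)
    u = rng.random(n)
    is_debris = u < truth.debris_fraction
    u2 = rng.random(n)
    classes[:] = "carrier"
    classes[u2 < truth.free_fraction] = "free"
    classes[is_debris] = "debris"

    green = np.empty(n)
    red = np.empty(n)
    for cls, (gm, gs, rm, rs) in truth.params.items():
        idx = classes == cls
        m = int(idx.sum())
        if m:
            green[idx] = 10.0 ** rng.normal(gm, gs, m)
            red[idx] = 10.0 ** rng.normal(rm, rs, m)
    df = pd.DataFrame({"green": green, "red": red, "true_class": classes})
    if metadata:
        for key, val in metadata.items():
            df[key] = val
    return df


# ---------------------------------------------------------------------------
# loss trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryTruth:
    """Parameters of the segregational-loss recursion.

    Per generation the plasmid-free fraction f evolves as

        f' = (f (1 + s) + (1 - f) lambda) / (f (1 + s) + (1 - f))

    where ``lambda_seg`` is the per-division probability of segregational
    loss and ``s_cost`` the per-generation growth advantage of plasmid-free
    cells (the cost of carriage).
    """

    lambda_seg: float = 1e-3
    s_cost: float = 0.05
    generations_per_day: float = 10.0
    days: int = 4
    f0: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.lambda_seg <= 1.0:
            raise ValueError("lambda_seg must be in [0, 1]")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must be in [0, 1]")


def _step(f: float, lam: float, s: float) -> float:
    num = f * (1.0 + s) + (1.0 - f) * lam
    den = f * (1.0 + s) + (1.0 - f)
    return num / den


def expected_loss_fractions(truth: TrajectoryTruth) -> np.ndarray:
    """Deterministic plasmid-free fraction at days 0..days."""
    f = truth.f0
    out = [f]
    g_per_day = truth.generations_per_day
    for _ in range(truth.days):
        n_whole = int(g_per_day)
        for _ in range(n_whole):
            f = _step(f, truth.lambda_seg, truth.s_cost)
        frac = g_per_day - n_whole
        if frac > 0:
            # fractional generation: linear interpolation of one step
            f = f + frac * (_step(f, truth.lambda_seg, truth.s_cost) - f)
        out.append(f)
    return np.asarray(out)


def generate_loss_timecourse(truth: TrajectoryTruth, sampling_n: int,
                             seed: int = 0) -> pd.DataFrame:
    """Expected and binomially sampled plasmid-free fraction per day.

    ``sampling_n`` cells are scored per day; with p = 0 or 1 the sampled
    fraction is noise-free.
    """
    if sampling_n < 1:
        raise ValueError("sampling_n must be >= 1")
    rng = np.random.default_rng(seed)
    expected = expected_loss_fractions(truth)
    days = np.arange(truth.days + 1)
    observed = rng.binomial(sampling_n, expected) / sampling_n
    return pd.DataFrame({"day": days, "f_expected": expected,
                         "f_observed": observed})
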