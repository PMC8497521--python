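"""Shared 3D image primitives.

Two-channel confocal stacks are represented as :class:`VoxelImage` — one 3D
``(z, y, x)`` intensity array per fluorescence channel plus anisotropic
voxel dimensions in micrometres. The red channel (mCherry) marks
plasmid-carrying cells; the green channel (GFP) marks cells that have lost
the plasmid.

Primitives: 3x3x3 median smoothing, histogram auto-thresholding
(Otsu / Yen / Moments), channel segmentation, and 26-connected component
labeling ("grouping adjacent voxels including diagonals").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi

__all__ = [
    "CHANNEL_CARRIER",
    "CHANNEL_FREE",
    "VoxelImage",
    "BinaryMask",
    "LabelMap",
    "median_smooth_3d",
    "auto_threshold",
    "segment_channel",
    "label_components",
    "read_stack",
    "write_stack",
    "write_mask",
]

#: channel label conventions: red fluorescence = plasmid-carrying,
#: green fluorescence = plasmid-free
CHANNEL_CARRIER = "red"
CHANNEL_FREE = "green"

THRESHOLD_METHODS = ("otsu", "yen", "moments")


@dataclass
class VoxelImage:
    """Two-channel 3D intensity stack with physical voxel dimensions."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) in um

    def __post_init__(self):
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not 3D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"channel {name!r} has non-finite or "
                                 "negative intensities")
            self.channels[name] = arr
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (um)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {list(self.channels)}")
        return self.channels[name]


@dataclass
class BinaryMask:
    """Segmented foreground for one channel, with threshold provenance."""

    foreground: np.ndarray
    channel: str
    method: str = ""
    threshold: float = float("nan")

    def __post_init__(self):
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if self.foreground.ndim != 3:
            raise ValueError("mask must be 3D")


@dataclass
class LabelMap:
    """Connected components: 0 = background, 1..K in raster order of the
    component's first voxel."""

    labels: np.ndarray
    n_components: int
    connectivity: int = 26


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def median_smooth_3d(img: np.ndarray) -> np.ndarray:
    """3x3x3 median filter with edge replication at the stack borders."""
    img = np.asarray(img)
    if img.ndim != 3 or min(img.shape) < 1:
        raise ValueError("expected a non-empty 3D array")
    return ndi.median_filter(img, size=3, mode="nearest")


# ---------------------------------------------------------------------------
# auto-thresholding
# ---------------------------------------------------------------------------

def intensity_histogram(data, nbins: int = 256):
    """Histogram (counts, bin centers) for thresholding.

    Data with at most ``nbins`` distinct values get one exact bin per value
    (no empty bins); otherwise ``nbins`` uniform bins over the range.
    """
    data = np.asarray(data).ravel()
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("degenerate histogram: constant intensities")
    uniq, uniq_counts = np.unique(data, return_counts=True)
    if uniq.size <= nbins:
        # exact-value bins: no empty bins, thresholds fall midway between
        # the actually occurring intensity levels
        return uniq_counts.astype(float), uniq.astype(float)
    counts, edges = np.histogram(data, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def _criterion_otsu(p, c):
    """Between-class variance for every cut k (classes {<=k}, {>k})."""
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    m = np.cumsum(p * c)
    mu_t = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m[:-1] / w0
        mu1 = (mu_t - m[:-1]) / w1
        crit = w0 * w1 * (mu0 - mu1) ** 2
    crit[(w0 <= 0) | (w1 <= 0)] = -np.inf
    return crit


def _criterion_yen(p, c):
    """Yen's maximum-correlation criterion for every cut k."""
    P1 = np.cumsum(p)[:-1]
    sq = np.cumsum(p * p)
    P1sq = sq[:-1]
    P2sq = sq[-1] - sq[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = (-np.log(P1sq * P2sq)
                + 2.0 * np.log(P1 * (1.0 - P1)))
    bad = (P1 <= 0) | (P1 >= 1) | (P1sq <= 0) | (P2sq <= 0)
    crit[bad] = -np.inf
    return crit


def _cut_moments(p, c):
    """Tsai's moment-preserving cut index.

    Finds the two-level image preserving the first three gray-level moments
    and returns the cut k such that the lower class holds the p0 fraction of
    the mass.
    """
    m1 = float(np.sum(p * c))
    m2 = float(np.sum(p * c ** 2))
    m3 = float(np.sum(p * c ** 3))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram: zero variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise ValueError("moments method failed: negative discriminant")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("moments method failed: coincident levels")
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    k = int(np.searchsorted(cum, p0, side="right"))
    return min(max(k, 0), p.size - 2)


def auto_threshold(data, method: str = "otsu", nbins: int = 256) -> float:
    """Histogram auto-threshold; foreground is ``intensity > t``.

    ``data`` may be an intensity array or a precomputed ``(counts, centers)``
    pair. The cut is chosen by exhaustive evaluation of the method's
    criterion over all candidate cuts (ties broken toward the lowest
    candidate) and the returned threshold is the midpoint between the last
    bin of the lower class and the first bin of the upper class.
    """
    method = method.lower()
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"unknown method {method!r}; "
                         f"choose from {THRESHOLD_METHODS}")
    if isinstance(data, tuple):
        counts, centers = data
        counts = np.asarray(counts, dtype=float)
        centers = np.asarray(centers, dtype=float)
    else:
        counts, centers = intensity_histogram(data, nbins=nbins)
    if centers.size < 2 or np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: need >=2 distinct values")
    p = counts / counts.sum()

    if method == "otsu":
        k = int(np.argmax(_criterion_otsu(p, centers)))
    elif method == "yen":
        k = int(np.argmax(_criterion_yen(p, centers)))
    else:
        k = _cut_moments(p, centers)
    return float(0.5 * (centers[k] + centers[k + 1]))


def segment_channel(img: VoxelImage, channel: str, method: str = "otsu",
                    smooth: bool = False, nbins: int = 256) -> BinaryMask:
    """Optional 3x3x3 median smoothing then auto-thresholding of a channel."""
    arr = img.channel(channel)
    if smooth:
        arr = median_smooth_3d(arr)
    try:
        t = auto_threshold(arr, method=method, nbins=nbins)
    except ValueError as exc:
        raise ValueError(f"channel {channel!r}: {exc}") from exc
    return BinaryMask(foreground=arr > t, channel=channel,
                      method=method, threshold=t)


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def label_components(mask, connectivity: int = 26) -> LabelMap:
    """Connected-component labeling of a 3D boolean mask.

    Default adjacency is 26-connected (face, edge and corner neighbors — the
    3D analogue of "including diagonals"). Labels 1..K are assigned in
    raster-scan order of each component's first-encountered voxel.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    fg = mask.foreground if isinstance(mask, BinaryMask) else \
        np.asarray(mask, dtype=bool)
    if fg.ndim != 3:
        raise ValueError("mask must be 3D")
    struct = ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw, k = ndi.label(fg, structure=struct)
    if k > 1:
        flat = raw.ravel()
        nz = flat[flat > 0]
        labels_sorted, first_idx = np.unique(nz, return_index=True)
        order = np.argsort(first_idx, kind="stable")
        lut = np.zeros(k + 1, dtype=raw.dtype)
        lut[labels_sorted[order]] = np.arange(1, k + 1)
        raw = lut[raw]
    return LabelMap(labels=raw, n_components=int(k), connectivity=connectivity)


# ---------------------------------------------------------------------------
# stack I/O: multi-page TIFF + YAML sidecar
# ---------------------------------------------------------------------------

def write_stack(img: VoxelImage, path) -> Path:
    """Write a stack as multi-page TIFF (axes ZCYX) with a YAML sidecar
    recording voxel sizes and channel order."""
    import tifffile

    path = Path(path)
    names = sorted(img.channels)  # deterministic channel order
    data = np.stack([img.channels[n] for n in names], axis=1)  # (z, c, y, x)
    dz, dy, dx = img.voxel_size
    tifffile.imwrite(
        path, data.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "ZCYX"},
        resolution=(1.0 / dx, 1.0 / dy),
    )
    sidecar = path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"voxel_size_um": [dz, dy, dx], "channels": names}, fh,
            sort_keys=False)
    return path


def read_stack(path, voxel_size=None, channels=None) -> VoxelImage:
    """Read a multi-page TIFF stack.

    Voxel size comes from OME metadata when present, else the YAML sidecar,
    else the ``voxel_size`` argument (config); otherwise an error is raised.
    """
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome_vs = None
        if tf.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                px = root.find(".//ome:Pixels", ns)
                ome_vs = (float(px.attrib["PhysicalSizeZ"]),
                          float(px.attrib["PhysicalSizeY"]),
                          float(px.attrib["PhysicalSizeX"]))
            except Exception:
                ome_vs = None

    sidecar = path.with_suffix(".yaml")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}

    vs = ome_vs or tuple(meta.get("voxel_size_um", ())) or voxel_size
    if not vs:
        raise ValueError(
            f"{path}: no voxel size in OME metadata or sidecar; "
            "pass voxel_size explicitly")

    names = channels or meta.get("channels")
    if data.ndim == 3:
        names = names or [CHANNEL_CARRIER]
        chans = {names[0]: data.astype(float)}
    elif data.ndim == 4:
        # assume (z, c, y, x); fall back to (c, z, y, x) if c-axis looks first
        if data.shape[1] <= 4:
            per = [data[:, i] for i in range(data.shape[1])]
        elif data.shape[0] <= 4:
            per = [data[i] for i in range(data.shape[0])]
        else:
            raise ValueError(f"{path}: cannot infer channel axis "
                             f"for shape {data.shape}")
        names = names or [CHANNEL_CARRIER, CHANNEL_FREE][: len(per)]
        chans = {n: a.astype(float) for n, a in zip(names, per)}
    else:
        raise ValueError(f"{path}: unsupported dimensionality {data.ndim}")
    return VoxelImage(channels=chans, voxel_size=tuple(float(v) for v in vs))


def write_mask(mask: BinaryMask, path) -> Path:
    """Export a binary mask as an 8-bit multi-page TIFF (255 = foreground)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, mask.foreground.astype(np.uint8) * 255,
                     photometric="minisblack")
    return path
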