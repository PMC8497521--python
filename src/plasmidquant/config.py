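"""Run configuration: defaults, YAML loading, and config hashing.

A single YAML file with per-experiment sections; CLI flags override config
values, which override the defaults below. The config hash (sha256 of the
canonical JSON form) is stamped into every output bundle so reruns are
attributable.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "config_hash", "dump_config"]


DEFAULT_CONFIG: dict = {
    "flowcell": {
        "voxel_size_um": [0.5, 0.2, 0.2],
        # per-experiment thresholding: which channel gets which algorithm is
        # an assumption (documented); green->yen, red->moments by default
        "threshold": {"green": "yen", "red": "moments"},
        "smooth": False,
        "loess_span": 0.75,
        "loess_degree": 2,
        "sim": {
            "n_layers": 40,
            "shape_yx": [96, 96],
            "p_loss_bottom": 0.05,
            "p_loss_top": 0.30,
            "biomass_per_layer": 2000,
            "noise_mean": 10.0,
            "noise_sd": 2.0,
            "fg_intensity": 1000.0,
            "plasmids": ["conjugative", "conjugation_deficient"],
            "n_replicates": 2,
            "images_per_replicate": 2,
        },
    },
    "bead": {
        "voxel_size_um": [2.0, 1.0, 1.0],
        "threshold": {"green": "otsu", "red": "otsu"},
        "smooth": True,
        "min_volume_um3": 50.0,
        "exclusion_factor": 1.1,
        "radius_quantile": 0.99,
        "sim": {
            "shape": [80, 192, 192],
            "radius_um": 80.0,
            "n_aggregates": 40,
            "free_fraction": 0.25,
            "size_model": {"free": [2.9, 0.8], "carrier": [2.6, 0.8]},
            "size_sd": 0.2,
            "bead_intercept_sd": 0.15,
            "strains": ["WT", "MRB1"],
            "beads_per_strain": 3,
        },
    },
    "facs": {
        "gate_n_sd": 3.0,
        "min_separation_sd": 2.0,
        "sim": {
            "events_per_sample": 2000,
            "control_events": 5000,
            "debris_fraction": 0.03,
            "days": 4,
            "generations_per_day": 10.0,
            "strains": {
                # MRB1 cannot disperse: lower effective growth advantage of
                # plasmid-free cells in the sampled population
                "WT": {"lambda_seg": 2.0e-3, "s_cost": 0.10},
                "MRB1": {"lambda_seg": 2.0e-3, "s_cost": 0.03},
            },
            "plasmids": ["conjugative", "conjugation_deficient"],
            "n_bio_reps": 4,
            "n_tech_reps": 3,
            "competition_generations": 10.0,
            "competition_growth_per_gen": 2.0,
            "competition_inoculum": 100000,
        },
    },
    "plots": True,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Defaults merged with an optional YAML override file."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """sha256 of the canonical JSON form (first 12 hex digits)."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def validate_config(cfg: dict) -> None:
    """Light range checks on the tunables that matter."""
    fc = cfg["flowcell"]
    if not 0 < fc["loess_span"] <= 1:
        raise ValueError("flowcell.loess_span must be in (0, 1]")
    bd = cfg["bead"]
    if bd["min_volume_um3"] < 0:
        raise ValueError("bead.min_volume_um3 must be >= 0")
    if bd["exclusion_factor"] <= 0:
        raise ValueError("bead.exclusion_factor must be positive")
    for section in ("flowcell", "bead"):
        vs = cfg[section]["voxel_size_um"]
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"{section}.voxel_size_um must be 3 positive "
                             "lengths")
    sim = cfg["flowcell"]["sim"]
    for key in ("p_loss_bottom", "p_loss_top"):
        if not 0 <= sim[key] <= 1:
            raise ValueError(f"flowcell.sim.{key} must be in [0, 1]")
    if not 0 <= cfg["bead"]["sim"]["free_fraction"] <= 1:
        raise ValueError("bead.sim.free_fraction must be in [0, 1]")
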