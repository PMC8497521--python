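"""Shared fixtures: small synthetic stacks and event tables.

Session-scoped where generation is expensive; everything is seeded so the
suite is deterministic.
"""

import numpy as np
import pytest

import plasmidquant as pq
from plasmidquant.imagecore import segment_channel


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_flowcell():
    """A modest flow-cell stack with a step loss profile, plus truth."""
    truth = pq.synth.FlowcellTruth(
        n_layers=16, shape_yx=(48, 48),
        loss_profile=pq.synth.step_profile(0.05, 0.30, 16),
        biomass_profile=500.0, seed=7)
    img, counts = pq.synth.generate_flowcell_stack(truth)
    return truth, img, counts


@pytest.fixture(scope="session")
def small_bead():
    """A small bead stack with ~30 aggregates, plus truth table."""
    truth = pq.synth.BeadTruth(
        shape=(60, 140, 140), radius_um=55.0, n_aggregates=30, seed=11)
    img, table = pq.synth.generate_bead_stack(truth)
    return truth, img, table


@pytest.fixture(scope="session")
def segmented_bead(small_bead):
    truth, img, table = small_bead
    free = segment_channel(img, "green", "otsu", smooth=True)
    carrier = segment_channel(img, "red", "otsu", smooth=True)
    return truth, img, table, free, carrier


@pytest.fixture(scope="session")
def facs_controls():
    """Well-separated pure-population control event tables."""
    carrier = pq.synth.generate_facs_events(pq.synth.FacsTruth(
        n_events=5000, free_fraction=0.0, debris_fraction=0.0, seed=21))
    free = pq.synth.generate_facs_events(pq.synth.FacsTruth(
        n_events=5000, free_fraction=1.0, debris_fraction=0.0, seed=22))
    return carrier, free
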