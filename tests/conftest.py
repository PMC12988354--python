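"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

import projwire as pw
from projwire.synthetic_data import _default_class_profiles

TARGETS8 = {
    "LHA-I": "PTi", "MD-I": "PTi",
    "CP-I": "ITi-M1", "RSP-I": "ITi-M1",
    "ACB-I": "ITi-M2", "BLA-I": "ITi-M2",
    "CP-C": "ITc-M3", "ACB-C": "ITc-M3",
}

QUADRANT_MEANS = {
    "PTi": (1.0, 1.0), "ITi-M1": (2.0, 1.0), "ITi-M2": (1.0, 2.0), "ITc-M3": (2.0, 2.0)
}


def distinct_config(n_cells=3000, alpha=0.6, **overrides):
    """Eight targets in four well-separated classes with per-target module
    coupling and quadrant spatial means — the planted-signal regime the
    recovery tests exercise."""
    tl = list(TARGETS8)
    base = dict(
        n_cells=n_cells,
        targets=dict(TARGETS8),
        class_profiles=_default_class_profiles(TARGETS8, 0.85, 0.01),
        spatial_means=dict(QUADRANT_MEANS),
        n_genes=160,
        n_modules=8,
        module_sizes=[15] * 8,
        module_target_coupling={f"M{i + 1}": (tl[i], alpha) for i in range(8)},
    )
    base.update(overrides)
    return pw.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """Default-condition dataset, 1500 cells, 24 targets."""
    cfg = pw.SimulationConfig(n_cells=1500)
    return pw.simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def distinct_sim():
    """Separable 4-class dataset with planted modules and spatial quadrants."""
    return pw.simulate_dataset(distinct_config(), seed=4)


@pytest.fixture(scope="session")
def distinct_profiles(distinct_sim):
    ds, _ = distinct_sim
    return pw.filter_background(ds.barcode)
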