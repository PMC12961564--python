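"""Shared fixtures: one default synthetic benchmark per session."""

from __future__ import annotations

import pytest

from dualscreen.calibration import calibrate_registry
from dualscreen.curation import LigandSet
from dualscreen.fingerprints import FingerprintMatrix, default_registry
from dualscreen.synthetic_data import BenchmarkSpec, generate_dual_benchmark


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def benchmark():
    """Default benchmark: 50 compounds per set, 10 planted pairs, seed 42."""
    spec = BenchmarkSpec()
    set_a, set_b, truth = generate_dual_benchmark(spec)
    return spec, set_a, set_b, truth


@pytest.fixture(scope="session")
def small_benchmark():
    spec = BenchmarkSpec(n_per_set=12, planted_pair_fraction=0.25, seed=7)
    set_a, set_b, truth = generate_dual_benchmark(spec)
    return spec, set_a, set_b, truth


@pytest.fixture(scope="session")
def calibrated(benchmark, registry):
    """Thresholds calibrated on the union background of the default benchmark."""
    spec, set_a, set_b, _ = benchmark
    background = LigandSet("background", "A", set_a.members + set_b.members)
    table = calibrate_registry(
        background, registry, n_pairs=100_000, seed=spec.seed
    )
    return table


@pytest.fixture(scope="session")
def benchmark_matrices(benchmark, registry):
    _, set_a, set_b, _ = benchmark
    mats_a = {s.name: FingerprintMatrix.from_ligand_set(set_a, s) for s in registry}
    mats_b = {s.name: FingerprintMatrix.from_ligand_set(set_b, s) for s in registry}
    return mats_a, mats_b
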