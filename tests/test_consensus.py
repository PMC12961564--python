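"""Consensus voting: inclusive thresholds, brute-force equivalence, monotonicity."""

from __future__ import annotations

import numpy as np
import pytest

from dualscreen.calibration import ThresholdEntry, ThresholdTable
from dualscreen.consensus import consensus_pairs, vote
from dualscreen.curation import LigandSet
from dualscreen.errors import ConfigError
from dualscreen.fingerprints import (
    FingerprintMatrix,
    compute_fingerprint,
    default_registry,
    tanimoto,
)


def table(values: dict[str, float]) -> ThresholdTable:
    return ThresholdTable(
        entries={k: ThresholdEntry(threshold=v, n_pairs=0, seed=0) for k, v in values.items()}
    )


class TestVote:
    def test_counts_passing_specs(self):
        sims = {"f1": 0.9, "f2": 0.8, "f3": 0.7}
        thr = table({"f1": 0.5, "f2": 0.5, "f3": 0.95})
        assert vote(sims, thr) == 2

    def test_all_below_is_zero(self):
        assert vote({"f1": 0.1}, table({"f1": 0.5})) == 0

    def test_exact_threshold_counts_inclusively(self):
        assert vote({"f1": 0.5}, table({"f1": 0.5})) == 1

    def test_spec_mismatch_is_config_error(self):
        with pytest.raises(ConfigError):
            vote({"f1": 0.5}, table({"f2": 0.5}))


def toy_sets(smiles_a, smiles_b):
    a = LigandSet("A", "A", [(f"a{i}", s, 1.0) for i, s in enumerate(smiles_a)])
    b = LigandSet("B", "B", [(f"b{i}", s, 1.0) for i, s in enumerate(smiles_b)])
    return a, b


SMILES_POOL = [
    "CCO", "CCN", "CCC", "c1ccccc1", "c1ccncc1", "c1ccc2[nH]ccc2c1",
    "CC(=O)N", "c1ccc(Cl)cc1", "CCOC", "c1ccc2ccccc2c1",
]


def brute_force(set_a, set_b, specs, thresholds, min_votes):
    """Exhaustive double loop with the scalar Tanimoto kernel."""
    fps = {
        s.name: {
            cid: compute_fingerprint(smi, s)
            for cid, smi in zip(set_a.ids + set_b.ids, set_a.smiles + set_b.smiles)
        }
        for s in specs
    }
    pairs = []
    for ca, _, _ in set_a.members:
        for cb, _, _ in set_b.members:
            votes = sum(
                1
                for s in specs
                if tanimoto(fps[s.name][ca], fps[s.name][cb]) >= thresholds[s.name]
            )
            if votes >= min_votes:
                pairs.append((ca, cb, votes))
    return sorted(pairs)


class TestConsensusPairs:
    def test_unique_lists_are_projections_of_passing_pairs(self):
        specs = default_registry()[:1]
        a, b = toy_sets(["CCO", "CCN"], ["CCO", "CCN"])
        thr = table({specs[0].name: 0.99})
        res = consensus_pairs(a, b, thr, specs, min_votes=1)
        assert res.unique_a == {p.id_a for p in res.pairs}
        assert res.unique_b == {p.id_b for p in res.pairs}

    def test_no_passing_pairs_gives_empty_uniques(self):
        specs = default_registry()[:2]
        a, b = toy_sets(["CCO"], ["c1ccc2ccccc2c1"])
        thr = table({s.name: 1.0 for s in specs})
        res = consensus_pairs(a, b, thr, specs, min_votes=2)
        assert res.pairs == []
        assert res.unique_a == set() and res.unique_b == set()

    def test_empty_set_is_empty_result_not_error(self):
        specs = default_registry()[:1]
        a, _ = toy_sets(["CCO"], [])
        b = LigandSet("B", "B", [])
        thr = table({specs[0].name: 0.5})
        res = consensus_pairs(a, b, thr, specs, min_votes=1)
        assert res.pairs == []

    @pytest.mark.parametrize("min_votes", [1, 2])
    def test_matches_exhaustive_double_loop_on_5x5(self, min_votes):
        specs = default_registry()[:2]
        a, b = toy_sets(SMILES_POOL[:5], SMILES_POOL[5:])
        thr = table({s.name: 0.25 for s in specs})
        res = consensus_pairs(a, b, thr, specs, min_votes=min_votes)
        got = sorted((p.id_a, p.id_b, p.votes) for p in res.pairs)
        assert got == brute_force(a, b, specs, thr, min_votes)

    def test_matches_exhaustive_oracle_on_benchmark_20x20(
        self, benchmark, calibrated, registry, benchmark_matrices
    ):
        _, set_a, set_b, _ = benchmark
        sub_a = LigandSet("A", "A", set_a.members[:20])
        sub_b = LigandSet("B", "B", set_b.members[:20])
        res = consensus_pairs(sub_a, sub_b, calibrated, registry, min_votes=3)
        got = sorted((p.id_a, p.id_b, p.votes) for p in res.pairs)
        assert got == brute_force(sub_a, sub_b, registry, calibrated, 3)

    def test_monotone_in_thresholds_and_min_votes(self, benchmark, calibrated, registry, benchmark_matrices):
        _, set_a, set_b, _ = benchmark
        mats_a, mats_b = benchmark_matrices
        base = consensus_pairs(set_a, set_b, calibrated, registry, min_votes=3,
                               matrices_a=mats_a, matrices_b=mats_b)
        stricter_votes = consensus_pairs(set_a, set_b, calibrated, registry, min_votes=5,
                                         matrices_a=mats_a, matrices_b=mats_b)
        base_keys = {(p.id_a, p.id_b) for p in base.pairs}
        assert {(p.id_a, p.id_b) for p in stricter_votes.pairs} <= base_keys

        raised = ThresholdTable(entries={
            name: ThresholdEntry(min(1.0, e.threshold + 0.1), e.n_pairs, e.seed)
            for name, e in calibrated.entries.items()
        })
        stricter_thr = consensus_pairs(set_a, set_b, raised, registry, min_votes=3,
                                       matrices_a=mats_a, matrices_b=mats_b)
        assert {(p.id_a, p.id_b) for p in stricter_thr.pairs} <= base_keys

    def test_swapping_sets_transposes_pairs(self, benchmark, calibrated, registry, benchmark_matrices):
        _, set_a, set_b, _ = benchmark
        mats_a, mats_b = benchmark_matrices
        fwd = consensus_pairs(set_a, set_b, calibrated, registry, min_votes=3,
                              matrices_a=mats_a, matrices_b=mats_b)
        rev = consensus_pairs(set_b, set_a, calibrated, registry, min_votes=3,
                              matrices_a=mats_b, matrices_b=mats_a)
        assert {(p.id_a, p.id_b) for p in fwd.pairs} == {(p.id_b, p.id_a) for p in rev.pairs}
        assert fwd.unique_a == rev.unique_b and fwd.unique_b == rev.unique_a

    def test_min_votes_beyond_registry_is_config_error(self, calibrated, registry):
        a, b = toy_sets(["CCO"], ["CCN"])
        with pytest.raises(ConfigError):
            consensus_pairs(a, b, calibrated, registry, min_votes=len(registry) + 1)

    def test_deterministic_pair_ordering(self):
        specs = default_registry()[:1]
        a, b = toy_sets(["CCO", "CCN", "CCC"], ["CCO", "CCN"])
        thr = table({specs[0].name: 0.0})
        res = consensus_pairs(a, b, thr, specs, min_votes=1)
        keys = [(p.id_a, p.id_b) for p in res.pairs]
        assert keys == sorted(keys)


def test_planted_pair_recovery(benchmark, calibrated, registry, benchmark_matrices):
    """>= 95% of planted analog pairs pass at min_votes = 3; decoy-only
    pass rate stays within the 5% alpha-consistent bound."""
    _, set_a, set_b, truth = benchmark
    mats_a, mats_b = benchmark_matrices
    res = consensus_pairs(set_a, set_b, calibrated, registry, min_votes=3,
                          matrices_a=mats_a, matrices_b=mats_b)
    passing = {(p.id_a, p.id_b) for p in res.pairs}
    recovered = sum(1 for pair in truth.planted_pairs if tuple(pair) in passing)
    assert recovered / len(truth.planted_pairs) >= 0.95

    planted = set(map(tuple, truth.planted_pairs))
    n_decoy_pairs = len(set_a) * len(set_b) - len(planted)
    decoy_passing = len(passing - planted)
    assert decoy_passing / n_decoy_pairs <= 0.05
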