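"""Multi-fingerprint consensus voting across two ligand sets.

A cross-set pair (a, b) receives one vote for every registered
fingerprint whose Tanimoto similarity meets (>=, inclusive) that
fingerprint's calibrated threshold.  Pairs with at least ``min_votes``
votes (default 3) are deemed similar; the unique compounds appearing in
any passing pair become the dual-candidate lists for each set.

The vote requires the >= min_votes fingerprints to agree within a
single pair; ``consensus_pairs(..., accumulate_votes=True)`` offers the
alternative reading in which a compound accumulates passing
fingerprints across different partners.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calibration import ThresholdTable
from .curation import LigandSet
from .errors import ConfigError
from .fingerprints import FingerprintMatrix, FingerprintSpec, pairwise_matrix


@dataclass
class PairVote:
    """One cross-set pair with per-fingerprint similarities and its vote count."""

    id_a: str
    id_b: str
    sims: dict[str, float]
    votes: int


@dataclass
class ConsensusResult:
    pairs: list[PairVote]
    unique_a: set[str]
    unique_b: set[str]
    min_votes: int
    spec_names: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id_A", "id_B", *self.spec_names, "votes"])
            for p in self.pairs:
                w.writerow(
                    [p.id_a, p.id_b]
                    + [f"{p.sims[s]:.6f}" for s in self.spec_names]
                    + [p.votes]
                )


def vote(sims: Mapping[str, float], thresholds: ThresholdTable) -> int:
    """Count fingerprints whose similarity meets its threshold (inclusive)."""
    missing = set(sims) ^ set(thresholds.names())
    if missing:
        raise ConfigError(f"specs do not match thresholds: {sorted(missing)}")
    return sum(1 for name, s in sims.items() if s >= thresholds[name])


def consensus_pairs(
    set_a: LigandSet,
    set_b: LigandSet,
    thresholds: ThresholdTable,
    specs: Sequence[FingerprintSpec],
    min_votes: int = 3,
    matrices_a: Mapping[str, FingerprintMatrix] | None = None,
    matrices_b: Mapping[str, FingerprintMatrix] | None = None,
    accumulate_votes: bool = False,
) -> ConsensusResult:
    """Full |A| x |B| consensus evaluation.

    Precomputed per-spec :class:`FingerprintMatrix` maps may be passed to
    avoid refingerprinting.  Output pairs are ordered by (id_A, id_B).

    With ``accumulate_votes`` a compound in A passes when the union of
    fingerprints it passes over all partners in B reaches ``min_votes``
    (and symmetrically for B); the pair list still reports per-pair votes.
    """
    names = [s.name for s in specs]
    missing = [n for n in names if n not in thresholds]
    if missing:
        raise ConfigError(f"no thresholds for specs: {missing}")
    if min_votes < 0 or min_votes > len(specs):
        raise ConfigError(
            f"min_votes {min_votes} outside [0, {len(specs)}] for this registry"
        )

    if matrices_a is None:
        matrices_a = {
            s.name: FingerprintMatrix.from_ligand_set(set_a, s) for s in specs
        }
    if matrices_b is None:
        matrices_b = {
            s.name: FingerprintMatrix.from_ligand_set(set_b, s) for s in specs
        }

    n_a, n_b = len(set_a), len(set_b)
    sim_stack = np.zeros((len(specs), n_a, n_b))
    votes = np.zeros((n_a, n_b), dtype=np.int64)
    for k, spec in enumerate(specs):
        sims = pairwise_matrix(matrices_a[spec.name], matrices_b[spec.name])
        sim_stack[k] = sims
        votes += sims >= thresholds[spec.name]

    pass_mask = votes >= min_votes
    ids_a, ids_b = set_a.ids, set_b.ids

    pairs: list[PairVote] = []
    order = sorted(zip(*np.nonzero(pass_mask)), key=lambda ij: (ids_a[ij[0]], ids_b[ij[1]]))
    for i, j in order:
        pairs.append(
            PairVote(
                id_a=ids_a[i],
                id_b=ids_b[j],
                sims={name: float(sim_stack[k, i, j]) for k, name in enumerate(names)},
                votes=int(votes[i, j]),
            )
        )

    if accumulate_votes:
        passed_stack = sim_stack >= np.array(
            [thresholds[n] for n in names]
        ).reshape(-1, 1, 1)
        acc_a = passed_stack.any(axis=2).sum(axis=0)  # specs passed by any partner
        acc_b = passed_stack.any(axis=1).sum(axis=0)
        unique_a = {ids_a[i] for i in np.nonzero(acc_a >= min_votes)[0]}
        unique_b = {ids_b[j] for j in np.nonzero(acc_b >= min_votes)[0]}
    else:
        unique_a = {p.id_a for p in pairs}
        unique_b = {p.id_b for p in pairs}

    return ConsensusResult(
        pairs=pairs,
        unique_a=unique_a,
        unique_b=unique_b,
        min_votes=min_votes,
        spec_names=names,
    )
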