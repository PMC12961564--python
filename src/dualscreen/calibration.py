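"""Per-fingerprint significance thresholds from random-pair similarity.

A fixed similarity cutoff (the "0.85 myth") ignores that different
fingerprints distribute random-pair similarity very differently: dense
substructure keys give high background similarity, sparse hashed paths
give low.  The remedy is an empirical null: sample random compound
pairs from a background library, compute their Tanimoto similarity
under each fingerprint, and set the per-fingerprint threshold Tc0.05 at
the (1 - alpha) quantile of that distribution — a pair scoring above it
is more similar than 95% of random pairs.

The quantile uses the nearest-rank rule (no interpolation): for n
sorted similarities the threshold is the value at index
ceil((1 - alpha) * n), 1-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .curation import LigandSet
from .errors import InsufficientData
from .fingerprints import FingerprintMatrix, FingerprintSpec

DEFAULT_N_PAIRS = 100_000


@dataclass
class ThresholdEntry:
    threshold: float
    n_pairs: int
    seed: int
    rule: str = "nearest-rank"
    alpha: float = 0.05


@dataclass
class ThresholdTable:
    """Per-fingerprint Tc0.05 thresholds with calibration provenance."""

    entries: dict[str, ThresholdEntry] = field(default_factory=dict)

    def __getitem__(self, spec_name: str) -> float:
        return self.entries[spec_name].threshold

    def __contains__(self, spec_name: str) -> bool:
        return spec_name in self.entries

    def names(self) -> list[str]:
        return sorted(self.entries)

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {
                "threshold": e.threshold,
                "n_pairs": e.n_pairs,
                "seed": e.seed,
                "rule": e.rule,
                "alpha": e.alpha,
            }
            for name, e in self.entries.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            entries={
                name: ThresholdEntry(
                    threshold=float(d["threshold"]),
                    n_pairs=int(d.get("n_pairs", 0)),
                    seed=int(d.get("seed", 0)),
                    rule=d.get("rule", "nearest-rank"),
                    alpha=float(d.get("alpha", 0.05)),
                )
                for name, d in payload.items()
            }
        )


def sample_random_pairs(
    library: LigandSet | Sequence[str], n_pairs: int, seed: int
) -> list[tuple[int, int]]:
    """Draw unordered index pairs uniformly, no self-pairs, reproducibly.

    Returns index pairs (i, j) with i < j into the library's member
    order.  Sampling is with replacement across pairs (the background
    distribution is what matters, not pair uniqueness).
    """
    n = len(library)
    if n < 2:
        raise InsufficientData("need at least 2 compounds to form a pair")
    if n_pairs < 0:
        raise InsufficientData("n_pairs must be >= 0")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_pairs)
    # draw j uniformly over the n-1 indices != i
    j = rng.integers(0, n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return list(zip(lo.tolist(), hi.tolist()))


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Nearest-rank quantile: sorted[ceil(q * n)] (1-based), clamped to [1, n]."""
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        raise InsufficientData("no values to take a quantile of")
    rank = min(max(math.ceil(q * n), 1), n)
    return float(vals[rank - 1])


def estimate_threshold(
    library: LigandSet,
    spec: FingerprintSpec,
    n_pairs: int = DEFAULT_N_PAIRS,
    seed: int = 0,
    alpha: float = 0.05,
    fp_matrix: FingerprintMatrix | None = None,
) -> ThresholdEntry:
    """Estimate Tc(alpha) for one fingerprint over a background library.

    ``fp_matrix`` may be supplied to avoid recomputing fingerprints when
    calibrating many specs over the same library.
    """
    if n_pairs <= 0:
        raise InsufficientData("n_pairs must be positive")
    if fp_matrix is None:
        fp_matrix = FingerprintMatrix.from_ligand_set(library, spec)
    pairs = sample_random_pairs(library, n_pairs, seed)
    idx_i = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
    idx_j = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
    A = fp_matrix.matrix.astype(np.int64)
    c = (A[idx_i] & A[idx_j]).sum(axis=1)
    a = A[idx_i].sum(axis=1)
    b = A[idx_j].sum(axis=1)
    denom = a + b - c
    sims = np.where(denom > 0, c / np.maximum(denom, 1), 0.0)
    thr = nearest_rank_quantile(sims.tolist(), 1.0 - alpha)
    return ThresholdEntry(threshold=thr, n_pairs=n_pairs, seed=seed, alpha=alpha)


def calibrate_registry(
    library: LigandSet,
    specs: Sequence[FingerprintSpec],
    n_pairs: int = DEFAULT_N_PAIRS,
    seed: int = 0,
    alpha: float = 0.05,
) -> ThresholdTable:
    """Estimate thresholds for every spec, one shared pair sample per spec.

    Each spec gets a seed derived from the master seed and its position
    so calibrations are independently reproducible.
    """
    table = ThresholdTable()
    for k, spec in enumerate(specs):
        spec_seed = (seed + 1000003 * k) % (2**31)
        mat = FingerprintMatrix.from_ligand_set(library, spec)
        table.entries[spec.name] = estimate_threshold(
            library, spec, n_pairs=n_pairs, seed=spec_seed, alpha=alpha, fp_matrix=mat
        )
    return table
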