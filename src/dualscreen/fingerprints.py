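"""Fingerprint registry, bit-vector computation and Tanimoto similarity.

A consensus similarity search gains robustness by agreeing across many
weakly correlated molecular representations.  The default registry holds
13 two-dimensional binary fingerprints spanning the structural-key,
circular, path/topological, atom-pair, torsion and pattern families —
all computed with RDKit so results are bit-exact across runs.  MACCS
keys (166 bits) serve double duty: one of the 13 consensus fingerprints
and the representation used for the chemical-space analysis.

Similarity is the Tanimoto coefficient Tc = c / (a + b - c), with a and
b the set-bit counts of the two vectors and c their shared set bits.
Two all-zero vectors are defined to have Tc = 0 (empty fingerprints
share no evidence of similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Avalon import pyAvalonTools

from .curation import LigandSet
from .errors import InvalidStructure, SpecError


@dataclass(frozen=True)
class FingerprintSpec:
    """Identity and parameters of one registered fingerprint."""

    name: str
    family: str  # structural_keys | circular | path_topological | atom_pair | torsion | pattern
    length: int
    parameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SpecError(f"fingerprint length must be > 0 ({self.name})")


def _morgan(radius: int, n_bits: int, features: bool) -> Callable[[Chem.Mol], np.ndarray]:
    inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen() if features else None
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits, atomInvariantsGenerator=inv
    )
    return lambda mol: np.frombuffer(
        gen.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
    ) - ord("0")


def _rdkit_path(max_path: int, n_bits: int, branched: bool = True) -> Callable:
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        maxPath=max_path, fpSize=n_bits, branchedPaths=branched
    )
    return lambda mol: np.frombuffer(
        gen.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
    ) - ord("0")


def _atom_pair(n_bits: int) -> Callable:
    gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
    return lambda mol: np.frombuffer(
        gen.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
    ) - ord("0")


def _torsion(n_bits: int) -> Callable:
    gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=n_bits)
    return lambda mol: np.frombuffer(
        gen.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
    ) - ord("0")


def _bv_to_array(bv) -> np.ndarray:
    return np.frombuffer(bv.ToBitString().encode(), dtype=np.uint8) - ord("0")


def _maccs(mol: Chem.Mol) -> np.ndarray:
    # RDKit emits 167 bits with bit 0 always unset; drop it for 166 keys
    return _bv_to_array(MACCSkeys.GenMACCSKeys(mol))[1:]


_COMPUTERS: dict[str, Callable[[Chem.Mol], np.ndarray]] = {}


def _register(spec: FingerprintSpec, fn: Callable[[Chem.Mol], np.ndarray]) -> FingerprintSpec:
    _COMPUTERS[spec.name] = fn
    return spec


MACCS_SPEC = _register(
    FingerprintSpec("maccs", "structural_keys", 166), _maccs
)

_DEFAULT_SPECS: list[FingerprintSpec] = [
    MACCS_SPEC,
    _register(
        FingerprintSpec("morgan_r2", "circular", 1024, {"radius": 2}),
        _morgan(2, 1024, features=False),
    ),
    _register(
        FingerprintSpec("morgan_r3", "circular", 1024, {"radius": 3}),
        _morgan(3, 1024, features=False),
    ),
    _register(
        FingerprintSpec("feat_morgan_r2", "circular", 1024, {"radius": 2, "features": True}),
        _morgan(2, 1024, features=True),
    ),
    _register(
        FingerprintSpec("feat_morgan_r3", "circular", 1024, {"radius": 3, "features": True}),
        _morgan(3, 1024, features=True),
    ),
    _register(
        FingerprintSpec("rdkit_path5", "path_topological", 2048, {"max_path": 5}),
        _rdkit_path(5, 2048),
    ),
    _register(
        FingerprintSpec("rdkit_path7", "path_topological", 2048, {"max_path": 7}),
        _rdkit_path(7, 2048),
    ),
    _register(
        FingerprintSpec(
            "rdkit_linear6", "path_topological", 2048, {"max_path": 6, "branched": False}
        ),
        _rdkit_path(6, 2048, branched=False),
    ),
    _register(
        FingerprintSpec("atom_pair", "atom_pair", 2048),
        _atom_pair(2048),
    ),
    _register(
        FingerprintSpec("torsion", "torsion", 2048),
        _torsion(2048),
    ),
    _register(
        FingerprintSpec("pattern", "pattern", 2048),
        lambda mol: _bv_to_array(Chem.PatternFingerprint(mol, fpSize=2048)),
    ),
    _register(
        FingerprintSpec("layered", "pattern", 2048),
        lambda mol: _bv_to_array(Chem.LayeredFingerprint(mol, fpSize=2048)),
    ),
    _register(
        FingerprintSpec("avalon", "pattern", 1024),
        lambda mol: _bv_to_array(pyAvalonTools.GetAvalonFP(mol, nBits=1024)),
    ),
]


def default_registry() -> list[FingerprintSpec]:
    """Return the 13 default fingerprint specifications.

    The roster spans structural keys (MACCS), circular (radius-2/3 atom
    and feature Morgan variants), path/topological, atom-pair, torsion
    and pattern/substructure families; any 13 specs may be substituted —
    the consensus logic is roster-agnostic.
    """
    return list(_DEFAULT_SPECS)


@dataclass
class BitVector:
    """A fixed-length binary fingerprint with cached popcount."""

    bits: np.ndarray  # uint8 0/1 array
    spec_name: str

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def __len__(self) -> int:
        return len(self.bits)


def compute_fingerprint(canonical_smiles: str, spec: FingerprintSpec) -> BitVector:
    """Compute one fingerprint; deterministic and SMILES-order invariant."""
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise InvalidStructure(f"unparseable SMILES: {canonical_smiles!r}")
    # re-parse from canonical SMILES so atom order (and thus any
    # order-sensitive hashing) is independent of how the input was written
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    try:
        fn = _COMPUTERS[spec.name]
    except KeyError:
        raise SpecError(f"no computer registered for spec {spec.name!r}") from None
    bits = np.asarray(fn(mol), dtype=np.uint8)
    if len(bits) != spec.length:
        raise SpecError(
            f"{spec.name}: computed {len(bits)} bits, spec says {spec.length}"
        )
    return BitVector(bits=bits, spec_name=spec.name)


@dataclass
class FingerprintMatrix:
    """Stacked bit vectors for an ordered list of compounds under one spec."""

    spec: FingerprintSpec
    rows: list[str]  # compound ids, order matching the source LigandSet
    matrix: np.ndarray  # (n_compounds, spec.length) uint8

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_ligand_set(cls, ligands: LigandSet, spec: FingerprintSpec) -> "FingerprintMatrix":
        vecs = [compute_fingerprint(s, spec).bits for s in ligands.smiles]
        mat = (
            np.vstack(vecs) if vecs else np.zeros((0, spec.length), dtype=np.uint8)
        )
        return cls(spec=spec, rows=list(ligands.ids), matrix=mat)

    @classmethod
    def from_smiles(
        cls, ids: Sequence[str], smiles: Sequence[str], spec: FingerprintSpec
    ) -> "FingerprintMatrix":
        vecs = [compute_fingerprint(s, spec).bits for s in smiles]
        mat = (
            np.vstack(vecs) if vecs else np.zeros((0, spec.length), dtype=np.uint8)
        )
        return cls(spec=spec, rows=list(ids), matrix=mat)


def tanimoto(x: BitVector | np.ndarray, y: BitVector | np.ndarray) -> float:
    """Tanimoto coefficient c / (a + b - c); both-empty convention 0.0."""
    xb = x.bits if isinstance(x, BitVector) else np.asarray(x)
    yb = y.bits if isinstance(y, BitVector) else np.asarray(y)
    if len(xb) != len(yb):
        raise SpecError(f"bit-vector length mismatch: {len(xb)} vs {len(yb)}")
    a = int(xb.sum())
    b = int(yb.sum())
    c = int((xb & yb).sum())
    denom = a + b - c
    return c / denom if denom else 0.0


def pairwise_matrix(
    set_a: FingerprintMatrix, set_b: FingerprintMatrix
) -> np.ndarray:
    """Cross Tanimoto table, entry (i, j) = Tc(A_i, B_j).

    Computed with an integer intersection matmul, so it agrees bit-exactly
    with the scalar :func:`tanimoto` path.
    """
    if set_a.spec.name != set_b.spec.name:
        raise SpecError(
            f"spec mismatch: {set_a.spec.name} vs {set_b.spec.name}"
        )
    A = set_a.matrix.astype(np.int64)
    B = set_b.matrix.astype(np.int64)
    if A.shape[0] == 0 or B.shape[0] == 0:
        return np.zeros((A.shape[0], B.shape[0]))
    c = A @ B.T
    a = A.sum(axis=1)[:, None]
    b = B.sum(axis=1)[None, :]
    denom = a + b - c
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, c / np.maximum(denom, 1), 0.0)
    return out
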