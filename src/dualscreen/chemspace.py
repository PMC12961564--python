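"""MACCS-based chemical-space analysis of the two ligand sets.

Before any similarity search it is worth asking whether the two ligand
populations occupy overlapping regions of chemical space at all.  This
module provides:

* a PCA projection of the pooled 166-bit MACCS key matrix (columns
  standardized; zero-variance keys dropped);
* intra-set and cross-set average Tanimoto similarity (intra averages
  exclude the self-similarity diagonal);
* counts of members of each set whose best cross-set MACCS similarity
  reaches a cutoff (default 0.80, inclusive) — the "potential dual"
  overlap statistic;
* Bemis–Murcko framework grouping for scaffold-based triage.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .curation import LigandSet
from .errors import InsufficientData
from .fingerprints import MACCS_SPEC, FingerprintMatrix, pairwise_matrix


@dataclass
class Projection:
    """PCA coordinates with explained variance and preprocessing record."""

    coordinates: np.ndarray  # (n, k)
    explained_variance_ratio: np.ndarray  # (k,)
    dropped_columns: list[int] = field(default_factory=list)

    def to_csv(self, path: str | Path, ids: list[str], labels: list[str]) -> None:
        k = self.coordinates.shape[1]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["compound_id", "set", *[f"PC{i+1}" for i in range(k)]])
            for cid, lab, row in zip(ids, labels, self.coordinates):
                w.writerow([cid, lab, *[f"{v:.6f}" for v in row]])


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    mean_intra_a: float
    mean_intra_b: float
    mean_cross: float
    count_a_high: int
    count_b_high: int
    cutoff: float = 0.80

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _maccs_matrix(ligands: LigandSet) -> FingerprintMatrix:
    return FingerprintMatrix.from_ligand_set(ligands, MACCS_SPEC)


def pca_project(keys_matrix: np.ndarray, k: int = 2) -> Projection:
    """PCA on a binary key matrix after per-column standardization.

    Zero-variance columns are dropped (and recorded) before scaling.
    Component sign is fixed by making each component's largest-magnitude
    loading positive, so projections are reproducible across runs.
    """
    X = np.asarray(keys_matrix, dtype=float)
    if X.shape[0] < 2:
        raise InsufficientData("PCA needs at least 2 compounds")
    variances = X.var(axis=0)
    keep = variances > 0
    dropped = np.nonzero(~keep)[0].tolist()
    X = X[:, keep]
    if X.shape[1] == 0:
        raise InsufficientData("all key columns are constant")
    Xs = StandardScaler().fit_transform(X)
    k_eff = min(k, min(Xs.shape))
    pca = PCA(n_components=k_eff, svd_solver="full")
    coords = pca.fit_transform(Xs)
    # sign convention: largest |loading| of each component is positive
    for c in range(k_eff):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1
    return Projection(
        coordinates=coords,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        dropped_columns=dropped,
    )


def average_similarity(
    set_x: LigandSet,
    set_y: LigandSet | None = None,
    fp_x: FingerprintMatrix | None = None,
    fp_y: FingerprintMatrix | None = None,
) -> float:
    """Mean MACCS Tanimoto similarity, intra-set or cross-set.

    Intra mode (``set_y`` omitted): mean over all unordered distinct
    pairs — the Tc = 1 diagonal is excluded so near-duplicate-free sets
    are not inflated.  Cross mode: mean over all |X| x |Y| pairs.
    """
    fx = fp_x if fp_x is not None else _maccs_matrix(set_x)
    if set_y is None or set_y is set_x:
        n = len(fx)
        if n < 2:
            raise InsufficientData("intra-set average needs >= 2 compounds")
        sims = pairwise_matrix(fx, fx)
        iu = np.triu_indices(n, k=1)
        return float(sims[iu].mean())
    fy = fp_y if fp_y is not None else _maccs_matrix(set_y)
    sims = pairwise_matrix(fx, fy)
    if sims.size == 0:
        raise InsufficientData("cross-set average needs non-empty sets")
    return float(sims.mean())


def high_overlap_counts(
    set_a: LigandSet,
    set_b: LigandSet,
    cutoff: float = 0.80,
    fp_a: FingerprintMatrix | None = None,
    fp_b: FingerprintMatrix | None = None,
) -> OverlapSummary:
    """Per-set counts of members with best cross-set MACCS Tc >= cutoff."""
    fa = fp_a if fp_a is not None else _maccs_matrix(set_a)
    fb = fp_b if fp_b is not None else _maccs_matrix(set_b)
    sims = pairwise_matrix(fa, fb)
    if sims.size:
        count_a = int((sims.max(axis=1) >= cutoff).sum())
        count_b = int((sims.max(axis=0) >= cutoff).sum())
        mean_cross = float(sims.mean())
    else:
        count_a = count_b = 0
        mean_cross = float("nan")
    mean_ia = average_similarity(set_a, fp_x=fa) if len(set_a) > 1 else float("nan")
    mean_ib = average_similarity(set_b, fp_x=fb) if len(set_b) > 1 else float("nan")
    return OverlapSummary(
        n_a=len(set_a),
        n_b=len(set_b),
        mean_intra_a=mean_ia,
        mean_intra_b=mean_ib,
        mean_cross=mean_cross,
        count_a_high=count_a,
        count_b_high=count_b,
        cutoff=cutoff,
    )


ACYCLIC_KEY = "acyclic"


def scaffold_groups(ligands: LigandSet) -> dict[str, list[str]]:
    """Partition a ligand set by Bemis–Murcko framework.

    Each compound maps to the canonical SMILES of its ring systems plus
    linkers with substituents stripped; acyclic molecules share the
    dedicated ``"acyclic"`` key.
    """
    groups: dict[str, list[str]] = {}
    for cid, smi, _ in ligands.members:
        core = MurckoScaffold.MurckoScaffoldSmiles(smi)
        key = core if core else ACYCLIC_KEY
        groups.setdefault(key, []).append(cid)
    return groups


def scaffold_groups_to_csv(groups: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["framework", "n_members", "compound_ids"])
        for fw in sorted(groups, key=lambda f: (-len(groups[f]), f)):
            w.writerow([fw, len(groups[fw]), ";".join(groups[fw])])


def plot_projection(
    proj: Projection,
    labels: list[str],
    path: str | Path,
    highlight: set[str] | None = None,
    ids: list[str] | None = None,
) -> None:
    """Scatter plot of the first two PCs, colored by set label (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    lab_arr = np.asarray(labels)
    for lab, marker in zip(sorted(set(labels)), "oshv^"):
        m = lab_arr == lab
        ax.scatter(
            proj.coordinates[m, 0], proj.coordinates[m, 1],
            s=12, alpha=0.6, marker=marker, label=lab,
        )
    if highlight and ids:
        hm = np.array([i in highlight for i in ids])
        ax.scatter(
            proj.coordinates[hm, 0], proj.coordinates[hm, 1],
            s=40, facecolors="none", edgecolors="red", label="high-overlap",
        )
    evr = proj.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
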