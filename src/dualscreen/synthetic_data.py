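"""Seeded, ground-truthed synthetic fixtures for every pipeline stage.

Real dual-pharmacology benchmarks require proprietary or downloadable
bioactivity extracts; this module builds self-contained substitutes by
template assembly: ring-system cores (written as SMILES) are decorated
with enumerated substituents at ring positions that can accept them, so
every generated structure is valid chemistry by construction.

Three fixture families are produced:

* **dual-ligand benchmark** — two ligand sets sharing a controllable
  fraction of planted cross-set analog pairs (same core, nearly the
  same substituents) amid structurally distinct decoys built from
  set-private cores;
* **activity tables** — curation exercises in which every input ligand
  receives a passing record while extra synthetic compounds cover each
  rejection rule (wrong organism, non-single-protein target, antagonist
  mode, validity warning, potency above cutoff, zero cooperativity),
  with boundary potencies and duplicate values planted on real members;
* **PPI fixture** — a scored random graph with two seed proteins and
  one pathway term planted among the seeds' top-scoring neighbors.

All randomness flows from a single spec-level seed: stage ``k`` uses
``numpy.random.default_rng([seed, k])``, so each fixture is
independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .curation import ActivityRecord, LigandSet, standardize_smiles
from .errors import DualScreenError
from .network_enrichment import GeneSet, ScoredEdge
from .selectivity import OffTargetRecord

# --------------------------------------------------------------------------
# structure templates

#: ring-system cores shared by both sets; planted analog pairs use these
SHARED_CORES = [
    "c1ccc2[nH]ccc2c1",            # indole
    "c1ccc2ncccc2c1",              # quinoline
    "c1ccc2c(c1)oc1ccccc12",       # dibenzofuran
    "c1ccc(-c2ccncc2)cc1",         # phenylpyridine
    "O=c1cc[nH]c(=O)[nH]1",        # uracil
]

#: cores private to set A decoys
CORES_A = [
    "c1ccc2c(c1)cccc2",            # naphthalene
    "c1ccc(-n2cccn2)cc1",          # phenylpyrazole
    "C1CCC2(CC1)CCCCC2",           # spiroundecane
    "c1csc(-c2ccccc2)c1",          # phenylthiophene
]

#: cores private to set B decoys
CORES_B = [
    "c1ccc2nc[nH]c2c1",            # benzimidazole
    "c1ccc(N2CCOCC2)cc1",          # phenylmorpholine
    "O=C1CCCN1c1ccccc1",           # phenylpyrrolidinone
    "c1cnc2[nH]ccc2c1",            # azaindole
]

#: substituent fragments; the first atom is the attachment point
SUBSTITUENTS = ["C", "CC", "CCC", "OC", "OCC", "N", "NC", "F", "Cl", "Br",
                "C(F)(F)F", "C#N", "C(C)C", "CO"]

#: near-analog replacement used to perturb one substituent in a planted pair
ANALOG_OF = {
    "C": "CC", "CC": "CCC", "CCC": "CC", "OC": "OCC", "OCC": "OC",
    "N": "NC", "NC": "N", "F": "Cl", "Cl": "F", "Br": "Cl",
    "C(F)(F)F": "C(C)C", "C#N": "N", "C(C)C": "CC", "CO": "OC",
}


def _attachment_sites(mol: Chem.Mol) -> list[int]:
    """Ring atoms able to accept one more single-bonded substituent."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.IsInRing() and a.GetTotalNumHs() >= 1 and a.GetSymbol() in ("C", "N")
    ]


def assemble(core_smiles: str, substituents: Sequence[str], sites: Sequence[int]) -> str:
    """Attach each substituent at the given core atom index; canonical SMILES out."""
    core = Chem.MolFromSmiles(core_smiles)
    if core is None:
        raise DualScreenError(f"bad core: {core_smiles}")
    mol = Chem.RWMol(core)
    for sub_smi, site in zip(substituents, sites):
        frag = Chem.MolFromSmiles(sub_smi)
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol, frag))
        mol.AddBond(site, offset, Chem.BondType.SINGLE)
        atom = mol.GetAtomWithIdx(site)
        # atoms written with explicit hydrogens ([nH]) must surrender one
        if atom.GetNumExplicitHs() > 0:
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


# --------------------------------------------------------------------------
# benchmark spec & ground truth

@dataclass
class BenchmarkSpec:
    n_per_set: int = 50
    n_scaffold_families: int = 4  # private decoy cores used per set
    planted_pair_fraction: float = 0.2
    decoy_diversity: int = 3  # max substituents per decoy
    seed: int = 42

    @property
    def n_planted(self) -> int:
        return round(self.planted_pair_fraction * self.n_per_set)


@dataclass
class GroundTruth:
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    curation_verdicts: dict[str, dict] = field(default_factory=dict)
    planted_term: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_pairs": self.planted_pairs,
                    "curation_verdicts": self.curation_verdicts,
                    "planted_term": self.planted_term,
                },
                fh, indent=2,
            )


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage])


def _decorate(core: str, rng: np.random.Generator, max_subs: int) -> tuple[str, list[str], list[int]]:
    mol = Chem.MolFromSmiles(core)
    sites = _attachment_sites(mol)
    n_subs = int(rng.integers(1, max_subs + 1))
    n_subs = min(n_subs, len(sites))
    chosen_sites = sorted(rng.choice(len(sites), size=n_subs, replace=False).tolist())
    site_ids = [sites[i] for i in chosen_sites]
    subs = [SUBSTITUENTS[i] for i in rng.integers(0, len(SUBSTITUENTS), size=n_subs)]
    return assemble(core, subs, site_ids), subs, site_ids


def generate_dual_benchmark(
    spec: BenchmarkSpec,
) -> tuple[LigandSet, LigandSet, GroundTruth]:
    """Build two ligand sets with planted cross-set analog pairs.

    Planted pairs share a core and all but one substituent (one is
    swapped for a close analog), so they score high under essentially
    every 2-D fingerprint.  Decoys are drawn from set-private core pools
    and therefore rarely resemble anything in the other set.
    """
    if spec.n_per_set < 2:
        raise DualScreenError("n_per_set must be >= 2")
    n_planted = spec.n_planted
    if n_planted > spec.n_per_set:
        raise DualScreenError("more planted pairs than members per set")

    rng = _rng(spec.seed, 1)
    truth = GroundTruth()
    members_a: list[tuple[str, str, float]] = []
    members_b: list[tuple[str, str, float]] = []

    for i in range(n_planted):
        core = SHARED_CORES[int(rng.integers(0, len(SHARED_CORES)))]
        mol = Chem.MolFromSmiles(core)
        sites = _attachment_sites(mol)
        n_subs = min(3, len(sites))
        chosen = sorted(rng.choice(len(sites), size=n_subs, replace=False).tolist())
        site_ids = [sites[c] for c in chosen]
        subs = [SUBSTITUENTS[k] for k in rng.integers(0, len(SUBSTITUENTS), size=n_subs)]
        smi_a = assemble(core, subs, site_ids)
        subs_b = list(subs)
        swap = int(rng.integers(0, n_subs))
        subs_b[swap] = ANALOG_OF[subs_b[swap]]
        smi_b = assemble(core, subs_b, site_ids)
        id_a, id_b = f"A{i:04d}", f"B{i:04d}"
        pot_a = float(np.round(10 ** rng.uniform(0.5, 2.5), 2))   # 3–300 nM
        pot_b = float(np.round(10 ** rng.uniform(0.5, 2.9), 2))   # 3–800 nM
        members_a.append((id_a, standardize_smiles(smi_a), pot_a))
        members_b.append((id_b, standardize_smiles(smi_b), pot_b))
        truth.planted_pairs.append((id_a, id_b))

    pool_a = CORES_A[: spec.n_scaffold_families]
    pool_b = CORES_B[: spec.n_scaffold_families]
    for i in range(n_planted, spec.n_per_set):
        core_a = pool_a[int(rng.integers(0, len(pool_a)))]
        smi_a, _, _ = _decorate(core_a, rng, spec.decoy_diversity)
        members_a.append(
            (f"A{i:04d}", standardize_smiles(smi_a),
             float(np.round(10 ** rng.uniform(0.5, 2.5), 2)))
        )
        core_b = pool_b[int(rng.integers(0, len(pool_b)))]
        smi_b, _, _ = _decorate(core_b, rng, spec.decoy_diversity)
        members_b.append(
            (f"B{i:04d}", standardize_smiles(smi_b),
             float(np.round(10 ** rng.uniform(0.5, 2.9), 2)))
        )

    set_a = LigandSet(name="setA", role="A", members=members_a)
    set_b = LigandSet(name="setB", role="B", members=members_b)
    return set_a, set_b, truth


# --------------------------------------------------------------------------
# activity-table generator

_FAIL_SMILES = "c1ccccc1CCN"  # structure for the planted failing records


def generate_activity_table(
    ligands: LigandSet, seed: int, role: str | None = None
) -> tuple[list[ActivityRecord], GroundTruth]:
    """Emit an activity table whose curated output is exactly ``ligands``.

    Every input ligand receives at least one record that passes all
    curation rules for its role; designated members exercise the
    passing edge cases (inclusive boundary potency, duplicate values
    averaged, assay-type priority, unit conversion, positive
    cooperativity for PAMs).  Additional synthetic compounds (ids
    ``XF...``) cover each rejection rule at least once.  Ground-truth
    verdicts record the expected pass/fail and governing rule per id.
    """
    if not ligands.members:
        raise DualScreenError("ligand set is empty")
    role = role or ligands.role
    rng = _rng(seed, 2)
    cutoff = 500.0 if role == "A" else 1000.0
    desc_pass = (
        "Agonist activity at human receptor"
        if role == "A"
        else "Positive allosteric modulation of human receptor"
    )
    target = "T_A" if role == "A" else "T_B"

    def rec(cid, smi, **kw) -> ActivityRecord:
        base = dict(
            compound_id=cid, smiles=smi, target_id=target,
            organism="Homo sapiens", target_type="SINGLE PROTEIN",
            assay_description=desc_pass, assay_type="functional",
            standard_type="EC50",
            standard_value=float(np.round(rng.uniform(10, cutoff * 0.8), 2)),
            standard_units="nM", data_validity_comment="",
        )
        base.update(kw)
        return ActivityRecord(**base)

    records: list[ActivityRecord] = []
    truth = GroundTruth()

    for idx, (cid, smi, _) in enumerate(ligands.members):
        variant = idx % 6
        if variant == 0:
            # inclusive boundary: exactly at the cutoff
            records.append(rec(cid, smi, standard_value=cutoff))
            rule = "boundary potency"
        elif variant == 1:
            # duplicate values under one assay -> arithmetic mean
            records.append(rec(cid, smi, standard_value=100.0))
            records.append(rec(cid, smi, standard_value=300.0))
            rule = "mean of duplicates"
        elif variant == 2:
            # two assay types; priority keeps the functional EC50
            records.append(rec(cid, smi, standard_value=50.0))
            records.append(
                rec(cid, smi, standard_type="Ki", assay_type="binding",
                    standard_value=cutoff * 40)
            )
            rule = "assay-type priority"
        elif variant == 3:
            # micromolar units that convert below the cutoff
            records.append(
                rec(cid, smi, standard_value=float(np.round(cutoff / 4000, 4)),
                    standard_units="uM")
            )
            rule = "unit conversion"
        elif variant == 4 and role == "B":
            # no concentration record; positive cooperativity carries it
            records.append(
                rec(cid, smi, standard_type="logAlphaBeta",
                    standard_value=0.3, standard_units="")
            )
            rule = "positive cooperativity"
        else:
            records.append(rec(cid, smi))
            rule = "plain pass"
        truth.curation_verdicts[cid] = {"expected": "pass", "rule": rule}

    fail_cases = [
        ("XF_ORG", dict(organism="Rattus norvegicus"), "organism mismatch"),
        ("XF_TT", dict(target_type="PROTEIN COMPLEX"), "target type mismatch"),
        ("XF_MODE", dict(assay_description="Antagonist activity at human receptor"),
         "assay mode mismatch"),
        ("XF_DVC", dict(data_validity_comment="Potential author error"),
         "data validity warning"),
        ("XF_POT", dict(standard_value=cutoff * 3), "potency above cutoff"),
    ]
    if role == "B":
        fail_cases.append(
            ("XF_COOP", dict(standard_type="logAlphaBeta", standard_value=0.0,
                             standard_units=""), "potency above cutoff"),
        )
        fail_cases.append(
            ("XF_NOQ", dict(standard_type="Ki", assay_type="binding",
                            standard_value=5.0), "no qualifying measurement"),
        )
    for cid, kw, rule in fail_cases:
        records.append(rec(cid, _FAIL_SMILES, **kw))
        truth.curation_verdicts[cid] = {"expected": "fail", "rule": rule}

    return records, truth


def activity_records_to_csv(records: Sequence[ActivityRecord], path: str | Path) -> None:
    import csv

    fields = [
        "compound_id", "smiles", "target_id", "organism", "target_type",
        "assay_description", "assay_type", "standard_type", "standard_value",
        "standard_units", "data_validity_comment",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(fields)
        for r in records:
            w.writerow([getattr(r, f) for f in fields])


# --------------------------------------------------------------------------
# off-target table generator

def generate_offtarget_table(
    candidates: LigandSet, seed: int, promiscuous_fraction: float = 0.3
) -> tuple[list[OffTargetRecord], set[str]]:
    """Off-target records making a chosen fraction of candidates promiscuous.

    Returns the records plus the ground-truth set of compound ids that a
    10-fold window should exclude.  One retained candidate is given a
    P-glycoprotein record to exercise the allowlist.
    """
    rng = _rng(seed, 3)
    n = len(candidates)
    n_bad = round(promiscuous_fraction * n)
    idx = rng.permutation(n)
    bad = {candidates.members[i][0] for i in idx[:n_bad]}
    records: list[OffTargetRecord] = []
    for i in idx:
        cid, _, pot = candidates.members[i]
        if cid in bad:
            off = pot * float(rng.uniform(1.0, 9.0))  # window < 10
            records.append(OffTargetRecord(cid, "OT1", "Off-target kinase", off))
        elif rng.random() < 0.3:
            off = pot * float(rng.uniform(20.0, 500.0))  # clean window
            records.append(OffTargetRecord(cid, "OT2", "Off-target GPCR", off))
    if n > n_bad:
        pgp_cid = candidates.members[int(idx[n_bad])][0]
        records.append(
            OffTargetRecord(pgp_cid, "PGP", "P-glycoprotein",
                            candidates.members[int(idx[n_bad])][2] * 2.0)
        )
    return records, bad


# --------------------------------------------------------------------------
# PPI fixture generator

def generate_ppi_fixture(
    n_nodes: int, seed: int, n_planted_neighbors: int = 10, n_decoy_terms: int = 8
) -> tuple[list[ScoredEdge], list[GeneSet], GroundTruth]:
    """Scored random PPI graph with one planted enriched pathway.

    Two seed proteins are wired to a shared neighborhood; the planted
    term's members are exactly the seeds' ``n_planted_neighbors``
    top-scoring neighbors, so the term is maximally over-represented in
    the expanded network.  Decoy terms sample nodes uniformly.
    """
    if n_nodes < 10:
        raise DualScreenError("n_nodes must be >= 10")
    rng = _rng(seed, 4)
    nodes = [f"P{i:04d}" for i in range(n_nodes)]
    seeds = ["SEED_R1", "SEED_R2"]

    edges: list[ScoredEdge] = []
    seen: set[tuple[str, str]] = set()

    def add(u: str, v: str, s: float) -> None:
        key = (u, v) if u < v else (v, u)
        if key in seen or u == v:
            return
        seen.add(key)
        edges.append(ScoredEdge(key[0], key[1], float(np.round(s, 3))))

    # each seed touches about half the nodes with mid/low scores
    for sd in seeds:
        for i in rng.permutation(n_nodes)[: n_nodes // 2]:
            add(sd, nodes[i], rng.uniform(0.15, 0.55))
    # strong neighborhood shared by both seeds: deterministic high scores
    top = [nodes[i] for i in rng.permutation(n_nodes)[:n_planted_neighbors]]
    for rank, nb in enumerate(top):
        score = 0.99 - 0.01 * rank
        for sd in seeds:
            key = (sd, nb) if sd < nb else (nb, sd)
            seen.discard(key)
            edges = [e for e in edges if (e.node_u, e.node_v) != key]
            add(sd, nb, score)
    # sparse background edges among non-seed nodes
    for _ in range(n_nodes * 2):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            add(nodes[i], nodes[j], rng.uniform(0.15, 0.9))

    genesets = [GeneSet("TERM_PLANTED", "planted pathway", frozenset(top))]
    for t in range(n_decoy_terms):
        size = int(rng.integers(8, max(9, n_nodes // 4)))
        members = frozenset(nodes[i] for i in rng.permutation(n_nodes)[:size])
        genesets.append(GeneSet(f"TERM_D{t:02d}", f"decoy pathway {t}", members))

    truth = GroundTruth(planted_term="TERM_PLANTED")
    edges.sort(key=lambda e: (e.node_u, e.node_v))
    return edges, genesets, truth
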