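"""Bioactivity curation: parsing, structure standardization and filtering.

The curation stage turns a raw ChEMBL-style activity export into a clean
ligand set for one pharmacological role:

* role ``A`` — orthosteric agonists / partial agonists of the first
  receptor, retained when EC50 <= 500 nM;
* role ``B`` — positive allosteric modulators (PAMs) of the second
  receptor, retained when EC50 or IP (inflection point) <= 1000 nM, or
  when the cooperativity factor log(alpha*beta) is strictly positive.

The pipeline is eligibility -> deduplication -> potency.  Eligibility
keeps human single-protein assays whose description matches the role's
pharmacology and that carry no data-validity warning.  Deduplication
keeps a single assay type per compound (configurable priority) and
averages duplicate values within it.  All boundary comparisons are
inclusive.
"""

from __future__ import annotations

import csv
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import InvalidStructure, SchemaError, UnitError

RDLogger.DisableLog("rdApp.*")

# Concentration units accepted on input, with the factor to nanomolar.
_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "M": 1e9, "mM": 1e6}

#: standard_type values that denote a concentration measurement
CONCENTRATION_TYPES = frozenset({"EC50", "IP", "Ki", "IC50"})


@dataclass
class ActivityRecord:
    """One bioactivity measurement; the unit of curation."""

    compound_id: str
    smiles: str
    target_id: str
    organism: str
    target_type: str
    assay_description: str
    assay_type: str  # binding / functional / other
    standard_type: str  # EC50 / IP / Ki / IC50 / logAlphaBeta / other
    standard_value: float
    standard_units: str  # nM after normalization; "" for unitless
    data_validity_comment: str = ""


@dataclass
class CurationConfig:
    """Rules applied during eligibility, deduplication and potency filtering."""

    required_organism: str = "Homo sapiens"
    required_target_type: str = "SINGLE PROTEIN"
    # accepted (and, prefixed with "!", rejected) case-insensitive keywords
    # in the assay description, per role
    mode_keywords: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "A": ("agonis", "partial agonis", "!antagonis"),
            "B": ("positive allosteric", "pam"),
        }
    )
    potency_cutoff_nM: Mapping[str, float] = field(
        default_factory=lambda: {"A": 500.0, "B": 1000.0}
    )
    accept_positive_log_alpha_beta: bool = True
    # standard_type preference for "one assay type per compound"
    assay_type_priority: Sequence[str] = ("EC50", "IP", "Ki", "IC50")

    def __post_init__(self) -> None:
        if not self.assay_type_priority:
            raise SchemaError("assay_type_priority must be non-empty")
        for role, cut in self.potency_cutoff_nM.items():
            if cut <= 0:
                raise SchemaError(f"potency cutoff for role {role!r} must be > 0")


@dataclass
class LigandSet:
    """A named collection of curated compounds with canonical structures.

    ``members`` maps compound_id -> (canonical_smiles, potency).  The
    potency is the summary value in nM for concentration-gated members,
    or the log(alpha*beta) value for cooperativity-gated PAMs.
    """

    name: str
    role: str
    members: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [m[0] for m in self.members]

    @property
    def smiles(self) -> list[str]:
        return [m[1] for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["compound_id", "canonical_smiles", "potency"])
            for row in self.members:
                w.writerow(row)

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "", role: str = "A") -> "LigandSet":
        members = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                members.append(
                    (
                        row["compound_id"],
                        row["canonical_smiles"],
                        float(row.get("potency") or "nan"),
                    )
                )
        return cls(name=name or str(path), role=role, members=members)


@dataclass
class RejectionReport:
    """Per-rule rejection counts plus the individual rejected records."""

    counts: dict[str, int] = field(default_factory=dict)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (compound_id, reason)

    def add(self, compound_id: str, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1
        self.rejected.append((compound_id, reason))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"counts": self.counts, "rejected": self.rejected}, fh, indent=2
            )


def standardize_smiles(smiles: str) -> str:
    """Return the canonical SMILES of the largest organic fragment.

    Salt stripping keeps the fragment with the most heavy atoms
    (ties broken by canonical SMILES, favouring carbon-containing
    fragments).  The result is idempotent:
    ``standardize_smiles(standardize_smiles(s)) == standardize_smiles(s)``.

    Raises
    ------
    InvalidStructure
        If ``smiles`` does not parse.
    """
    if not smiles or not smiles.strip():
        raise InvalidStructure("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructure(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        def key(m: Chem.Mol) -> tuple:
            has_c = any(a.GetSymbol() == "C" for a in m.GetAtoms())
            return (has_c, m.GetNumHeavyAtoms(), Chem.MolToSmiles(m))

        mol = max(frags, key=key)
    return Chem.MolToSmiles(mol)


_MANDATORY = (
    "compound_id",
    "smiles",
    "target_id",
    "organism",
    "target_type",
    "assay_description",
    "assay_type",
    "standard_type",
    "standard_value",
    "standard_units",
)


def parse_activity_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[ActivityRecord], RejectionReport]:
    """Parse a delimited activity table into :class:`ActivityRecord` rows.

    ``schema`` maps record field names to column headers in the file;
    identity mapping by default.  Concentration values are normalized to
    nM.  Rows that fail structural parsing or unit conversion are
    collected in the returned :class:`RejectionReport`, never silently
    dropped.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    schema = dict(schema or {})
    colmap = {f: schema.get(f, f) for f in _MANDATORY}
    colmap["data_validity_comment"] = schema.get(
        "data_validity_comment", "data_validity_comment"
    )

    records: list[ActivityRecord] = []
    report = RejectionReport()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for f, c in colmap.items() if f != "data_validity_comment" and c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        for row in reader:
            cid = row[colmap["compound_id"]]
            smi = (row[colmap["smiles"]] or "").strip()
            if not smi:
                report.add(cid, "missing structure")
                continue
            if Chem.MolFromSmiles(smi) is None:
                report.add(cid, "unparseable structure")
                continue
            stype = row[colmap["standard_type"]]
            units = (row[colmap["standard_units"]] or "").strip()
            try:
                value = float(row[colmap["standard_value"]])
            except (TypeError, ValueError):
                report.add(cid, "non-numeric value")
                continue
            if stype in CONCENTRATION_TYPES:
                if units not in _UNIT_TO_NM:
                    report.add(cid, f"unsupported units: {units or 'none'}")
                    continue
                value *= _UNIT_TO_NM[units]
                if value < 0:
                    report.add(cid, "negative concentration")
                    continue
                units = "nM"
            records.append(
                ActivityRecord(
                    compound_id=cid,
                    smiles=smi,
                    target_id=row[colmap["target_id"]],
                    organism=row[colmap["organism"]],
                    target_type=row[colmap["target_type"]],
                    assay_description=row[colmap["assay_description"]],
                    assay_type=row[colmap["assay_type"]],
                    standard_type=stype,
                    standard_value=value,
                    standard_units=units,
                    data_validity_comment=(row.get(colmap["data_validity_comment"]) or "").strip(),
                )
            )
    return records, report


def _mode_matches(description: str, patterns: Sequence[str]) -> bool:
    """Case-insensitive keyword match with "!"-prefixed veto patterns."""
    desc = description.lower()
    vetoes = [p[1:].lower() for p in patterns if p.startswith("!")]
    accepts = [p.lower() for p in patterns if not p.startswith("!")]
    if any(v in desc for v in vetoes):
        return False
    return any(a in desc for a in accepts)


def apply_eligibility_filters(
    records: Iterable[ActivityRecord],
    config: CurationConfig,
    role: str,
    report: RejectionReport | None = None,
) -> tuple[list[ActivityRecord], RejectionReport]:
    """Keep records from human single-protein assays in the right mode.

    A record survives iff its organism and target type match the config,
    its assay description matches the role's mode keywords, and its
    data-validity comment is empty.
    """
    report = report if report is not None else RejectionReport()
    patterns = config.mode_keywords[role]
    kept: list[ActivityRecord] = []
    for r in records:
        if r.organism != config.required_organism:
            report.add(r.compound_id, "organism mismatch")
        elif r.target_type != config.required_target_type:
            report.add(r.compound_id, "target type mismatch")
        elif not _mode_matches(r.assay_description, patterns):
            report.add(r.compound_id, "assay mode mismatch")
        elif r.data_validity_comment:
            report.add(r.compound_id, "data validity warning")
        else:
            kept.append(r)
    return kept, report


def deduplicate(
    records: Sequence[ActivityRecord], config: CurationConfig
) -> list[ActivityRecord]:
    """Collapse each compound to one record.

    For every compound the highest-priority standard type present (per
    ``config.assay_type_priority``) is selected; remaining duplicate
    values within it are replaced by their arithmetic mean.  Types not
    in the priority list (e.g. the unitless cooperativity factor) are
    kept as separate per-type summaries so the potency filter can see
    them; the compound still contributes at most one record per type.
    """
    by_compound: dict[str, list[ActivityRecord]] = defaultdict(list)
    order: list[str] = []
    for r in records:
        if r.compound_id not in by_compound:
            order.append(r.compound_id)
        by_compound[r.compound_id].append(r)

    prio = {t: i for i, t in enumerate(config.assay_type_priority)}
    out: list[ActivityRecord] = []
    for cid in order:
        recs = by_compound[cid]
        conc = [r for r in recs if r.standard_type in prio]
        other = [r for r in recs if r.standard_type not in prio]
        if conc:
            best_type = min((r.standard_type for r in conc), key=prio.__getitem__)
            chosen = [r for r in conc if r.standard_type == best_type]
            units = {r.standard_units for r in chosen}
            if len(units) > 1:
                raise UnitError(f"irreconcilable units for compound {cid}: {sorted(units)}")
            mean_val = sum(r.standard_value for r in chosen) / len(chosen)
            proto = chosen[0]
            out.append(
                ActivityRecord(
                    compound_id=proto.compound_id,
                    smiles=proto.smiles,
                    target_id=proto.target_id,
                    organism=proto.organism,
                    target_type=proto.target_type,
                    assay_description=proto.assay_description,
                    assay_type=proto.assay_type,
                    standard_type=best_type,
                    standard_value=mean_val,
                    standard_units=proto.standard_units,
                    data_validity_comment="",
                )
            )
        for stype in sorted({r.standard_type for r in other}):
            same = [r for r in other if r.standard_type == stype]
            mean_val = sum(r.standard_value for r in same) / len(same)
            proto = same[0]
            out.append(
                ActivityRecord(
                    compound_id=proto.compound_id,
                    smiles=proto.smiles,
                    target_id=proto.target_id,
                    organism=proto.organism,
                    target_type=proto.target_type,
                    assay_description=proto.assay_description,
                    assay_type=proto.assay_type,
                    standard_type=stype,
                    standard_value=mean_val,
                    standard_units=proto.standard_units,
                    data_validity_comment="",
                )
            )
    return out


def apply_potency_filter(
    records: Sequence[ActivityRecord],
    config: CurationConfig,
    role: str,
    name: str = "",
    report: RejectionReport | None = None,
) -> tuple[LigandSet, RejectionReport]:
    """Gate deduplicated records on potency and build the ligand set.

    Role ``A``: keep iff EC50 <= cutoff (500 nM default, inclusive).
    Role ``B``: keep iff EC50 or IP <= cutoff (1000 nM default), or
    log(alpha*beta) > 0 when ``accept_positive_log_alpha_beta`` is set.
    """
    report = report if report is not None else RejectionReport()
    cutoff = config.potency_cutoff_nM[role]
    by_compound: dict[str, list[ActivityRecord]] = defaultdict(list)
    order: list[str] = []
    for r in records:
        if r.compound_id not in by_compound:
            order.append(r.compound_id)
        by_compound[r.compound_id].append(r)

    qualifying = {"A": ("EC50",), "B": ("EC50", "IP")}[role]
    members: list[tuple[str, str, float]] = []
    for cid in order:
        recs = by_compound[cid]
        conc = [r for r in recs if r.standard_type in qualifying]
        coop = [r for r in recs if r.standard_type == "logAlphaBeta"]
        passed = None
        if conc and conc[0].standard_value <= cutoff:
            passed = conc[0].standard_value
        elif (
            role == "B"
            and config.accept_positive_log_alpha_beta
            and coop
            and coop[0].standard_value > 0
        ):
            passed = coop[0].standard_value
        if passed is None:
            if not conc and not coop:
                report.add(cid, "no qualifying measurement")
            else:
                report.add(cid, "potency above cutoff")
            continue
        members.append((cid, standardize_smiles(recs[0].smiles), passed))
    return LigandSet(name=name or f"role_{role}", role=role, members=members), report


def curate(
    records: Iterable[ActivityRecord],
    config: CurationConfig,
    role: str,
    name: str = "",
) -> tuple[LigandSet, RejectionReport]:
    """Full curation pipeline: eligibility -> deduplicate -> potency."""
    report = RejectionReport()
    eligible, report = apply_eligibility_filters(records, config, role, report)
    deduped = deduplicate(eligible, config)
    return apply_potency_filter(deduped, config, role, name=name, report=report)
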