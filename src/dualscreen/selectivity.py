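"""Selectivity filtering of consensus candidates against off-target data.

A candidate that is nearly as potent at a reported off-target as at its
intended receptor is a promiscuity liability.  The filter computes, for
each off-target record, the fold window

    window = off_target_potency / on_target_potency

(both in nM; larger = more selective for the intended target) and
excludes the candidate if any non-allowlisted off-target gives a window
below the configured fold cutoff (default 10).  Efflux-transporter
liabilities such as P-glycoprotein are allowlisted by default: binding
there does not indicate pharmacological promiscuity and may stay
relevant for peripheral indications.  Candidates with no off-target
records are retained (absence of evidence), and records carrying only a
qualitative flag (no potency) annotate but never exclude.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .curation import LigandSet
from .errors import DualScreenError


@dataclass
class OffTargetRecord:
    compound_id: str
    off_target_id: str
    off_target_name: str
    potency_nM: float | None  # None = qualitative-only flag
    potency_type: str = "Ki"


@dataclass
class SelectivityConfig:
    window: float = 10.0
    allowlist: frozenset[str] = frozenset({"P-glycoprotein"})

    def __post_init__(self) -> None:
        if self.window <= 1:
            raise DualScreenError("selectivity window must be > 1")


@dataclass
class ExclusionReport:
    excluded: dict[str, dict] = field(default_factory=dict)
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"excluded": self.excluded, "annotations": self.annotations},
                fh, indent=2,
            )


def selectivity_window(on_potency_nM: float, off_potency_nM: float) -> float:
    """Fold selectivity off/on; requires both potencies > 0."""
    if on_potency_nM <= 0 or off_potency_nM <= 0:
        raise DualScreenError("potencies must be positive")
    return off_potency_nM / on_potency_nM


def load_offtarget_csv(path: str | Path) -> list[OffTargetRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = (row.get("potency_nM") or "").strip()
            records.append(
                OffTargetRecord(
                    compound_id=row["compound_id"],
                    off_target_id=row.get("off_target_id", ""),
                    off_target_name=row.get("off_target_name", ""),
                    potency_nM=float(raw) if raw else None,
                    potency_type=row.get("potency_type", ""),
                )
            )
    return records


def filter_promiscuous(
    candidates: LigandSet,
    off_records: Iterable[OffTargetRecord],
    config: SelectivityConfig | None = None,
    on_potency: Mapping[str, float] | None = None,
) -> tuple[LigandSet, ExclusionReport]:
    """Split candidates into retained and excluded by the window rule.

    On-target potencies default to the ligand set's member potency
    column; an explicit ``on_potency`` map overrides.  A candidate is
    excluded iff at least one non-allowlisted off-target record yields
    ``window < config.window``.
    """
    config = config or SelectivityConfig()
    by_compound: dict[str, list[OffTargetRecord]] = {}
    for r in off_records:
        by_compound.setdefault(r.compound_id, []).append(r)

    potency = dict(on_potency) if on_potency else {
        cid: pot for cid, _, pot in candidates.members
    }

    report = ExclusionReport()
    retained: list[tuple[str, str, float]] = []
    for cid, smi, pot in candidates.members:
        on = potency.get(cid, pot)
        verdict_excluded = False
        for rec in by_compound.get(cid, []):
            if rec.off_target_name in config.allowlist:
                continue
            if rec.potency_nM is None:
                report.annotations.setdefault(cid, []).append(
                    f"qualitative off-target flag: {rec.off_target_name}"
                )
                continue
            w = selectivity_window(on, rec.potency_nM)
            if w < config.window:
                report.excluded[cid] = {
                    "off_target": rec.off_target_name,
                    "off_potency_nM": rec.potency_nM,
                    "on_potency_nM": on,
                    "window": w,
                }
                verdict_excluded = True
                break
        if not verdict_excluded:
            retained.append((cid, smi, pot))

    retained_set = LigandSet(
        name=f"{candidates.name}_selective", role=candidates.role, members=retained
    )
    return retained_set, report
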