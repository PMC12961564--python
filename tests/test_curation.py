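"""Curation rules: parsing, standardization, eligibility, dedup, potency."""

from __future__ import annotations

import pytest

from dualscreen.curation import (
    ActivityRecord,
    CurationConfig,
    LigandSet,
    apply_eligibility_filters,
    apply_potency_filter,
    curate,
    deduplicate,
    parse_activity_table,
    standardize_smiles,
)
from dualscreen.errors import InvalidStructure, SchemaError, UnitError
from dualscreen.synthetic_data import activity_records_to_csv, generate_activity_table


def make_record(**kw) -> ActivityRecord:
    base = dict(
        compound_id="C1", smiles="CCO", target_id="T", organism="Homo sapiens",
        target_type="SINGLE PROTEIN",
        assay_description="Agonist activity at human receptor",
        assay_type="functional", standard_type="EC50",
        standard_value=100.0, standard_units="nM", data_validity_comment="",
    )
    base.update(kw)
    return ActivityRecord(**base)


class TestStandardize:
    def test_salt_strip_keeps_largest_organic_fragment(self):
        assert standardize_smiles("CCO.Cl") == standardize_smiles("CCO")

    def test_canonicalization_is_writing_order_invariant(self):
        assert standardize_smiles("OCC") == standardize_smiles("CCO")

    @pytest.mark.parametrize("bad", ["C1CC", "", "not-a-smiles"])
    def test_unparseable_raises(self, bad):
        with pytest.raises(InvalidStructure):
            standardize_smiles(bad)

    def test_idempotent_on_benchmark(self, benchmark):
        _, set_a, set_b, _ = benchmark
        for smi in set_a.smiles + set_b.smiles:
            assert standardize_smiles(smi) == smi


class TestParse(object):
    HEADER = (
        "compound_id,smiles,target_id,organism,target_type,assay_description,"
        "assay_type,standard_type,standard_value,standard_units,data_validity_comment\n"
    )

    def write(self, tmp_path, rows):
        p = tmp_path / "acts.csv"
        p.write_text(self.HEADER + "".join(rows))
        return p

    def test_direct_mapping_and_unit_conversion(self, tmp_path):
        p = self.write(tmp_path, [
            "CHEMBL001,CCO,T,Homo sapiens,SINGLE PROTEIN,Agonist,functional,EC50,500,nM,\n",
            "CHEMBL002,CCO,T,Homo sapiens,SINGLE PROTEIN,Agonist,functional,EC50,0.5,uM,\n",
        ])
        records, report = parse_activity_table(p)
        assert [r.standard_value for r in records] == [500.0, 500.0]
        assert all(r.standard_units == "nM" for r in records)
        assert not report.rejected

    def test_missing_structure_reported_not_dropped_silently(self, tmp_path):
        p = self.write(tmp_path, [
            "CHEMBL003,,T,Homo sapiens,SINGLE PROTEIN,Agonist,functional,EC50,10,nM,\n",
        ])
        records, report = parse_activity_table(p)
        assert records == []
        assert report.rejected == [("CHEMBL003", "missing structure")]

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("compound_id,smiles\nX,CCO\n")
        with pytest.raises(SchemaError):
            parse_activity_table(p)


class TestEligibility:
    @pytest.mark.parametrize(
        "kw,kept",
        [
            ({}, True),
            ({"data_validity_comment": "Potential author error"}, False),
            ({"assay_description": "Antagonist activity at human receptor"}, False),
            ({"organism": "Rattus norvegicus"}, False),
            ({"target_type": "PROTEIN COMPLEX"}, False),
        ],
    )
    def test_role_a_rules(self, kw, kept):
        out, _ = apply_eligibility_filters([make_record(**kw)], CurationConfig(), "A")
        assert bool(out) is kept

    def test_pam_keywords_for_role_b(self):
        rec = make_record(assay_description="Positive allosteric modulation of receptor")
        out, _ = apply_eligibility_filters([rec], CurationConfig(), "B")
        assert len(out) == 1
        out, _ = apply_eligibility_filters([make_record()], CurationConfig(), "B")
        assert out == []


class TestDeduplicate:
    def test_mean_of_duplicate_values(self):
        recs = [make_record(standard_value=100.0), make_record(standard_value=300.0)]
        out = deduplicate(recs, CurationConfig())
        assert len(out) == 1
        assert out[0].standard_value == 200.0

    def test_assay_type_priority(self):
        recs = [
            make_record(standard_type="Ki", standard_value=5.0),
            make_record(standard_type="EC50", standard_value=50.0),
        ]
        out = deduplicate(recs, CurationConfig())
        assert len(out) == 1
        assert out[0].standard_type == "EC50"

    def test_single_record_identity(self):
        rec = make_record()
        out = deduplicate([rec], CurationConfig())
        assert len(out) == 1
        assert out[0].standard_value == rec.standard_value

    def test_irreconcilable_units_name_the_compound(self):
        recs = [
            make_record(standard_units="nM"),
            make_record(standard_units="mg/mL"),
        ]
        with pytest.raises(UnitError, match="C1"):
            deduplicate(recs, CurationConfig())

    def test_mean_lies_within_range(self):
        vals = [10.0, 70.0, 400.0]
        out = deduplicate([make_record(standard_value=v) for v in vals], CurationConfig())
        assert min(vals) <= out[0].standard_value <= max(vals)


class TestPotency:
    def test_role_a_boundary_inclusive(self):
        out, _ = apply_potency_filter(
            [make_record(standard_value=500.0)], CurationConfig(), "A"
        )
        assert out.ids == ["C1"]

    def test_role_a_above_cutoff_excluded(self):
        out, rep = apply_potency_filter(
            [make_record(standard_value=500.01)], CurationConfig(), "A"
        )
        assert len(out) == 0
        assert rep.counts.get("potency above cutoff") == 1

    def test_role_b_positive_cooperativity_retains(self):
        rec = make_record(standard_type="logAlphaBeta", standard_value=0.3,
                          standard_units="")
        out, _ = apply_potency_filter([rec], CurationConfig(), "B")
        assert out.ids == ["C1"]

    def test_role_b_zero_cooperativity_is_not_positive(self):
        rec = make_record(standard_type="logAlphaBeta", standard_value=0.0,
                          standard_units="")
        out, _ = apply_potency_filter([rec], CurationConfig(), "B")
        assert len(out) == 0

    def test_role_b_fails_both_criteria(self):
        rec = make_record(standard_value=1500.0)
        out, _ = apply_potency_filter([rec], CurationConfig(), "B")
        assert len(out) == 0

    def test_no_qualifying_measurement_reason(self):
        rec = make_record(standard_type="Ki", standard_value=5.0)
        out, rep = apply_potency_filter([rec], CurationConfig(), "B")
        assert len(out) == 0
        assert rep.counts.get("no qualifying measurement") == 1


def brute_force_curate(records, config, role):
    """Single-pass oracle: per-compound rule evaluation by explicit loops."""
    from dualscreen.curation import _mode_matches

    eligible = [
        r for r in records
        if r.organism == config.required_organism
        and r.target_type == config.required_target_type
        and _mode_matches(r.assay_description, config.mode_keywords[role])
        and not r.data_validity_comment
    ]
    passed = set()
    for cid in {r.compound_id for r in eligible}:
        recs = [r for r in eligible if r.compound_id == cid]
        prio = {t: i for i, t in enumerate(config.assay_type_priority)}
        conc = [r for r in recs if r.standard_type in prio]
        cutoff = config.potency_cutoff_nM[role]
        qual = ("EC50",) if role == "A" else ("EC50", "IP")
        value = None
        if conc:
            best = min((r.standard_type for r in conc), key=prio.__getitem__)
            chosen = [r.standard_value for r in conc if r.standard_type == best]
            if best in qual:
                value = sum(chosen) / len(chosen)
        if value is not None and value <= cutoff:
            passed.add(cid)
            continue
        if role == "B":
            coop = [r.standard_value for r in recs if r.standard_type == "logAlphaBeta"]
            if coop and sum(coop) / len(coop) > 0:
                passed.add(cid)
    return passed


@pytest.mark.parametrize("role,seed", [("A", 11), ("B", 12)])
def test_pipeline_matches_single_pass_oracle(role, seed, tmp_path):
    """Eligibility -> dedup -> potency equals a brute-force per-compound pass."""
    ligands = LigandSet("toy", role, [
        (f"L{i}", smi, 100.0)
        for i, smi in enumerate(["CCO", "c1ccccc1", "CCN", "c1ccncc1", "CCCO"])
    ])
    records, _ = generate_activity_table(ligands, seed, role=role)
    path = tmp_path / "acts.csv"
    activity_records_to_csv(records, path)
    parsed, _ = parse_activity_table(path)
    assert len(parsed) <= 50

    config = CurationConfig()
    curated, report = curate(parsed, config, role)
    assert set(curated.ids) == brute_force_curate(parsed, config, role)
    # conservation: every input record is either retained or rejected
    retained_records = sum(
        1 for r in parsed if r.compound_id in set(curated.ids)
    )
    assert len(report.rejected) + retained_records == len(parsed)


def test_output_never_larger_than_input():
    recs = [make_record(compound_id=f"C{i}") for i in range(5)]
    config = CurationConfig()
    eligible, _ = apply_eligibility_filters(recs, config, "A")
    deduped = deduplicate(eligible, config)
    final, _ = apply_potency_filter(deduped, config, "A")
    assert len(final) <= len(deduped) <= len(eligible) <= len(recs)
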