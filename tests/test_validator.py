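"""Record normalization, validation checks, batch contract, corrections."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnmstage import generate_records
from tnmstage.validator import (
    CaseRecord,
    normalize_record,
    propose_corrections,
    read_records_csv,
    records_to_frame,
    render_corrections,
    validate_batch,
    validate_record,
)


def raw_fig8(**over):
    raw = {
        "record_id": "fig8", "tnm_edition": "7", "topography": "C50.1",
        "morphology": "8050/2", "pT": "is", "cN": "0", "cM": "0",
        "stage_group": "0",
    }
    raw.update(over)
    return raw


class TestNormalizeRecord:
    def test_dots_slashes_and_prefixes(self):
        rec = normalize_record(raw_fig8())
        assert rec.topography == "C501"
        assert rec.morphology == "M_8050"
        assert rec.behaviour == "2"
        assert rec.pT == "PTis" and rec.cN == "CN0" and rec.cM == "CM0"
        assert rec.declared_stage == "0"
        assert rec.format_findings == []

    def test_idempotent_via_csv_dialect(self):
        rec = normalize_record(raw_fig8())
        row = records_to_frame([rec]).to_dict(orient="records")[0]
        again = normalize_record(row)
        assert again == rec

    def test_malformed_morphology_is_a_format_finding(self):
        rec = normalize_record(raw_fig8(morphology="815X/3"))
        assert any(f.check_id == "V6" and f.field == "morphology"
                   for f in rec.format_findings)

    def test_case_and_prefix_tolerance(self):
        rec = normalize_record({"record_id": "r", "pT": "pT1A", "cN": "cn2B",
                                "cM": "M1", "cT": "T1a"})
        assert rec.pT == "PT1a" and rec.cN == "CN2b"
        assert rec.cM == "CM1" and rec.cT == "CT1a"

    def test_behaviour_conflict_prefers_slash_with_warning(self):
        rec = normalize_record(raw_fig8(morphology="8050/2", behaviour="3"))
        assert rec.behaviour == "2"
        assert any(f.severity == "warning" for f in rec.format_findings)


class TestValidateRecord:
    def test_fig8_record_is_valid_stage_0(self, kb):
        rep = validate_record(kb, normalize_record(raw_fig8()))
        assert rep.verdict == "valid"
        assert rep.inferred_site == "TNMSiteEd7Breast"
        assert rep.inferred_stage == "0"
        assert rep.findings == []

    def test_declared_iv_against_inferred_0(self, kb):
        rep = validate_record(kb, normalize_record(raw_fig8(stage_group="IV")))
        assert rep.verdict == "invalid"
        v5 = [f for f in rep.errors() if f.check_id == "V5"]
        assert len(v5) == 1 and v5[0].expected == ("0",)
        # stage IV also demands invasive behaviour, so V3 flags the in situ code
        assert any(f.check_id == "V3" for f in rep.errors())

    def test_iiic_requires_t_inside_code_space(self, kb):
        """A T outside the breast space blocks IIIC even with N3 M0: the
        code-space term on the rule's left-hand side is what catches the
        data-validation error a T-independent rule would miss."""
        rep = validate_record(kb, normalize_record({
            "record_id": "r", "tnm_edition": "7", "topography": "C50.2",
            "morphology": "8500/3", "cT": "9", "cN": "3", "cM": "0",
            "stage_group": "IIIC"}))
        assert rep.inferred_stage is None
        assert [f.check_id for f in rep.errors()] == ["V2"]

    def test_stage0_demands_in_situ_behaviour(self, kb):
        rep = validate_record(kb, normalize_record(raw_fig8(morphology="8050/3")))
        assert any(f.check_id == "V3" and f.expected == ("2",)
                   for f in rep.errors())

    def test_unknown_declared_stage_for_site(self, kb):
        rep = validate_record(kb, normalize_record(raw_fig8(stage_group="IVB")))
        v4 = [f for f in rep.errors() if f.check_id == "V4"]
        assert len(v4) == 1 and "IIIC" in v4[0].expected

    def test_record_without_tnm_data_is_unstaged(self, kb):
        rep = validate_record(kb, normalize_record({
            "record_id": "r", "tnm_edition": "7", "topography": "C509",
            "morphology": "8140/3"}))
        assert rep.verdict == "unstaged"
        assert rep.findings == [] and rep.inferred_site == "TNMSiteEd7Breast"

    def test_unknown_topography_is_ineligible(self, kb):
        rep = validate_record(kb, normalize_record(raw_fig8(topography="C99.9")))
        assert rep.verdict == "ineligible"
        assert [f.check_id for f in rep.errors()] == ["V1"]

    def test_non_carcinoma_morphology_is_ineligible_for_breast(self, kb):
        rep = validate_record(kb, normalize_record(raw_fig8(morphology="9050/3")))
        assert rep.verdict == "ineligible"

    def test_x_code_abstains_from_staging(self, kb):
        rep = validate_record(kb, normalize_record({
            "record_id": "r", "tnm_edition": "7", "topography": "C501",
            "morphology": "8500/3", "cT": "X", "cN": "3", "cM": "0",
            "stage_group": "IIIC"}))
        assert rep.inferred_stage is None
        assert not any(f.check_id == "V5" for f in rep.findings)
        assert rep.verdict == "valid"  # X participates in V2 only

    def test_lenient_accepts_coarse_declared_stage(self, kb):
        raw = {"record_id": "r", "tnm_edition": "7", "topography": "C501",
               "morphology": "8500/3", "pT": "2", "pN": "3a", "pM": "0",
               "stage_group": "III"}
        strict = validate_record(kb, normalize_record(raw))
        lenient = validate_record(kb, normalize_record(raw),
                                  strictness="lenient-stage")
        assert strict.verdict == "invalid"
        assert any(f.check_id == "V4" for f in strict.errors())
        assert lenient.verdict == "valid"
        assert lenient.inferred_stage == "IIIC"

    def test_pathological_precedes_clinical_for_staging(self, kb):
        raw = {"record_id": "r", "tnm_edition": "7", "topography": "C501",
               "morphology": "8500/3", "cT": "1", "pT": "2", "cN": "0",
               "pN": "0", "cM": "0", "stage_group": "IIA"}
        rep = validate_record(kb, normalize_record(raw))
        assert rep.inferred_stage == "IIA" and rep.verdict == "valid"

    def test_malformed_record_is_excluded_from_staging(self, kb):
        rep = validate_record(kb, normalize_record(raw_fig8(pT="1$")))
        assert rep.verdict == "invalid"
        assert rep.inferred_site is None
        assert [f.check_id for f in rep.errors()] == ["V6"]


class TestBatch:
    def test_179_records_yield_179_reports(self, kb):
        pairs = generate_records(kb, per_site=60, seed=3)
        records = [rec for rec, _ in pairs][:179]
        reports = validate_batch(kb, records, block_size=50, mode="direct")
        assert len(reports) == 179
        assert [r.record_id for r in reports] == [r.record_id for r in records]

    @settings(max_examples=10, deadline=None)
    @given(block_size=st.integers(min_value=1, max_value=60))
    def test_reports_independent_of_block_size(self, kb, block_size):
        pairs = generate_records(kb, per_site=9, seed=11)
        records = [rec for rec, _ in pairs]
        baseline = validate_batch(kb, records, block_size=1, mode="direct")
        got = validate_batch(kb, records, block_size=block_size, mode="direct")
        assert [r.__dict__ for r in got] == [r.__dict__ for r in baseline]

    def test_reasoner_and_direct_modes_agree(self, kb):
        pairs = generate_records(kb, per_site=15, seed=5)
        records = [rec for rec, _ in pairs]
        a = validate_batch(kb, records, mode="reasoner")
        b = validate_batch(kb, records, mode="direct")
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]


class TestCorrections:
    def fig12_record(self):
        # declared stage 0 but T=T1 and behaviour 3: both parameters wrong
        return normalize_record({
            "record_id": "fig12", "tnm_edition": "7", "topography": "C501",
            "morphology": "8050/3", "cT": "1", "cN": "0", "cM": "0",
            "stage_group": "0"})

    def test_unique_proposals_for_t_and_behaviour(self, kb):
        rec = self.fig12_record()
        rep = validate_record(kb, rec)
        props = propose_corrections(kb, rec, rep)
        assert ("T", ("PTis",), True) in props
        assert ("behaviour", ("2",), True) in props
        assert len(props) == 2

    def test_rendering_marks_wrong_inputs(self, kb):
        rec = self.fig12_record()
        props = propose_corrections(kb, rec, validate_record(kb, rec))
        text = render_corrections(rec, props)
        assert "» PTis !" in text and "» 2 !" in text
        assert "CN0     » CN0" in text  # correct inputs are not flagged

    def test_valid_record_has_no_proposals(self, kb):
        rec = normalize_record(raw_fig8())
        assert propose_corrections(kb, rec, validate_record(kb, rec)) == []

    def test_multiple_admissible_values_are_not_unique(self, kb):
        rec = normalize_record({
            "record_id": "r", "tnm_edition": "7", "topography": "C501",
            "morphology": "8500/3", "cT": "9", "cN": "3", "cM": "0",
            "stage_group": "IIIC"})
        props = propose_corrections(kb, rec, validate_record(kb, rec))
        (field, values, unique) = props[0]
        assert field == "T" and unique is False
        # every non-X breast T code satisfies the "Any T" IIIC rule
        assert len(values) == 26

    def test_unique_proposals_repair_generated_records(self, kb):
        """Applying every unique proposal to a corrupted record yields a
        record that validates as valid (soundness of correction)."""
        rng = random.Random(4)
        pairs = generate_records(kb, per_site=30, seed=rng.randint(0, 10**6))
        checked = 0
        for rec, label in pairs:
            if label.scenario != "corrupted_parameter":
                continue
            rep = validate_record(kb, rec, mode="direct")
            props = propose_corrections(kb, rec, rep)
            if not props or not all(unique for _f, _v, unique in props):
                continue
            fixed = CaseRecord(**{k: v for k, v in rec.__dict__.items()
                                  if k != "format_findings"})
            for field, values, _unique in props:
                value = values[0]
                if field == "behaviour":
                    fixed.behaviour = value
                else:
                    setattr(fixed, "c" + field, None)
                    setattr(fixed, "p" + field, None)
                    attr = ("p" if value.startswith("P") else "c") + field
                    setattr(fixed, attr, value)
            assert validate_record(kb, fixed, mode="direct").verdict == "valid"
            checked += 1
        assert checked >= 5


class TestCsvDialect:
    def test_round_trip_through_frame(self, kb, tmp_path):
        pairs = generate_records(kb, per_site=6, seed=2)
        records = [rec for rec, _ in pairs]
        path = tmp_path / "records.csv"
        records_to_frame(records).to_csv(path, index=False)
        again = read_records_csv(path)
        for a, b in zip(records, again):
            assert a == b
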