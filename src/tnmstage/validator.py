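"""Registry-record normalization, validation, staging and error correction.

A record carries the summary facts a cancer registry holds for one case:
ICD-O-3 topography, morphology and behaviour, optional grade and age, the
TNM edition, clinical/pathological T, N, M codes, and the declared stage
group.  Validation resolves the TNM site from topography + morphology +
edition, checks every code against the site's edition-specific code space,
infers the stage group from the codes, and compares it with the declared
stage.  Two execution modes are supported — ``reasoner`` (generic
saturation) and ``direct`` (indexed single-pass lookup) — with an exact
equivalence contract between them.

Checks
------
V1  site resolution (topography + morphology + edition -> one edition-site)
V2  T/N/M code inside the site's declared code space
V3  behaviour consistent with the declared stage (stage 0 = in situ)
V4  declared stage among the site's permissible stage groups
V5  declared stage equals the most specific inferred stage
V6  code syntax / record format
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .engine import (
    FactSet,
    classify_direct,
    most_specific_stages,
    query_stage_groups,
    saturate,
)
from .model import Atomic, Existential, KnowledgeBase, NumericCondition

logger = logging.getLogger("tnmstage")

STAGE_PREFIX = "TNMStage"

#: CSV dialect of the batch interface (empty string = absent).
CSV_COLUMNS = [
    "record_id", "tnm_edition", "topography", "morphology", "behaviour",
    "grade", "age", "cT", "cN", "cM", "pT", "pN", "pM", "stage_group",
]

_BEHAVIOUR_DIGITS = {"0", "1", "2", "3", "6", "9"}


@dataclass
class ValidationFinding:
    check_id: str  # V1..V6
    severity: str  # error | warning
    field: str
    message: str
    expected: tuple[str, ...] = ()


@dataclass
class CaseRecord:
    """One registry record, in normalized (concept-token) form."""

    record_id: str
    tnm_edition: Optional[int] = None
    topography: Optional[str] = None  # e.g. C501
    morphology: Optional[str] = None  # e.g. M_8050
    behaviour: Optional[str] = None  # digit
    grade: Optional[str] = None  # digit
    age: Optional[int] = None
    cT: Optional[str] = None  # concept ids, e.g. CT1a
    cN: Optional[str] = None
    cM: Optional[str] = None
    pT: Optional[str] = None  # e.g. PTis
    pN: Optional[str] = None
    pM: Optional[str] = None
    declared_stage: Optional[str] = None  # numeral, e.g. "0", "IIIC"
    format_findings: list[ValidationFinding] = field(default_factory=list)

    def has_tnm_data(self) -> bool:
        return any(
            v is not None
            for v in (self.cT, self.cN, self.cM, self.pT, self.pN, self.pM,
                      self.declared_stage)
        )

    def effective(self, category: str) -> tuple[Optional[str], Optional[str]]:
        """(field name, code) used for staging: pathological first."""
        p = getattr(self, "p" + category)
        if p is not None:
            return "p" + category, p
        c = getattr(self, "c" + category)
        if c is not None:
            return "c" + category, c
        return None, None


@dataclass
class ValidationReport:
    record_id: str
    findings: list[ValidationFinding] = field(default_factory=list)
    inferred_site: Optional[str] = None
    inferred_stage: Optional[str] = None  # numeral
    verdict: str = "valid"  # valid | invalid | unstaged | ineligible

    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    def summary(self) -> dict:
        return {
            "record_id": self.record_id,
            "verdict": self.verdict,
            "inferred_site": self.inferred_site or "",
            "inferred_stage": self.inferred_stage or "",
            "n_errors": len(self.errors()),
        }


# ---------------------------------------------------------------------------
# Normalization

_TOPO_RE = re.compile(r"^C\d{2}\d?$")
_MORPH_RE = re.compile(r"^(?:M[_-])?(\d{4})(?:/(\d))?$", re.IGNORECASE)
_TNM_BASE_RE = re.compile(r"^(?:IS|X|\d{1,2}(?:MI|[A-D])?)$", re.IGNORECASE)


def stage_concept(numeral: str) -> str:
    return STAGE_PREFIX + numeral


def stage_numeral(concept: str) -> str:
    return concept[len(STAGE_PREFIX):] if concept.startswith(STAGE_PREFIX) else concept


def _norm_tnm_code(value: str, category: str, prefix: str) -> Optional[str]:
    """Canonical concept token for a T/N/M value, or None when malformed.

    Accepts ``is``, ``1a``, ``T1a``, ``pT1a``, ``x`` ...; the C/P prefix is
    taken from the field of origin, not the value.
    """
    v = value.strip()
    if not v:
        return None
    low = v.lower()
    if low[0] in "cp" and len(low) > 1 and (low[1] == category.lower() or low[1:2].isdigit()):
        low = low[1:]
    if low.startswith(category.lower()):
        low = low[1:]
    if not _TNM_BASE_RE.match(low):
        raise ValueError(f"malformed {category} code {value!r}")
    if low == "is":
        base = "is"
    elif low == "x":
        base = "X"
    else:
        base = low  # digits + lowercase suffix
    return f"{prefix}{category}{base}"


def normalize_record(raw: dict) -> CaseRecord:
    """Normalize one raw CSV row (strings) into a :class:`CaseRecord`.

    Dots are stripped from topography (C50.1 -> C501), ``8140/3`` is split
    into morphology + behaviour, and T/N/M codes get their C/P prefix from
    the clinical/pathological field of origin.  Idempotent on normalized
    input.  Malformed code syntax yields a V6 finding and excludes the
    record from staging; missing optional fields stay absent.
    """
    rec = CaseRecord(record_id=str(raw.get("record_id", "")).strip())
    findings = rec.format_findings

    def bad(field_name: str, message: str) -> None:
        findings.append(ValidationFinding("V6", "error", field_name, message))

    v = str(raw.get("tnm_edition", "") or "").strip()
    if v:
        try:
            rec.tnm_edition = int(v)
        except ValueError:
            bad("tnm_edition", f"malformed TNM edition {v!r}")

    v = str(raw.get("topography", "") or "").strip().upper().replace(".", "")
    if v:
        if _TOPO_RE.match(v):
            rec.topography = v
        else:
            bad("topography", f"malformed topography code {v!r}")

    v = str(raw.get("morphology", "") or "").strip()
    slash_behaviour = None
    if v:
        m = _MORPH_RE.match(v)
        if m:
            rec.morphology = "M_" + m.group(1)
            slash_behaviour = m.group(2)
        else:
            bad("morphology", f"malformed morphology code {v!r}")

    v = str(raw.get("behaviour", "") or "").strip()
    behaviour = v or None
    if slash_behaviour is not None:
        if behaviour is not None and behaviour != slash_behaviour:
            findings.append(ValidationFinding(
                "V6", "warning", "behaviour",
                f"behaviour field {behaviour!r} conflicts with morphology "
                f"suffix /{slash_behaviour}; the suffix is used",
            ))
        behaviour = slash_behaviour
    if behaviour is not None:
        if behaviour in _BEHAVIOUR_DIGITS:
            rec.behaviour = behaviour
        else:
            bad("behaviour", f"unknown behaviour digit {behaviour!r}")

    v = str(raw.get("grade", "") or "").strip()
    if v:
        if v in {"1", "2", "3", "4", "9"}:
            rec.grade = v
        else:
            bad("grade", f"unknown grade digit {v!r}")

    v = str(raw.get("age", "") or "").strip()
    if v:
        try:
            age = int(float(v))
            if not 0 <= age <= 130:
                raise ValueError
            rec.age = age
        except ValueError:
            bad("age", f"malformed age {v!r}")

    for field_name, category, prefix in (
        ("cT", "T", "C"), ("cN", "N", "C"), ("cM", "M", "C"),
        ("pT", "T", "P"), ("pN", "N", "P"), ("pM", "M", "P"),
    ):
        v = str(raw.get(field_name, "") or "")
        try:
            setattr(rec, field_name, _norm_tnm_code(v, category, prefix))
        except ValueError as exc:
            bad(field_name, str(exc))

    v = str(raw.get("stage_group", "") or "").strip().upper()
    if v:
        rec.declared_stage = v

    return rec


# ---------------------------------------------------------------------------
# Fact construction


def build_facts(kb: KnowledgeBase, rec: CaseRecord) -> FactSet:
    """Asserted facts for staging: one effective code per T/N/M category
    (pathological preferred), plus topography, morphology, behaviour, grade
    and edition.  Codes unknown to the KB contribute nothing (they are
    reported by V2 instead)."""
    facts = FactSet()

    def assert_known(role: str, cid: Optional[str]) -> None:
        if cid is not None and cid in kb.concepts:
            facts.assert_code(role, cid)

    assert_known("hasTopography", rec.topography)
    assert_known("hasMorphology", rec.morphology)
    if rec.behaviour is not None:
        assert_known("hasBehaviour", f"BehaviourCode{rec.behaviour}")
    if rec.grade is not None:
        assert_known("hasGrade", f"GradeCode{rec.grade}")
    if rec.tnm_edition is not None:
        assert_known("hasTNMEdition", f"TNMEd{rec.tnm_edition}")
    for category, role in (("T", "hasT"), ("N", "hasN"), ("M", "hasM")):
        _, code = rec.effective(category)
        assert_known(role, code)
    if rec.age is not None:
        facts.numeric_attributes["age"] = float(rec.age)
    return facts


def _is_x_code(kb: KnowledgeBase, code: Optional[str]) -> bool:
    if code is None or code not in kb.concepts:
        return False
    return bool(kb.ancestors(code) & {"TX", "NX", "MX"})


def infer_stage(
    kb: KnowledgeBase, rec: CaseRecord, mode: str = "reasoner"
) -> tuple[Optional[str], list[str], set[str]]:
    """(inferred site, most-specific stage concepts, derived set).

    Stage inference abstains (empty stage list) when any effective T/N/M
    code is an X ("cannot be assessed") code.
    """
    facts = build_facts(kb, rec)
    if mode == "reasoner":
        done, _trace = saturate(kb, facts)
    elif mode == "direct":
        done = classify_direct(kb, facts)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sites = sorted(
        c for c in done.derived if kb.concepts[c].kind == "edition_site"
    )
    site = sites[0] if len(sites) == 1 else None
    abstain = any(
        _is_x_code(kb, rec.effective(cat)[1]) for cat in ("T", "N", "M")
    )
    stages = [] if abstain else most_specific_stages(kb, done.derived)
    return site, stages, done.derived


# ---------------------------------------------------------------------------
# validate_record


def validate_record(
    kb: KnowledgeBase,
    rec: CaseRecord,
    mode: str = "reasoner",
    strictness: str = "strict",
) -> ValidationReport:
    """Run all checks on one normalized record.

    ``mode='reasoner'`` classifies through generic saturation;
    ``mode='direct'`` through single-pass indexed evaluation.  The two are
    contractually equivalent report-for-report.
    """
    report = ValidationReport(rec.record_id)
    report.findings.extend(rec.format_findings)
    if any(f.severity == "error" for f in rec.format_findings):
        report.verdict = "invalid"
        return report

    facts = build_facts(kb, rec)
    done = saturate(kb, facts)[0] if mode == "reasoner" else classify_direct(kb, facts)
    sites = sorted(c for c in done.derived if kb.concepts[c].kind == "edition_site")

    if not sites:  # V1: no eligible TNM site
        report.findings.append(ValidationFinding(
            "V1", "error", "topography",
            "no TNM site derivable from topography, morphology and edition",
        ))
        report.verdict = "ineligible"
        return report
    if len(sites) > 1:
        report.findings.append(ValidationFinding(
            "V1", "error", "topography",
            "record derives more than one TNM site: " + ", ".join(sites),
        ))
        report.verdict = "invalid"
        return report
    site = sites[0]
    report.inferred_site = site

    if not rec.has_tnm_data():
        report.verdict = "unstaged"
        return report

    # V2: every present T/N/M code inside the site's code space
    spaces = kb.site_code_spaces.get(site, {})
    for field_name, role in (("cT", "hasT"), ("pT", "hasT"), ("cN", "hasN"),
                             ("pN", "hasN"), ("cM", "hasM"), ("pM", "hasM")):
        code = getattr(rec, field_name)
        space = spaces.get(role)
        if code is None or space is None:
            continue
        if code not in space.codes:
            report.findings.append(ValidationFinding(
                "V2", "error", field_name,
                f"code {code} outside the {role[3:]} code space of {site}",
                expected=tuple(sorted(space.codes)),
            ))

    permitted = {stage_numeral(s) for s in query_stage_groups(kb, site)}
    stage_rules = kb.site_stage_rules.get(site, [])

    # V4: declared stage recognised for this site
    v4_ok = True
    if rec.declared_stage is not None:
        accepted = rec.declared_stage in permitted
        if not accepted and strictness == "lenient-stage":
            declared_concept = stage_concept(rec.declared_stage)
            if declared_concept in kb.concepts:
                accepted = any(
                    declared_concept in kb.ancestors(stage_concept(p))
                    for p in permitted
                )
        if not accepted:
            v4_ok = False
            report.findings.append(ValidationFinding(
                "V4", "error", "stage_group",
                f"stage group {rec.declared_stage!r} is not recognised for {site}",
                expected=tuple(sorted(permitted)),
            ))

    # V3: behaviour consistent with the declared stage
    v3_ok = True
    if rec.declared_stage is not None and v4_ok and rec.behaviour is not None:
        admissible = _stage_behaviours(kb, stage_rules, rec.declared_stage, strictness)
        if admissible and rec.behaviour not in admissible:
            v3_ok = False
            report.findings.append(ValidationFinding(
                "V3", "error", "behaviour",
                f"behaviour {rec.behaviour} inconsistent with stage "
                f"{rec.declared_stage} (stage 0 is in situ)",
                expected=tuple(sorted(admissible)),
            ))

    # V5: declared stage against the inferred stage
    abstain = any(_is_x_code(kb, rec.effective(c)[1]) for c in ("T", "N", "M"))
    stages = [] if abstain else most_specific_stages(kb, done.derived)
    if len(stages) > 1:
        report.findings.append(ValidationFinding(
            "V5", "error", "stage_group",
            "incomparable stage groups derived (rule-set inconsistency): "
            + ", ".join(stage_numeral(s) for s in stages),
        ))
    elif len(stages) == 1:
        report.inferred_stage = stage_numeral(stages[0])

    complete = all(rec.effective(c)[1] is not None for c in ("T", "N", "M"))
    can_check = (
        rec.declared_stage is not None
        and v4_ok
        and complete
        and rec.behaviour is not None
        and not abstain
        and len(stages) <= 1
    )
    if can_check:
        if report.inferred_stage is not None:
            matches = rec.declared_stage == report.inferred_stage
            if not matches and strictness == "lenient-stage":
                matches = stage_concept(rec.declared_stage) in kb.ancestors(
                    stage_concept(report.inferred_stage)
                )
            if not matches:
                report.findings.append(ValidationFinding(
                    "V5", "error", "stage_group",
                    f"declared stage {rec.declared_stage} does not match "
                    f"inferred stage {report.inferred_stage}",
                    expected=(report.inferred_stage,),
                ))
        elif v3_ok and not any(f.check_id == "V2" for f in report.errors()):
            report.findings.append(ValidationFinding(
                "V5", "error", "stage_group",
                "T/N/M/behaviour combination yields no stage group for "
                f"declared stage {rec.declared_stage}",
            ))

    report.verdict = "invalid" if report.errors() else "valid"
    return report


def _stage_behaviours(
    kb: KnowledgeBase, stage_rules, declared: str, strictness: str
) -> set[str]:
    """Behaviour digits admissible across the declared stage's rules."""
    target = stage_concept(declared)
    out: set[str] = set()
    for rule in stage_rules:
        ok = rule.rhs == target
        if not ok and strictness == "lenient-stage" and target in kb.concepts:
            ok = target in kb.ancestors(rule.rhs)
        if not ok:
            continue
        for lit in rule.lhs:
            if isinstance(lit, Existential) and lit.role == "hasBehaviour":
                out.add(lit.filler.removeprefix("BehaviourCode"))
    return out


# ---------------------------------------------------------------------------
# Batch processing


def validate_batch(
    kb: KnowledgeBase,
    records: Sequence[CaseRecord],
    block_size: int = 100,
    mode: str = "reasoner",
    strictness: str = "strict",
) -> list[ValidationReport]:
    """Validate records block-wise.

    Facts for one block are inserted, classified and fully retracted before
    the next block is loaded, so reports are independent of ``block_size``
    and keep input order.  Per-record findings never abort the batch.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    reports: list[ValidationReport] = []
    for start in range(0, len(records), block_size):
        block = records[start:start + block_size]
        logger.info("block %d..%d: %d records",
                    start, start + len(block) - 1, len(block))
        block_reports = [validate_record(kb, rec, mode, strictness) for rec in block]
        reports.extend(block_reports)  # block retracted: nothing persists
        logger.info("block %d..%d: %d with errors", start,
                    start + len(block) - 1,
                    sum(1 for r in block_reports if r.errors()))
    return reports


# ---------------------------------------------------------------------------
# Error correction

_CORRECTION_FIELDS = ("T", "N", "M", "behaviour")


def propose_corrections(
    kb: KnowledgeBase, rec: CaseRecord, report: ValidationReport
) -> list[tuple[str, tuple[str, ...], bool]]:
    """Correction proposals under the assumption that the declared stage is
    right and the error lies in the other parameters.

    Searches the smallest set of fields whose reassignment (over the site's
    code space / behaviour digits) satisfies some stage rule of the declared
    stage; per field the proposal lists every value occurring in a satisfying
    assignment, and is *unique* when exactly one value does.
    Empty when the record has no correctable error or no rule applies.
    """
    site = report.inferred_site
    if site is None or rec.declared_stage is None:
        return []
    if not any(f.check_id in ("V2", "V3", "V5") for f in report.errors()):
        return []
    permitted = {stage_numeral(s) for s in query_stage_groups(kb, site)}
    if rec.declared_stage not in permitted:
        return []
    target = stage_concept(rec.declared_stage)
    rules = [r for r in kb.site_stage_rules.get(site, []) if r.rhs == target]
    if not rules:
        return []

    spaces = kb.site_code_spaces.get(site, {})
    domains: dict[str, list[str]] = {}
    for category, role in (("T", "hasT"), ("N", "hasN"), ("M", "hasM")):
        space = spaces.get(role)
        if space is None:
            return []
        domains[category] = sorted(
            c for c in space.codes if not _is_x_code(kb, c)
        )
    domains["behaviour"] = sorted(
        c.id.removeprefix("BehaviourCode")
        for c in kb.concepts.values()
        if c.id.startswith("BehaviourCode")
    )

    current = {
        "T": rec.effective("T")[1],
        "N": rec.effective("N")[1],
        "M": rec.effective("M")[1],
        "behaviour": rec.behaviour,
    }

    def satisfies(assign: dict[str, Optional[str]]) -> bool:
        for rule in rules:
            if _stage_rule_holds(kb, rule, site, spaces, assign, rec.age):
                return True
        return False

    if satisfies(current):
        return []

    for size in range(1, len(_CORRECTION_FIELDS) + 1):
        satisfying: dict[str, set[str]] = {}
        found = False
        for fields in itertools.combinations(_CORRECTION_FIELDS, size):
            for values in itertools.product(*(domains[f] for f in fields)):
                assign = dict(current)
                assign.update(dict(zip(fields, values)))
                if satisfies(assign):
                    found = True
                    for f, v in zip(fields, values):
                        satisfying.setdefault(f, set()).add(v)
        if found:
            return [
                (f, tuple(sorted(vals)), len(vals) == 1)
                for f, vals in sorted(satisfying.items())
            ]
    return []


def _stage_rule_holds(kb, rule, site, spaces, assign, age) -> bool:
    role_to_cat = {"hasT": "T", "hasN": "N", "hasM": "M"}
    for lit in rule.lhs:
        if isinstance(lit, Atomic):
            if lit.concept == site:
                continue
            matched = False
            for role, cat in role_to_cat.items():
                space = spaces.get(role)
                if space is not None and lit.concept == space.space_concept:
                    matched = assign.get(cat) in space.codes
                    break
            if not matched:
                return False
        elif isinstance(lit, Existential):
            if lit.role == "hasBehaviour":
                digit = assign.get("behaviour")
                code = f"BehaviourCode{digit}" if digit is not None else None
            else:
                code = assign.get(role_to_cat.get(lit.role, ""))
            if code is None or code not in kb.concepts:
                return False
            if lit.filler not in kb.ancestors(code):
                return False
        elif isinstance(lit, NumericCondition):
            if age is None or not lit.holds(float(age)):
                return False
    return True


def render_corrections(
    rec: CaseRecord, proposals: list[tuple[str, tuple[str, ...], bool]]
) -> str:
    """Chevron rendering: input value, expected value(s) after ``»``, and a
    highlighted ``!`` marking each incorrect input."""
    wrong = {f: values for f, values, _unique in proposals}
    lines = [f"record {rec.record_id} (declared stage {rec.declared_stage})"]
    display = {
        "T": rec.effective("T")[1], "N": rec.effective("N")[1],
        "M": rec.effective("M")[1], "behaviour": rec.behaviour,
    }
    for f in _CORRECTION_FIELDS:
        cur = display[f] or "-"
        if f in wrong:
            lines.append(f"  {f + ':':<11}{cur:<8}» {' | '.join(wrong[f])} !")
        else:
            lines.append(f"  {f + ':':<11}{cur:<8}» {cur}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# CSV interfaces


def read_records_csv(path_or_buffer) -> list[CaseRecord]:
    """Read the batch CSV dialect and normalize every row."""
    frame = pd.read_csv(path_or_buffer, dtype=str, keep_default_na=False)
    return [normalize_record(row) for row in frame.to_dict(orient="records")]


def _strip_code(code: Optional[str]) -> str:
    if code is None:
        return ""
    base = code[1:] if code[:1] in "CP" else code
    return base[1:] if base[:1] in "TNM" else base


def records_to_frame(records: Iterable[CaseRecord]) -> pd.DataFrame:
    """Render normalized records back into the CSV dialect."""
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "tnm_edition": "" if r.tnm_edition is None else str(r.tnm_edition),
            "topography": r.topography or "",
            "morphology": (r.morphology or "").removeprefix("M_"),
            "behaviour": r.behaviour or "",
            "grade": r.grade or "",
            "age": "" if r.age is None else str(r.age),
            "cT": _strip_code(r.cT), "cN": _strip_code(r.cN),
            "cM": _strip_code(r.cM), "pT": _strip_code(r.pT),
            "pN": _strip_code(r.pN), "pM": _strip_code(r.pM),
            "stage_group": r.declared_stage or "",
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def reports_to_frame(reports: Iterable[ValidationReport]) -> pd.DataFrame:
    """One row per finding plus a per-record summary row."""
    rows = []
    for rep in reports:
        for f in rep.findings:
            rows.append({
                "record_id": rep.record_id, "row_type": "finding",
                "check_id": f.check_id, "severity": f.severity,
                "field": f.field, "message": f.message,
                "expected": "|".join(f.expected),
                "verdict": "", "inferred_site": "", "inferred_stage": "",
            })
        s = rep.summary()
        rows.append({
            "record_id": rep.record_id, "row_type": "summary",
            "check_id": "", "severity": "", "field": "",
            "message": f"{s['n_errors']} error(s)",
            "expected": "", "verdict": rep.verdict,
            "inferred_site": s["inferred_site"],
            "inferred_stage": s["inferred_stage"],
        })
    return pd.DataFrame(rows, columns=[
        "record_id", "row_type", "check_id", "severity", "field", "message",
        "expected", "verdict", "inferred_site", "inferred_stage",
    ])
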