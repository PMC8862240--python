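"""Packaged knowledge base and synthetic record generation.

``build_kb`` loads the shipped rule modules (ICD-O-3 codes, morphology
groupings, generic TNM, TNM edition 7) and merges them into one knowledge
base.  ``generate_records`` produces labelled synthetic registry records
covering, for every site, the three canonical test scenarios of a staging
validator: correctly specified records, records with corrupted parameters,
and records declaring a stage group unknown for the site.

``brute_force_stage_oracle`` is an independent lookup over a literal
transcription of the edition-7 breast stage table; it shares no code with
the rule engine and exists to cross-check it exhaustively.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .compiler import merge_imports, parse_module
from .engine import query_codes_in_category, query_stage_groups
from .model import (
    Atomic,
    Existential,
    KnowledgeBase,
    KnowledgeModule,
    NumericCondition,
)
from .validator import CaseRecord, stage_numeral, validate_record

_MODULE_FILES = (
    "icdo_generic.yaml",
    "morph_grouping.yaml",
    "tnm_generic.yaml",
    "tnm_ed7.yaml",
)

ROOT_MODULE = "tnm-ed7"


def load_modules() -> dict[str, KnowledgeModule]:
    """Parse the packaged rule-module files into a registry keyed by id."""
    registry = {}
    for fname in _MODULE_FILES:
        text = resources.files("tnmstage.data").joinpath(fname).read_text()
        mod = parse_module(text, name=fname)
        registry[mod.id] = mod
    return registry


def build_kb() -> KnowledgeBase:
    """Merge the packaged modules (rooted at the edition-7 module)."""
    registry = load_modules()
    return merge_imports(registry[ROOT_MODULE], registry)


# backwards-friendly alias used in docs and scripts
build_paper_kb = build_kb


# ---------------------------------------------------------------------------
# Scenario labels and record generation

SCENARIOS = ("valid", "corrupted_parameter", "unknown_stage")


@dataclass
class ScenarioLabel:
    scenario: str
    corrupted_fields: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if (self.scenario == "valid") != (not self.corrupted_fields):
            raise ValueError(
                "corrupted_fields must be empty exactly for the valid scenario")


_UNDECLARED = {"T": "T9", "N": "N9", "M": "M3"}
_ROLE_OF = {"T": "hasT", "N": "hasN", "M": "hasM"}


class _SiteSampler:
    """Samples satisfying records for one edition-site's stage rules."""

    def __init__(self, kb: KnowledgeBase, site: str):
        self.kb = kb
        self.site = site
        self.rules = kb.site_stage_rules[site]
        self.spaces = kb.site_code_spaces[site]
        self.edition = self._edition_number()
        self.topographies, self.morph_category = self._site_definition()
        self.permitted = {stage_numeral(s) for s in query_stage_groups(kb, site)}

    def _edition_number(self) -> int:
        for rule in self.kb.rules:
            if rule.rhs == self.site and rule.rule_id.startswith("edsite:"):
                for lit in rule.lhs:
                    if isinstance(lit, Existential) and lit.role == "hasTNMEdition":
                        return int(lit.filler.removeprefix("TNMEd"))
        raise ValueError(f"no edition axiom for {self.site}")

    def _site_definition(self) -> tuple[list[str], str]:
        generic = None
        for rule in self.kb.rules:
            if rule.rhs == self.site and rule.rule_id.startswith("edsite:"):
                for lit in rule.lhs:
                    if isinstance(lit, Atomic):
                        generic = lit.concept
        for rule in self.kb.rules:
            if rule.rhs == generic and rule.origin == "equivalence":
                topo = morph = None
                for lit in rule.lhs:
                    if isinstance(lit, Existential):
                        if lit.role == "hasTopography":
                            topo = lit.filler
                        elif lit.role == "hasMorphology":
                            morph = lit.filler
                topos = sorted(
                    c for c in self.kb.descendants(topo)
                    if len(c) == 4  # 4-character = full ICD-O topography code
                ) or [topo]
                return topos, morph
        raise ValueError(f"no site definition behind {self.site}")

    def space_codes(self, category: str, include_x: bool = False) -> list[str]:
        codes = self.spaces[_ROLE_OF[category]].codes
        if include_x:
            return sorted(codes)
        return sorted(
            c for c in codes if not (self.kb.ancestors(c) & {"TX", "NX", "MX"})
        )

    def sample_valid(self, rng: random.Random, index: int) -> CaseRecord:
        rule = rng.choice(self.rules)
        rec = CaseRecord(record_id=f"{self.site.removeprefix('TNMSiteEd7')}-{index:04d}")
        rec.tnm_edition = self.edition
        rec.topography = rng.choice(self.topographies)
        rec.declared_stage = stage_numeral(rule.rhs)
        behaviour = "3"
        age_bounds: Optional[tuple[int, int]] = None
        for lit in sorted(rule.lhs, key=str):
            if isinstance(lit, Existential):
                if lit.role == "hasBehaviour":
                    behaviour = lit.filler.removeprefix("BehaviourCode")
                elif lit.role in ("hasT", "hasN", "hasM"):
                    cat = lit.role[3]
                    choices = [
                        c for c in self.space_codes(cat)
                        if lit.filler in self.kb.ancestors(c)
                    ]
                    self._set_code(rec, cat, rng.choice(choices))
            elif isinstance(lit, Atomic):
                for cat in ("T", "N", "M"):
                    space = self.spaces[_ROLE_OF[cat]]
                    if lit.concept == space.space_concept:
                        self._set_code(rec, cat, rng.choice(self.space_codes(cat)))
            elif isinstance(lit, NumericCondition):
                age_bounds = _age_window(lit)
        if age_bounds is not None:
            rec.age = rng.randint(*age_bounds)
        rec.behaviour = behaviour
        morphs = sorted(
            query_codes_in_category(self.kb, self.morph_category, behaviour)
        )
        rec.morphology = rng.choice(morphs)
        return rec

    @staticmethod
    def _set_code(rec: CaseRecord, category: str, code: str) -> None:
        attr = ("p" if code.startswith("P") else "c") + category
        setattr(rec, attr, code)

    def clear_code(self, rec: CaseRecord, category: str) -> None:
        setattr(rec, "c" + category, None)
        setattr(rec, "p" + category, None)


def _age_window(lit: NumericCondition) -> tuple[int, int]:
    t = int(lit.threshold)
    return {
        "<": (max(1, t - 25), t - 1),
        "<=": (max(1, t - 25), t),
        ">": (t + 1, t + 35),
        ">=": (t, t + 35),
    }[lit.comparator]


def generate_records(
    kb: KnowledgeBase,
    per_site: int = 10,
    mix: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> list[tuple[CaseRecord, ScenarioLabel]]:
    """Generate ``per_site`` labelled records for every site with stage rules.

    Scenario (valid): a stage rule is sampled and satisfying codes are drawn
    uniformly from the admissible values (X codes excluded, so the declared
    stage is verifiable).  Scenario (corrupted_parameter): one parameter is
    rewritten, half the time to a code outside the site's code space, half
    the time to an in-space code inconsistent with the declared stage
    (rejection-checked to actually produce an error).  Scenario
    (unknown_stage): the declared stage group is replaced by one absent from
    the site's permissible set.  Fully reproducible for a fixed seed.
    """
    if per_site < 3:
        raise ValueError("per_site must be >= 3 (one record per scenario)")
    mix = mix or {s: 1 / 3 for s in SCENARIOS}
    rng = random.Random(seed)
    out: list[tuple[CaseRecord, ScenarioLabel]] = []
    for site in sorted(kb.site_stage_rules):
        sampler = _SiteSampler(kb, site)
        counts = _scenario_counts(per_site, mix)
        index = 0
        for scenario in SCENARIOS:
            for _ in range(counts[scenario]):
                index += 1
                rec = sampler.sample_valid(rng, index)
                if scenario == "valid":
                    out.append((rec, ScenarioLabel("valid")))
                elif scenario == "corrupted_parameter":
                    fields = _corrupt(kb, sampler, rec, rng)
                    out.append((rec, ScenarioLabel("corrupted_parameter", fields)))
                else:
                    _unknown_stage(kb, sampler, rec, rng)
                    out.append((rec, ScenarioLabel("unknown_stage", ["stage_group"])))
    return out


def _scenario_counts(per_site: int, mix: dict[str, float]) -> dict[str, int]:
    total = sum(mix.get(s, 0.0) for s in SCENARIOS)
    counts = {s: max(1, int(round(per_site * mix.get(s, 0.0) / total)))
              for s in SCENARIOS}
    # adjust to the exact per-site total, keeping every scenario >= 1
    order = sorted(SCENARIOS, key=lambda s: -counts[s])
    i = 0
    while sum(counts.values()) > per_site:
        s = order[i % len(order)]
        if counts[s] > 1:
            counts[s] -= 1
        i += 1
    while sum(counts.values()) < per_site:
        counts[order[i % len(order)]] += 1
        i += 1
    return counts


def _corrupt(kb, sampler: _SiteSampler, rec: CaseRecord, rng: random.Random) -> list[str]:
    """Corrupt one parameter; guarantees the record validates with >=1 error."""
    categories = ["T", "N", "M", "behaviour"]
    rng.shuffle(categories)
    outside_first = rng.random() < 0.5
    for cat in categories:
        if cat == "behaviour":
            new = "2" if rec.behaviour == "3" else "3"
            old = rec.behaviour
            rec.behaviour = new
            if validate_record(kb, rec, mode="direct").errors():
                return ["behaviour"]
            rec.behaviour = old
            continue
        field_name, old = rec.effective(cat)
        if old is None:
            continue
        modes = ["outside", "inside"] if outside_first else ["inside", "outside"]
        for corruption in modes:
            if corruption == "outside":
                declared = sorted(
                    c.id for c in kb.concepts.values()
                    if c.role == _ROLE_OF[cat] and c.id[:1] in "CP"
                )
                space = set(sampler.spaces[_ROLE_OF[cat]].codes)
                pool = [c for c in declared if c not in space
                        and not (kb.ancestors(c) & {"TX", "NX", "MX"})]
                candidates = [rng.choice(pool)] if pool else [
                    old[:1] + _UNDECLARED[cat]
                ]
            else:
                candidates = [c for c in sampler.space_codes(cat) if c != old]
                rng.shuffle(candidates)
            for new in candidates:
                sampler.clear_code(rec, cat)
                sampler._set_code(rec, cat, new)
                if validate_record(kb, rec, mode="direct").errors():
                    return [field_name]
            sampler.clear_code(rec, cat)
            sampler._set_code(rec, cat, old)
    raise RuntimeError(f"could not corrupt record {rec.record_id}")  # pragma: no cover


def _unknown_stage(kb, sampler: _SiteSampler, rec: CaseRecord, rng: random.Random) -> None:
    all_stages = {stage_numeral(s) for s in kb.stage_concepts()}
    coarse = set()
    for p in sampler.permitted:
        for anc in kb.ancestors("TNMStage" + p):
            coarse.add(stage_numeral(anc))
    pool = sorted(all_stages - sampler.permitted - coarse)
    rec.declared_stage = rng.choice(pool)


# ---------------------------------------------------------------------------
# Independent breast edition-7 stage-table oracle

#: Literal transcription of the edition-7 breast stage table.  ``"ANY"``
#: means any code of the site-specific code space (never the global code
#: universe).  Kept as data so the oracle shares nothing with the engine.
BREAST_ED7_TABLE = {
    "spaces": {
        "T": ["CT0", "CT1", "CT1a", "CT1b", "CT1c", "CT2", "CT3", "CT4",
              "CT4a", "CT4b", "CT4c", "CT4d", "CTX", "PT0", "PT1", "PT1a",
              "PT1b", "PT1c", "PT1mi", "PT2", "PT3", "PT4", "PT4a", "PT4b",
              "PT4c", "PT4d", "PTX", "PTis"],
        "N": ["CN0", "CN1", "CN2", "CN2a", "CN2b", "CN3", "CN3a", "CN3b",
              "CN3c", "CNX", "PN0", "PN1", "PN1mi", "PN1a", "PN1b", "PN1c",
              "PN2", "PN2a", "PN2b", "PN3", "PN3a", "PN3b", "PN3c", "PNX"],
        "M": ["CM0", "CM1", "PM0", "PM1"],
    },
    "rows": [
        {"t": ["Tis"], "n": ["N0"], "m": "M0", "behaviour": "2", "stage": "0"},
        {"t": ["T1"], "n": ["N0"], "m": "M0", "behaviour": "3", "stage": "IA"},
        {"t": ["T0", "T1"], "n": ["N1mi"], "m": "M0", "behaviour": "3", "stage": "IB"},
        {"t": ["T0", "T1"], "n": ["N1"], "m": "M0", "behaviour": "3", "stage": "IIA"},
        {"t": ["T2"], "n": ["N0"], "m": "M0", "behaviour": "3", "stage": "IIA"},
        {"t": ["T2"], "n": ["N1"], "m": "M0", "behaviour": "3", "stage": "IIB"},
        {"t": ["T3"], "n": ["N0"], "m": "M0", "behaviour": "3", "stage": "IIB"},
        {"t": ["T0", "T1", "T2"], "n": ["N2"], "m": "M0", "behaviour": "3", "stage": "IIIA"},
        {"t": ["T3"], "n": ["N1", "N2"], "m": "M0", "behaviour": "3", "stage": "IIIA"},
        {"t": ["T4"], "n": ["N0", "N1", "N2"], "m": "M0", "behaviour": "3", "stage": "IIIB"},
        {"t": "ANY", "n": ["N3"], "m": "M0", "behaviour": "3", "stage": "IIIC"},
        {"t": "ANY", "n": "ANY", "m": "M1", "behaviour": "3", "stage": "IV"},
    ],
}

_T_GROUP = {
    "Tis": "Tis", "T0": "T0", "T1": "T1", "T1a": "T1", "T1b": "T1",
    "T1c": "T1", "T1mi": "T1", "T2": "T2", "T3": "T3", "T4": "T4",
    "T4a": "T4", "T4b": "T4", "T4c": "T4", "T4d": "T4", "TX": "TX",
}
_N_GROUP = {
    "N0": "N0", "N1": "N1", "N1a": "N1", "N1b": "N1", "N1c": "N1",
    "N1mi": "N1mi", "N2": "N2", "N2a": "N2", "N2b": "N2",
    "N3": "N3", "N3a": "N3", "N3b": "N3", "N3c": "N3", "NX": "NX",
}


def _strip_prefix(code: str) -> str:
    return code[1:] if code[:1] in "CP" else code


def brute_force_stage_oracle(table: dict, rec: CaseRecord) -> Optional[str]:
    """Row lookup of a breast edition-7 record in the transcribed table.

    Independent of the rule engine: plain string grouping plus list
    membership.  Returns the stage numeral, or ``None`` when the
    combination has no row or any category is X (cannot be assessed).
    """
    codes = {}
    for cat in ("T", "N", "M"):
        _, code = rec.effective(cat)
        if code is None or code not in table["spaces"][cat]:
            return None
        codes[cat] = code
    t = _T_GROUP.get(_strip_prefix(codes["T"]))
    n = _N_GROUP.get(_strip_prefix(codes["N"]))
    m = _strip_prefix(codes["M"])
    if t in (None, "TX") or n in (None, "NX"):
        return None
    matches = set()
    for row in table["rows"]:
        if row["behaviour"] != rec.behaviour:
            continue
        if row["m"] != m:
            continue
        t_ok = (codes["T"] in table["spaces"]["T"]) if row["t"] == "ANY" else t in row["t"]
        n_ok = (codes["N"] in table["spaces"]["N"]) if row["n"] == "ANY" else n in row["n"]
        if t_ok and n_ok:
            matches.add(row["stage"])
    if len(matches) > 1:  # pragma: no cover - table rows are disjoint
        raise ValueError(f"ambiguous table rows: {matches}")
    return matches.pop() if matches else None
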