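"""Forward-chaining saturation over GCI rules.

A record's coded facts are classified by computing the least fixpoint of
the rule set: any rule whose conjunction fully matches fires, adding its
right-hand concept (and that concept's hierarchy ancestors) to the derived
set, until nothing new can be added.  Because rules only ever add concepts,
the result is a unique least fixpoint, independent of firing order.

This replaces the external description-logic reasoner: completeness is
claimed (and tested) only for the rule fragment the compiler emits —
conjunctions of atomic, existential and numeric literals with atomic
right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    Atomic,
    ConceptLiteral,
    Existential,
    GCIRule,
    KnowledgeBase,
    NumericCondition,
    UnknownConceptError,
)


@dataclass
class FactSet:
    """Coded facts of one record plus the concepts derived for it."""

    assertions: set[tuple[str, str]] = field(default_factory=set)  # (role, code)
    numeric_attributes: dict[str, float] = field(default_factory=dict)
    derived: set[str] = field(default_factory=set)

    def assert_code(self, role: str, code: str) -> None:
        self.assertions.add((role, code))

    def copy(self) -> "FactSet":
        return FactSet(set(self.assertions), dict(self.numeric_attributes), set(self.derived))


@dataclass
class InferenceTrace:
    """Ordered record of rule firings; replaying it from the same facts
    reproduces the derived set exactly."""

    firings: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def rule_ids(self) -> list[str]:
        return [rid for rid, _ in self.firings]


def literal_matches(kb: KnowledgeBase, lit: ConceptLiteral, facts: FactSet) -> bool:
    """Does one conjunct hold for the given facts?

    * ``Atomic(c)`` — c has been derived;
    * ``∃role.f`` — some asserted code under ``role`` has ``f`` among its
      reflexive-transitive ancestors (so ``∃hasTopography.C50`` matches a
      record coded C501, and ``∃hasMorphology.Carcinoma`` matches any code
      grouped, directly or transitively, under the carcinoma category);
    * numeric condition — the attribute is present and the comparison holds
      (absent attribute never matches: open-world reading of missing data).
    """
    if isinstance(lit, Atomic):
        return lit.concept in facts.derived
    if isinstance(lit, Existential):
        for role, code in facts.assertions:
            if role == lit.role and lit.filler in kb.ancestors(code):
                return True
        return False
    value = facts.numeric_attributes.get(lit.attribute)
    return value is not None and lit.holds(value)


def _rule_matches(kb: KnowledgeBase, rule: GCIRule, facts: FactSet) -> bool:
    return all(literal_matches(kb, lit, facts) for lit in rule.lhs)


def saturate(kb: KnowledgeBase, facts: FactSet) -> tuple[FactSet, InferenceTrace]:
    """Compute the least fixpoint of the rule set over ``facts``.

    Returns a new :class:`FactSet` with the completed derived set and the
    trace of firings.  Terminates because the derived set grows
    monotonically within the finite concept universe.
    """
    out = facts.copy()
    trace = InferenceTrace()
    pending = list(kb.rules)
    changed = True
    while changed:
        changed = False
        still = []
        for rule in pending:
            if rule.rhs in out.derived and kb.ancestors(rule.rhs) <= out.derived:
                continue
            if _rule_matches(kb, rule, out):
                out.derived.update(kb.ancestors(rule.rhs))
                trace.firings.append(
                    (rule.rule_id, tuple(sorted(str(l) for l in rule.lhs)))
                )
                changed = True
            else:
                still.append(rule)
        pending = still
    return out, trace


def classify_direct(kb: KnowledgeBase, facts: FactSet) -> FactSet:
    """Single-pass classification without the generic fixpoint loop.

    Rules are evaluated in dependency (topological) order of their atomic
    prerequisites, mirroring a direct lookup over the asserted axioms; on
    the acyclic fragment the compiler emits this visits every rule once and
    yields the same derived set as :func:`saturate`.
    """
    out = facts.copy()
    for stratum in kb.rule_strata():
        local = True
        while local:
            local = False
            for rule in stratum:
                if kb.ancestors(rule.rhs) <= out.derived:
                    continue
                if _rule_matches(kb, rule, out):
                    out.derived.update(kb.ancestors(rule.rhs))
                    if len(stratum) > 1:
                        local = True
    return out


# ---------------------------------------------------------------------------
# Queries over the compiled rule set
#
# These answer the standing registry information needs — permissible stages
# of a site, codes of a morphology category, categories of a code — by index
# lookup over the asserted rules; no inverse-role reasoning is needed.


def query_stage_groups(kb: KnowledgeBase, site: str) -> set[str]:
    """All stage groups reachable by the stage rules of an edition-site."""
    concept = kb.concept(site)
    if concept.kind != "edition_site":
        raise UnknownConceptError(f"{site!r} is not an edition-site concept")
    return {rule.rhs for rule in kb.site_stage_rules.get(site, [])}


def query_codes_in_category(
    kb: KnowledgeBase, category: str, behaviour: Optional[str] = None
) -> set[str]:
    """Four-digit morphology codes grouped under a morphology category.

    Three-digit prefix concepts are expanded to their four-digit children;
    ``behaviour`` (an ICD-O behaviour digit) filters on each code's
    admissible behaviours where the KB declares them.
    """
    c = kb.concept(category)
    if c.kind != "category":
        raise UnknownConceptError(f"{category!r} is not a morphology category")
    out = set()
    for cid in kb.descendants(category):
        cc = kb.concepts[cid]
        if cc.kind != "code":
            continue
        digits = cid.split("_", 1)[-1]
        if len(digits) != 4:
            continue  # 3-digit prefix concept; its children are reported
        if behaviour is not None and cc.behaviours and behaviour not in cc.behaviours:
            continue
        out.add(cid)
    return out


def query_category_of_code(kb: KnowledgeBase, code: str) -> list[str]:
    """Morphology categories of a code, most specific first."""
    c = kb.concept(code)
    if c.role != "hasMorphology":
        raise UnknownConceptError(f"{code!r} is not a morphology concept")
    cats = [
        cid
        for cid in kb.ancestors(code)
        if cid != code and kb.concepts[cid].kind == "category"
    ]
    # more specific = has more category ancestors of its own
    return sorted(
        cats,
        key=lambda cid: (-len([a for a in kb.ancestors(cid)
                               if kb.concepts[a].kind == "category"]), cid),
    )


def most_specific_stages(kb: KnowledgeBase, derived: set[str]) -> list[str]:
    """Minimal (most specific) stage concepts among the derived set.

    A single element is the inferred stage; two or more incomparable stages
    indicate a rule-authoring inconsistency and are all returned.
    """
    stages = {c for c in derived if kb.concepts[c].kind == "stage"}
    minimal = [
        s for s in stages
        if not any(o != s and s in kb.ancestors(o) for o in stages)
    ]
    return sorted(minimal)
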