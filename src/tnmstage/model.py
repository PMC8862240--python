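"""Domain model for the TNM staging knowledge base.

The knowledge base is a set of atomic *concepts* (ICD-O-3 topography and
morphology codes, T/N/M category codes, morphology categories, TNM sites,
stage groups, editions) arranged in per-role hierarchies, plus a set of
normalized rules.  Every rule is a general concept inclusion (GCI): a
conjunction of literals — atomic concepts, existential role restrictions
(``∃hasTopography.C50``), or numeric comparisons on the age attribute —
entailing a single atomic concept.  Records are classified by computing the
least fixpoint of these rules over the record's asserted codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

# ---------------------------------------------------------------------------
# Roles and attributes

#: Closed enumeration of object-property roles a code concept can be bound to.
ROLES = (
    "hasTopography",
    "hasMorphology",
    "hasBehaviour",
    "hasGrade",
    "hasT",
    "hasN",
    "hasM",
    "hasTNMEdition",
)

#: The single numeric (datatype) attribute used by age-dependent sites.
AGE_ATTRIBUTE = "age"

#: Comparators allowed in numeric conditions.
COMPARATORS = ("<", "<=", ">", ">=")

#: Concept kinds.
KINDS = (
    "code",
    "category",
    "site",
    "edition_site",
    "code_space",
    "stage",
    "edition",
    "auxiliary",
)


class KBError(Exception):
    """Base class for knowledge-base errors."""


class UnknownConceptError(KBError):
    pass


class UnknownRoleError(KBError):
    pass


class RoleMixError(KBError):
    """A union or hierarchy mixes concepts bound to different roles."""


# ---------------------------------------------------------------------------
# Concepts and literals


@dataclass(frozen=True)
class Concept:
    """An atomic named concept.

    ``role`` is the object property the concept is matched through when it
    (or a descendant) is asserted on a record; hierarchy edges may only link
    concepts bound to the same role.  Stage concepts form their own small
    hierarchy (``role=None``, ``kind='stage'``) so that "most specific
    stage" is well defined.
    """

    id: str
    kind: str
    role: Optional[str] = None
    module_id: str = ""
    #: admissible ICD-O behaviour digits, morphology codes only ('' = any)
    behaviours: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise KBError(f"unknown concept kind {self.kind!r} for {self.id}")
        if self.role is not None and self.role not in ROLES:
            raise UnknownRoleError(f"unknown role {self.role!r} for {self.id}")


@dataclass(frozen=True)
class Atomic:
    """Literal matched when the concept has already been derived."""

    concept: str

    def __str__(self) -> str:
        return self.concept


@dataclass(frozen=True)
class Existential:
    """``∃role.filler`` — matched when an asserted code has the filler
    among its reflexive-transitive ancestors."""

    role: str
    filler: str

    def __str__(self) -> str:
        return f"∃{self.role}.{self.filler}"


@dataclass(frozen=True)
class NumericCondition:
    """Comparison on a numeric record attribute (age in years)."""

    attribute: str
    comparator: str
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise KBError(f"unknown comparator {self.comparator!r}")

    def holds(self, value: float) -> bool:
        return {
            "<": value < self.threshold,
            "<=": value <= self.threshold,
            ">": value > self.threshold,
            ">=": value >= self.threshold,
        }[self.comparator]

    def __str__(self) -> str:
        return f"{self.attribute} {self.comparator} {self.threshold:g}"


ConceptLiteral = Atomic | Existential | NumericCondition


@dataclass(frozen=True)
class GCIRule:
    """Normalized rule: conjunction of literals entailing one atomic concept.

    ``origin`` records whether the rule was normalized from an equivalence
    (defined-class) axiom — those are the ones examined for accidental
    definition clashes.
    """

    lhs: frozenset
    rhs: str
    rule_id: str
    source: str = ""
    origin: str = "gci"  # "gci" | "equivalence"

    def signature(self) -> tuple:
        return (self.lhs, self.rhs)

    def __str__(self) -> str:
        body = " ⊓ ".join(sorted(str(l) for l in self.lhs))
        return f"{body} ⊑ {self.rhs}"


@dataclass
class CodeSpace:
    """The permissible codes of one T/N/M role for one edition-site."""

    site: str
    role: str
    space_concept: str
    union_concept: str
    codes: tuple[str, ...]


@dataclass
class KnowledgeModule:
    """One parsed rule-module file (pre-normalization)."""

    id: str
    imports: list[str] = field(default_factory=list)
    concepts: dict[str, Concept] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)  # child, parent
    axioms: list = field(default_factory=list)


class KnowledgeBase:
    """Merged import closure: concepts, hierarchies, normalized rules, indexes."""

    def __init__(self) -> None:
        self.concepts: dict[str, Concept] = {}
        self.parents: dict[str, set[str]] = {}
        self.rules: list[GCIRule] = []
        self.code_spaces: list[CodeSpace] = []
        # indexes
        self.site_stage_rules: dict[str, list[GCIRule]] = {}
        self.site_code_spaces: dict[str, dict[str, CodeSpace]] = {}
        self.module_ids: list[str] = []
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}
        self._strata: Optional[list[list[GCIRule]]] = None

    # -- declaration helpers ------------------------------------------------

    def add_concept(self, c: Concept) -> None:
        self.concepts[c.id] = c
        self.parents.setdefault(c.id, set())

    def add_edge(self, child: str, parent: str) -> None:
        for cid in (child, parent):
            if cid not in self.concepts:
                raise UnknownConceptError(f"undeclared concept {cid!r} in hierarchy edge")
        self.parents.setdefault(child, set()).add(parent)
        self._anc_cache.clear()
        self._desc_cache.clear()

    def concept(self, cid: str) -> Concept:
        try:
            return self.concepts[cid]
        except KeyError:
            raise UnknownConceptError(f"unknown concept {cid!r}") from None

    # -- closures -----------------------------------------------------------

    def ancestors(self, cid: str) -> frozenset[str]:
        """Reflexive-transitive ancestor closure of ``cid``."""
        if cid not in self.concepts:
            raise UnknownConceptError(f"unknown concept {cid!r}")
        cached = self._anc_cache.get(cid)
        if cached is not None:
            return cached
        seen = {cid}
        frontier = [cid]
        while frontier:
            nxt: list[str] = []
            for node in frontier:
                for p in self.parents.get(node, ()):
                    if p not in seen:
                        seen.add(p)
                        nxt.append(p)
            frontier = nxt
        result = frozenset(seen)
        self._anc_cache[cid] = result
        return result

    def descendants(self, cid: str) -> frozenset[str]:
        """Reflexive-transitive descendant closure of ``cid``."""
        if cid not in self.concepts:
            raise UnknownConceptError(f"unknown concept {cid!r}")
        cached = self._desc_cache.get(cid)
        if cached is not None:
            return cached
        children: dict[str, set[str]] = {}
        for child, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(child)
        seen = {cid}
        frontier = [cid]
        while frontier:
            nxt = []
            for node in frontier:
                for ch in children.get(node, ()):
                    if ch not in seen:
                        seen.add(ch)
                        nxt.append(ch)
            frontier = nxt
        result = frozenset(seen)
        self._desc_cache[cid] = result
        return result

    # -- integrity ----------------------------------------------------------

    def check_hierarchy(self) -> list[str]:
        """Return findings for hierarchy cycles and role-disjointness breaches.

        Empty list iff every hierarchy is acyclic and no edge links concepts
        bound to different roles (T, N, M, topography ... are disjoint).
        """
        findings: list[str] = []
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        for cycle in nx.simple_cycles(g):
            findings.append("hierarchy cycle: " + " -> ".join(cycle + [cycle[0]]))
        for child, ps in self.parents.items():
            crole = self.concepts[child].role
            for p in ps:
                prole = self.concepts[p].role
                if crole != prole:
                    findings.append(
                        f"role disjointness: edge {child} -> {p} links role "
                        f"{crole!r} to role {prole!r}"
                    )
                elif crole is None:
                    ck, pk = self.concepts[child].kind, self.concepts[p].kind
                    if ck != pk:
                        findings.append(
                            f"kind mismatch: edge {child} -> {p} links kind "
                            f"{ck!r} to kind {pk!r}"
                        )
        return findings

    # -- rule stratification (direct mode) ----------------------------------

    def rule_strata(self) -> list[list[GCIRule]]:
        """Rules grouped so that each group only atomically depends on
        earlier groups; within a group evaluation iterates to a local
        fixpoint (groups are singletons when the rule graph is acyclic)."""
        if self._strata is not None:
            return self._strata
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.rules)))
        produces: dict[str, list[int]] = {}
        for i, r in enumerate(self.rules):
            for a in self.ancestors(r.rhs):
                produces.setdefault(a, []).append(i)
        for j, r in enumerate(self.rules):
            for lit in r.lhs:
                if isinstance(lit, Atomic):
                    for i in produces.get(lit.concept, ()):
                        if i != j:
                            g.add_edge(i, j)
        cond = nx.condensation(g)
        strata = []
        for scc in nx.topological_sort(cond):
            strata.append([self.rules[i] for i in sorted(cond.nodes[scc]["members"])])
        self._strata = strata
        return strata

    def rule_signatures(self) -> set[tuple]:
        return {r.signature() for r in self.rules}

    def stage_concepts(self) -> list[str]:
        return sorted(c.id for c in self.concepts.values() if c.kind == "stage")

    def __repr__(self) -> str:
        return (
            f"<KnowledgeBase {len(self.concepts)} concepts, "
            f"{len(self.rules)} rules, modules={self.module_ids}>"
        )


# ---------------------------------------------------------------------------
# Module-level convenience API (spec surface)


def ancestors(kb: KnowledgeBase, cid: str) -> frozenset[str]:
    """``cid`` plus every concept reachable via parent edges."""
    return kb.ancestors(cid)


def check_hierarchy_acyclic(kb: KnowledgeBase) -> list[str]:
    """Findings list; empty iff all role hierarchies are acyclic and disjoint."""
    return kb.check_hierarchy()
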