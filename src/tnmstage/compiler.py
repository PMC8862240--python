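"""Rule-module compiler.

Rule modules are declarative YAML documents (one per file).  A module
declares concepts (codes, categories, sites, stages, editions), hierarchy
edges, and axioms in one of three surface forms:

* *equivalences* — morphology-category unions and site definitions.  These
  are normalized into one-directional GCI rules (the reverse inclusion is
  deliberately dropped so identical defining expressions can never collapse
  two named concepts into an unintended equivalence);
* *code spaces* — the permissible T/N/M codes of an edition-site, compiled
  into an auxiliary union concept plus one GCI;
* *stage rules* — conjunctions of site/code-space/T/N/M/behaviour/age
  literals entailing a stage group.

Modules import one another; ``merge_imports`` resolves the acyclic import
closure into a single :class:`~tnmstage.model.KnowledgeBase`.

Document schema (all sections optional, order-independent)::

    module:       {id, imports: [ids]}
    concepts:     [{id, kind, role?, parent?}]
    codes:        [{role, id, parent?, behaviours?}]
    category:     [{id, role?, members: [...], parent?}]
    site:         [{id, topography, morphology, grade?, age?}]
    edition_site: [{id, site, edition}]
    code_space:   [{site, role, codes: [...]}]
    stage_rule:   [{site, stage, t?|any_t?, n?|any_n?, m?|any_m?,
                    behaviour?, age?: {op, value}}]
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .model import (
    AGE_ATTRIBUTE,
    Atomic,
    COMPARATORS,
    Concept,
    ConceptLiteral,
    Existential,
    GCIRule,
    KBError,
    KnowledgeBase,
    KnowledgeModule,
    NumericCondition,
    ROLES,
    RoleMixError,
    UnknownConceptError,
)

# ---------------------------------------------------------------------------
# Axiom surface forms


@dataclass
class EquivalenceAxiom:
    """``lhs ≡ union(members)`` or ``lhs ≡ conjunction(literals)``."""

    lhs: str
    union: Optional[list[str]] = None  # member concept ids
    role: Optional[str] = None  # role through which union members are matched
    conjunction: Optional[list[ConceptLiteral]] = None
    source: str = ""


@dataclass
class CodeSpaceDeclaration:
    site: str
    role: str  # hasT | hasN | hasM
    codes: list[str]
    space_concept: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.space_concept:
            self.space_concept = space_concept_name(self.site, self.role)


@dataclass
class RawGCI:
    """An axiom already in GCI form (edition-site and stage rules)."""

    lhs: list[ConceptLiteral]
    rhs: str
    rule_id: str
    source: str = ""


def space_concept_name(site: str, role: str) -> str:
    # deterministic: site + role suffix, e.g. TNMSiteEd7BreastCodeSpaceT
    return f"{site}CodeSpace{role[3:]}"


class DSLError(KBError):
    """Parse or schema error in a rule-module document."""

    def __init__(self, message: str, line: Optional[int] = None, doc: str = ""):
        self.line = line
        where = f"{doc or '<module>'}"
        if line is not None:
            where += f", line {line}"
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# YAML loading with line tracking


class _LineLoader(yaml.SafeLoader):
    """SafeLoader that records the source line of every mapping."""

    def construct_mapping(self, node, deep=False):
        mapping = super().construct_mapping(node, deep=deep)
        mapping["__line__"] = node.start_mark.line + 1
        return mapping


def _line(entry) -> Optional[int]:
    return entry.get("__line__") if isinstance(entry, dict) else None


_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _require(entry: dict, key: str, doc: str):
    if key not in entry:
        raise DSLError(f"missing field {key!r}", _line(entry), doc)
    return entry[key]


def _check_role(role: str, entry: dict, doc: str) -> str:
    if role not in ROLES:
        raise DSLError(f"unknown role {role!r}", _line(entry), doc)
    return role


def _check_id(cid, entry: dict, doc: str) -> str:
    cid = str(cid)
    if not _ID_RE.match(cid):
        raise DSLError(f"malformed concept id {cid!r}", _line(entry), doc)
    return cid


# ---------------------------------------------------------------------------
# parse_module


def parse_module(text: str, name: str = "<module>") -> KnowledgeModule:
    """Parse one rule-module document into a :class:`KnowledgeModule`.

    The parse is total and order-independent: declarations may reference
    concepts from imported modules; cross-references are resolved at merge
    time.  Syntax and local schema errors carry the offending line number.
    """
    try:
        doc = yaml.load(text, Loader=_LineLoader)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else None
        raise DSLError(f"YAML syntax error: {exc}", line, name) from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise DSLError("document root must be a mapping", None, name)

    header = doc.get("module") or {}
    mod = KnowledgeModule(
        id=str(header.get("id", name)),
        imports=[str(i) for i in header.get("imports", [])],
    )

    def declare(concept: Concept, entry: dict) -> None:
        if concept.id in mod.concepts:
            raise DSLError(f"duplicate concept id {concept.id!r}", _line(entry), name)
        mod.concepts[concept.id] = concept

    for entry in doc.get("concepts", []) or []:
        cid = _check_id(_require(entry, "id", name), entry, name)
        kind = _require(entry, "kind", name)
        role = entry.get("role")
        if role is not None:
            role = _check_role(role, entry, name)
        try:
            declare(Concept(cid, kind, role, mod.id), entry)
        except KBError as exc:
            raise DSLError(str(exc), _line(entry), name) from exc
        for parent in _parents(entry):
            mod.edges.append((cid, parent))

    for entry in doc.get("codes", []) or []:
        role = _check_role(_require(entry, "role", name), entry, name)
        cid = _check_id(_require(entry, "id", name), entry, name)
        behaviours = tuple(str(b) for b in entry.get("behaviours", []))
        declare(Concept(cid, "code", role, mod.id, behaviours), entry)
        for parent in _parents(entry):
            mod.edges.append((cid, parent))

    for entry in doc.get("category", []) or []:
        cid = _check_id(_require(entry, "id", name), entry, name)
        role = _check_role(entry.get("role", "hasMorphology"), entry, name)
        members = [str(m) for m in _require(entry, "members", name)]
        if not members:
            raise DSLError(f"category {cid!r} has no members", _line(entry), name)
        declare(Concept(cid, "category", role, mod.id), entry)
        for m in members:
            mod.edges.append((m, cid))
        for parent in _parents(entry):
            mod.edges.append((cid, parent))
        mod.axioms.append(
            EquivalenceAxiom(cid, union=members, role=role, source=f"{mod.id}:category:{cid}")
        )

    for entry in doc.get("site", []) or []:
        cid = _check_id(_require(entry, "id", name), entry, name)
        declare(Concept(cid, "site", None, mod.id), entry)
        conj: list[ConceptLiteral] = [
            Existential("hasTopography", str(_require(entry, "topography", name))),
            Existential("hasMorphology", str(_require(entry, "morphology", name))),
        ]
        if "grade" in entry:
            conj.append(Existential("hasGrade", str(entry["grade"])))
        if "age" in entry:
            conj.append(_age_condition(entry["age"], entry, name))
        mod.axioms.append(
            EquivalenceAxiom(cid, conjunction=conj, source=f"{mod.id}:site:{cid}")
        )

    for entry in doc.get("edition_site", []) or []:
        cid = _check_id(_require(entry, "id", name), entry, name)
        declare(Concept(cid, "edition_site", None, mod.id), entry)
        site = str(_require(entry, "site", name))
        edition = str(_require(entry, "edition", name))
        mod.axioms.append(
            RawGCI(
                [Atomic(site), Existential("hasTNMEdition", edition)],
                cid,
                rule_id=f"edsite:{cid}",
                source=f"{mod.id}:edition_site:{cid}",
            )
        )

    for entry in doc.get("code_space", []) or []:
        site = str(_require(entry, "site", name))
        role = _check_role(_require(entry, "role", name), entry, name)
        if role not in ("hasT", "hasN", "hasM"):
            raise DSLError(f"code_space role must be hasT/hasN/hasM, got {role!r}",
                           _line(entry), name)
        codes = [str(c) for c in _require(entry, "codes", name)]
        if not codes:
            raise DSLError("code_space has no codes", _line(entry), name)
        decl = CodeSpaceDeclaration(site, role, codes,
                                    source=f"{mod.id}:code_space:{site}:{role}")
        declare(Concept(decl.space_concept, "code_space", None, mod.id), entry)
        mod.axioms.append(decl)

    counters: dict[tuple[str, str], int] = {}
    for entry in doc.get("stage_rule", []) or []:
        site = str(_require(entry, "site", name))
        stage = str(_require(entry, "stage", name))
        key = (site, stage)
        for lhs in _expand_stage_rule(entry, site, name):
            counters[key] = counters.get(key, 0) + 1
            mod.axioms.append(
                RawGCI(
                    lhs,
                    stage,
                    rule_id=f"stage:{site}:{stage}:{counters[key]}",
                    source=f"{mod.id}:stage_rule:{site}:{stage}",
                )
            )

    return mod


def _parents(entry: dict) -> list[str]:
    out = []
    if entry.get("parent"):
        out.append(str(entry["parent"]))
    for p in entry.get("parents", []) or []:
        out.append(str(p))
    return out


def _age_condition(spec, entry, doc) -> NumericCondition:
    if not isinstance(spec, dict):
        raise DSLError("age condition must be a mapping {op, value}", _line(entry), doc)
    op = str(spec.get("op", ""))
    if op not in COMPARATORS:
        raise DSLError(f"unknown age comparator {op!r}", _line(entry), doc)
    return NumericCondition(AGE_ATTRIBUTE, op, float(spec["value"]))


def _expand_stage_rule(entry: dict, site: str, doc: str):
    """Expand alternative code lists into one conjunction per combination."""
    alt_axes: list[list[ConceptLiteral]] = []
    anchors: list[ConceptLiteral] = []
    anchored = False
    for axis, role in (("t", "hasT"), ("n", "hasN"), ("m", "hasM")):
        if entry.get(f"any_{axis}"):
            anchors.append(Atomic(space_concept_name(site, role)))
            anchored = True
        elif axis in entry:
            alts = [Existential(role, str(c)) for c in entry[axis]]
            if not alts:
                raise DSLError(f"empty code list for {axis!r}", _line(entry), doc)
            alt_axes.append(alts)
    if not anchored:
        anchors.append(Atomic(site))
    for b in entry.get("behaviour", []) or []:
        anchors.append(Existential("hasBehaviour", f"BehaviourCode{b}"))
    if "age" in entry:
        anchors.append(_age_condition(entry["age"], entry, doc))

    def product(axes):
        if not axes:
            yield []
            return
        for head in axes[0]:
            for rest in product(axes[1:]):
                yield [head] + rest

    for combo in product(alt_axes):
        yield anchors + combo


# ---------------------------------------------------------------------------
# Normalization


def normalize_equivalence(eq: EquivalenceAxiom) -> list[GCIRule]:
    """Remodel an equivalence as one-directional GCI rules.

    A union of *n* members yields exactly *n* rules, each
    ``∃role.member ⊑ lhs``; a conjunction yields a single rule
    ``conjunction ⊑ lhs``.  The reverse inclusion (``lhs ⊑ rhs``) is never
    emitted.
    """
    if eq.union is not None:
        if not eq.union:
            raise KBError(f"equivalence {eq.lhs} has empty union")
        if eq.role is None:
            raise RoleMixError(f"equivalence {eq.lhs}: union without a role")
        rules = []
        for i, member in enumerate(eq.union, start=1):
            rules.append(
                GCIRule(
                    frozenset([Existential(eq.role, member)]),
                    eq.lhs,
                    rule_id=f"eq:{eq.lhs}:{i}",
                    source=eq.source,
                    origin="equivalence",
                )
            )
        return rules
    if eq.conjunction:
        return [
            GCIRule(
                frozenset(eq.conjunction),
                eq.lhs,
                rule_id=f"eq:{eq.lhs}",
                source=eq.source,
                origin="equivalence",
            )
        ]
    raise KBError(f"equivalence {eq.lhs} has empty right-hand side")


def compile_code_space(
    decl: CodeSpaceDeclaration, concepts: Optional[dict[str, Concept]] = None
) -> tuple[list[tuple[str, str]], GCIRule]:
    """Compile a code-space declaration.

    Creates a deterministic auxiliary union concept; every listed code
    becomes a hierarchy child of it, and one GCI
    ``site ⊓ ∃role.union ⊑ space_concept`` is emitted.
    """
    if not decl.codes:
        raise KBError(f"code space {decl.space_concept} has no codes")
    if concepts is not None:
        for code in decl.codes:
            c = concepts.get(code)
            if c is None:
                raise UnknownConceptError(
                    f"code space {decl.space_concept}: undeclared code {code!r}"
                )
            if c.role != decl.role:
                raise RoleMixError(
                    f"code space {decl.space_concept}: code {code} is bound to "
                    f"{c.role}, not {decl.role}"
                )
    union = decl.space_concept + "Union"
    edges = [(code, union) for code in decl.codes]
    rule = GCIRule(
        frozenset([Atomic(decl.site), Existential(decl.role, union)]),
        decl.space_concept,
        rule_id=f"space:{decl.space_concept}",
        source=decl.source,
        origin="equivalence",
    )
    return edges, rule


# ---------------------------------------------------------------------------
# Merge


def merge_imports(root: KnowledgeModule, registry: dict[str, KnowledgeModule]) -> KnowledgeBase:
    """Resolve the import closure of ``root`` and build the merged KB.

    Deterministic depth-first postorder; importing modules may reference but
    never redefine imported concepts.  All equivalences and code spaces are
    normalized and the stage-rule / code-space indexes are built.
    Merging is idempotent: re-merging the same modules yields an identical
    rule set.
    """
    order: list[KnowledgeModule] = []
    state: dict[str, str] = {}

    def visit(mod: KnowledgeModule, chain: list[str]) -> None:
        if state.get(mod.id) == "done":
            return
        if state.get(mod.id) == "open":
            raise KBError("cyclic import: " + " -> ".join(chain + [mod.id]))
        state[mod.id] = "open"
        for imp in mod.imports:
            if imp not in registry:
                raise KBError(f"module {mod.id}: missing import {imp!r}")
            visit(registry[imp], chain + [mod.id])
        state[mod.id] = "done"
        order.append(mod)

    visit(root, [])

    kb = KnowledgeBase()
    kb.module_ids = [m.id for m in order]
    for mod in order:
        for cid, concept in mod.concepts.items():
            if cid in kb.concepts:
                raise KBError(
                    f"concept redefinition clash: {cid!r} declared in "
                    f"{kb.concepts[cid].module_id!r} and {mod.id!r}"
                )
            kb.add_concept(concept)
    for mod in order:
        for child, parent in mod.edges:
            kb.add_edge(child, parent)

    for mod in order:
        for ax in mod.axioms:
            if isinstance(ax, EquivalenceAxiom):
                kb.rules.extend(normalize_equivalence(ax))
            elif isinstance(ax, CodeSpaceDeclaration):
                edges, rule = compile_code_space(ax, kb.concepts)
                union = ax.space_concept + "Union"
                if union not in kb.concepts:
                    kb.add_concept(Concept(union, "auxiliary", ax.role, mod.id))
                for child, parent in edges:
                    kb.add_edge(child, parent)
                kb.rules.append(rule)
                from .model import CodeSpace

                cs = CodeSpace(ax.site, ax.role, ax.space_concept, union, tuple(ax.codes))
                kb.code_spaces.append(cs)
                kb.site_code_spaces.setdefault(ax.site, {})[ax.role] = cs
            elif isinstance(ax, RawGCI):
                kb.rules.append(
                    GCIRule(frozenset(ax.lhs), ax.rhs, ax.rule_id, ax.source)
                )
            else:  # pragma: no cover - parser emits only the above
                raise KBError(f"unknown axiom type {type(ax).__name__}")

    _check_references(kb)
    _build_stage_index(kb)
    return kb


def _check_references(kb: KnowledgeBase) -> None:
    space_sites = {cs.space_concept: cs.site for cs in kb.code_spaces}
    for rule in kb.rules:
        if rule.rhs not in kb.concepts:
            raise UnknownConceptError(f"rule {rule.rule_id}: undeclared rhs {rule.rhs!r}")
        for lit in rule.lhs:
            if isinstance(lit, Atomic):
                if lit.concept not in kb.concepts:
                    raise UnknownConceptError(
                        f"rule {rule.rule_id}: undeclared concept {lit.concept!r}"
                    )
            elif isinstance(lit, Existential):
                filler = kb.concepts.get(lit.filler)
                if filler is None:
                    raise UnknownConceptError(
                        f"rule {rule.rule_id}: undeclared filler {lit.filler!r}"
                    )
                if filler.role is not None and filler.role != lit.role:
                    raise RoleMixError(
                        f"rule {rule.rule_id}: filler {lit.filler} bound to "
                        f"{filler.role}, used under {lit.role}"
                    )
    del space_sites


def _build_stage_index(kb: KnowledgeBase) -> None:
    space_sites = {cs.space_concept: cs.site for cs in kb.code_spaces}
    for rule in kb.rules:
        rhs = kb.concepts.get(rule.rhs)
        if rhs is None or rhs.kind != "stage":
            continue
        sites = set()
        for lit in rule.lhs:
            if isinstance(lit, Atomic):
                c = kb.concepts.get(lit.concept)
                if c is not None and c.kind == "edition_site":
                    sites.add(lit.concept)
                elif lit.concept in space_sites:
                    sites.add(space_sites[lit.concept])
        for site in sites:
            kb.site_stage_rules.setdefault(site, []).append(rule)


def detect_definition_clashes(kb: KnowledgeBase) -> list[tuple[GCIRule, GCIRule]]:
    """Pairs of equivalence-origin rules whose normalized left-hand sides are
    identical but whose defined classes differ.

    Such pairs are exactly the configurations that would have produced an
    unintended equivalence inference had the axioms been kept as defined
    classes.  Symmetric pairs are reported once, in deterministic order.
    """
    by_lhs: dict[frozenset, list[GCIRule]] = {}
    for rule in kb.rules:
        if rule.origin == "equivalence":
            by_lhs.setdefault(rule.lhs, []).append(rule)
    clashes = []
    for rules in by_lhs.values():
        rules = sorted(rules, key=lambda r: (r.rhs, r.rule_id))
        for i in range(len(rules)):
            for j in range(i + 1, len(rules)):
                if rules[i].rhs != rules[j].rhs:
                    clashes.append((rules[i], rules[j]))
    clashes.sort(key=lambda p: (p[0].rhs, p[1].rhs, p[0].rule_id, p[1].rule_id))
    return clashes


# ---------------------------------------------------------------------------
# OWL functional-syntax export / import

_FACETS = {">=": "xsd:minInclusive", ">": "xsd:minExclusive",
           "<=": "xsd:maxInclusive", "<": "xsd:maxExclusive"}
_FACETS_INV = {v: k for k, v in _FACETS.items()}

_IRI = "http://example.org/tnmstage/kb"


def _render_literal(lit: ConceptLiteral) -> str:
    if isinstance(lit, Atomic):
        return f":{lit.concept}"
    if isinstance(lit, Existential):
        return f"ObjectSomeValuesFrom(:{lit.role} :{lit.filler})"
    value = f"{lit.threshold:g}"
    return (
        f"DataSomeValuesFrom(:{lit.attribute} DatatypeRestriction(xsd:decimal "
        f'{_FACETS[lit.comparator]} "{value}"^^xsd:decimal))'
    )


def export_owl(kb: KnowledgeBase) -> str:
    """Render the KB in OWL 2 functional syntax.

    Hierarchy edges become ``SubClassOf(child parent)``; every rule becomes a
    GCI ``SubClassOf(<complex class> rhs)``.  Output is deterministic
    (sorted) so exports are reproducible byte-for-byte.
    """
    lines = [
        f"Prefix(:=<{_IRI}#>)",
        "Prefix(xsd:=<http://www.w3.org/2001/XMLSchema#>)",
        f"Ontology(<{_IRI}>",
    ]
    for cid in sorted(kb.concepts):
        lines.append(f"Declaration(Class(:{cid}))")
    for role in ROLES:
        lines.append(f"Declaration(ObjectProperty(:{role}))")
    lines.append(f"Declaration(DataProperty(:{AGE_ATTRIBUTE}))")
    edges = sorted(
        (child, parent) for child, ps in kb.parents.items() for parent in ps
    )
    for child, parent in edges:
        lines.append(f"SubClassOf(:{child} :{parent})")
    rendered = []
    for rule in kb.rules:
        parts = sorted(_render_literal(l) for l in rule.lhs)
        lhs = parts[0] if len(parts) == 1 else "ObjectIntersectionOf(" + " ".join(parts) + ")"
        rendered.append(f"SubClassOf({lhs} :{rule.rhs})")
    lines.extend(sorted(set(rendered)))
    lines.append(")")
    return "\n".join(lines) + "\n"


@dataclass
class OwlDocument:
    """Minimal parse of a functional-syntax export: edges and GCI rules."""

    classes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    rules: list[GCIRule] = field(default_factory=list)

    def rule_signatures(self) -> set[tuple]:
        return {r.signature() for r in self.rules}


def _tokenize(text: str):
    for tok in re.findall(r"[()]|[^\s()]+", text):
        yield tok


def _parse_sexpr(tokens: list[str], pos: int):
    # tokens[pos] is a head atom; if followed by '(' parse an expression list
    head = tokens[pos]
    if pos + 1 < len(tokens) and tokens[pos + 1] == "(":
        args = []
        i = pos + 2
        while tokens[i] != ")":
            node, i = _parse_sexpr(tokens, i)
            args.append(node)
        return (head, args), i + 1
    return head, pos + 1


def _strip(name: str) -> str:
    return name[1:] if name.startswith(":") else name


def _literal_from_node(node) -> ConceptLiteral:
    if isinstance(node, str):
        return Atomic(_strip(node))
    head, args = node
    if head == "ObjectSomeValuesFrom":
        return Existential(_strip(args[0]), _strip(args[1]))
    if head == "DataSomeValuesFrom":
        attribute = _strip(args[0])
        rest_head, rest = args[1]
        if rest_head != "DatatypeRestriction":
            raise KBError(f"unsupported data range {rest_head!r}")
        facet = rest[1]
        value = rest[2].split("^^")[0].strip('"')
        return NumericCondition(attribute, _FACETS_INV[facet], float(value))
    raise KBError(f"unsupported class expression {head!r}")


def parse_owl_functional(text: str) -> OwlDocument:
    """Re-parse a functional-syntax export produced by :func:`export_owl`.

    Only the constructs the exporter emits are supported; re-parsing an
    export therefore reconstructs the normalized rule set exactly.
    """
    tokens = list(_tokenize(text))
    doc = OwlDocument()
    i = 0
    n = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in ("Declaration", "SubClassOf") and tokens[i + 1] == "(":
            node, i = _parse_sexpr(tokens, i)
            head, args = node
            if head == "Declaration":
                inner_head, inner = args[0]
                if inner_head == "Class":
                    doc.classes.add(_strip(inner[0]))
                continue
            sub, sup = args
            if isinstance(sub, str) and isinstance(sup, str):
                doc.edges.add((_strip(sub), _strip(sup)))
                continue
            if isinstance(sub, tuple) and sub[0] == "ObjectIntersectionOf":
                literals = [_literal_from_node(a) for a in sub[1]]
            else:
                literals = [_literal_from_node(sub)]
            n += 1
            doc.rules.append(
                GCIRule(frozenset(literals), _strip(sup), rule_id=f"owl:{n}")
            )
        else:
            i += 1
    return doc
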