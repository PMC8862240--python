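"""DSL parsing, normalization, merging, clash detection and OWL round trip."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnmstage.compiler import (
    CodeSpaceDeclaration,
    DSLError,
    EquivalenceAxiom,
    compile_code_space,
    detect_definition_clashes,
    export_owl,
    merge_imports,
    normalize_equivalence,
    parse_module,
    parse_owl_functional,
)
from tnmstage.model import (
    Atomic,
    Concept,
    Existential,
    KBError,
    RoleMixError,
)


class TestParseModule:
    def test_stage_rule_block_parses_to_one_conjunction(self):
        mod = parse_module(
            """
module: {id: m}
stage_rule:
  - {site: TNMSiteEd7Breast, stage: TNMStage0,
     t: [Tis], n: [N0], m: [M0], behaviour: [2]}
""")
        assert len(mod.axioms) == 1
        ax = mod.axioms[0]
        assert ax.rhs == "TNMStage0"
        assert Existential("hasBehaviour", "BehaviourCode2") in ax.lhs
        assert Existential("hasT", "Tis") in ax.lhs
        assert Atomic("TNMSiteEd7Breast") in ax.lhs

    def test_empty_document_yields_empty_module(self):
        mod = parse_module("", name="empty")
        assert mod.axioms == [] and mod.concepts == {}

    def test_unknown_role_error_names_the_line(self):
        text = "module: {id: m}\ncodes:\n  - {role: hasFoo, id: Z1}\n"
        with pytest.raises(DSLError) as err:
            parse_module(text, name="bad")
        assert "hasFoo" in str(err.value) and "line 3" in str(err.value)

    def test_duplicate_concept_id_rejected(self):
        text = """
module: {id: m}
codes:
  - {role: hasT, id: T1}
  - {role: hasT, id: T1}
"""
        with pytest.raises(DSLError, match="duplicate"):
            parse_module(text)

    def test_yaml_syntax_error_carries_position(self):
        with pytest.raises(DSLError, match="syntax"):
            parse_module("module: {id: m\ncodes: [")


class TestNormalizeEquivalence:
    def test_mesothelioma_union_yields_six_rules(self):
        eq = EquivalenceAxiom(
            "Mesothelioma",
            union=[f"M_905{i}" for i in range(6)],
            role="hasMorphology",
        )
        rules = normalize_equivalence(eq)
        assert len(rules) == 6
        assert {r.rhs for r in rules} == {"Mesothelioma"}
        assert rules[0].lhs == frozenset({Existential("hasMorphology", "M_9050")})
        # the reverse inclusion is never emitted
        assert all(r.origin == "equivalence" for r in rules)

    def test_singleton_union(self):
        rules = normalize_equivalence(
            EquivalenceAxiom("A", union=["B"], role="hasT"))
        assert len(rules) == 1

    def test_kidney_conjunction_yields_one_rule(self):
        eq = EquivalenceAxiom(
            "TNMSiteKidney",
            conjunction=[
                Existential("hasMorphology", "Carcinoma"),
                Existential("hasTopography", "C649"),
            ],
        )
        (rule,) = normalize_equivalence(eq)
        assert rule.lhs == frozenset({
            Existential("hasMorphology", "Carcinoma"),
            Existential("hasTopography", "C649"),
        })
        assert rule.rhs == "TNMSiteKidney"

    def test_union_without_role_is_a_role_mix(self):
        with pytest.raises(RoleMixError):
            normalize_equivalence(EquivalenceAxiom("A", union=["B", "C"]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=1, max_value=20))
    def test_rule_count_equals_union_arity(self, arity):
        eq = EquivalenceAxiom("Cat", union=[f"M_{i}" for i in range(arity)],
                              role="hasMorphology")
        assert len(normalize_equivalence(eq)) == arity


class TestCodeSpaces:
    def test_breast_t_space_compiles_to_28_edges_and_one_rule(self, kb):
        space = kb.site_code_spaces["TNMSiteEd7Breast"]["hasT"]
        decl = CodeSpaceDeclaration("TNMSiteEd7Breast", "hasT", list(space.codes))
        edges, rule = compile_code_space(decl)
        assert len(edges) == 28
        assert rule.rhs == "TNMSiteEd7BreastCodeSpaceT"
        assert Atomic("TNMSiteEd7Breast") in rule.lhs

    def test_single_code_space(self):
        edges, rule = compile_code_space(CodeSpaceDeclaration("S", "hasM", ["CM0"]))
        assert edges == [("CM0", "SCodeSpaceMUnion")]
        assert rule.rhs == "SCodeSpaceM"

    def test_membership_in_breast_t_space(self, kb):
        codes = kb.site_code_spaces["TNMSiteEd7Breast"]["hasT"].codes
        assert "CT1c" in codes
        assert "CT4e" not in codes

    def test_code_bound_to_wrong_role_rejected(self):
        concepts = {"CN1": Concept("CN1", "code", "hasN")}
        with pytest.raises(RoleMixError):
            compile_code_space(
                CodeSpaceDeclaration("S", "hasT", ["CN1"]), concepts)


class TestMergeImports:
    def test_fixture_modules_merge(self, kb):
        assert kb.module_ids == ["icdo-generic", "morph-grouping",
                                 "tnm-generic", "tnm-ed7"]
        assert len(kb.rules) > 40

    def test_self_import_is_a_cycle_error(self):
        mod = parse_module("module: {id: loop, imports: [loop]}")
        with pytest.raises(KBError, match="cyclic import"):
            merge_imports(mod, {"loop": mod})

    def test_missing_import_reported(self):
        mod = parse_module("module: {id: m, imports: [nowhere]}")
        with pytest.raises(KBError, match="missing import"):
            merge_imports(mod, {"m": mod})

    def test_concept_redefinition_clash(self, registry):
        extra = parse_module(
            "module: {id: extra, imports: [tnm-ed7]}\n"
            "codes:\n  - {role: hasT, id: CT1}\n")
        registry["extra"] = extra
        with pytest.raises(KBError, match="redefinition"):
            merge_imports(extra, registry)

    def test_edition_module_swap_changes_exactly_one_rule(self, registry):
        """Replacing the edition module with a copy holding one altered
        stage rule yields a KB differing in exactly that rule."""
        from importlib import resources

        base = merge_imports(registry["tnm-ed7"], registry)
        text = resources.files("tnmstage.data").joinpath("tnm_ed7.yaml").read_text()
        altered = text.replace(
            "t: [Tis], n: [N0], m: [M0], behaviour: [2]",
            "t: [Tis], n: [N0], m: [M0], behaviour: [9]",
        )
        assert altered != text
        registry["tnm-ed7"] = parse_module(altered, name="tnm_ed7b.yaml")
        swapped = merge_imports(registry["tnm-ed7"], registry)
        gone = base.rule_signatures() - swapped.rule_signatures()
        new = swapped.rule_signatures() - base.rule_signatures()
        assert len(gone) == 1 and len(new) == 1
        assert next(iter(gone))[1] == next(iter(new))[1] == "TNMStage0"


class TestDefinitionClashes:
    def test_fixture_kb_has_no_clashes(self, kb):
        assert detect_definition_clashes(kb) == []

    def test_duplicate_site_definitions_clash(self, registry):
        extra = parse_module(
            "module: {id: extra, imports: [tnm-ed7]}\n"
            "site:\n"
            "  - {id: TNMSiteKidneyBis, topography: C649, morphology: Carcinoma}\n")
        registry["extra"] = extra
        kb = merge_imports(extra, registry)
        clashes = detect_definition_clashes(kb)
        assert len(clashes) == 1
        assert {clashes[0][0].rhs, clashes[0][1].rhs} == {
            "TNMSiteKidney", "TNMSiteKidneyBis"}

    def test_detection_matches_all_pairs_brute_force(self, kb):
        eq_rules = [r for r in kb.rules if r.origin == "equivalence"]
        brute = {
            frozenset((a.rule_id, b.rule_id))
            for a, b in itertools.combinations(eq_rules, 2)
            if a.lhs == b.lhs and a.rhs != b.rhs
        }
        got = {frozenset((a.rule_id, b.rule_id))
               for a, b in detect_definition_clashes(kb)}
        assert got == brute


class TestOwlRoundTrip:
    def test_kidney_rule_renders_as_gci(self, kb):
        text = export_owl(kb)
        assert ("SubClassOf(ObjectIntersectionOf("
                "ObjectSomeValuesFrom(:hasMorphology :Carcinoma) "
                "ObjectSomeValuesFrom(:hasTopography :C649)) :TNMSiteKidney)"
                ) in text

    def test_empty_kb_exports_valid_document(self):
        from tnmstage.model import KnowledgeBase

        doc = parse_owl_functional(export_owl(KnowledgeBase()))
        assert doc.rules == [] and doc.edges == set()

    def test_round_trip_preserves_rules_and_edges(self, kb):
        doc = parse_owl_functional(export_owl(kb))
        assert doc.rule_signatures() == kb.rule_signatures()
        edges = {(c, p) for c, ps in kb.parents.items() for p in ps}
        assert doc.edges == edges
        assert doc.classes == set(kb.concepts)

    def test_export_is_deterministic(self, kb, registry):
        again = merge_imports(registry["tnm-ed7"], registry)
        assert export_owl(kb) == export_owl(again)

    def test_numeric_condition_survives_round_trip(self, kb):
        doc = parse_owl_functional(export_owl(kb))
        numeric = [
            lit
            for r in doc.rules
            for lit in r.lhs
            if lit.__class__.__name__ == "NumericCondition"
        ]
        assert numeric and all(lit.threshold == 45.0 for lit in numeric)
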