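"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from tnmstage import build_kb, load_modules
from tnmstage.engine import FactSet
from tnmstage.model import (
    Atomic,
    Concept,
    Existential,
    GCIRule,
    KnowledgeBase,
    NumericCondition,
)


@pytest.fixture(scope="session")
def kb():
    """The packaged edition-7 knowledge base (treated as read-only)."""
    return build_kb()


@pytest.fixture()
def registry():
    """Freshly parsed module registry (mutable per test)."""
    return load_modules()


# ---------------------------------------------------------------------------
# Independent naive fixpoint oracle (no engine code involved)


def naive_closure(parents: dict[str, set[str]], cid: str) -> set[str]:
    out = {cid}
    stack = [cid]
    while stack:
        for p in parents.get(stack.pop(), ()):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def naive_fixpoint(kb: KnowledgeBase, facts: FactSet) -> set[str]:
    """Brute-force least fixpoint: re-scan every rule until exhaustion,
    using its own ancestor walk rather than the engine's caches."""
    derived = set(facts.derived)
    changed = True
    while changed:
        changed = False
        for rule in kb.rules:
            ok = True
            for lit in rule.lhs:
                if isinstance(lit, Atomic):
                    ok = lit.concept in derived
                elif isinstance(lit, Existential):
                    ok = any(
                        role == lit.role
                        and lit.filler in naive_closure(kb.parents, code)
                        for role, code in facts.assertions
                    )
                else:
                    v = facts.numeric_attributes.get(lit.attribute)
                    ok = v is not None and lit.holds(v)
                if not ok:
                    break
            if ok:
                new = naive_closure(kb.parents, rule.rhs)
                if not new <= derived:
                    derived |= new
                    changed = True
    return derived


# ---------------------------------------------------------------------------
# Random small KB / fact-set generator


def make_random_kb(rng: random.Random, max_concepts: int = 50,
                   max_rules: int = 15) -> tuple[KnowledgeBase, FactSet]:
    kb = KnowledgeBase()
    roles = ["hasT", "hasMorphology"]
    by_role: dict[str, list[str]] = {r: [] for r in roles}
    targets: list[str] = []
    n = rng.randint(6, max_concepts)
    for i in range(n):
        if rng.random() < 0.3:
            cid = f"X{i}"
            kb.add_concept(Concept(cid, "category", "hasMorphology"))
            targets.append(cid)
            by_role["hasMorphology"].append(cid)
        else:
            role = rng.choice(roles)
            cid = f"C{i}"
            kb.add_concept(Concept(cid, "code", role))
            by_role[role].append(cid)
        # random forest edge to an earlier concept of the same role
        role = kb.concepts[cid].role
        earlier = [c for c in by_role[role] if c != cid]
        if earlier and rng.random() < 0.6:
            kb.add_edge(cid, rng.choice(earlier))
    if not targets:
        kb.add_concept(Concept("X_only", "category", "hasMorphology"))
        targets.append("X_only")
        by_role["hasMorphology"].append("X_only")
    for j in range(rng.randint(1, max_rules)):
        lhs: list = []
        for _ in range(rng.randint(1, 3)):
            kind = rng.random()
            if kind < 0.35:
                lhs.append(Atomic(rng.choice(targets)))
            elif kind < 0.85:
                role = rng.choice(roles)
                if by_role[role]:
                    lhs.append(Existential(role, rng.choice(by_role[role])))
            else:
                lhs.append(NumericCondition(
                    "age", rng.choice(["<", "<=", ">", ">="]),
                    rng.randint(20, 80)))
        if not lhs:
            lhs.append(Atomic(rng.choice(targets)))
        kb.rules.append(GCIRule(frozenset(lhs), rng.choice(targets), f"r{j}"))
    facts = FactSet()
    for role in roles:
        codes = by_role[role]
        for code in rng.sample(codes, k=min(len(codes), rng.randint(0, 3))):
            facts.assert_code(role, code)
    if rng.random() < 0.5:
        facts.numeric_attributes["age"] = float(rng.randint(10, 90))
    return kb, facts
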