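# Methods

## Rule language and normalization

The knowledge base is a set of atomic concepts arranged in per-role
hierarchies plus a set of normalized rules.  A rule (general concept
inclusion, GCI) is a conjunction of literals entailing one named concept;
literals are atomic concepts, existential role restrictions over the
closed role set {hasTopography, hasMorphology, hasBehaviour, hasGrade,
hasT, hasN, hasM, hasTNMEdition}, or numeric comparisons on the single
age attribute (years).  Concept identifiers are underscore-normalized
tokens (`C50.1 → C501`, `8140/3 → M_8140` + `BehaviourCode3`), so the two
code dialects found in registry data share one canonical internal form.

Three surface forms are compiled into this normal form:

* **Equivalences.**  A defined class `A ≡ B₁ ⊔ … ⊔ Bₙ` is remodelled into
  exactly *n* one-way rules `∃r.Bᵢ ⊑ A`; a conjunctive definition becomes
  a single rule.  The reverse inclusion is deliberately never emitted:
  with one-way GCIs, two classes that happen to share a defining
  expression can never be inferred equivalent by accident.  The dropped
  direction is not needed for record classification, and the queries that
  would have used it (stages of a site, codes of a category) are answered
  by index lookup over the compiled rules instead — no inverse-role
  reasoning is implemented.
* **Code spaces.**  The permissible T (or N, M) codes of an edition-site
  are compiled into an auxiliary union concept with the codes as hierarchy
  children plus one rule `site ⊓ ∃role.union ⊑ spaceConcept`.  Auxiliary
  names are deterministic (`TNMSiteEd7Breast` + `CodeSpaceT` [+ `Union`])
  so exports are reproducible byte-for-byte.
* **Stage rules.**  Lists of alternative category codes expand into one
  rule per combination.  "Any T"/"Any N" table rows use the code-space
  concept as an atomic left-hand term, which ties the rule to the
  site-specific code set rather than the global code universe: a T code
  outside the space blocks the stage inference and surfaces as a
  code-space error.

Hierarchies must be acyclic, and edges may only link concepts bound to
the same role (T, N, M, topography, morphology … are disjoint); a lint
operation reports violations rather than raising.  Morphology categories
(Carcinoma, Adenocarcinoma, Mesothelioma, …) live inside the morphology
hierarchy as parents of code concepts, so `∃hasMorphology.Carcinoma`
matches any transitively grouped code; 4-digit morphology codes sit under
their 3-digit prefix concept.  Stage concepts form their own small lattice
(IIIA/IIIB/IIIC under III, …) so "most specific inferred stage" is well
defined.  One deliberate exception: pN1mi is *not* nested under N1,
because T0/T1+N1mi and T0/T1+N1 map to different breast stage groups (IB
vs IIA) and nesting would fire both rows at once.

Modules are YAML documents with an acyclic import graph; merging resolves
the depth-first import closure, forbids concept redefinition across
modules, and is idempotent.  Supporting another TNM edition means writing
one new edition module; everything else is untouched.

## Inference

Records are classified by forward-chaining saturation: every rule whose
conjunction matches fires, adding its right-hand concept and that
concept's ancestors to the derived set, until a fixpoint is reached.
Because rules only add concepts, the fixpoint is least and unique, so the
result is independent of rule order (property-tested) and equal to a
naive brute-force evaluator on random rule sets.  Completeness is claimed
only for the fragment the compiler emits — conjunctions of
atomic/existential/numeric literals with atomic right-hand sides — not
for arbitrary description-logic TBoxes.

A second execution mode (`direct`) evaluates the rules once in
topological order of their atomic dependencies (strongly connected
components are iterated locally), mirroring a plain indexed lookup over
the asserted axioms.  On the acyclic compiled fragment both modes are
provably identical and the batch validator enforces this contractually;
the mode flag exists because a registry pipeline may prefer the
single-pass evaluator for bulk runs.

Missing data is read open-world: an absent age never satisfies a numeric
condition, and a record without T/N/M data is *unstaged*, not invalid.
X codes ("cannot be assessed") participate in the code-space check only;
stage inference abstains when any effective category is X, since no stage
rule is meant to consume an unassessable value.  When both clinical and
pathological codes are present, both must lie in the code space, and
staging uses the pathological code first (registry practice of
pathological confirmation); no rule decides between conflicting C/P codes
beyond that precedence.  If two incomparable stages are ever derived the
validator reports a rule-authoring inconsistency instead of choosing.

## Validation checks and verdicts

V1 resolves the edition-site from topography + morphology category +
edition (none → verdict *ineligible*); V2 checks each present T/N/M code
against the site's code space; V3 checks behaviour against the declared
stage's rules (stage 0 requires in situ behaviour 2; invasive stages
behaviour 3 — applied wherever the stage rule carries a behaviour
literal); V4 checks the declared stage against the site's permissible
stage set; V5 compares declared and most specific inferred stage; V6
flags malformed code syntax at normalization and excludes the record from
staging.  A record with no TNM data at all is *unstaged* with no
findings.  A configurable leniency flag (default strict) accepts a coarse
declared stage (III when IIIC is inferred); registries submit both
granularities.  Batch processing inserts, classifies and retracts one
block of records at a time (default block size 100, an arbitrary
choice); reports are independent of block size and keep input order.

Correction proposals assume the declared stage is right and the error
lies in the other parameters: the smallest set of fields is sought whose
reassignment over the site's code space (X codes excluded) and the
behaviour digits satisfies a stage rule of the declared stage; per field
the proposal lists every value occurring in a satisfying assignment and
is marked unique when exactly one does.  Output renders expected values
after chevrons with `!` marking the incorrect inputs; spacing of that
rendering is cosmetic, not contractual.

## Shipped knowledge base

The packaged modules cover the edition-7 breast site in full: the
28-code T space (clinical CT0–CTX; pathological PT0–PTX including PT1mi
and PTis), N and M spaces transcribed from the edition-7 breast table
(MX is excluded — withdrawn in edition 7), and the complete anatomic
stage table 0–IV with the in situ behaviour condition on stage 0.  The
kidney site definition (C64.9 ∩ carcinoma) is included with a
*synthetic, simplified* edition-7 ruleset, as is an age-conditioned
thyroid-like site (threshold 45 years) exercising numeric conditions;
both are marked synthetic in the fixture file and are not faithful
transcriptions of their real edition-7 tables.  The full edition-7
classification spans roughly 55 sites; transcribing them is data entry,
not new machinery.

## Synthetic records and oracles

The generator emits, per site and seed-reproducibly, three scenarios:
(i) *valid* — a stage rule is sampled and satisfying codes are drawn
uniformly from the admissible non-X values, with topography and
morphology drawn from the codes deriving the site and the rule's
behaviour/age constraints honoured; (ii) *corrupted parameter* — one
T/N/M/behaviour value is rewritten, half the time to a code outside the
site's code space (an undeclared token when the space exhausts the
declared codes), half the time to an in-space value inconsistent with
the declared stage; candidates are rejection-checked so the corruption
provably produces at least one error finding; (iii) *unknown stage* — the
declared stage is replaced by one outside the site's permissible set
(and not a coarse ancestor of it, so the record is invalid under either
strictness).  Labels are ground truth and the validator's verdicts are
tested to match them exactly.

What the generator does *not* emulate: real registry records carry
missing fields, transcription noise, historical edition mixtures and
site distributions that synthetic sampling does not model, so passing
these tests shows rule-engine correctness, not field-data robustness.

Two independent oracles guard the engine.  A literal transcription of
the edition-7 breast stage table (plain string grouping + row lookup,
sharing no code with the engine) is compared against the engine over the
full 28×24×4×2 product of T × N × M × behaviour — 5 376 combinations,
well under a minute.  A naive fixpoint evaluator with its own ancestor
walk is compared against saturation on 200 random small rule sets.

## Numerical and procedural choices

Determinism throughout: sorted iteration orders, deterministic auxiliary
names, a single `random.Random(seed)` stream in the generator.  Age
windows for sampling satisfying records extend 25–35 years around the
threshold.  OWL 2 functional-syntax export writes hierarchy edges as
`SubClassOf` between named classes and rules as GCIs
(`ObjectSomeValuesFrom`, `DataSomeValuesFrom` with XSD facets); the
bundled reader supports exactly the constructs the writer emits, giving
an exact round trip on normalized rule sets — parsing third-party OWL is
out of scope.

## Known limitations

* No ABox/individuals, no tableau reasoning, no qualified cardinality;
  duplicate topography or morphology assertions per record are excluded
  by the record format rather than by axioms.
* Completeness holds for the compiled rule fragment only.
* The kidney/thyroid-like rulesets are simplified synthetic exercisers.
* Verdicts for abstained records (X codes) are lenient: a declared stage
  that V4 accepts is not contradicted, since the codes cannot refute it.
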