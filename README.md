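# tnmstage

An executable TNM staging knowledge base for population-based cancer
registries: it classifies summary cancer-case records to TNM sites and
stage groups, validates declared stage and T/N/M codes against
edition-specific rules, and proposes corrections — with a small
forward-chaining inference engine instead of an external description-logic
reasoner.

## Who this is for

Cancer registries verify that the synthesized stage group of each case
record accords with its T (tumour extent), N (nodal involvement) and
M (metastasis) codes, which in turn depend on anatomical site (ICD-O-3
topography), morphology, behaviour, TNM edition — and for some sites on
grade or age.  This package encodes those rules as data and makes them
executable, queryable and exportable.

## The model

Every rule is a *general concept inclusion* (GCI): a conjunction of
literals entailing a single named concept.  Literals are atomic concepts,
existential role restrictions, or numeric conditions on age.  For the
edition-7 breast site, for example:

```
∃hasTopography.C50 ⊓ ∃hasMorphology.Carcinoma                  ⊑ TNMSiteBreast
TNMSiteBreast ⊓ ∃hasTNMEdition.TNMEd7                          ⊑ TNMSiteEd7Breast
TNMSiteEd7Breast ⊓ ∃hasT.(CT0 ⊔ … ⊔ PTis)                      ⊑ TNMSiteEd7BreastCodeSpaceT
TNMSiteEd7Breast ⊓ ∃hasBehaviour.BehaviourCode2
                 ⊓ ∃hasT.Tis ⊓ ∃hasN.N0 ⊓ ∃hasM.M0             ⊑ TNMStage0
TNMSiteEd7BreastCodeSpaceT ⊓ ∃hasN.N3 ⊓ ∃hasM.M0
                 ⊓ ∃hasBehaviour.BehaviourCode3                ⊑ TNMStageIIIC
```

Equivalence (defined-class) axioms — morphology-category unions like
`Mesothelioma ≡ M_9050 ⊔ … ⊔ M_9055`, site definitions, code spaces — are
*remodelled* into one-directional GCIs at compile time, which makes
unintended equivalences between identically-defined classes impossible.
A record is staged by saturating the rule set to its least fixpoint over
the record's asserted codes; "Any T" stage rows are expressed through the
site's own code-space concept, so an out-of-space T code blocks the
inference and is reported instead of being silently accepted.

Rule modules are YAML files that import one another; the edition-specific
module can be swapped out to support another TNM edition without touching
the rest of the knowledge base.  The package ships the edition-7 breast
ruleset plus smaller kidney and age-conditioned thyroid-like exercisers.

## Worked example

```
$ tnmstage stage --topography C50.1 --morphology 8050/2 --edition 7 \
      --pt is --cn 0 --cm 0
site: TNMSiteEd7Breast
code space M: CM0 CM1 PM0 PM1
code space N: CN0 CN1 CN2 CN2a CN2b CN3 CN3a CN3b CN3c CNX PN0 PN1 PN1a ...
code space T: CT0 CT1 CT1a CT1b CT1c CT2 CT3 CT4 CT4a CT4b CT4c CT4d CTX ...
stage: 0
```

The record (an in situ papillary carcinoma of the breast, C50.1 / 8050/2,
pTis cN0 cM0, edition 7) resolves to the breast edition-7 site; the
printed code spaces are the permissible values for each category, and the
inferred stage group is 0.

Batch validation, KB queries, synthetic-record generation and OWL export:

```
tnmstage generate --per-site 10 --seed 1 --out records.csv
tnmstage validate records.csv --mode reasoner --out report.csv
tnmstage query stages-of-site TNMSiteEd7Breast
tnmstage query codes-of-category Mesothelioma
tnmstage export-owl --out kb.ofn
```

`validate` exits 0 when every record is valid or unstaged, 1 when any
error finding was produced, 2 on unreadable input.  The report CSV holds
one row per finding (checks V1–V6: site resolution, code space, behaviour
consistency, permissible stage, inferred-vs-declared stage, format) plus a
summary row per record.  With `--corrections` the tool prints
expected-value proposals for records whose declared stage is trusted:

```
record fig12 (declared stage 0)
  T:         CT1     » PTis !
  N:         CN0     » CN0
  M:         CM0     » CM0
  behaviour: 3       » 2 !
```

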