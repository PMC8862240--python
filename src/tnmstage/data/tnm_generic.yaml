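# Edition-independent TNM module: T/N/M category codes with their clinical
# (C-prefixed) and pathological (P-prefixed) concrete codes, the stage-group
# lattice, TNM editions, and the edition-independent site definitions
# (topography x morphology category).
#
# Hierarchy conventions:
#   * sub-codes nest under their category (CT1a -> T1a -> T1), so a stage
#     rule over T1 matches any T1 sub-code;
#   * pN1mi (micrometastasis) is deliberately NOT nested under N1: in the
#     edition-7 breast table T0/T1+N1mi is stage IB while T0/T1+N1 is
#     stage IIA, so nesting would fire both rules at once.
module:
  id: tnm-generic
  imports: [morph-grouping]

concepts:
  - {id: TNMEd7, kind: edition, role: hasTNMEdition}
  # stage-group lattice: sub-stages under their coarse stage
  - {id: TNMStage0, kind: stage}
  - {id: TNMStageI, kind: stage}
  - {id: TNMStageIA, kind: stage, parent: TNMStageI}
  - {id: TNMStageIB, kind: stage, parent: TNMStageI}
  - {id: TNMStageII, kind: stage}
  - {id: TNMStageIIA, kind: stage, parent: TNMStageII}
  - {id: TNMStageIIB, kind: stage, parent: TNMStageII}
  - {id: TNMStageIII, kind: stage}
  - {id: TNMStageIIIA, kind: stage, parent: TNMStageIII}
  - {id: TNMStageIIIB, kind: stage, parent: TNMStageIII}
  - {id: TNMStageIIIC, kind: stage, parent: TNMStageIII}
  - {id: TNMStageIV, kind: stage}
  - {id: TNMStageIVA, kind: stage, parent: TNMStageIV}
  - {id: TNMStageIVB, kind: stage, parent: TNMStageIV}
  - {id: TNMStageIVC, kind: stage, parent: TNMStageIV}

codes:
  # ---- T categories and concrete codes
  - {role: hasT, id: Tis}
  - {role: hasT, id: CTis, parent: Tis}
  - {role: hasT, id: PTis, parent: Tis}
  - {role: hasT, id: T0}
  - {role: hasT, id: CT0, parent: T0}
  - {role: hasT, id: PT0, parent: T0}
  - {role: hasT, id: T1}
  - {role: hasT, id: CT1, parent: T1}
  - {role: hasT, id: PT1, parent: T1}
  - {role: hasT, id: T1a, parent: T1}
  - {role: hasT, id: CT1a, parent: T1a}
  - {role: hasT, id: PT1a, parent: T1a}
  - {role: hasT, id: T1b, parent: T1}
  - {role: hasT, id: CT1b, parent: T1b}
  - {role: hasT, id: PT1b, parent: T1b}
  - {role: hasT, id: T1c, parent: T1}
  - {role: hasT, id: CT1c, parent: T1c}
  - {role: hasT, id: PT1c, parent: T1c}
  - {role: hasT, id: T1mi, parent: T1}
  - {role: hasT, id: PT1mi, parent: T1mi}
  - {role: hasT, id: T2}
  - {role: hasT, id: CT2, parent: T2}
  - {role: hasT, id: PT2, parent: T2}
  - {role: hasT, id: T3}
  - {role: hasT, id: CT3, parent: T3}
  - {role: hasT, id: PT3, parent: T3}
  - {role: hasT, id: T4}
  - {role: hasT, id: CT4, parent: T4}
  - {role: hasT, id: PT4, parent: T4}
  - {role: hasT, id: T4a, parent: T4}
  - {role: hasT, id: CT4a, parent: T4a}
  - {role: hasT, id: PT4a, parent: T4a}
  - {role: hasT, id: T4b, parent: T4}
  - {role: hasT, id: CT4b, parent: T4b}
  - {role: hasT, id: PT4b, parent: T4b}
  - {role: hasT, id: T4c, parent: T4}
  - {role: hasT, id: CT4c, parent: T4c}
  - {role: hasT, id: PT4c, parent: T4c}
  - {role: hasT, id: T4d, parent: T4}
  - {role: hasT, id: CT4d, parent: T4d}
  - {role: hasT, id: PT4d, parent: T4d}
  - {role: hasT, id: TX}
  - {role: hasT, id: CTX, parent: TX}
  - {role: hasT, id: PTX, parent: TX}

  # ---- N categories and concrete codes
  - {role: hasN, id: N0}
  - {role: hasN, id: CN0, parent: N0}
  - {role: hasN, id: PN0, parent: N0}
  - {role: hasN, id: N1}
  - {role: hasN, id: CN1, parent: N1}
  - {role: hasN, id: PN1, parent: N1}
  - {role: hasN, id: N1a, parent: N1}
  - {role: hasN, id: PN1a, parent: N1a}
  - {role: hasN, id: N1b, parent: N1}
  - {role: hasN, id: PN1b, parent: N1b}
  - {role: hasN, id: N1c, parent: N1}
  - {role: hasN, id: PN1c, parent: N1c}
  - {role: hasN, id: N1mi}
  - {role: hasN, id: PN1mi, parent: N1mi}
  - {role: hasN, id: N2}
  - {role: hasN, id: CN2, parent: N2}
  - {role: hasN, id: PN2, parent: N2}
  - {role: hasN, id: N2a, parent: N2}
  - {role: hasN, id: CN2a, parent: N2a}
  - {role: hasN, id: PN2a, parent: N2a}
  - {role: hasN, id: N2b, parent: N2}
  - {role: hasN, id: CN2b, parent: N2b}
  - {role: hasN, id: PN2b, parent: N2b}
  - {role: hasN, id: N3}
  - {role: hasN, id: CN3, parent: N3}
  - {role: hasN, id: PN3, parent: N3}
  - {role: hasN, id: N3a, parent: N3}
  - {role: hasN, id: CN3a, parent: N3a}
  - {role: hasN, id: PN3a, parent: N3a}
  - {role: hasN, id: N3b, parent: N3}
  - {role: hasN, id: CN3b, parent: N3b}
  - {role: hasN, id: PN3b, parent: N3b}
  - {role: hasN, id: N3c, parent: N3}
  - {role: hasN, id: CN3c, parent: N3c}
  - {role: hasN, id: PN3c, parent: N3c}
  - {role: hasN, id: NX}
  - {role: hasN, id: CNX, parent: NX}
  - {role: hasN, id: PNX, parent: NX}

  # ---- M categories and concrete codes (MX was withdrawn in edition 7
  #      and is not declared)
  - {role: hasM, id: M0}
  - {role: hasM, id: CM0, parent: M0}
  - {role: hasM, id: PM0, parent: M0}
  - {role: hasM, id: M1}
  - {role: hasM, id: CM1, parent: M1}
  - {role: hasM, id: PM1, parent: M1}

# Edition-independent site definitions (defined classes, remodelled by the
# compiler into one-way GCIs: topography ⊓ morphology-category ⊑ site).
site:
  - {id: TNMSiteBreast, topography: C50, morphology: Carcinoma}
  - {id: TNMSiteKidney, topography: C649, morphology: Carcinoma}
  # synthetic age-conditioned site patterned on the thyroid gland, whose
  # staging depends on age at diagnosis (threshold 45 years)
  - {id: TNMSiteThyroidSynth, topography: C73, morphology: Carcinoma}
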