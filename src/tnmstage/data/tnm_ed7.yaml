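# TNM edition-7 module: edition-sites, per-site T/N/M code spaces and
# stage-group rules.  Swapping this file for an edition-8 counterpart is the
# intended way to support another edition; nothing else changes.
#
# Provenance:
#   * breast T code space: the 28 clinical/pathological codes of the
#     edition-7 breast classification (UICC TNM 7th ed.; ENCR/JRC table
#     after Martos et al.);
#   * breast N and M spaces: transcribed from the same edition-7 breast
#     table rows (clinical N0-N3c + NX; pathological adds pN1mi, pN1a-c;
#     M0/M1 clinical and pathological).  MX is excluded - withdrawn in
#     edition 7;
#   * breast stage rules: edition-7 breast anatomic stage table.  Stage 0
#     requires in situ behaviour (2); invasive stages require behaviour 3.
#     "Any T"/"Any N" rows (IIIC, IV) are expressed against the site's own
#     code space, never the global code universe;
#   * kidney and thyroid-like rulesets are SYNTHETIC simplifications
#     (reduced code spaces, coarse stage rows) shipped so that the record
#     generator covers several sites and an age-conditioned rule; they are
#     not a faithful transcription of the edition-7 kidney/thyroid tables.
module:
  id: tnm-ed7
  imports: [tnm-generic]

edition_site:
  - {id: TNMSiteEd7Breast, site: TNMSiteBreast, edition: TNMEd7}
  - {id: TNMSiteEd7Kidney, site: TNMSiteKidney, edition: TNMEd7}
  - {id: TNMSiteEd7ThyroidSynth, site: TNMSiteThyroidSynth, edition: TNMEd7}

code_space:
  - site: TNMSiteEd7Breast
    role: hasT
    codes: [CT0, CT1, CT1a, CT1b, CT1c, CT2, CT3, CT4, CT4a, CT4b, CT4c,
            CT4d, CTX, PT0, PT1, PT1a, PT1b, PT1c, PT1mi, PT2, PT3, PT4,
            PT4a, PT4b, PT4c, PT4d, PTX, PTis]
  - site: TNMSiteEd7Breast
    role: hasN
    codes: [CN0, CN1, CN2, CN2a, CN2b, CN3, CN3a, CN3b, CN3c, CNX,
            PN0, PN1, PN1mi, PN1a, PN1b, PN1c, PN2, PN2a, PN2b,
            PN3, PN3a, PN3b, PN3c, PNX]
  - site: TNMSiteEd7Breast
    role: hasM
    codes: [CM0, CM1, PM0, PM1]

  # synthetic simplified kidney spaces
  - site: TNMSiteEd7Kidney
    role: hasT
    codes: [CT1, CT1a, CT1b, CT2, CT3, CT4, CTX,
            PT1, PT1a, PT1b, PT2, PT3, PT4, PTX]
  - site: TNMSiteEd7Kidney
    role: hasN
    codes: [CN0, CN1, CNX, PN0, PN1, PNX]
  - site: TNMSiteEd7Kidney
    role: hasM
    codes: [CM0, CM1, PM0, PM1]

  # synthetic simplified thyroid-like spaces
  - site: TNMSiteEd7ThyroidSynth
    role: hasT
    codes: [CT1, CT2, CT3, CT4, CTX, PT1, PT2, PT3, PT4, PTX]
  - site: TNMSiteEd7ThyroidSynth
    role: hasN
    codes: [CN0, CN1, CNX, PN0, PN1, PNX]
  - site: TNMSiteEd7ThyroidSynth
    role: hasM
    codes: [CM0, CM1, PM0, PM1]

stage_rule:
  # ---- breast, edition 7 ------------------------------------------------
  # stage 0: in situ (behaviour 2), Tis N0 M0
  - {site: TNMSiteEd7Breast, stage: TNMStage0,
     t: [Tis], n: [N0], m: [M0], behaviour: [2]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIA,
     t: [T1], n: [N0], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIB,
     t: [T0, T1], n: [N1mi], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIIA,
     t: [T0, T1], n: [N1], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIIA,
     t: [T2], n: [N0], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIIB,
     t: [T2], n: [N1], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIIB,
     t: [T3], n: [N0], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIIIA,
     t: [T0, T1, T2], n: [N2], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIIIA,
     t: [T3], n: [N1, N2], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIIIB,
     t: [T4], n: [N0, N1, N2], m: [M0], behaviour: [3]}
  # "Any T" = any code of the breast T code space (code-space term on the
  # left-hand side, so an out-of-space T blocks the inference)
  - {site: TNMSiteEd7Breast, stage: TNMStageIIIC,
     any_t: true, n: [N3], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Breast, stage: TNMStageIV,
     any_t: true, any_n: true, m: [M1], behaviour: [3]}

  # ---- kidney, edition 7 (synthetic simplification) ----------------------
  - {site: TNMSiteEd7Kidney, stage: TNMStageI,
     t: [T1], n: [N0], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Kidney, stage: TNMStageII,
     t: [T2], n: [N0], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Kidney, stage: TNMStageIII,
     t: [T3], n: [N0], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Kidney, stage: TNMStageIII,
     t: [T1, T2, T3], n: [N1], m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Kidney, stage: TNMStageIV,
     t: [T4], any_n: true, m: [M0], behaviour: [3]}
  - {site: TNMSiteEd7Kidney, stage: TNMStageIV,
     any_t: true, any_n: true, m: [M1], behaviour: [3]}

  # ---- thyroid-like age-conditioned site (synthetic) ---------------------
  # under 45 years: M0 -> stage I, M1 -> stage II, whatever T and N
  - {site: TNMSiteEd7ThyroidSynth, stage: TNMStageI,
     any_t: true, any_n: true, m: [M0], behaviour: [3],
     age: {op: "<", value: 45}}
  - {site: TNMSiteEd7ThyroidSynth, stage: TNMStageII,
     any_t: true, any_n: true, m: [M1], behaviour: [3],
     age: {op: "<", value: 45}}
  # 45 years and over
  - {site: TNMSiteEd7ThyroidSynth, stage: TNMStageI,
     t: [T1], n: [N0], m: [M0], behaviour: [3], age: {op: ">=", value: 45}}
  - {site: TNMSiteEd7ThyroidSynth, stage: TNMStageII,
     t: [T2], n: [N0], m: [M0], behaviour: [3], age: {op: ">=", value: 45}}
  - {site: TNMSiteEd7ThyroidSynth, stage: TNMStageIII,
     t: [T3], n: [N0], m: [M0], behaviour: [3], age: {op: ">=", value: 45}}
  - {site: TNMSiteEd7ThyroidSynth, stage: TNMStageIII,
     t: [T1, T2, T3], n: [N1], m: [M0], behaviour: [3],
     age: {op: ">=", value: 45}}
  - {site: TNMSiteEd7ThyroidSynth, stage: TNMStageIVA,
     t: [T4], any_n: true, m: [M0], behaviour: [3], age: {op: ">=", value: 45}}
  - {site: TNMSiteEd7ThyroidSynth, stage: TNMStageIVC,
     any_t: true, any_n: true, m: [M1], behaviour: [3],
     age: {op: ">=", value: 45}}
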