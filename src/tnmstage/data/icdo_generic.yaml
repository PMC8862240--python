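# ICD-O-3 code module: topography and morphology code hierarchies,
# behaviour digits and grade digits.  Codes are normalized tokens
# (C50.1 -> C501; morphology 8140/3 -> M_8140 + BehaviourCode3).
# Deliberately partial: only the codes exercised by the shipped TNM
# edition-7 sites are declared, not the full ICD-O-3 code book.
module:
  id: icdo-generic

codes:
  # --- topography: breast (C50), kidney (C64), thyroid gland (C73)
  - {role: hasTopography, id: C50}
  - {role: hasTopography, id: C500, parent: C50}
  - {role: hasTopography, id: C501, parent: C50}
  - {role: hasTopography, id: C502, parent: C50}
  - {role: hasTopography, id: C503, parent: C50}
  - {role: hasTopography, id: C504, parent: C50}
  - {role: hasTopography, id: C505, parent: C50}
  - {role: hasTopography, id: C506, parent: C50}
  - {role: hasTopography, id: C508, parent: C50}
  - {role: hasTopography, id: C509, parent: C50}
  - {role: hasTopography, id: C64}
  - {role: hasTopography, id: C649, parent: C64}
  - {role: hasTopography, id: C73}
  - {role: hasTopography, id: C739, parent: C73}

  # --- morphology: 4-digit codes under their 3-digit prefix concepts
  # papillary / squamous-lineage carcinomas (M_805-)
  - {role: hasMorphology, id: M_805}
  - {role: hasMorphology, id: M_8050, parent: M_805, behaviours: ["2", "3"]}
  - {role: hasMorphology, id: M_8051, parent: M_805, behaviours: ["3"]}
  - {role: hasMorphology, id: M_8052, parent: M_805, behaviours: ["2", "3"]}
  # basal cell carcinomas (M_809-)
  - {role: hasMorphology, id: M_809}
  - {role: hasMorphology, id: M_8090, parent: M_809, behaviours: ["3"]}
  - {role: hasMorphology, id: M_8091, parent: M_809, behaviours: ["3"]}
  - {role: hasMorphology, id: M_8092, parent: M_809, behaviours: ["3"]}
  - {role: hasMorphology, id: M_8093, parent: M_809, behaviours: ["3"]}
  # adenocarcinomas: ductal/lobular family (M_850-) and adenocarcinoma NOS
  - {role: hasMorphology, id: M_850}
  - {role: hasMorphology, id: M_8500, parent: M_850, behaviours: ["2", "3"]}
  - {role: hasMorphology, id: M_8503, parent: M_850, behaviours: ["2", "3"]}
  - {role: hasMorphology, id: M_8504, parent: M_850, behaviours: ["2", "3"]}
  - {role: hasMorphology, id: M_8140, behaviours: ["2", "3"]}
  # mesotheliomas (M_905-)
  - {role: hasMorphology, id: M_905}
  - {role: hasMorphology, id: M_9050, parent: M_905, behaviours: ["3"]}
  - {role: hasMorphology, id: M_9051, parent: M_905, behaviours: ["3"]}
  - {role: hasMorphology, id: M_9052, parent: M_905, behaviours: ["3"]}
  - {role: hasMorphology, id: M_9053, parent: M_905, behaviours: ["3"]}
  - {role: hasMorphology, id: M_9054, parent: M_905, behaviours: ["3"]}
  - {role: hasMorphology, id: M_9055, parent: M_905, behaviours: ["3"]}

  # --- ICD-O behaviour digits (0 benign, 1 uncertain, 2 in situ,
  #     3 malignant, 6 metastatic, 9 unknown)
  - {role: hasBehaviour, id: BehaviourCode0}
  - {role: hasBehaviour, id: BehaviourCode1}
  - {role: hasBehaviour, id: BehaviourCode2}
  - {role: hasBehaviour, id: BehaviourCode3}
  - {role: hasBehaviour, id: BehaviourCode6}
  - {role: hasBehaviour, id: BehaviourCode9}

  # --- histologic grade digits
  - {role: hasGrade, id: GradeCode1}
  - {role: hasGrade, id: GradeCode2}
  - {role: hasGrade, id: GradeCode3}
  - {role: hasGrade, id: GradeCode4}
  - {role: hasGrade, id: GradeCode9}
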