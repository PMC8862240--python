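# Morphology-category groupings (ICD-O-3 first revision, Table 25 style).
# Each category is declared as an equivalence with the union of its member
# codes; the compiler remodels every union of n members into n one-way GCI
# rules (the reverse inclusion is dropped) and places the members under the
# category in the morphology hierarchy, so an existential over a category
# matches any descendant code.
module:
  id: morph-grouping
  imports: [icdo-generic]

category:
  - {id: Carcinoma, members: [M_805]}
  - {id: Adenocarcinoma, members: [M_850, M_8140], parent: Carcinoma}
  - {id: BasalCellCarcinoma, members: [M_809], parent: Carcinoma}
  # mesothelioma union over the six 4-digit codes M_9050..M_9055
  - id: Mesothelioma
    members: [M_9050, M_9051, M_9052, M_9053, M_9054, M_9055]
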