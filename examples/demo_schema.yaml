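categories:
- name: NamedThing
- name: BiologicalEntity
  parents:
  - NamedThing
- name: ChemicalEntity
  parents:
  - NamedThing
- name: Drug
  parents:
  - ChemicalEntity
- name: SmallMolecule
  parents:
  - ChemicalEntity
- name: Gene
  parents:
  - BiologicalEntity
- name: Protein
  parents:
  - BiologicalEntity
- name: Disease
  parents:
  - BiologicalEntity
- name: PhenotypicFeature
  parents:
  - BiologicalEntity
- name: Pathway
  parents:
  - BiologicalEntity
predicates:
- name: related_to
  symmetric: true
- name: interacts_with
  parents:
  - related_to
  symmetric: true
- name: physically_interacts_with
  parents:
  - interacts_with
  symmetric: true
- name: associated_with
  parents:
  - related_to
  symmetric: true
- name: affects
  parents:
  - related_to
- name: regulates
  parents:
  - affects
  canonical: true
  inverse: regulated_by
- name: regulated_by
  parents:
  - related_to
  inverse: regulates
- name: treats
  parents:
  - affects
  canonical: true
  inverse: treated_by
- name: treated_by
  parents:
  - related_to
  inverse: treats
- name: causes
  parents:
  - affects
- name: participates_in
  parents:
  - related_to
- name: subclass_of
  parents:
  - related_to
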