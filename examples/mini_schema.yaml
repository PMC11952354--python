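categories:
- name: NamedThing
- name: ChemicalEntity
  parents:
  - NamedThing
- name: Drug
  parents:
  - ChemicalEntity
- name: Gene
  parents:
  - NamedThing
- name: Disease
  parents:
  - NamedThing
predicates:
- name: related_to
  symmetric: true
- name: interacts_with
  parents:
  - related_to
  symmetric: true
- name: affects
  parents:
  - related_to
- name: treats
  parents:
  - affects
  canonical: true
  inverse: treated_by
- name: treated_by
  parents:
  - related_to
  inverse: treats
- name: subclass_of
  parents:
  - related_to
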