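# Compact hierarchical biomedical vocabulary used as the engine's type system.
# Modeled on the upper levels of the Biolink data model: single-inheritance
# trees of entity concepts and predicates. Entries without a parent attach to
# the roots (named_thing / related_to).
concepts:
  - name: biological_entity
  - name: gene
    parent: biological_entity
  - name: protein
    parent: biological_entity
  - name: disease_or_phenotypic_feature
    parent: biological_entity
  - name: disease
    parent: disease_or_phenotypic_feature
  - name: phenotypic_feature
    parent: disease_or_phenotypic_feature
  - name: chemical_substance
  - name: drug
    parent: chemical_substance
  - name: metabolite
    parent: chemical_substance
  - name: population_of_individual_organisms
  - name: anatomical_entity
  - name: cell
    parent: anatomical_entity
  - name: biological_process
  - name: pathway
    parent: biological_process
  - name: environmental_feature
predicates:
  - name: association
  - name: associated_with
    parent: association
  - name: gene_associated_with_condition
    parent: associated_with
  - name: chemical_affects_gene
    parent: association
  - name: interacts_with
  - name: treats
  - name: causes
  - name: has_phenotype
  - name: part_of
  - name: participates_in
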