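# Diseases differentially diagnosed by sex, with their associated genes and
# the chemical substances interacting with those genes.
select population_of_individual_organisms->disease->gene->chemical_substance
  from "/schema"
 where icees.feature = "sex"
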