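# Merge order: ontologies and genes first, proteins and events next,
# chemicals and their dependents after, cross-cutting edges last.
steps:
  - {source: hetionet, routine: renames}
  - {source: mondo, routine: mondo}
  - {source: disease_ontology, routine: disease_ontology}
  - {source: entrez, routine: entrez}
  - {source: omim, routine: omim}
  - {source: pathways, routine: pathways}
  - {source: uniprot, routine: uniprot}
  - {source: go, routine: go}
  - {source: iid, routine: iid}
  - {source: reactome, routine: reactome}
  - {source: clinvar, routine: clinvar}
  - {source: drugbank, routine: drugbank}
  - {source: hpo, routine: hpo}
  - {source: ctd, routine: ctd}
  - {source: ndfrt, routine: ndfrt}
  - {source: reactome, routine: reactome_chemicals}
  - {source: clinvar, routine: clinvar_chemicals}
  - {source: drugbank, routine: drugbank_remainder}
  - {source: sider, routine: sider}
  - {source: aeolus, routine: aeolus}
  - {source: pharmgkb, routine: pharmgkb_entities}
  - {source: dbsnp, routine: dbsnp}
  - {source: pharmgkb, routine: pharmgkb_edges}
  - {source: pharmebinet, routine: equal_allele}
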