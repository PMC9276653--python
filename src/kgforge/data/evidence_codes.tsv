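code	description
EXP	Inferred from Experiment
IDA	Inferred from Direct Assay
IPI	Inferred from Physical Interaction
IMP	Inferred from Mutant Phenotype
IGI	Inferred from Genetic Interaction
IEP	Inferred from Expression Pattern
HTP	Inferred from High Throughput Experiment
HDA	Inferred from High Throughput Direct Assay
HMP	Inferred from High Throughput Mutant Phenotype
HGI	Inferred from High Throughput Genetic Interaction
HEP	Inferred from High Throughput Expression Pattern
IBA	Inferred from Biological aspect of Ancestor
IBD	Inferred from Biological aspect of Descendant
IKR	Inferred from Key Residues
IRD	Inferred from Rapid Divergence
ISS	Inferred from Sequence or structural Similarity
ISO	Inferred from Sequence Orthology
ISA	Inferred from Sequence Alignment
ISM	Inferred from Sequence Model
IGC	Inferred from Genomic Context
RCA	Inferred from Reviewed Computational Analysis
TAS	Traceable Author Statement
NAS	Non-traceable Author Statement
IC	Inferred by Curator
ND	No biological Data available
IEA	Inferred from Electronic Annotation
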