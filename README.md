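# kgforge

`kgforge` is a toolkit for forging heterogeneous biomedical sources into a
single merged, validated property graph (a *hetnet*): drugs, diseases,
genes, proteins, gene variants, pathways, GO terms, pathway events,
pharmacological classes and adverse drug reactions, connected by typed,
provenance-carrying edges and exported as GraphML. It is aimed at
bioinformaticians who need a reproducible, fully scripted construction
path from raw source files (OBO ontologies, TSV/GAF tables, SDF structure
files, FASTA, GMT gene sets, GraphML subgraphs) to a clean knowledge
graph — for example as a substrate for drug-repurposing or
adverse-drug-reaction (ADR) analyses.

## The method

Construction runs in four stages:

1. **Prepare** — each source is parsed into normalized node/edge tables
   and passed through its quality rules: genes restricted to NCBI
   taxonomy id 9606; chemical–disease and gene–disease associations
   required to carry direct evidence and literature references;
   drug–outcome signals retained only when the reporting frequency is at
   least 0.1 % *and* the pair appears in at least 100 reports; clinical
   annotations restricted to evidence levels {1, 2, 3} and variant
   annotations to `significance = yes`; protein interactions restricted
   to experimental evidence; pathway providers restricted to a licensing
   whitelist.
2. **Integrate** — prepared tables and subgraphs are loaded into one
   in-memory property graph as disconnected, source-marked subgraphs
   alongside a seed hetnet.
3. **Merge** — an ordered plan of per-source routines resolves incoming
   entities against the merged schema through *mapping cascades* (ordered
   strategies over identifiers, cross-reference tables, normalized names
   and synonyms, and chemical structures) and applies match-or-create
   merging. Every merged edge type obeys the naming grammar

   ```
   <RELATION>_<SRC><rel><DST>        e.g.  TREATS_CHtD
   ```

   — the uppercase relation, the source-label abbreviation, the
   lowercased initials of the relation words, and the target-label
   abbreviation. Compound structures are fingerprinted (Morgan, radius 2,
   2048 bits) and `RESEMBLES_CrC` edges emitted for pairs whose
   Tanimoto/Dice score reaches 0.75:

   Tanimoto(A, B) = |A∩B| / |A∪B|,  Dice(A, B) = 2|A∩B| / (|A|+|B|).

   n-ary relations (protein interactions, treatments, clinical and
   variant annotations) are reified as *edge-nodes*; label hierarchies
   (Chemical ⊃ Compound ⊃ Salt; the Phenotype, Variant and
   ReactionLikeEvent grouping labels) are applied as a closure; and
   `EQUAL_*` / `IS_ALLEL_OF_ViaoV` edges link phenotype-class nodes of
   equal meaning and variants sharing an rs-identifier.
4. **Validate and extract** — a naming-scheme validator (every edge type
   must parse and its abbreviations must match the incident node labels),
   a resource-tag validator (every source named in a `resource` list must
   leave a tag property), and a human-only check run over the result; the
   merged-schema subgraph is extracted, dropping the source subgraphs,
   and written to GraphML together with its index definitions.

Because the real sources are huge and partly licensed, the package ships
a deterministic fixture generator that emulates the full source landscape
at toy scale (19 sources plus a seed hetnet) and records the expected
merged graph constructively, so the whole pipeline can be verified
end-to-end against an independent oracle.

## Worked example

```bash
forge fixtures --seed 42 --out corpus/
forge build --corpus corpus/ --out merged.graphml --report report.json
forge validate --graph merged.graphml
```

prints

```
corpus written to corpus/: 142 expected nodes, 140 expected edges
merged graph: 142 nodes, 140 edges; violations: 0
{"edge_names": 0, "resource_tags": 0, "human_only": 0}
```

The corpus plants, among much else, the classic pharmacogenomics
example: the warfarin-response variants CYP2C9\*2, CYP2C9\*3 and
VKORC1 −1639G>A. The ADR plausibility query — variant ← `HAS_GhV` —
gene — `PRODUCES_GpP` → protein ← `BINDS_CHbP` — chemical — returns one
walk per variant sitting on a gene whose protein the drug binds:

```python
from kgforge.graph import find_paths
from kgforge.fixtures import fig4_topology, variant_to_drug_pattern

store = fig4_topology()   # the three-variant / two-gene / one-drug topology
paths = find_paths(store, variant_to_drug_pattern("DB00682"))
print(len(paths))         # 3 — one walk per variant
```

Running the same pattern on the merged corpus graph
(`find_paths(graphml.read_graphml("merged.graphml"),
variant_to_drug_pattern("DB001"))`) returns 9 walks: the three classic
variants plus the corpus's synthetic variants on the same two genes.
Each walk says: this variant sits on a gene whose protein the drug
binds, so altered protein function can plausibly change the drug's
effect — the graph-level signal for a pharmacogenomic ADR risk.

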