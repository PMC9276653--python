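# Methods

This note documents the model behind `kgforge`, the defaults that matter,
what the synthetic corpus does and does not emulate, and the design
choices made where the design was genuinely open.

## The graph model

The toolkit builds a *labelled property graph*: nodes carry an ordered
set of labels (`Compound`, `Chemical`, ...) and a property map whose
values are scalars or lists; edges are directed and typed. Node identity
is the pair (primary label, `identifier` property); internally every
node has a surrogate id so that replacing a node's properties during
merging never breaks its incident edges — the mechanism behind
"replace-or-remove" updates that preserve degree.

Provenance is carried twice: a `resource` list naming every source that
contributed to an entity, and per-source *tag properties* whose names
begin with the lowercased source name (`ctd_id`, `mondo_id`,
`hetionet_id`). The resource-tag validator enforces the pairing.

### Edge-type grammar

Merged-schema edge types render as `<RELATION>_<SRC><rel><DST>`:
uppercase relation words joined by underscores, the uppercase
source-label abbreviation, the lowercase initials of the relation words,
and the uppercase target-label abbreviation (`PARTICIPATES_IN_GpiPW`).
Because abbreviations are uppercase and initials lowercase, the trailing
segment splits unambiguously into case runs, making the grammar
invertible; `parse_edge_type` returns a structured failure value naming
the mismatched component rather than raising. The bundled catalog
(`data/edge_types.tsv`, 163 types) is the authoritative list of the
merged schema's edge vocabulary; a test asserts every row parses and
regenerates byte-identically.

One deliberate irregularity is preserved: the phenotype–gene association
`ASSOCIATES_PaG` uses `P` although `Phenotype` abbreviates to `PT`
elsewhere (`P` normally means `Protein`). The catalog transcribes the
type as printed, and the edge-name validator accepts `P` for nodes
labelled either `Protein` or `Phenotype` through a documented alias, so
a correctly built graph validates with zero violations.

### Label hierarchy

`Chemical ⊃ Compound ⊃ Salt` plus grouping labels: `Phenotype` over
Disease/Symptom/SideEffect, `Variant` over GeneVariant/Haplotype/
Genotype, and `ReactionLikeEvent` over the five pathway-event labels.
The hierarchy is applied as a transitive closure and is idempotent; a
cycle in a user-supplied hierarchy is rejected at construction.

## Entity resolution

Incoming records are resolved through *mapping cascades*: an ordered
list of strategies, tried until one yields candidates. Strategy kinds:

- **identifier** — exact string comparison of an entity key against a
  node property (optionally after namespace-prefix stripping); list
  properties match element-wise.
- **xref** — bridge through a generic two-column cross-reference table.
  Licensed mapping systems (UMLS, RxNorm, MedDRA bridges) are
  represented *only* as such tables; no service calls.
- **name** — normalized comparison (lowercase, trimmed, internal
  whitespace collapsed, a fixed punctuation set stripped) of names and
  synonym lists on both sides.
- **structure** — fingerprint similarity against chemical nodes at the
  retention threshold; valid only for chemical targets.

Ambiguous results (≥2 candidates) are never auto-merged: the merge
routines treat them as unmatched, and `mapping_report` surfaces them —
together with unique matches whose normalized names disagree — for
manual review. This is deliberately conservative; silently picking one
candidate would fabricate cross-source links.

The bundled cascades (`configs/cascades.yaml`) encode, per entity class,
the strategy orders used by the merge routines (for chemicals:
CAS → UMLS → RxNorm → UNII → InChIKey → MeSH → name; for diseases:
OMIM → ORPHA → DO → UMLS → name; and so on). Where two identifier
systems would disagree, cascade order decides.

## Quality rules

All per-source filters are pure, deterministic, order-preserving row
predicates; each is idempotent. Defaults:

| rule | default | unit |
|---|---|---|
| gene taxon | 9606 | NCBI taxonomy id (human) |
| drug–outcome frequency | ≥ 0.1 | percent of reports, inclusive |
| drug–outcome count | ≥ 100 | reports, inclusive |
| clinical annotation level | {1, 2, 3} | evidence level |
| variant annotation | "yes" | significance flag |
| interaction evidence | contains "exp" | evidence-type token |
| references | non-empty | PubMed id list |
| pathway providers | WikiPathways, Reactome, Panther, NetPath, PathBank | whitelist |

The adverse-event thresholds are inclusive ("at least"), which the
acceptance suite probes behaviorally at the exact boundary.

## Chemical similarity

Fingerprints are hashed circular-neighborhood (Morgan) bitvectors
computed with RDKit, radius 2, 2048 bits — standard practice for
drug-likeness similarity. Similarity uses Tanimoto |A∩B|/|A∪B| and Dice
2|A∩B|/(|A|+|B|); a pair of all-zero fingerprints scores 0 under both
measures so structure-less entries never produce edges. A `RESEMBLES_CrC`
edge is emitted for an unordered pair iff the **maximum** score over the
configured measure set reaches the threshold (default 0.75); the
per-measure scores are stored on the edge. The max rule is this
package's documented choice for combining multiple metrics; since
Dice ≥ Tanimoto algebraically, enabling both measures makes retention
more permissive than Tanimoto alone.

## Merge plan

Merging runs in a fixed order (`configs/merge_plan.yaml`): edge renames
exposing the Chemical label; disease ontology replacement and
enrichment; gene replacement; phenotype–gene associations; pathway
rebuild; proteins, interactions and gene–disease links; GO term rebuild
and annotations; more interactions; pathway events; variants; drugs,
salts, products and structure similarity; symptoms; chemical-centric
sources; pharmacological classes; treatment and event chemistry;
variant–drug associations; drug targets and ATC classes; side-effect
rebuild; adverse-event signals; pharmacogenomic entities; rs-identifier
reconciliation and pruning (removals cascade to the incident
combination-ADR edges); annotation edge-nodes; and finally EQUAL and
allele edges.

Every routine is written match-or-create, so re-running the full plan on
its own output changes nothing — a property the tests check across
corpus seeds. Property conflicts on update keep the existing value and
store the incoming one under `<name>_<source>`.

EQUAL edges link phenotype-class nodes sharing a UMLS identifier or a
normalized name. The published vocabulary has four cross-label types
(`EQUAL_DeSE`, `EQUAL_DeS`, `EQUAL_PTeSE`, `EQUAL_SeSE`); because every
Symptom/SideEffect also carries the Phenotype grouping label, this
package prefers the *specific* label pair and uses the Phenotype type
only as the fallback for pure-Phenotype nodes — otherwise `EQUAL_SeSE`
could never occur. One edge is created per unordered pair; for allele
edges (`IS_ALLEL_OF_ViaoV`, all pairs within an rs-identifier group) the
lexicographically smaller identifier is the source.

## The synthetic corpus

`kgforge.corpus.generate_corpus` emits a miniature, fully synthetic
source landscape: a seed hetnet (GraphML), disease/phenotype/GO
ontologies (OBO), a mixed-taxa gene table, GAF annotations, two GMT
gene-set files, protein and interaction tables, a pathway-event graph,
two variant releases, drug/salt/product/target/ATC tables with SDF
structures, symptom annotations, chemical–gene–disease tables,
class/relation tables, side-effect and adverse-event tables, an
annotation graph, an rs-identifier stub list, and a MedDRA→UMLS
cross-reference table. The manifest scales bulk entities (extra genes,
diseases, compounds, outcome pairs, variants) and their overlap
fractions; the same seed always yields a byte-identical corpus.

Ground truth — the expected merged node set (identifier + label set),
edge set (type + endpoint identifiers) and filter survivor counts — is
computed **constructively while planting**, never by running the
pipeline, so end-to-end agreement is a genuine two-route check. Compound
structures are drawn from a frozen molecule pool whose pairwise
similarity structure is known (one deliberate above-threshold pair, the
two coumarin anticoagulants; all other distinct members score below
0.75 under both measures), letting the generator predict the
`RESEMBLES_CrC` edge set without fingerprinting.

What the corpus does **not** emulate: realistic biology or chemistry,
source-scale data volumes, messy real-world identifier noise (beyond the
planted ambiguities), licensed-source schemas, or release-to-release
drift. Passing the end-to-end check therefore demonstrates that the
construction machinery implements its rules exactly at small scale, not
that real-source ingestion would be artifact-free.

Default problem sizes: the corpus merges to roughly 140 nodes and 140
edges over 26 labels and ~70 edge types; oracle-equivalence checks run
at 500 nodes (resolution), 200 compounds (similarity) and 100 nodes
(path search); round-trip and conservation properties run across 100
random seeds. These sizes make the full suite complete in seconds while
still exercising every routine and rule.

## Numerical and procedural choices

- **Path search** is bounded-depth DFS over the alternating
  node/edge-constraint pattern, expanding neighbors in lexicographic
  order of node identifiers, so results are deterministic and returned
  walks may revisit nodes (they are walks, not simple paths).
- **TSV conventions**: UTF-8, tab-separated, header row, `|` as the list
  delimiter; cells containing the delimiter are split on load.
- **GraphML dialect**: node labels in a `labels` attribute as a
  ":"-prefixed concatenation, edge type in `label`; list properties are
  declared with `attr.list` on the key and serialized as JSON arrays.
  Scalar files remain readable by networkx.
- **GAF qualifiers → relations**: the annotation edge vocabulary uses
  the qualifier-derived relations ENABLES, INVOLVED_IN, LOCATED_IN,
  PART_OF, generated through the grammar for both gene and protein
  endpoints; the full production vocabulary is larger, and the mapping
  is this package's choice.
- **Adverse-event outcomes** marked as disease outcomes are only matched
  against existing diseases (for `MIGHT_INDUCES_CHmiD`); side-effect
  outcomes are matched or created as SideEffect nodes. Creating disease
  nodes from reporting-system outcomes was judged too noisy.
- **Obsolete ontology terms** are flagged in node tables but contribute
  no nodes or edges to the merged graph.
- **alt_id tags** in OBO files are folded into the xref list column.

## Known limitations

- The resolver's structure strategy scores against every chemical node
  (no prefiltering); fine at corpus scale, quadratic in general.
- Edge-node matching is by identifier only; two sources reifying the
  same underlying interaction under different identifiers yield two
  Interaction nodes.
- The validators check schema consistency, not biological correctness.
- Cypher generation, database-engine loading and transactional
  persistence are out of scope; GraphML is the interchange boundary.
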