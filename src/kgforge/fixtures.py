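"""Deterministic miniature fixtures: topologies, fingerprint panels, manifest.

The corpus generator itself lives in :mod:`kgforge.corpus`; this module
holds the shared building blocks: the frozen molecule pool with known
pairwise similarity structure, the manifest describing corpus sizes and
overlaps, the pharmacogenomic path-query topology (three gene variants
connected to one drug through two genes and their proteins), and the
fingerprint panel generator used to probe similarity thresholds.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .chem import Fingerprint
from .errors import ContractError
from .graph import EdgeConstraint, GraphStore, NodeConstraint, PathPattern

#: Frozen SMILES pool used by the corpus.  Distinct members score below the
#: similarity retention threshold under both Tanimoto and Dice on Morgan
#: radius-2/2048 fingerprints, with one deliberate exception: the two
#: coumarin anticoagulants (warfarin, acenocoumarol) score above it.
SMILES_POOL: dict[str, str] = {
    "warfarin": "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "acenocoumarol": "CC(=O)CC(c1ccc(cc1)[N+](=O)[O-])c1c(O)c2ccccc2oc1=O",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "ethanol": "CCO",
    "salicylic acid": "O=C(O)c1ccccc1O",
    "theophylline": "Cn1c(=O)c2[nH]cnc2n(C)c1=O",
    "hexane": "CCCCCC",
}

#: Unordered pool-member pairs that score at or above the 0.75 retention
#: threshold despite being distinct molecules.
SIMILAR_POOL_PAIRS: frozenset[frozenset[str]] = frozenset(
    {frozenset({"warfarin", "acenocoumarol"})}
)


def pool_pair_similar(key_a: str, key_b: str) -> bool:
    """Whether two pool assignments imply a retained similarity edge."""
    return key_a == key_b or frozenset({key_a, key_b}) in SIMILAR_POOL_PAIRS


@dataclass(frozen=True)
class FixtureManifest:
    """Sizes, overlap fractions and seed describing one generated corpus.

    The hand-planted core of the corpus is fixed; the manifest scales the
    bulk entities layered on top of it.  The same seed always yields a
    byte-identical corpus and ground truth.
    """

    seed: int = 42
    n_extra_genes: int = 20
    extra_gene_overlap: float = 0.3
    n_extra_diseases: int = 15
    extra_disease_overlap: float = 0.4
    n_extra_compounds: int = 10
    extra_compound_overlap: float = 0.5
    n_extra_outcome_pairs: int = 20
    n_extra_variants: int = 15
    extra_variant_missing_rs: float = 0.2

    def __post_init__(self):
        for name in (
            "n_extra_genes", "n_extra_diseases", "n_extra_compounds",
            "n_extra_outcome_pairs", "n_extra_variants",
        ):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be >= 0")
        for name in (
            "extra_gene_overlap", "extra_disease_overlap",
            "extra_compound_overlap", "extra_variant_missing_rs",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ContractError(f"{name} must be in [0, 1]")


# ------------------------------------------------------- path-query fixture


def fig4_topology() -> GraphStore:
    """Warfarin-style pharmacogenomics topology: three gene variants on two
    genes, each gene producing a protein bound by one drug."""
    store = GraphStore()
    chem = store.add_node(
        ["Compound", "Chemical"], {"identifier": "DB00682", "name": "warfarin"}
    )
    gene_a = store.add_node(["Gene"], {"identifier": "1559", "name": "CYP2C9"})
    gene_b = store.add_node(["Gene"], {"identifier": "79001", "name": "VKORC1"})
    prot_a = store.add_node(["Protein"], {"identifier": "P11712", "name": "CYP2C9"})
    prot_b = store.add_node(["Protein"], {"identifier": "Q9BQB6", "name": "VKORC1"})
    variants = [
        ("VCV000634", "CYP2C9*2 c.430C>T (p.Arg144Cys)", gene_a),
        ("VCV000636", "CYP2C9*3 c.1075A>C (p.Ile359Leu)", gene_a),
        ("VCV000639", "VKORC1 c.-1639G>A", gene_b),
    ]
    for identifier, name, gene in variants:
        vid = store.add_node(
            ["GeneVariant", "Variant"], {"identifier": identifier, "name": name}
        )
        store.add_edge("HAS_GhV", gene, vid)
    store.add_edge("PRODUCES_GpP", gene_a, prot_a)
    store.add_edge("PRODUCES_GpP", gene_b, prot_b)
    store.add_edge("BINDS_CHbP", chem, prot_a)
    store.add_edge("BINDS_CHbP", chem, prot_b)
    return store


def variant_to_drug_pattern(chemical_identifier: str | None = None) -> PathPattern:
    """Variant -> gene -> protein -> chemical walk pattern (the ADR
    plausibility query): traverses HAS_GhV backwards, PRODUCES_GpP
    forwards, and any protein-chemical edge backwards."""
    chem_constraint = (
        NodeConstraint.of("Chemical", identifier=chemical_identifier)
        if chemical_identifier
        else NodeConstraint.of("Chemical")
    )
    return PathPattern(
        (
            NodeConstraint.of("Variant"),
            EdgeConstraint("HAS_GhV", "in"),
            NodeConstraint.of("Gene"),
            EdgeConstraint("PRODUCES_GpP", "out"),
            NodeConstraint.of("Protein"),
            EdgeConstraint(None, "in"),
            chem_constraint,
        )
    )


# ------------------------------------------------------- fingerprint panel


def generate_fingerprint_panel(
    seed: int,
    targets: list[float],
    length: int = 2048,
) -> list[tuple[Fingerprint, Fingerprint, float]]:
    """Bitvector pairs whose Tanimoto scores land within 0.01 of each target.

    Construction is exact set arithmetic: for target t the pair shares
    k = 2*round(100*t) bits out of a union of 200, giving Tanimoto k/200
    (identical vectors for t = 1, disjoint for t = 0).  Bit positions are
    shuffled by the seed; scores do not depend on the shuffle.
    """
    rng = random.Random(seed)
    panel: list[tuple[Fingerprint, Fingerprint, float]] = []
    for target in targets:
        if not 0.0 <= target <= 1.0:
            raise ContractError(f"target {target} outside [0, 1]")
        k = 2 * round(100 * target)
        union = 200 if k < 200 else k
        if union > length:
            raise ContractError("bit length too small for requested target")
        size = (union + k) // 2  # |A| = |B|
        positions = rng.sample(range(length), union)
        shared = positions[:k]
        only_a = positions[k:size]
        only_b = positions[size:union]
        fp_a = Fingerprint(frozenset(shared + only_a), length, f"panel-{length}")
        fp_b = Fingerprint(frozenset(shared + only_b), length, f"panel-{length}")
        achieved = k / union if union else 0.0
        if abs(achieved - target) > 0.01:
            raise ContractError(
                f"target {target} unreachable: achieved {achieved}"
            )
        panel.append((fp_a, fp_b, achieved))
    return panel
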