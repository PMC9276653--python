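"""Compound fingerprints and Tanimoto/Dice structure similarity.

Fingerprints are hashed circular-neighborhood (Morgan) bitvectors
computed with RDKit; radius 2 and 2048 bits by default, standard practice
for drug-likeness similarity work.  Similarity edges of type
``RESEMBLES_CrC`` are emitted for every unordered compound pair whose
maximum score over the configured measures reaches the retention
threshold (0.75 by default); all scores are stored as edge properties.

Conventions: a pair of all-zero fingerprints scores 0 (not 1) under both
measures, so structure-less entries never produce spurious edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import ContractError, StructureError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048
#: Retention threshold for similarity edges.
DEFAULT_SIMILARITY_THRESHOLD = 0.75
RESEMBLES_TYPE = "RESEMBLES_CrC"


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bitvector identified by its generator scheme."""

    bits: frozenset[int]
    length: int
    generator_id: str

    def __post_init__(self):
        if self.bits and max(self.bits) >= self.length:
            raise ContractError("fingerprint bit index exceeds length")

    @property
    def popcount(self) -> int:
        return len(self.bits)


def _mol_from_structure(structure: str):
    text = str(structure).strip()
    if not text:
        return None
    if "\n" in text or text.startswith("M  END"):
        return Chem.MolFromMolBlock(text)
    return Chem.MolFromSmiles(text)


def fingerprint(
    structure: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    """Morgan fingerprint of a SMILES string or V2000 structure block.

    Deterministic for identical input and invariant under atom renumbering
    (RDKit canonicalizes the molecular graph before hashing).  Raises
    :class:`StructureError` for unparseable structures.
    """
    mol = _mol_from_structure(structure)
    if mol is None:
        raise StructureError(f"unparseable structure {structure!r:.60}")
    generator = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = generator.GetFingerprint(mol)
    return Fingerprint(
        bits=frozenset(bv.GetOnBits()),
        length=n_bits,
        generator_id=f"morgan-r{radius}-{n_bits}",
    )


def _check_compatible(a: Fingerprint, b: Fingerprint) -> None:
    if a.length != b.length or a.generator_id != b.generator_id:
        raise ContractError(
            f"incompatible fingerprints: {a.generator_id}/{a.length} vs "
            f"{b.generator_id}/{b.length}"
        )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B|; 0 when both fingerprints are empty."""
    _check_compatible(a, b)
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def dice(a: Fingerprint, b: Fingerprint) -> float:
    """2|A∩B| / (|A|+|B|); 0 when both fingerprints are empty."""
    _check_compatible(a, b)
    total = len(a.bits) + len(b.bits)
    if total == 0:
        return 0.0
    return 2 * len(a.bits & b.bits) / total


_MEASURES = {"tanimoto": tanimoto, "dice": dice}


@dataclass(frozen=True)
class SimilarityScore:
    pair: tuple[str, str]
    measure: str
    generator_id: str
    value: float


def resemblance_edges(
    compounds: list[tuple[str, Fingerprint | str]],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    measures: tuple[str, ...] = ("tanimoto", "dice"),
) -> list[dict]:
    """Similarity edges over all unordered compound pairs.

    ``compounds`` holds (identifier, fingerprint-or-structure) tuples;
    structures that fail to parse are skipped with a log entry.  A pair is
    retained iff the maximum score over the configured measures is at
    least ``threshold``.  Each emitted edge dict carries both endpoint
    identifiers (lexicographically ordered) and every measure's score.
    """
    for measure in measures:
        if measure not in _MEASURES:
            raise ContractError(f"unknown similarity measure {measure!r}")
    prints: list[tuple[str, Fingerprint]] = []
    for ident, structure in compounds:
        if isinstance(structure, Fingerprint):
            prints.append((ident, structure))
            continue
        try:
            prints.append((ident, fingerprint(structure)))
        except StructureError as exc:
            logger.warning("skipping compound %r: %s", ident, exc)
    prints.sort(key=lambda p: p[0])
    edges: list[dict] = []
    for i in range(len(prints)):
        ident_a, fp_a = prints[i]
        for j in range(i + 1, len(prints)):
            ident_b, fp_b = prints[j]
            scores = {m: _MEASURES[m](fp_a, fp_b) for m in measures}
            if max(scores.values()) >= threshold:
                edges.append(
                    {
                        "source": min(ident_a, ident_b),
                        "target": max(ident_a, ident_b),
                        **{f"{m}_score": round(s, 6) for m, s in scores.items()},
                    }
                )
    return edges
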