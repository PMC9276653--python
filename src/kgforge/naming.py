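"""Edge-type naming grammar for the merged hetnet schema.

Merged-schema edge types are rendered as ``<RELATION>_<SRC><rel><DST>``:
the uppercase, underscore-separated relation name, an underscore, the
uppercase abbreviation of the source node label, the lowercase initials of
the relation words, and the uppercase abbreviation of the target node
label.  ``TREATS`` between a ``Chemical`` and a ``Disease`` therefore
renders as ``TREATS_CHtD``.

The grammar is invertible: because label abbreviations are uppercase and
the relation initials are lowercase, the trailing segment of a rendered
type splits unambiguously into uppercase/lowercase/uppercase runs.
:func:`parse_edge_type` exploits this and returns a structured failure
value (never raises) so validators can report what mismatched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import RegistryError

#: Label -> uppercase abbreviation for every label of the merged schema.
DEFAULT_ABBREVIATIONS: dict[str, str] = {
    "Chemical": "CH",
    "Compound": "C",
    "Salt": "SA",
    "Product": "PR",
    "Disease": "D",
    "Gene": "G",
    "Protein": "P",
    "Pathway": "PW",
    "SideEffect": "SE",
    "Symptom": "S",
    "Phenotype": "PT",
    "PharmacologicalClass": "PC",
    "Variant": "V",
    "GeneVariant": "GV",
    "Haplotype": "H",
    "Genotype": "GT",
    "BiologicalProcess": "BP",
    "CellularComponent": "CC",
    "MolecularFunction": "MF",
    "Interaction": "I",
    "ReactionLikeEvent": "RLE",
    "Treatment": "T",
    "ClinicalAnnotation": "CA",
    "VariantAnnotation": "VA",
}

_RELATION_RE = re.compile(r"^[A-Z0-9]+(_[A-Z0-9]+)*$")
_TAIL_RE = re.compile(r"^([A-Z]+)([a-z]+)([A-Z]+)$")


class AbbreviationRegistry:
    """Bidirectional label <-> abbreviation map under the naming grammar.

    Abbreviations must be uppercase and unique; the default registry covers
    the full merged schema.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        mapping = dict(DEFAULT_ABBREVIATIONS if mapping is None else mapping)
        seen: dict[str, str] = {}
        for label, abbrev in mapping.items():
            if not abbrev.isupper():
                raise RegistryError(f"abbreviation {abbrev!r} for {label!r} is not uppercase")
            if abbrev in seen:
                raise RegistryError(
                    f"abbreviation {abbrev!r} assigned to both {seen[abbrev]!r} and {label!r}"
                )
            seen[abbrev] = label
        self._label_to_abbrev = mapping
        self._abbrev_to_label = seen

    def abbreviate(self, label: str) -> str:
        try:
            return self._label_to_abbrev[label]
        except KeyError:
            raise RegistryError(f"label {label!r} has no registered abbreviation") from None

    def label_for(self, abbrev: str) -> str:
        try:
            return self._abbrev_to_label[abbrev]
        except KeyError:
            raise RegistryError(f"abbreviation {abbrev!r} is not registered") from None

    def has_label(self, label: str) -> bool:
        return label in self._label_to_abbrev

    def has_abbrev(self, abbrev: str) -> bool:
        return abbrev in self._abbrev_to_label

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._label_to_abbrev)


#: Registry instance used wherever none is passed explicitly.
DEFAULT_REGISTRY = AbbreviationRegistry()


def relation_abbrev(relation: str) -> str:
    """Lowercase initials of the underscore-separated relation words.

    >>> relation_abbrev("MIGHT_SUBCELLULAR_LOCATES")
    'msl'
    """
    return "".join(word[0] for word in relation.split("_") if word).lower()


@dataclass(frozen=True)
class EdgeTypeName:
    """Parsed merged-schema edge type."""

    relation: str
    src_abbrev: str
    rel_abbrev: str
    dst_abbrev: str

    def render(self) -> str:
        return f"{self.relation}_{self.src_abbrev}{self.rel_abbrev}{self.dst_abbrev}"

    def __bool__(self) -> bool:  # parse results are truth-testable
        return True


@dataclass(frozen=True)
class ParseFailure:
    """Structured, falsy failure value returned by :func:`parse_edge_type`."""

    type_name: str
    reason: str

    def __bool__(self) -> bool:
        return False


def generate_edge_type(
    relation: str,
    src_label: str,
    dst_label: str,
    registry: AbbreviationRegistry = DEFAULT_REGISTRY,
) -> str:
    """Render the grammar-conformant edge type for ``relation`` between two labels.

    >>> generate_edge_type("TREATS", "Chemical", "Disease")
    'TREATS_CHtD'
    """
    if not _RELATION_RE.match(relation):
        raise RegistryError(f"relation {relation!r} must be uppercase underscore-separated words")
    return EdgeTypeName(
        relation=relation,
        src_abbrev=registry.abbreviate(src_label),
        rel_abbrev=relation_abbrev(relation),
        dst_abbrev=registry.abbreviate(dst_label),
    ).render()


def load_edge_type_catalog():
    """The bundled catalog of merged-schema edge types.

    Returns a pandas DataFrame with columns ``type_name``, ``relation``,
    ``source_label`` and ``target_label``; every row regenerates its
    ``type_name`` through :func:`generate_edge_type`.
    """
    from importlib import resources

    import pandas as pd

    path = resources.files("kgforge").joinpath("data/edge_types.tsv")
    return pd.read_csv(str(path), sep="\t", dtype=str)


def parse_edge_type(
    type_name: str,
    registry: AbbreviationRegistry = DEFAULT_REGISTRY,
) -> EdgeTypeName | ParseFailure:
    """Inverse of :func:`generate_edge_type` on its image.

    Returns an :class:`EdgeTypeName` on success and a falsy
    :class:`ParseFailure` explaining which component mismatched otherwise.
    """
    if "_" not in type_name:
        return ParseFailure(type_name, "no underscore separating relation and abbreviations")
    relation, tail = type_name.rsplit("_", 1)
    if not _RELATION_RE.match(relation):
        return ParseFailure(type_name, f"relation part {relation!r} is not uppercase words")
    match = _TAIL_RE.match(tail)
    if not match:
        return ParseFailure(
            type_name, f"trailing segment {tail!r} does not split into SRC/rel/DST runs"
        )
    src_abbrev, rel, dst_abbrev = match.groups()
    if not registry.has_abbrev(src_abbrev):
        return ParseFailure(type_name, f"unknown source abbreviation {src_abbrev!r}")
    if not registry.has_abbrev(dst_abbrev):
        return ParseFailure(type_name, f"unknown target abbreviation {dst_abbrev!r}")
    expected = relation_abbrev(relation)
    if rel != expected:
        return ParseFailure(
            type_name,
            f"relation abbreviation {rel!r} does not match initials {expected!r} of {relation!r}",
        )
    return EdgeTypeName(relation, src_abbrev, rel, dst_abbrev)
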