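"""Core domain objects shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; conversion
to 1-based inclusive happens only at the RepeatMasker/GFF3 boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

#: Canonical TE class vocabulary.
TE_CLASSES = ("LTR", "LINE", "TIR", "Helitron", "Unknown")

#: Superfamilies that imply a class regardless of the raw class string.
_SUPERFAMILY_CLASS = {
    "copia": "LTR",
    "gypsy": "LTR",
    "cacta": "TIR",
    "mutator": "TIR",
    "hat": "TIR",
    "pif-harbinger": "TIR",
    "harbinger": "TIR",
    "tc1-mariner": "TIR",
    "mariner": "TIR",
    "helitron": "Helitron",
}


def classify_label(raw: str) -> tuple[str, str]:
    """Split a RepeatMasker-style ``class/superfamily`` label.

    Returns ``(te_class, superfamily)`` in the canonical vocabulary.
    DIRS elements are folded into LTR and Penelope-like (PLE) elements into
    LINE, matching the convention used for class-level divergence landscapes.
    Unrecognised labels map to class ``Unknown`` rather than raising.
    """
    raw = raw.strip()
    if "/" in raw:
        cls, sup = raw.split("/", 1)
    else:
        cls, sup = raw, ""
    cls_l, sup_l = cls.strip().lower(), sup.strip().lower()

    if sup_l in _SUPERFAMILY_CLASS:
        return _SUPERFAMILY_CLASS[sup_l], sup_l
    if cls_l in ("ltr", "dirs"):
        return "LTR", sup_l or ("dirs" if cls_l == "dirs" else "")
    if cls_l in ("line", "ple", "penelope", "sine"):
        # SINEs are rare in these libraries; treat as LINE-like retroelements.
        return "LINE", sup_l or (cls_l if cls_l != "line" else "")
    if cls_l in ("dna", "tir", "mite"):
        return "TIR", sup_l
    if cls_l == "rc" or "helitron" in cls_l:
        return "Helitron", "helitron"
    return "Unknown", sup_l


@dataclass
class KimuraEstimate:
    """Kimura 2-parameter divergence between two aligned sequences.

    ``P`` and ``Q`` are the transition and transversion proportions over the
    ``aligned_sites`` ungapped, unambiguous alignment columns.  ``K`` is the
    K2P distance, ``None`` when the estimator saturates
    (``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``).
    """

    P: float
    Q: float
    K: Optional[float]
    aligned_sites: int
    low_confidence: bool = False

    @property
    def defined(self) -> bool:
        return self.K is not None and math.isfinite(self.K)


@dataclass
class TECopy:
    """One annotated genomic TE interval."""

    sequence_id: str
    start: int
    end: int
    strand: str
    consensus_id: str
    te_class: str = "Unknown"
    superfamily: str = ""
    family: Optional[str] = None
    intact: bool = False
    divergence: Optional[KimuraEstimate] = None
    copy_id: Optional[str] = None  # in-memory link to simulator truth rows

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"degenerate interval {self.sequence_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """All TE copies annotated on one genome assembly."""

    genome_id: str
    copies: list[TECopy] = field(default_factory=list)
    sequence_ids: set[str] = field(default_factory=set)
    subgenome_map: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        for c in self.copies:
            self.sequence_ids.add(c.sequence_id)

    def add(self, copy: TECopy) -> None:
        self.copies.append(copy)
        self.sequence_ids.add(copy.sequence_id)

    def subgenome_of(self, sequence_id: str) -> str:
        if self.subgenome_map is None:
            raise ValueError(f"{self.genome_id}: no subgenome map attached")
        try:
            return self.subgenome_map[sequence_id]
        except KeyError:
            raise ValueError(
                f"{self.genome_id}: sequence {sequence_id!r} not in subgenome map"
            ) from None

    def __len__(self) -> int:
        return len(self.copies)

    def __iter__(self):
        return iter(self.copies)


@dataclass
class TEConsensus:
    """One entry of a (pan-genome) TE consensus library."""

    id: str
    sequence: str
    te_class: str = "Unknown"
    superfamily: str = ""
    family: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)


def consensus_index(library: Iterable[TEConsensus]) -> dict[str, TEConsensus]:
    """Index a library by id, rejecting duplicates."""
    out: dict[str, TEConsensus] = {}
    dups = []
    for c in library:
        if c.id in out:
            dups.append(c.id)
        out[c.id] = c
    if dups:
        raise ValueError(f"duplicate consensus ids: {sorted(set(dups))}")
    return out
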