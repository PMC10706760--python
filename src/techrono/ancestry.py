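"""Shared-TE ancestry inference.

An allopolyploid inherits the TE complement of each of its diploid
progenitors, so the pan-library consensus sequences that have intact copies
in a subgenome should overlap most strongly with the true donor genome.
Sharing is assessed at the consensus level by default: a consensus id
counts once per genome no matter how many intact copies carry it
(copy-level counting is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import GenomeAnnotation

DEFAULT_CLASSES = frozenset({"LTR", "TIR", "Helitron"})


def intact_consensus_set(
    annotation: GenomeAnnotation,
    classes: Iterable[str] = DEFAULT_CLASSES,
) -> set[str]:
    """Consensus ids with at least one intact copy in the given classes."""
    classes = set(classes)
    return {c.consensus_id for c in annotation
            if c.intact and c.te_class in classes}


def venn_counts(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exact region counts for a 2-4 way Venn diagram.

    Keys are frozensets of set names; the value for key S is the number of
    elements belonging to exactly the sets in S.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError(f"venn_counts supports 2-4 sets, got {len(names)}")
    regions: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            regions[frozenset(combo)] = 0
    for el in set().union(*sets.values()):
        membership = frozenset(n for n in names if el in sets[n])
        regions[membership] += 1
    return regions


@dataclass
class SharedCopyMatrix:
    """Subgenome x ancestor matrix of shared intact-TE consensus counts."""

    table: pd.DataFrame            # rows: subgenomes, cols: ancestors
    row_totals: pd.Series
    level: str = "consensus"

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "total", self.row_totals)
        out.index.name = "subgenome"
        return out

    def donor_calls(self) -> pd.Series:
        """Most-shared ancestor per subgenome (ties broken by column order)."""
        return self.table.idxmax(axis=1)


def split_by_subgenome(annotation: GenomeAnnotation) -> dict[str, GenomeAnnotation]:
    """Split a polyploid annotation into per-subgenome annotations.

    Every copy's sequence_id must resolve through the attached subgenome
    map; unmapped sequences are reported together.
    """
    if annotation.subgenome_map is None:
        raise ValueError(f"{annotation.genome_id}: no subgenome map attached")
    missing = sorted({c.sequence_id for c in annotation
                      if c.sequence_id not in annotation.subgenome_map})
    if missing:
        raise ValueError(
            f"{annotation.genome_id}: sequences without subgenome assignment: {missing}")
    out: dict[str, GenomeAnnotation] = {}
    for c in annotation:
        sg = annotation.subgenome_map[c.sequence_id]
        out.setdefault(sg, GenomeAnnotation(genome_id=sg)).add(c)
    return out


def shared_matrix(
    subgenome_annotations: Mapping[str, GenomeAnnotation],
    ancestor_annotations: Mapping[str, GenomeAnnotation],
    classes: Iterable[str] = DEFAULT_CLASSES,
    level: str = "consensus",
) -> SharedCopyMatrix:
    """Count intact-TE sharing between each subgenome and each ancestor.

    level="consensus" (default): cell(s, a) is the number of pan-library
    consensus ids with intact copies in both s and a; the row total is the
    size of s's intact consensus set.  level="copy": cell(s, a) is the
    number of intact copies in s whose consensus id also has an intact copy
    in a.
    """
    if level not in ("consensus", "copy"):
        raise ValueError(f"unknown level {level!r}")
    classes = set(classes)
    anc_sets = {a: intact_consensus_set(ann, classes)
                for a, ann in ancestor_annotations.items()}
    rows, totals = {}, {}
    for s, ann in subgenome_annotations.items():
        s_set = intact_consensus_set(ann, classes)
        if level == "consensus":
            rows[s] = {a: len(s_set & aset) for a, aset in anc_sets.items()}
            totals[s] = len(s_set)
        else:
            intact = [c for c in ann if c.intact and c.te_class in classes]
            rows[s] = {a: sum(c.consensus_id in aset for c in intact)
                       for a, aset in anc_sets.items()}
            totals[s] = len(intact)
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table = table[list(ancestor_annotations)]
    return SharedCopyMatrix(table=table,
                            row_totals=pd.Series(totals).sort_index(),
                            level=level)
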