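"""Readers and writers for the external formats the pipeline touches.

Single source of truth for coordinate and strand conventions: internal
coordinates are 0-based half-open; RepeatMasker ``.out`` and GFF3 use
1-based inclusive and are converted exactly once, here.  RepeatMasker's
``C`` strand maps to ``-``.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GenomeAnnotation, TECopy, TEConsensus, classify_label

logger = logging.getLogger(__name__)

TE_TSV_COLUMNS = [
    "sequence_id", "start", "end", "strand", "consensus_id",
    "te_class", "superfamily", "family", "intact",
]

PathOrStream = Union[str, IO]


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(stream: PathOrStream, genome_id: str = "genome") -> GenomeAnnotation:
    """Parse a RepeatMasker ``.out`` file into a GenomeAnnotation.

    The dialect has 3 header lines followed by whitespace-separated records:
    score, %div, %del, %ins, query, begin, end, (left), strand (+/C),
    repeat name, class/family, repeat begin/end/(left)[, ID].  Coordinates
    are converted from 1-based inclusive to 0-based half-open.
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream)
        close = True
    try:
        ann = GenomeAnnotation(genome_id=genome_id)
        for lineno, line in enumerate(stream, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 14:
                raise ValueError(
                    f"line {lineno}: expected >=14 whitespace-separated "
                    f"columns, got {len(fields)}"
                )
            seq_id = fields[4]
            start1, end1 = int(fields[5]), int(fields[6])
            strand = "-" if fields[8] in ("C", "-") else "+"
            name = fields[9]
            te_class, superfamily = classify_label(fields[10])
            ann.add(TECopy(
                sequence_id=seq_id, start=start1 - 1, end=end1,
                strand=strand, consensus_id=name,
                te_class=te_class, superfamily=superfamily,
            ))
        return ann
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# TE TSV (BED-like dialect with named columns)
# ---------------------------------------------------------------------------

def read_te_tsv(stream: PathOrStream, genome_id: str = "genome") -> GenomeAnnotation:
    """Read the package's TE annotation TSV (0-based half-open).

    Required columns: sequence_id, start, end, strand, consensus_id,
    te_class, superfamily, family, intact.  Extra columns are ignored with
    a warning.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TE TSV missing required columns: {missing}")
    extra = [c for c in df.columns if c not in TE_TSV_COLUMNS]
    if extra:
        logger.warning("ignoring extra TE TSV columns: %s", extra)
    ann = GenomeAnnotation(genome_id=genome_id)
    for row in df.itertuples(index=False):
        ann.add(TECopy(
            sequence_id=row.sequence_id,
            start=int(row.start), end=int(row.end),
            strand=row.strand, consensus_id=row.consensus_id,
            te_class=row.te_class, superfamily=row.superfamily,
            family=row.family or None,
            intact=row.intact in ("1", "True", "true", "yes"),
        ))
    return ann


def write_te_tsv(annotation: GenomeAnnotation, stream: PathOrStream) -> None:
    rows = [{
        "sequence_id": c.sequence_id, "start": c.start, "end": c.end,
        "strand": c.strand, "consensus_id": c.consensus_id,
        "te_class": c.te_class, "superfamily": c.superfamily,
        "family": c.family or "", "intact": int(c.intact),
    } for c in annotation]
    pd.DataFrame(rows, columns=TE_TSV_COLUMNS).to_csv(stream, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(stream: PathOrStream) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercased sequence) pairs; duplicate ids error."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(stream, "fasta")]
    seen: set[str] = set()
    dups = sorted({i for i, _ in records if i in seen or seen.add(i)})
    if dups:
        raise ValueError(f"duplicate FASTA ids: {dups}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], stream: PathOrStream) -> None:
    seqs = (SeqRecord(Seq(s), id=i, description="") for i, s in records)
    SeqIO.write(seqs, stream, "fasta")


def read_consensus_fasta(stream: PathOrStream,
                         class_hints: Optional[Mapping[str, tuple[str, str]]] = None
                         ) -> list[TEConsensus]:
    """Read a consensus library.

    Classification is taken from a ``#class/superfamily`` suffix on the id
    (RepeatMasker library convention) when present, else from
    ``class_hints``, else Unknown.
    """
    out = []
    for rid, seq in read_fasta(stream):
        if "#" in rid:
            name, label = rid.split("#", 1)
            te_class, superfamily = classify_label(label)
        else:
            name = rid
            te_class, superfamily = (class_hints or {}).get(rid, ("Unknown", ""))
        out.append(TEConsensus(id=name, sequence=seq,
                               te_class=te_class, superfamily=superfamily))
    return out


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(stream: PathOrStream) -> dendropy.Tree:
    """Read a rooted Newick tree, requiring branch lengths on every edge.

    Multifurcating trees and trees with missing branch lengths are
    rejected: downstream phylogenetically independent contrasts are only
    defined on strictly bifurcating trees with positive branch lengths.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            text = fh.read()
    else:
        text = stream.read()
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges with missing branch lengths")
        if edge.length <= 0:
            raise ValueError(f"non-positive branch length {edge.length}")
    for node in tree.preorder_node_iter():
        nch = len(node.child_nodes())
        if nch not in (0, 2):
            raise ValueError(
                f"tree must be strictly bifurcating; found node with {nch} children"
            )
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# GFF3 (writer only, for simulated annotations)
# ---------------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, stream: PathOrStream) -> None:
    """Emit simulated annotations as GFF3 ``dispersed_repeat`` features."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, "w")
        close = True
    try:
        stream.write("##gff-version 3\n")
        for i, c in enumerate(annotation):
            attrs = (
                f"ID=te{i};consensus_id={c.consensus_id};"
                f"te_class={c.te_class};family={c.family or '.'};"
                f"intact={int(c.intact)}"
            )
            stream.write("\t".join([
                c.sequence_id, "techrono", "dispersed_repeat",
                str(c.start + 1), str(c.end), ".", c.strand, ".", attrs,
            ]) + "\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

def read_trait_table(stream: PathOrStream) -> pd.DataFrame:
    """Read a per-species trait TSV indexed by its ``species`` column."""
    df = pd.read_csv(stream, sep="\t")
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    return df.set_index("species")
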