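"""Thin pairwise-alignment layer on top of edlib.

Two alignment modes are used in the pipeline:

* ``fragment`` — global on the query with free end gaps on the target
  (edlib ``HW``).  Used when the query is expected to be a fragment of the
  target: a genomic TE copy against its consensus, or a library candidate
  against a longer kept representative.
* ``global`` — plain Needleman–Wunsch (edlib ``NW``), used when both
  sequences are expected to span the same element, e.g. the two terminal
  repeats of one LTR retrotransposon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentSummary:
    """Column tallies of one pairwise alignment.

    ``matches``/``mismatches`` count ungapped columns; ``query_gaps`` are
    columns consuming only target (deletion from the query), ``target_gaps``
    columns consuming only query.
    """

    matches: int
    mismatches: int
    query_gaps: int
    target_gaps: int
    column_pairs: list[tuple[str, str]]

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches

    @property
    def identity(self) -> float:
        """matches / aligned non-gap columns (0 if nothing aligned)."""
        n = self.aligned_columns
        return self.matches / n if n else 0.0


def align_pair(query: str, target: str, mode: str = "fragment") -> AlignmentSummary:
    """Align ``query`` to ``target`` and return per-column tallies.

    mode="fragment" leaves the unaligned target ends unpenalised; the
    returned tallies cover only the aligned region.
    """
    edmode = {"fragment": "HW", "global": "NW"}[mode]
    res = edlib.align(query.upper(), target.upper(), mode=edmode, task="path")
    cigar = res["cigar"]
    if cigar is None:  # pragma: no cover - edlib always returns a path here
        raise RuntimeError("alignment failed")
    start = res["locations"][0][0] if res["locations"] else 0
    qi, ti = 0, start
    matches = mismatches = qgaps = tgaps = 0
    pairs: list[tuple[str, str]] = []
    q, t = query.upper(), target.upper()
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            matches += n
            pairs.extend(zip(q[qi:qi + n], t[ti:ti + n]))
            qi += n
            ti += n
        elif op == "X":
            mismatches += n
            pairs.extend(zip(q[qi:qi + n], t[ti:ti + n]))
            qi += n
            ti += n
        elif op == "I":  # consumes query only -> gap in target
            tgaps += n
            qi += n
        elif op == "D":  # consumes target only -> gap in query
            qgaps += n
            ti += n
    return AlignmentSummary(matches, mismatches, qgaps, tgaps, pairs)


def identity_and_coverage(candidate: str, reference: str) -> tuple[float, float]:
    """Best-strand identity and candidate coverage against a reference.

    Identity is matches over aligned non-gap columns; coverage is the
    fraction of the candidate's length sitting in aligned (non-gap) columns.
    Both strands of the candidate are tried; the strand with the higher
    identity*coverage product wins.
    """
    best = (0.0, 0.0)
    for seq in (candidate, reverse_complement(candidate)):
        s = align_pair(seq, reference, mode="fragment")
        ident = s.identity
        cov = s.aligned_columns / len(candidate) if candidate else 0.0
        if ident * cov > best[0] * best[1]:
            best = (ident, cov)
    return best
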