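"""Kimura 2-parameter divergence of TE copies and divergence landscapes.

Every annotated TE copy is aligned to its library consensus, transitions
(P) and transversions (Q) are tallied over ungapped, unambiguous columns,
and the K2P distance

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

is accumulated into per-class genome-coverage histograms ("repeat
landscapes"): each copy contributes its genomic length to the integer bin
floor(100*K), capped at bin 50.  Peaks in the landscape mark historical
transposition bursts; the x position of a peak is a proxy for its age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .align import align_pair, reverse_complement
from .model import GenomeAnnotation, KimuraEstimate, TECopy, TEConsensus

MAX_BIN = 50

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_UNAMBIGUOUS = frozenset("ACGT")


def kimura2p(P: float, Q: float) -> Optional[float]:
    """K2P distance from transition (P) and transversion (Q) proportions.

    Returns ``None`` when the estimator saturates (log argument <= 0).
    Raises on inputs outside the simplex ``P, Q >= 0, P + Q <= 1``.
    """
    if P < 0 or Q < 0:
        raise ValueError(f"P and Q must be non-negative (P={P}, Q={Q})")
    if P + Q > 1:
        raise ValueError(f"P + Q must not exceed 1 (P={P}, Q={Q})")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return None
    return -0.5 * math.log(a * math.sqrt(b))


def count_site_patterns(column_pairs: Iterable[tuple[str, str]]) -> tuple[int, int, int]:
    """Count (transitions, transversions, usable sites) over aligned columns.

    Columns containing a gap or any non-ACGT symbol are excluded from both
    numerator and denominator.
    """
    ts = tv = n = 0
    for x, y in column_pairs:
        if x not in _UNAMBIGUOUS or y not in _UNAMBIGUOUS:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return ts, tv, n


def pair_divergence(
    copy_seq: str,
    consensus_seq: str,
    strand: str = "+",
    mode: str = "fragment",
    min_coverage: float = 0.5,
) -> KimuraEstimate:
    """K2P divergence between one TE copy and its consensus.

    The copy is reverse-complemented first when annotated on the minus
    strand, then aligned to the consensus (free end gaps on the consensus:
    genomic copies are typically fragments of the full-length consensus).
    Estimates whose aligned fraction of the copy falls below
    ``min_coverage`` are flagged low-confidence and excluded from
    landscapes.
    """
    if not copy_seq or not consensus_seq:
        raise ValueError("empty sequence")
    q = reverse_complement(copy_seq) if strand == "-" else copy_seq
    summary = align_pair(q, consensus_seq, mode=mode)
    ts, tv, n = count_site_patterns(summary.column_pairs)
    if n == 0:
        return KimuraEstimate(P=0.0, Q=0.0, K=None, aligned_sites=0,
                              low_confidence=True)
    P, Q = ts / n, tv / n
    K = kimura2p(P, Q)
    low = summary.aligned_columns < min_coverage * len(copy_seq)
    return KimuraEstimate(P=P, Q=Q, K=K, aligned_sites=n, low_confidence=low)


@dataclass
class DivergenceLandscape:
    """Genome bp covered by TEs, by class and integer Kimura bin (0..50)."""

    genome_id: str
    coverage: dict[tuple[str, int], int] = field(default_factory=dict)
    total_te_bp: int = 0
    skipped: list[str] = field(default_factory=list)

    def add(self, te_class: str, K: float, bp: int) -> None:
        b = min(int(math.floor(100.0 * K)), MAX_BIN)
        key = (te_class, b)
        self.coverage[key] = self.coverage.get(key, 0) + bp
        self.total_te_bp += bp

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"genome_id": self.genome_id, "te_class": c, "bin": b, "bp": bp}
            for (c, b), bp in sorted(self.coverage.items())
        ]
        return pd.DataFrame(rows, columns=["genome_id", "te_class", "bin", "bp"])

    def class_track(self, te_class: str) -> np.ndarray:
        track = np.zeros(MAX_BIN + 1, dtype=int)
        for (c, b), bp in self.coverage.items():
            if c == te_class:
                track[b] += bp
        return track

    def peak_bin(self, te_class: Optional[str] = None) -> int:
        if te_class is not None:
            track = self.class_track(te_class)
        else:
            track = np.zeros(MAX_BIN + 1, dtype=int)
            for (_, b), bp in self.coverage.items():
                track[b] += bp
        return int(np.argmax(track))


def build_landscape(
    annotation: GenomeAnnotation,
    consensus_library: Mapping[str, TEConsensus],
    genome_sequences: Mapping[str, str],
    min_coverage: float = 0.5,
) -> DivergenceLandscape:
    """Divergence landscape of one genome.

    Copies whose consensus id is missing from the library, or whose K2P
    estimate is saturated or low-confidence, are listed in ``skipped`` and
    excluded from the coverage totals.
    """
    ls = DivergenceLandscape(genome_id=annotation.genome_id)
    for copy in annotation:
        cons = consensus_library.get(copy.consensus_id)
        if cons is None:
            ls.skipped.append(f"{copy.consensus_id}: not in library")
            continue
        est = copy.divergence
        if est is None:
            seq = genome_sequences[copy.sequence_id][copy.start:copy.end]
            est = pair_divergence(seq, cons.sequence, strand=copy.strand,
                                  min_coverage=min_coverage)
            copy.divergence = est
        if not est.defined or est.low_confidence:
            ls.skipped.append(f"{copy.consensus_id}: undefined or low-confidence K")
            continue
        ls.add(copy.te_class, est.K, copy.length)
    return ls
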