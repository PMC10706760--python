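"""Pan-genome TE library construction.

Per-genome consensus sets are merged into one non-redundant library:

1. drop sequences shorter than 80 bp;
2. drop simple/satellite repeats (>= 80% of the sequence covered by exact
   tandem arrays of period <= 10 bp);
3. greedy redundancy removal with the 80/80 rule: scanning sequences from
   longest to shortest, a candidate is discarded when an already-kept
   sequence aligns to it at >= 80% identity over >= 80% of the candidate's
   length, on either strand.

The coverage denominator is the candidate (shorter) sequence, so fragments
contained in a full-length consensus collapse onto it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import identity_and_coverage
from .model import TEConsensus

logger = logging.getLogger(__name__)


@dataclass
class PanlibParams:
    min_identity: float = 80.0      # percent
    min_coverage: float = 80.0      # percent of candidate length
    min_length: int = 80            # bp
    tandem_fraction_threshold: float = 0.8
    max_tandem_period: int = 10

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def is_simple_repeat(sequence: str, params: PanlibParams | None = None) -> bool:
    """True when the sequence is mostly exact tandem repeat.

    A position counts as tandem-covered when it lies in an exact tandem
    array of period p <= max_tandem_period spanning at least max(2p, 8) bp.
    The sequence is called simple when the covered fraction reaches the
    threshold (default 0.8).
    """
    if not sequence:
        raise ValueError("empty sequence")
    params = params or PanlibParams()
    s = sequence.upper()
    n = len(s)
    covered = bytearray(n)
    for p in range(1, params.max_tandem_period + 1):
        run = 0
        for i in range(p, n):
            if s[i] == s[i - p]:
                run += 1
            else:
                if run + p >= max(2 * p, 8):
                    covered[i - run - p:i] = b"\x01" * (run + p)
                run = 0
        if run + p >= max(2 * p, 8):
            covered[n - run - p:n] = b"\x01" * (run + p)
    return sum(covered) / n >= params.tandem_fraction_threshold


def redundancy_collapse(
    consensus_list: Sequence[TEConsensus],
    params: PanlibParams | None = None,
) -> tuple[list[TEConsensus], dict[str, str]]:
    """Greedy 80/80 redundancy removal.

    Sequences are scanned longest-first (ties broken by id); a candidate is
    redundant iff some already-kept sequence covers >= min_coverage% of it
    at >= min_identity% identity on either strand.  Returns the kept list
    and a map candidate_id -> representative_id for every discarded entry.
    """
    params = params or PanlibParams()
    ordered = sorted(consensus_list, key=lambda c: (-len(c.sequence), c.id))
    kept: list[TEConsensus] = []
    redundancy: dict[str, str] = {}
    for cand in ordered:
        rep = None
        for k in kept:
            ident, cov = identity_and_coverage(cand.sequence, k.sequence)
            if (ident * 100 >= params.min_identity
                    and cov * 100 >= params.min_coverage):
                rep = k
                break
        if rep is None:
            kept.append(cand)
        else:
            redundancy[cand.id] = rep.id
            if (cand.te_class, cand.superfamily) != (rep.te_class, rep.superfamily):
                logger.info("collapsed %s (%s/%s) into %s (%s/%s); labels differ",
                            cand.id, cand.te_class, cand.superfamily,
                            rep.id, rep.te_class, rep.superfamily)
    return kept, redundancy


_CLASS_GROUP = {"LTR": "Class I", "LINE": "Class I",
                "TIR": "Class II", "Helitron": "Class II",
                "Unknown": "Unknown"}


def summarize_library(library: Iterable[TEConsensus]) -> pd.DataFrame:
    """Count library entries by class group / te_class / superfamily."""
    rows = [{"group": _CLASS_GROUP[c.te_class], "te_class": c.te_class,
             "superfamily": c.superfamily or "-"} for c in library]
    df = pd.DataFrame(rows, columns=["group", "te_class", "superfamily"])
    if df.empty:
        return pd.DataFrame(columns=["group", "te_class", "superfamily", "count"])
    out = (df.value_counts().rename("count").reset_index()
           .sort_values(["group", "te_class", "superfamily"])
           .reset_index(drop=True))
    total = pd.DataFrame([{"group": "Total", "te_class": "-",
                           "superfamily": "-", "count": len(rows)}])
    return pd.concat([out, total], ignore_index=True)


def build_panlib(
    per_genome_libraries: dict[str, Sequence[TEConsensus]],
    params: PanlibParams | None = None,
) -> tuple[list[TEConsensus], dict[str, str], pd.DataFrame]:
    """Merge per-genome consensus sets into one non-redundant pan-library.

    Ids are provenance-encoded as ``genome#originalname`` when the input
    comes from more than one genome.  Returns (kept, redundancy map,
    summary table).
    """
    params = params or PanlibParams()
    merged: list[TEConsensus] = []
    multi = len(per_genome_libraries) > 1
    for gid, lib in per_genome_libraries.items():
        for c in lib:
            cid = f"{gid}#{c.id}" if multi and "#" not in c.id else c.id
            merged.append(TEConsensus(id=cid, sequence=c.sequence,
                                      te_class=c.te_class,
                                      superfamily=c.superfamily,
                                      family=c.family))
    filtered = [c for c in merged
                if len(c.sequence) >= params.min_length
                and not is_simple_repeat(c.sequence, params)]
    if not filtered:
        raise ValueError("no sequences left after length/simple-repeat filters")
    kept, redundancy = redundancy_collapse(filtered, params)
    return kept, redundancy, summarize_library(kept)
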