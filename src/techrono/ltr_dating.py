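"""Insertion-time dating of intact LTR retrotransposons.

The two terminal repeats of an LTR-RT are identical at the moment of
insertion and thereafter accumulate substitutions independently, so their
K2P divergence K grows at twice the neutral substitution rate r.  The
insertion time is therefore

    T = K / (2 r)

with r the per-site per-year neutral rate (default 2.8e-9, the estimate
used for strawberry).  Ages are summarised as histograms with 500,000-year
bins anchored at the present, and as kernel density estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .divergence import pair_divergence
from .model import KimuraEstimate

DEFAULT_RATE = 2.8e-9
DEFAULT_BIN_WIDTH = 5e5


@dataclass
class LTRPair:
    """The two terminal repeats of one intact LTR-RT."""

    element_id: str
    ltr5_seq: str
    ltr3_seq: str
    superfamily: str = ""
    family: Optional[str] = None
    K: Optional[KimuraEstimate] = None
    T: Optional[float] = None


def date_ltr(K: float, r: float = DEFAULT_RATE) -> float:
    """Insertion time in years from inter-LTR K2P divergence."""
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    if K < 0:
        raise ValueError(f"divergence must be non-negative, got {K}")
    return K / (2.0 * r)


def pairs_from_fasta(records: Sequence[tuple[str, str]]) -> list[LTRPair]:
    """Group a pairs-FASTA (``<id>/5ltr``, ``<id>/3ltr`` records) into LTRPairs."""
    if len(records) % 2:
        raise ValueError(f"odd number of records ({len(records)}) in pairs FASTA")
    by_id: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rid, seq in records:
        if "/" not in rid:
            raise ValueError(f"record id {rid!r} lacks a /5ltr or /3ltr suffix")
        eid, which = rid.rsplit("/", 1)
        if which not in ("5ltr", "3ltr"):
            raise ValueError(f"record id {rid!r}: suffix must be 5ltr or 3ltr")
        if eid not in by_id:
            order.append(eid)
        by_id.setdefault(eid, {})[which] = seq
    pairs = []
    for eid in order:
        d = by_id[eid]
        if set(d) != {"5ltr", "3ltr"}:
            raise ValueError(f"element {eid!r} is missing one of its LTRs")
        pairs.append(LTRPair(element_id=eid, ltr5_seq=d["5ltr"], ltr3_seq=d["3ltr"]))
    return pairs


def date_all(pairs: Iterable[LTRPair], r: float = DEFAULT_RATE) -> pd.DataFrame:
    """Date every LTR pair; rows with saturated K keep T as NaN."""
    rows = []
    for p in pairs:
        if p.K is None:
            p.K = pair_divergence(p.ltr5_seq, p.ltr3_seq, mode="global",
                                  min_coverage=0.0)
        k = p.K.K
        p.T = date_ltr(k, r) if k is not None else None
        rows.append({
            "element_id": p.element_id,
            "superfamily": p.superfamily,
            "family": p.family or "",
            "K": np.nan if k is None else k,
            "T": np.nan if p.T is None else p.T,
        })
    return pd.DataFrame(rows, columns=["element_id", "superfamily", "family", "K", "T"])


@dataclass
class AgeHistogram:
    """Insertion-time counts in fixed-width bins anchored at the present.

    Bin i counts ages in [i*w, (i+1)*w); trailing empty bins are trimmed.
    """

    bin_width: float = DEFAULT_BIN_WIDTH
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    genome_id: str = ""
    superfamily: Optional[str] = None

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(len(self.counts)) + 0.5) * self.bin_width


def bin_ages(times: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH,
             genome_id: str = "") -> AgeHistogram:
    """Bin insertion times (years); NaN/undefined entries are dropped."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = np.asarray([x for x in times if x is not None], dtype=float)
    t = t[np.isfinite(t)]
    if np.any(t < 0):
        raise ValueError("insertion times must be non-negative")
    if t.size == 0:
        return AgeHistogram(bin_width=bin_width, genome_id=genome_id)
    idx = np.floor(t / bin_width).astype(int)
    counts = np.bincount(idx)
    return AgeHistogram(bin_width=bin_width, counts=counts, genome_id=genome_id)


def age_density(times: Sequence[float], bandwidth: Optional[float] = None,
                n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of insertion times on a uniform grid over [0, max T].

    Bandwidth defaults to Silverman's rule.  Returns (grid, density); the
    trapezoid integral of the density over the grid is ~1.
    """
    t = np.asarray([x for x in times if x is not None], dtype=float)
    t = t[np.isfinite(t)]
    if t.size < 2:
        raise ValueError("need at least 2 defined insertion times for a density")
    if np.ptp(t) == 0:
        # Degenerate sample: a narrow Gaussian bump centred on the value.
        sd = max(t[0] * 0.01, 1.0)
        grid = np.linspace(max(t[0] - 4 * sd, 0.0), t[0] + 4 * sd, n_grid)
        dens = np.exp(-0.5 * ((grid - t[0]) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        return grid, dens
    kde = gaussian_kde(t, bw_method="silverman" if bandwidth is None else
                       bandwidth / t.std(ddof=1))
    grid = np.linspace(0.0, float(t.max()), n_grid)
    dens = kde(grid)
    # Renormalise over the evaluation window so the trapezoid integral is 1.
    area = np.trapezoid(dens, grid)
    return grid, dens / area
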