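"""Synthetic TE-evolution simulator with known ground truth.

Generates genomes carrying TE copies whose full history is recorded, so
every downstream estimator can be tested by parameter recovery:

* insertion ages are drawn per family from a constant-rate process plus
  optional burst pulses;
* each inserted copy survives to the present with probability
  exp(-lambda * age), lambda = ln2 / half-life — the constant-removal
  model the decay fit assumes;
* surviving copies start as exact copies of the family consensus and decay
  under the Kimura 2-parameter substitution process at rate r per site per
  year (default 2.8e-9), so copy-vs-consensus divergence has expectation
  ~ r * age;
* LTR elements carry two terminal repeats, identical at insertion and
  mutated independently, so inter-LTR divergence has expectation ~ 2*r*age;
* copies are placed at non-overlapping positions on an i.i.d. random
  background, on random strands.

Several genomes can be simulated from one shared family pool with a
per-genome ancestry plan, giving allopolyploid-style shared-TE structure
with known donors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .align import reverse_complement
from .ltr_dating import LTRPair
from .model import GenomeAnnotation, TECopy, TEConsensus

DEFAULT_RATE = 2.8e-9

_BASES = np.frombuffer(b"AGCT", dtype=np.uint8)  # A<->G, C<->T transitions


@dataclass
class FamilySpec:
    """One TE family: its consensus and its insertion process."""

    name: str
    te_class: str = "LTR"
    superfamily: str = "copia"
    consensus_length: int = 1000
    ltr_length: int = 0                      # >0 only for LTR families
    rate_per_my: float = 0.0                 # constant insertions per My
    bursts: Sequence[tuple[float, int]] = field(default_factory=tuple)
    burst_sd_my: float = 0.05                # age jitter around a pulse

    def __post_init__(self) -> None:
        if self.te_class == "LTR" and self.ltr_length <= 0:
            raise ValueError(f"LTR family {self.name!r} needs ltr_length > 0")
        if self.te_class != "LTR" and self.ltr_length:
            raise ValueError(f"non-LTR family {self.name!r} cannot have LTRs")
        if self.ltr_length and 2 * self.ltr_length >= self.consensus_length:
            raise ValueError(f"{self.name!r}: LTRs longer than the element")
        for t, n in self.bursts:
            if n < 0:
                raise ValueError("burst copy count must be >= 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    r: float = DEFAULT_RATE                   # substitutions / site / year
    kappa: float = 2.0                        # transition/transversion ratio
    families: Sequence[FamilySpec] = field(default_factory=tuple)
    removal_half_life_my: float = 3.0
    horizon_my: float = 10.0                  # oldest simulated insertion
    genome_length_bp: int = 1_000_000
    n_genomes: int = 1
    ancestry: Optional[Mapping[str, Sequence[str]]] = None  # genome -> families
    truncation_prob: float = 0.0              # else removal is all-or-nothing

    def __post_init__(self) -> None:
        if min(self.r, self.kappa, self.removal_half_life_my, self.horizon_my) <= 0:
            raise ValueError("r, kappa, removal_half_life_my, horizon_my must be > 0")
        for f in self.families:
            for t, _ in f.bursts:
                if t > self.horizon_my:
                    raise ValueError(
                        f"burst at {t} My beyond horizon {self.horizon_my} My")

    def genome_ids(self) -> list[str]:
        if self.ancestry is not None:
            return list(self.ancestry)
        return [f"g{i}" for i in range(self.n_genomes)]


@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: dict[str, str]                         # genome_id -> chromosome seq
    annotations: dict[str, GenomeAnnotation]
    consensus_library: list[TEConsensus]
    ltr_pairs: dict[str, list[LTRPair]]
    truth: pd.DataFrame


def k2p_probabilities(t_years: float, r: float, kappa: float) -> tuple[float, float]:
    """Exact per-site transition (P) and transversion (Q) probabilities.

    Total substitution rate r is partitioned as alpha + 2*beta = r with
    alpha/beta = kappa; the K2P transition matrix then gives
    P(t) = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2(alpha+beta) t} and
    Q(t) = 1/2 - 1/2 e^{-4 beta t}.
    """
    beta = r / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t_years)
    e2 = math.exp(-2.0 * (alpha + beta) * t_years)
    P = 0.25 + 0.25 * e1 - 0.5 * e2
    Q = 0.5 - 0.5 * e1
    return P, Q


def mutate_k2p(sequence: str, t_years: float, r: float, kappa: float,
               rng: np.random.Generator) -> str:
    """Evolve a sequence for t years under the K2P substitution process.

    Each site is substituted independently with the exact time-t K2P
    probabilities (not a small-t approximation), so the expected
    copy-vs-original K2P estimate equals the model divergence for any t.
    """
    if t_years < 0:
        raise ValueError("time must be non-negative")
    enc = _encode(sequence)
    out = _mutate_encoded(enc, t_years, r, kappa, rng)
    return _decode(out)


def _encode(sequence: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"AGCT"):
        lut[b] = i
        lut[b + 32] = i
    enc = lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if np.any(enc == 255):
        raise ValueError("sequence contains non-ACGT symbols")
    return enc


def _decode(enc: np.ndarray) -> str:
    return _BASES[enc].tobytes().decode()


def _mutate_encoded(enc: np.ndarray, t: float, r: float, kappa: float,
                    rng: np.random.Generator) -> np.ndarray:
    P, Q = k2p_probabilities(t, r, kappa)
    u = rng.random(enc.size)
    out = enc.copy()
    ts = u < P
    out[ts] ^= 1                                   # transition partner
    tv = (u >= P) & (u < P + Q)
    flip = rng.integers(0, 2, size=int(tv.sum()), dtype=np.uint8)
    out[tv] = (enc[tv] ^ 2) ^ flip                 # one of the two transversions
    return out


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _draw_ages(spec: FamilySpec, cfg: SimulationConfig,
               rng: np.random.Generator) -> np.ndarray:
    ages = []
    if spec.rate_per_my > 0:
        n = rng.poisson(spec.rate_per_my * cfg.horizon_my)
        ages.append(rng.uniform(0.0, cfg.horizon_my, size=n))
    for t, count in spec.bursts:
        a = rng.normal(t, spec.burst_sd_my, size=count)
        ages.append(np.clip(a, 0.0, cfg.horizon_my))
    if not ages:
        return np.zeros(0)
    return np.concatenate(ages) * 1e6              # years


def simulate_genomes(config: SimulationConfig) -> SimulationResult:
    """Run the full simulation; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    lam = math.log(2) / (config.removal_half_life_my * 1e6)

    spec_by_name = {f.name: f for f in config.families}
    if len(spec_by_name) != len(config.families):
        raise ValueError("duplicate family names")

    # One shared consensus per family across all genomes.  LTR-family
    # consensus carries identical terminal repeats, as a real element does
    # at the moment of insertion.
    cons_enc: dict[str, np.ndarray] = {}
    for f in config.families:
        if f.ltr_length:
            ltr = _random_seq(f.ltr_length, rng)
            internal = _random_seq(f.consensus_length - 2 * f.ltr_length, rng)
            cons_enc[f.name] = np.concatenate([ltr, internal, ltr])
        else:
            cons_enc[f.name] = _random_seq(f.consensus_length, rng)
    library = [
        TEConsensus(id=f.name, sequence=_decode(cons_enc[f.name]),
                    te_class=f.te_class, superfamily=f.superfamily,
                    family=f.name)
        for f in config.families]

    genomes: dict[str, str] = {}
    annotations: dict[str, GenomeAnnotation] = {}
    ltr_pairs: dict[str, list[LTRPair]] = {}
    truth_rows: list[dict] = []

    for gid in config.genome_ids():
        fam_names = (list(config.ancestry[gid]) if config.ancestry is not None
                     else [f.name for f in config.families])
        placed: list[tuple[str, FamilySpec, float, bool, str, np.ndarray]] = []
        counter = 0
        for fname in fam_names:
            spec = spec_by_name[fname]
            for age in _draw_ages(spec, config, rng):
                copy_id = f"{gid}:{fname}:{counter}"
                counter += 1
                survives = rng.random() < math.exp(-lam * age)
                truth_rows.append({
                    "genome_id": gid, "copy_id": copy_id, "family": fname,
                    "te_class": spec.te_class, "age_years": age,
                    "surviving": survives, "intact": False,
                })
                if not survives:
                    continue
                seq, intact = _evolve_copy(copy_id, spec, cons_enc[fname], age,
                                           config, rng, ltr_pairs.setdefault(gid, []))
                truth_rows[-1]["intact"] = intact
                strand = "+" if rng.random() < 0.5 else "-"
                placed.append((copy_id, spec, age, intact, strand, seq))

        ltr_pairs.setdefault(gid, [])
        genomes[gid], annotations[gid] = _assemble(gid, placed, config, rng)

    truth = pd.DataFrame(truth_rows, columns=[
        "genome_id", "copy_id", "family", "te_class", "age_years",
        "surviving", "intact"])
    return SimulationResult(config=config, genomes=genomes,
                            annotations=annotations,
                            consensus_library=library,
                            ltr_pairs=ltr_pairs, truth=truth)


def _evolve_copy(copy_id: str, spec: FamilySpec, cons: np.ndarray, age: float,
                 cfg: SimulationConfig, rng: np.random.Generator,
                 pair_sink: list[LTRPair]) -> tuple[np.ndarray, bool]:
    """Mutate one surviving copy for its age; record its LTR pair if any."""
    intact = True
    if cfg.truncation_prob > 0 and rng.random() < cfg.truncation_prob:
        intact = False
    if spec.ltr_length:
        L = spec.ltr_length
        ltr = cons[:L]
        internal = cons[L:len(cons) - L]
        ltr5 = _mutate_encoded(ltr, age, cfg.r, cfg.kappa, rng)
        ltr3 = _mutate_encoded(ltr, age, cfg.r, cfg.kappa, rng)
        mid = _mutate_encoded(internal, age, cfg.r, cfg.kappa, rng)
        seq = np.concatenate([ltr5, mid, ltr3])
        if intact:
            pair_sink.append(LTRPair(
                element_id=copy_id, ltr5_seq=_decode(ltr5),
                ltr3_seq=_decode(ltr3), superfamily=spec.superfamily,
                family=spec.name))
    else:
        seq = _mutate_encoded(cons, age, cfg.r, cfg.kappa, rng)
    if not intact:
        keep = max(int(len(seq) * rng.uniform(0.2, 0.8)), 30)
        seq = seq[:keep]
    return seq, intact


def _assemble(gid: str, placed: list, cfg: SimulationConfig,
              rng: np.random.Generator) -> tuple[str, GenomeAnnotation]:
    te_bp = sum(len(p[5]) for p in placed)
    if te_bp > 0.9 * cfg.genome_length_bp:
        raise ValueError(
            f"{gid}: requested {te_bp} bp of TE copies will not fit in a "
            f"{cfg.genome_length_bp} bp genome")
    order = rng.permutation(len(placed))
    free = cfg.genome_length_bp - te_bp
    gaps = rng.multinomial(free, np.full(len(placed) + 1, 1.0 / (len(placed) + 1)))
    pieces: list[np.ndarray] = []
    ann = GenomeAnnotation(genome_id=gid)
    seq_id = f"{gid}_chr1"
    pos = 0
    for i, idx in enumerate(order):
        copy_id, spec, age, intact, strand, seq = placed[idx]
        gap = int(gaps[i])
        pieces.append(_random_seq(gap, rng))
        pos += gap
        genomic = seq if strand == "+" else _revcomp_encoded(seq)
        pieces.append(genomic)
        ann.add(TECopy(sequence_id=seq_id, start=pos, end=pos + len(seq),
                       strand=strand, consensus_id=spec.name,
                       te_class=spec.te_class, superfamily=spec.superfamily,
                       family=spec.name, intact=intact, copy_id=copy_id))
        pos += len(seq)
    pieces.append(_random_seq(int(gaps[-1]), rng))
    genome = _decode(np.concatenate(pieces)) if pieces else ""
    ann.sequence_ids.add(seq_id)
    return genome, ann


def _revcomp_encoded(enc: np.ndarray) -> np.ndarray:
    # A=0,G=1,C=2,T=3: complement is A<->T (0<->3), G<->C (1<->2) => 3 - x
    return (3 - enc)[::-1]


def default_config(seed: int = 0) -> SimulationConfig:
    """A small multi-class configuration with a recent copia burst.

    Used by the demo pipeline: five families spanning the major TE classes,
    constant background insertion over 10 My, a copia burst 1 My ago, and a
    3 My removal half-life.
    """
    fams = [
        FamilySpec("copia_A", "LTR", "copia", consensus_length=1500,
                   ltr_length=250, rate_per_my=40, bursts=[(1.0, 300)]),
        FamilySpec("gypsy_A", "LTR", "gypsy", consensus_length=2000,
                   ltr_length=300, rate_per_my=60),
        FamilySpec("line_A", "LINE", "l1", consensus_length=1200, rate_per_my=30),
        FamilySpec("tir_A", "TIR", "mutator", consensus_length=600, rate_per_my=50),
        FamilySpec("helitron_A", "Helitron", "helitron", consensus_length=900,
                   rate_per_my=25),
    ]
    return SimulationConfig(seed=seed, families=fams, removal_half_life_my=3.0,
                            horizon_my=10.0, genome_length_bp=2_000_000)


# ---------------------------------------------------------------------------
# Phylogenetic simulation helpers (for comparative-analysis testing)
# ---------------------------------------------------------------------------

def random_binary_tree(n_taxa: int, rng: np.random.Generator,
                       mean_branch: float = 1.0) -> dendropy.Tree:
    """Random rooted bifurcating tree by repeated pair joining.

    Branch lengths are exponential with the given mean; leaves are labelled
    t0..t{n-1}.
    """
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_taxa):
        nd = dendropy.Node(taxon=taxa[i])
        nd.edge.length = float(rng.exponential(mean_branch))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(mean_branch))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.edge.length = None
    tree.seed_node = root
    return tree


def simulate_brownian_traits(tree: dendropy.Tree, sigma: np.ndarray,
                             rng: np.random.Generator
                             ) -> tuple[dict[str, float], dict[str, float]]:
    """Correlated two-trait Brownian motion along a tree.

    sigma is the 2x2 per-unit-branch-length covariance of trait increments.
    Returns the two leaf trait maps.
    """
    chol = np.linalg.cholesky(sigma)
    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(2)}
    x: dict[str, float] = {}
    y: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        b = float(node.edge.length)
        step = chol @ rng.standard_normal(2) * math.sqrt(b)
        values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            x[node.taxon.label] = float(values[id(node)][0])
            y[node.taxon.label] = float(values[id(node)][1])
    return x, y
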