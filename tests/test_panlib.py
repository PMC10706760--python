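import numpy as np
import pytest

from techrono.align import identity_and_coverage, reverse_complement
from techrono.model import TEConsensus
from techrono.panlib import (PanlibParams, build_panlib, is_simple_repeat,
                             redundancy_collapse, summarize_library)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSimpleRepeat:
    def test_dinucleotide_repeat(self):
        assert is_simple_repeat("AC" * 100)

    def test_homopolymer(self):
        assert is_simple_repeat("T" * 120)

    def test_random_false_positive_rate_below_1pct(self):
        rng = np.random.default_rng(0)
        hits = sum(is_simple_repeat(random_seq(rng, 200)) for _ in range(1000))
        assert hits / 1000 < 0.01

    def test_half_tandem_below_threshold(self):
        rng = np.random.default_rng(1)
        seq = "AT" * 50 + random_seq(rng, 100)
        assert not is_simple_repeat(seq)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            is_simple_repeat("")


class TestRedundancyCollapse:
    def test_identical_pair(self, rng):
        s = random_seq(rng, 300)
        kept, red = redundancy_collapse([TEConsensus("a", s),
                                         TEConsensus("b", s)])
        assert len(kept) == 1
        assert red == {"b": "a"}

    def test_containment_collapses(self, rng):
        s = random_seq(rng, 1000)
        kept, red = redundancy_collapse([
            TEConsensus("full", s), TEConsensus("frag", s[50:900])])
        assert [k.id for k in kept] == ["full"]
        assert red == {"frag": "full"}

    def test_reverse_complement_detected(self, rng):
        s = random_seq(rng, 500)
        kept, red = redundancy_collapse([
            TEConsensus("fwd", s), TEConsensus("rev", reverse_complement(s))])
        assert len(kept) == 1

    def test_diverged_pair_both_kept(self, rng):
        s = random_seq(rng, 1000)
        arr = list(s)
        idx = rng.choice(1000, size=330, replace=False)
        for i in idx:
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        s2 = "".join(arr)
        ident, cov = identity_and_coverage(s2, s)
        assert ident < 0.80  # confirm the construction is below threshold
        kept, _ = redundancy_collapse([TEConsensus("a", s),
                                       TEConsensus("b", s2)])
        assert len(kept) == 2

    def test_every_discard_maps_to_a_representative(self, rng):
        seqs = [random_seq(rng, 400) for _ in range(5)]
        lib = [TEConsensus(f"s{i}", s) for i, s in enumerate(seqs)]
        lib += [TEConsensus(f"d{i}", s[20:380]) for i, s in enumerate(seqs)]
        kept, red = redundancy_collapse(lib)
        kept_ids = {k.id for k in kept}
        assert set(red) | kept_ids == {c.id for c in lib}
        assert all(rep in kept_ids for rep in red.values())

    def test_order_stability(self, rng):
        seqs = [random_seq(rng, 200 + 10 * i) for i in range(8)]
        lib = [TEConsensus(f"s{i}", s) for i, s in enumerate(seqs)]
        lib.append(TEConsensus("dup", seqs[0]))
        kept1, _ = redundancy_collapse(lib)
        rng.shuffle(lib)
        kept2, _ = redundancy_collapse(lib)
        assert sorted(len(k.sequence) for k in kept1) == \
            sorted(len(k.sequence) for k in kept2)
        assert len(kept1) == len(kept2)


def certificate_holds(kept, params=None):
    """No retained pair aligns at >=80% identity over >=80% of the shorter."""
    params = params or PanlibParams()
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            short, long_ = sorted((a, b), key=lambda c: len(c.sequence))
            ident, cov = identity_and_coverage(short.sequence, long_.sequence)
            if (ident * 100 >= params.min_identity
                    and cov * 100 >= params.min_coverage):
                return False
    return True


class TestBuildPanlib:
    def test_short_and_simple_filtered(self, rng):
        lib = {"g": [TEConsensus("short", "ACGTACGT"),
                     TEConsensus("simple", "AG" * 100),
                     TEConsensus("ok", random_seq(rng, 300))]}
        kept, red, summary = build_panlib(lib)
        assert [k.id for k in kept] == ["ok"]

    def test_idempotent(self, rng):
        libs = {f"g{j}": [TEConsensus(f"c{i}", random_seq(rng, 250 + 30 * i))
                          for i in range(4)] for j in range(2)}
        kept, _, _ = build_panlib(libs)
        again, red, _ = build_panlib({"pan": kept})
        assert [k.sequence for k in again] == [k.sequence for k in kept]
        assert not red

    def test_provenance_ids_multi_genome(self, rng):
        libs = {"gA": [TEConsensus("c1", random_seq(rng, 300))],
                "gB": [TEConsensus("c1", random_seq(rng, 280))]}
        kept, _, _ = build_panlib(libs)
        assert {k.id for k in kept} == {"gA#c1", "gB#c1"}

    def test_shared_families_counted_once(self, rng):
        """Distinct families stay; families shared across genomes collapse."""
        shared = [random_seq(rng, 400) for _ in range(6)]
        own = {g: [random_seq(rng, 350) for _ in range(4)]
               for g in ("g0", "g1", "g2")}
        libs = {g: [TEConsensus(f"sh{i}", s) for i, s in enumerate(shared)]
                + [TEConsensus(f"own{i}", s) for i, s in enumerate(own[g])]
                for g in ("g0", "g1", "g2")}
        kept, _, _ = build_panlib(libs)
        assert len(kept) == 6 + 3 * 4

    def test_certificate_on_output(self, rng):
        seqs = [random_seq(rng, 300) for _ in range(10)]
        lib = [TEConsensus(f"s{i}", s) for i, s in enumerate(seqs)]
        lib += [TEConsensus(f"m{i}", s[:250]) for i, s in enumerate(seqs[:5])]
        kept, _, _ = build_panlib({"g": lib})
        assert certificate_holds(kept)

    def test_empty_after_filter_errors(self):
        with pytest.raises(ValueError, match="no sequences left"):
            build_panlib({"g": [TEConsensus("x", "ACGT")]})


def test_summary_table_layout():
    lib = [TEConsensus("a", "A", te_class="LTR", superfamily="copia"),
           TEConsensus("b", "A", te_class="LTR", superfamily="gypsy"),
           TEConsensus("c", "A", te_class="TIR", superfamily="cacta"),
           TEConsensus("d", "A", te_class="Unknown")]
    s = summarize_library(lib)
    assert s.loc[s["group"] == "Total", "count"].item() == 4
    assert set(s["group"]) == {"Class I", "Class II", "Unknown", "Total"}
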