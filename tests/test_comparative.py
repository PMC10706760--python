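import io
import math

import numpy as np
import pandas as pd
import pytest

from techrono import io as tio
from techrono.comparative import (cluster_species, family_profile, pearson,
                                  pic_contrasts, pic_correlation)
from techrono.simulate import random_binary_tree, simulate_brownian_traits


def tree_of(newick):
    return tio.read_newick(io.StringIO(newick))


def dated(families, times_my):
    return pd.DataFrame({"family": families,
                         "T": np.asarray(times_my) * 1e6})


# ---------------------------------------------------------------------------
# family profiles
# ---------------------------------------------------------------------------

class TestFamilyProfile:
    def test_percentages(self):
        tabs = {"sp1": dated(["Ale"] * 3 + ["Athila"] * 7, [0.5] * 10)}
        prof = family_profile(tabs)
        assert prof.percentages.loc["sp1", "Ale"] == pytest.approx(30.0)
        assert prof.percentages.loc["sp1", "Athila"] == pytest.approx(70.0)

    def test_window_boundary_excludes(self):
        tabs = {"sp1": dated(["Ale", "Ale", "Tekay"], [0.2, 1.2, 0.9])}
        prof = family_profile(tabs, window_my=1.0)
        assert prof.percentages.loc["sp1", "Ale"] == pytest.approx(50.0)

    def test_species_without_recent_copies_warned_out(self):
        tabs = {"young": dated(["Ale"] * 4, [0.1] * 4),
                "old": dated(["Ale"] * 4, [5.0] * 4)}
        with pytest.warns(UserWarning, match="old"):
            prof = family_profile(tabs)
        assert list(prof.percentages.index) == ["young"]

    def test_rank_order_follows_burst_intensity(self):
        tabs = {"sp": dated(["big"] * 60 + ["mid"] * 30 + ["small"] * 10,
                            [0.5] * 100)}
        row = family_profile(tabs).percentages.loc["sp"]
        assert row["big"] > row["mid"] > row["small"]

    def test_log2_zero_handling(self):
        tabs = {"a": dated(["x"] * 2, [0.5, 0.5]),
                "b": dated(["y"] * 2, [0.5, 0.5])}
        prof = family_profile(tabs)
        assert np.isfinite(prof.log2_matrix.values).all()
        assert prof.pseudo == pytest.approx(50.0)  # half the smallest nonzero


class TestClusterSpecies:
    def test_identical_profiles_merge_at_zero(self):
        tabs = {s: dated(["Ale", "Tekay"], [0.5, 0.5]) for s in ("a", "b")}
        prof = family_profile(tabs)
        _, Z = cluster_species(prof)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_two_spectra_separate(self):
        tabs = {}
        for i in range(3):
            tabs[f"cladeA_{i}"] = dated(["Ale"] * 9 + ["Tekay"], [0.5] * 10)
            tabs[f"cladeB_{i}"] = dated(["Ale"] + ["Tekay"] * 9, [0.5] * 10)
        import dendropy
        newick, Z = cluster_species(family_profile(tabs))
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        root_children = tree.seed_node.child_nodes()
        sides = [{l.taxon.label for l in ch.leaf_iter()}
                 for ch in root_children]
        assert {f"cladeA_{i}" for i in range(3)} in sides

    def test_species_order_invariance(self):
        tabs = {"a": dated(["x"] * 3 + ["y"], [0.5] * 4),
                "b": dated(["x"] + ["y"] * 3, [0.5] * 4),
                "c": dated(["x"] * 2 + ["y"] * 2, [0.5] * 4)}
        n1, _ = cluster_species(family_profile(tabs))
        reordered = {k: tabs[k] for k in ("c", "a", "b")}
        n2, _ = cluster_species(family_profile(reordered))
        assert n1 == n2

    def test_requires_two_species(self):
        prof = family_profile({"a": dated(["x"], [0.5])})
        with pytest.raises(ValueError):
            cluster_species(prof)


# ---------------------------------------------------------------------------
# pearson
# ---------------------------------------------------------------------------

class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        rho, p = pearson(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_after_centering(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        rho, p = pearson(x, y)
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form(self):
        x = np.array([2.1, 3.3, 1.0, 5.2, 4.4, 2.2, 6.8])
        y = np.array([1.2, 2.9, 0.4, 4.8, 5.0, 2.5, 5.9])
        rho, _ = pearson(x, y)
        # independent brute-force arithmetic
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt((n * (x ** 2).sum() - x.sum() ** 2)
                        * (n * (y ** 2).sum() - y.sum() ** 2))
        assert rho == pytest.approx(num / den, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1, _ = pearson(x, y)
        r2, _ = pearson(y, x)
        assert r1 == r2
        assert -1 <= r1 <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts
# ---------------------------------------------------------------------------

class TestPicContrasts:
    def test_two_leaf_closed_form(self):
        tree = tree_of("(A:2,B:3);")
        c = pic_contrasts(tree, {"A": 10.0, "B": 4.0})
        assert c == pytest.approx([(10 - 4) / math.sqrt(5)])

    def test_constant_trait_gives_zero_contrasts(self):
        tree = tree_of("((A:1,B:1):1,(C:1,D:1):1);")
        assert pic_contrasts(tree, dict.fromkeys("ABCD", 3.3)) == \
            pytest.approx([0, 0, 0])

    def test_four_leaf_hand_worked(self):
        """Hand-executed pruning on a balanced unit-branch tree."""
        tree = tree_of("((A:1,B:1):1,(C:1,D:1):1);")
        c = pic_contrasts(tree, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 5.0})
        # node AB: (1-2)/sqrt(2); value 1.5; branch 1 + 1/2
        # node CD: (3-5)/sqrt(2); value 4.0; branch 1 + 1/2
        # root:    (1.5-4)/sqrt(3)
        expected = [-1 / math.sqrt(2), -2 / math.sqrt(2), -2.5 / math.sqrt(3)]
        assert c == pytest.approx(expected, abs=1e-10)

    def test_missing_trait_rejected(self):
        tree = tree_of("(A:1,B:1);")
        with pytest.raises(ValueError, match="undefined"):
            pic_contrasts(tree, {"A": 1.0})

    def test_polytomy_rejected(self):
        import dendropy
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
        with pytest.raises(ValueError, match="bifurcating"):
            pic_contrasts(tree, {"A": 1, "B": 2, "C": 3})


def vcv_matrix(tree, leaves):
    """Phylogenetic covariance: shared root-to-MRCA path length."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node = leaf
        while node.parent_node is not None:
            chain.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = list(reversed(chain))
    C = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is nb:
                    shared += na.edge.length
                else:
                    break
            C[i, j] = shared
    return C


def gls_correlation(tree, x, y):
    """GLS oracle: correlation under the Brownian covariance structure."""
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    C = vcv_matrix(tree, leaves)
    Ci = np.linalg.inv(C)
    one = np.ones(len(leaves))
    xv = np.array([x[l] for l in leaves])
    yv = np.array([y[l] for l in leaves])
    mx = (one @ Ci @ xv) / (one @ Ci @ one)
    my = (one @ Ci @ yv) / (one @ Ci @ one)
    rx, ry = xv - mx, yv - my
    return (rx @ Ci @ ry) / math.sqrt((rx @ Ci @ rx) * (ry @ Ci @ ry))


class TestPicCorrelation:
    def test_proportional_traits(self):
        tree = tree_of("((A:1,B:2):1,(C:1,D:3):2);")
        x = {"A": 1.0, "B": 4.0, "C": 2.0, "D": 9.0}
        y = {k: 3 * v for k, v in x.items()}
        rho, _ = pic_correlation(tree, x, y)
        assert rho == pytest.approx(1.0)

    @pytest.mark.parametrize("newick", [
        "((A:1,B:1):1,C:2);",
        "((A:1.5,B:0.7):0.6,(C:1.1,D:2.2):0.4);",
        "(((A:1,B:2):1,C:3):1,(D:2,E:1):2);",
        "((((A:1,B:1):1,C:1):1,(D:1,E:1):1):1,F:4);",
    ])
    def test_matches_gls_oracle(self, newick, rng):
        tree = tree_of(newick)
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        x = {l: float(v) for l, v in zip(leaves, rng.normal(size=len(leaves)))}
        y = {l: float(v) for l, v in zip(leaves, rng.normal(size=len(leaves)))}
        rho, _ = pic_correlation(tree, x, y)
        assert rho == pytest.approx(gls_correlation(tree, x, y), abs=1e-10)

    def test_sign_invariance_under_child_swap(self):
        t1 = tree_of("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = tree_of("((B:1,A:1):1,(D:1,C:1):1);")
        x = {"A": 1.0, "B": 2.5, "C": 0.3, "D": 4.0}
        y = {"A": 2.0, "B": 1.5, "C": 3.3, "D": 0.4}
        assert pic_correlation(t1, x, y)[0] == \
            pytest.approx(pic_correlation(t2, x, y)[0], abs=1e-12)

    def test_brownian_recovery(self):
        """Mean recovered contrast correlation ~0.9 over 200 replicates."""
        rng = np.random.default_rng(77)
        true_rho = 0.9
        sigma = np.array([[1.0, true_rho], [true_rho, 1.0]])
        rhos = []
        for _ in range(200):
            tree = random_binary_tree(50, rng)
            x, y = simulate_brownian_traits(tree, sigma, rng)
            rhos.append(pic_correlation(tree, x, y)[0])
        assert np.mean(rhos) == pytest.approx(true_rho, abs=0.05)

    def test_contrasts_standard_normal_under_brownian(self):
        """Standardized contrasts of a unit-rate Brownian trait are N(0,1)."""
        from scipy import stats
        rng = np.random.default_rng(78)
        all_contrasts = []
        for _ in range(40):
            tree = random_binary_tree(30, rng)
            x, _ = simulate_brownian_traits(tree, np.eye(2), rng)
            all_contrasts.extend(pic_contrasts(tree, x))
        _, p = stats.kstest(all_contrasts, "norm")
        assert p > 0.01
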