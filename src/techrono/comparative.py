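"""Cross-species comparative analyses.

Two strands of analysis live here:

* recent-burst LTR family profiling — for each species, the percentage of
  each LTR-RT family among copies dated within a recent window (default the
  last 1 My), log2-transformed and hierarchically clustered to reveal which
  species share recent amplification spectra;
* trait correlations — Pearson correlation of per-species scalars (TE
  content, LTR-RT half-life, genome size), both raw and adjusted for shared
  ancestry with Felsenstein's phylogenetically independent contrasts (PIC).

PIC is implemented directly (post-order pruning): species values are not
independent draws — close relatives resemble each other — and contrasts
restore independence under a Brownian-motion null, at the cost of one
degree of freedom and of forcing the contrast correlation through the
origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, complete, linkage, ward
from scipy.spatial.distance import pdist
from scipy.stats import t as t_dist


# ---------------------------------------------------------------------------
# Family profiles and species clustering
# ---------------------------------------------------------------------------

@dataclass
class FamilyProfile:
    """Per-species family percentages within a recent insertion window."""

    percentages: pd.DataFrame      # species x family, percent
    window_my: float
    log2_matrix: pd.DataFrame      # log2(percent + pseudo)
    pseudo: float


def family_profile(
    dated_tables: Mapping[str, pd.DataFrame],
    window_my: float = 1.0,
    classified_only: bool = True,
    pseudo: Optional[float] = None,
) -> FamilyProfile:
    """Family composition of recently inserted LTR-RTs per species.

    Each input table needs columns ``family`` and ``T`` (years).  Copies
    with T <= window are retained; the percentage of each family is taken
    over the classified copies in the window (or over all windowed copies
    with ``classified_only=False``).  Zero percentages get a pseudo-value
    (half the smallest nonzero entry by default) before the log2 transform.
    """
    window_years = window_my * 1e6
    per_species: dict[str, pd.Series] = {}
    for sp, df in dated_tables.items():
        sub = df[np.isfinite(df["T"]) & (df["T"] <= window_years)]
        if classified_only:
            sub = sub[sub["family"].astype(str) != ""]
        if len(sub) == 0:
            warnings.warn(f"species {sp!r} has no dated copies in the window; excluded")
            continue
        per_species[sp] = 100.0 * sub["family"].value_counts() / len(sub)
    if not per_species:
        raise ValueError("no species with dated copies in the window")
    mat = pd.DataFrame(per_species).T.fillna(0.0).sort_index()
    mat = mat[sorted(mat.columns)]
    if pseudo is None:
        nonzero = mat.values[mat.values > 0]
        pseudo = float(nonzero.min()) / 2.0 if nonzero.size else 1.0
    log2 = np.log2(mat + pseudo)
    return FamilyProfile(percentages=mat, window_my=window_my,
                         log2_matrix=log2, pseudo=pseudo)


_LINKAGES = {"average": average, "complete": complete, "ward": ward}


def cluster_species(profile: FamilyProfile, method: str = "average"
                    ) -> tuple[str, np.ndarray]:
    """Hierarchical clustering of species on the log2 profile matrix.

    Euclidean distance, average linkage by default.  Returns a Newick
    string (branch lengths from merge heights) and the scipy linkage table.
    """
    mat = profile.log2_matrix.sort_index()
    if len(mat) < 2:
        raise ValueError("need at least 2 species to cluster")
    Z = _LINKAGES[method](pdist(mat.values, metric="euclidean"))
    labels = list(mat.index)
    return _linkage_to_newick(Z, labels), Z


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + k] = h
    return node[n + len(Z) - 1] + ";"


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t test (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc ** 2).sum()), np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    rho = float((xc * yc).sum() / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    p = _t_pvalue(rho, n - 2)
    return rho, p


def _t_pvalue(rho: float, df: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    tstat = rho * np.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * t_dist.sf(abs(tstat), df))


# ---------------------------------------------------------------------------
# Phylogenetically independent contrasts
# ---------------------------------------------------------------------------

def _check_tree(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        nch = len(node.child_nodes())
        if nch not in (0, 2):
            raise ValueError("PIC requires a strictly bifurcating tree")
        if node is not tree.seed_node:
            if node.edge.length is None or node.edge.length <= 0:
                raise ValueError("PIC requires positive branch lengths on every edge")


def pic_contrasts(tree: dendropy.Tree, trait: Mapping[str, float]) -> np.ndarray:
    """Standardized independent contrasts by Felsenstein's pruning pass.

    At each internal node with children (x_l, b_l), (x_r, b_r) — child
    values and branch lengths, the latter already extended for estimation
    error below — the contrast is (x_l - x_r)/sqrt(b_l + b_r); the node's
    value is the 1/b-weighted average of the children and its own parent
    branch is extended by b_l*b_r/(b_l + b_r).  Returns the n-1 contrasts
    in post-order.
    """
    _check_tree(tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in trait]
    if missing:
        raise ValueError(f"trait undefined for leaves: {sorted(missing)}")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")

    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[float] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            values[id(node)] = float(trait[node.taxon.label])
            lengths[id(node)] = float(node.edge.length or 0.0)
        else:
            left, right = node.child_nodes()
            xl, xr = values[id(left)], values[id(right)]
            bl, br = lengths[id(left)], lengths[id(right)]
            contrasts.append((xl - xr) / np.sqrt(bl + br))
            values[id(node)] = (xl / bl + xr / br) / (1.0 / bl + 1.0 / br)
            own = float(node.edge.length or 0.0)
            lengths[id(node)] = own + bl * br / (bl + br)
    return np.asarray(contrasts)


def pic_correlation(tree: dendropy.Tree, trait_x: Mapping[str, float],
                    trait_y: Mapping[str, float]) -> tuple[float, float]:
    """Correlation of two traits via independent contrasts.

    The contrast vectors have no meaningful mean direction (each contrast's
    sign depends on an arbitrary left/right choice), so the correlation is
    taken through the origin: rho = sum(uv)/sqrt(sum(u^2) sum(v^2)), with a
    two-sided t test on n-2 df for n-1 contrasts.
    """
    u = pic_contrasts(tree, trait_x)
    v = pic_contrasts(tree, trait_y)
    su, sv = np.sqrt((u ** 2).sum()), np.sqrt((v ** 2).sum())
    if su == 0 or sv == 0:
        raise ValueError("zero-variance contrasts")
    rho = float((u * v).sum() / (su * sv))
    rho = max(-1.0, min(1.0, rho))
    df = len(u) - 1  # n taxa -> n-1 contrasts -> n-2 df
    return rho, _t_pvalue(rho, df)
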