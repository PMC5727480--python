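"""Phylogenetic independent contrasts and morphospace axis correlations.

Felsenstein's contrasts remove the expected covariance among tip values
induced by shared ancestry under Brownian motion: each internal node of a
binary dated tree yields one standardized contrast (x1 - x2)/sqrt(b1 + b2),
the node is assigned the branch-length-weighted average of its daughters,
and its own branch is lengthened by b1*b2/(b1 + b2).  Contrast vectors are
correlated *through the origin* (contrasts have an arbitrary sign and zero
expectation), and |r| is reported alongside r because ordination axis
orientations are themselves arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import Phylogeny
from .ordination import OrdinationResult

__all__ = ["ContrastSet", "pic", "axis_correlations"]


@dataclass
class ContrastSet:
    contrasts: np.ndarray  # (n_tips - 1,) standardized contrasts
    node_clades: list  # frozenset of tip labels per contrast, same order


def pic(tree: Phylogeny, tip_values: dict) -> ContrastSet:
    """Standardized independent contrasts for one variable.

    ``tip_values`` maps every tip label to a scalar.  The tree must be
    binary with positive branch lengths.
    """
    work = tree.clone()
    vals: dict = {}
    lens: dict = {}
    clades: dict = {}
    contrasts, order = [], []
    for node in work.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_values:
                raise KeyError(f"missing tip value for {label!r}")
            vals[node] = float(tip_values[label])
            lens[node] = node.edge.length if node.edge.length is not None else 0.0
            clades[node] = frozenset([label])
            if lens[node] <= 0 and node.parent_node is not None:
                raise ValueError("PIC requires positive branch lengths")
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError("PIC requires a fully binary tree")
        c1, c2 = kids
        b1, b2 = lens[c1], lens[c2]
        contrasts.append((vals[c1] - vals[c2]) / np.sqrt(b1 + b2))
        clades[node] = clades[c1] | clades[c2]
        order.append(clades[node])
        vals[node] = (vals[c1] / b1 + vals[c2] / b2) / (1.0 / b1 + 1.0 / b2)
        own = node.edge.length if node.edge.length is not None else 0.0
        lens[node] = own + b1 * b2 / (b1 + b2)
    return ContrastSet(contrasts=np.array(contrasts), node_clades=order)


def _origin_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation through the origin with its t-test p-value."""
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return np.nan, np.nan
    r = float((x * y).sum() / denom)
    n = len(x)
    df = n - 1
    if df < 1 or abs(r) >= 1:
        return r, 0.0 if abs(r) >= 1 else np.nan
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def axis_correlations(
    pc_scores: OrdinationResult,
    pco_scores: OrdinationResult,
    tree: Phylogeny,
    k: int,
    through_origin: bool = True,
):
    """Per-axis Pearson correlation of contrast-transformed scores.

    Axis pairing is positional (PC1 with PCo1 and so on, up to ``k``).
    Returns a list of dicts with axis, r, abs_r and p.
    """
    if set(pc_scores.taxa) != set(pco_scores.taxa):
        raise ValueError("the two score sets must cover the same taxa")
    if k > pc_scores.scores.shape[1] or k > pco_scores.scores.shape[1]:
        raise ValueError(f"k={k} exceeds available axes")
    out = []
    for i in range(k):
        xv = {t: pc_scores.scores[pc_scores.taxa.index(t), i] for t in pc_scores.taxa}
        yv = {t: pco_scores.scores[pco_scores.taxa.index(t), i] for t in pco_scores.taxa}
        cx = pic(tree, xv)
        cy = pic(tree, yv)
        x, y = cx.contrasts, cy.contrasts
        if through_origin:
            r, p = _origin_correlation(x, y)
        else:
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
        out.append({"axis": i + 1, "r": float(r), "abs_r": float(abs(r)), "p": float(p)})
    return out
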