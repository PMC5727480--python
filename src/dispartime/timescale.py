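"""Node-age calibration from stratigraphically consistent outgroup ages.

The root (and, recursively, every internal node) is dated with the
outgroup-based Bayesian approach of Hedman as extended to whole trees by
Lloyd and colleagues: given the first-appearance ages of successively more
distant outgroups, each successive divergence is taken to be uniformly
distributed between the previous (older) divergence and the outgroup's own
age, and the node age itself is uniform between the last divergence and the
oldest age of the node's descendants.  The resulting posterior is computed
exactly on a discretized age grid, so convergence can be checked by
refining the grid.

Joint tree calibration draws node ages in preorder: each node's posterior
is evaluated once (anchored at the mean of its parent's sampled ages; the
root at the user's maximum-age constraint) and each draw is taken from that
posterior truncated at the parent's drawn age, which guarantees
stratigraphic consistency (parent >= child) in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Phylogeny, TaxonRecord
from .stages import make_bins  # noqa: F401  (re-exported: binning lives with the chart)

__all__ = ["AgeDistribution", "AgePosterior", "hedman_node_age", "calibrate_tree", "make_bins"]


@dataclass
class AgeDistribution:
    """Discretized age distribution on an ascending grid (Ma)."""

    grid: np.ndarray  # ascending ages, node_min .. t_max
    mass: np.ndarray  # probability mass per grid point, sums to 1

    @property
    def mean(self) -> float:
        return float(self.grid @ self.mass)

    def sample(self, rng: np.random.Generator, upper: float | None = None) -> float:
        """Inverse-CDF draw, optionally truncated to ages <= ``upper``."""
        cdf = np.cumsum(self.mass)
        if upper is None:
            total = cdf[-1]
            hi = len(self.grid) - 1
        else:
            hi = int(np.searchsorted(self.grid, upper, side="right")) - 1
            if hi < 0:
                return float(upper)  # no mass at or below the bound: clamp
            total = cdf[hi]
            if total <= 0:
                return float(min(upper, self.grid[0]))
        u = rng.random() * total
        idx = int(np.searchsorted(cdf[: hi + 1], u, side="left"))
        return float(self.grid[min(idx, hi)])


def _spread_uniform(mass: np.ndarray, grid: np.ndarray, lower: float) -> np.ndarray:
    """Propagate one uniform-divergence step on the grid.

    Mass at grid point k is spread uniformly over grid points in
    [lower, grid[k]]; mass already below ``lower`` collapses onto the
    nearest grid point at ``lower``.
    """
    n = len(grid)
    i_lo = int(np.searchsorted(grid, lower, side="left"))
    i_lo = min(i_lo, n - 1)
    out = np.zeros(n)
    # mass below the admissible window piles up at its floor
    below = mass[:i_lo].sum()
    out[i_lo] += below
    counts = np.arange(n) - i_lo + 1  # points in [lower, grid[k]] for k >= i_lo
    q = np.zeros(n)
    valid = np.arange(n) >= i_lo
    q[valid] = mass[valid] / counts[valid]
    # out[j] = sum_{k >= j} q[k] for j >= i_lo
    suffix = np.cumsum(q[::-1])[::-1]
    out[i_lo:] += suffix[i_lo:]
    return out


def hedman_node_age(
    outgroup_ages,
    node_min_age: float,
    t_max: float,
    grid_resolution: int = 1000,
) -> AgeDistribution:
    """Posterior age distribution of a node from successive outgroup ages.

    ``outgroup_ages`` are ordered oldest (most distant outgroup) to youngest
    (sister group).  The posterior lives on [node_min_age, t_max].
    """
    if t_max < node_min_age:
        raise ValueError(f"t_max ({t_max}) < node minimum age ({node_min_age})")
    ages = [float(a) for a in outgroup_ages]
    if not all(np.isfinite(ages)) or not np.isfinite([node_min_age, t_max]).all():
        raise ValueError("ages must be finite")
    if t_max == node_min_age:
        return AgeDistribution(grid=np.array([t_max]), mass=np.array([1.0]))
    grid = np.linspace(node_min_age, t_max, max(int(grid_resolution), 2))
    mass = np.zeros_like(grid)
    mass[-1] = 1.0  # anchor: the chain starts at the maximum-age constraint
    for a in ages:
        mass = _spread_uniform(mass, grid, max(a, node_min_age))
    mass = _spread_uniform(mass, grid, node_min_age)  # final step: the node itself
    mass = mass / mass.sum()
    return AgeDistribution(grid=grid, mass=mass)


@dataclass
class AgePosterior:
    """Sampled node ages keyed by the node's descendant tip-label set."""

    draws: dict  # frozenset[str] -> np.ndarray of sampled ages (Ma)
    mean_ages: dict  # frozenset[str] -> float


def _clade_labels(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def check_outgroup_consistency(outgroups) -> None:
    """Outgroup ages must be non-increasing from most distant to sister."""
    for (n1, a1), (n2, a2) in zip(outgroups, outgroups[1:]):
        if a2 > a1:
            raise ValueError(
                f"outgroups stratigraphically inconsistent: {n2!r} ({a2} Ma) is "
                f"older than the more distant {n1!r} ({a1} Ma)"
            )


def calibrate_tree(
    tree: Phylogeny,
    taxa: list[TaxonRecord],
    outgroups,
    root_max: float,
    n_draws: int = 1000,
    seed: int | None = None,
    grid_resolution: int = 500,
) -> tuple[Phylogeny, AgePosterior]:
    """Date every internal node of ``tree`` and return the mean-age tree.

    ``outgroups`` is an ordered list of (name, age Ma) pairs, most distant
    first; tips are placed at their taxon's first appearance (FAD).  Node
    ages for each internal node are drawn jointly root-to-tips (parent >=
    child in every draw); the returned tree carries per-node mean ages,
    clamped where averaging would violate stratigraphic order, and branch
    lengths equal to parent-minus-child age.
    """
    outgroups = list(outgroups)
    check_outgroup_consistency(outgroups)
    rng = np.random.default_rng(seed)
    fad = {r.name: r.fad for r in taxa}
    dated = tree.clone()
    for leaf in dated.tree.leaf_node_iter():
        if leaf.taxon.label not in fad:
            raise KeyError(f"no stratigraphic record for tip {leaf.taxon.label!r}")
        leaf.age_ma = fad[leaf.taxon.label]

    # oldest descendant FAD per node
    min_age: dict = {}
    for node in dated.tree.postorder_node_iter():
        if node.is_leaf():
            min_age[node] = node.age_ma
        else:
            min_age[node] = max(min_age[c] for c in node.child_nodes())

    external_ages = [a for (_n, a) in outgroups]
    draws: dict = {}
    node_draws: dict = {}
    for node in dated.tree.preorder_internal_node_iter():
        # successive outgroup ages: external outgroups, then the oldest FAD
        # of the sister clade at each ancestor, root-side first
        candidates = list(external_ages)
        lineage = []
        anc = node
        while anc.parent_node is not None:
            p = anc.parent_node
            sisters = [c for c in p.child_nodes() if c is not anc]
            lineage.append(max(min_age[s] for s in sisters))
            anc = p
        candidates.extend(reversed(lineage))
        # keep the stratigraphically consistent (non-increasing) subsequence
        seq, floor = [], np.inf
        for a in candidates:
            if a <= floor:
                seq.append(a)
                floor = a
        if node.parent_node is None:
            t_anchor = float(root_max)
            parent_draws = None
        else:
            parent_draws = node_draws[node.parent_node]
            t_anchor = float(np.mean(parent_draws))
        post = hedman_node_age(seq, min_age[node], t_anchor, grid_resolution)
        if parent_draws is None:
            samples = np.array([post.sample(rng) for _ in range(n_draws)])
        else:
            samples = np.array(
                [post.sample(rng, upper=parent_draws[d]) for d in range(n_draws)]
            )
        node_draws[node] = samples
        draws[_clade_labels(node)] = samples

    # mean-age tree, clamped to remain stratigraphically consistent
    mean_ages: dict = {}
    for node in dated.tree.preorder_internal_node_iter():
        m = float(np.mean(node_draws[node]))
        if node.parent_node is not None:
            m = min(m, node.parent_node.age_ma)
        m = max(m, min_age[node])
        node.age_ma = m
        mean_ages[_clade_labels(node)] = m
    dated.branch_lengths_from_ages()
    return dated, AgePosterior(draws=draws, mean_ages=mean_ages)
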