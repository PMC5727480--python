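"""Time-binned diversity and disparity, ghost-lineage imputation and
clade-shape (center of gravity) statistics.

Disparity of the taxa occupying a time bin is measured on ordination
scores as the sum of per-axis sample variances (dispersion) or per-axis
ranges (morphospace extent).  Ghost lineages — branches of the dated tree
crossing a bin midpoint without a sampled taxon in that bin — can be
added as pseudo-taxa whose scores are inferred under Brownian motion:
ancestral values are maximum-likelihood estimates (per axis) and each
crossing branch is evaluated at the bin midpoint by linear interpolation
in time.  The scaled center of gravity (CGS) of a disparity profile
locates the profile's mass on the clade's [0, 1] time axis; the null
expectation is the CG of a flat profile over the same bins, which absorbs
unequal bin durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .datamodel import Phylogeny, TaxonRecord, TimeBinSet
from .ordination import OrdinationResult

__all__ = [
    "BinMembership",
    "DisparityProfile",
    "CgsResult",
    "assign_bins",
    "sum_of_variances",
    "sum_of_ranges",
    "bootstrap_disparity",
    "estimate_ancestral_states",
    "ghost_lineage_scores",
    "phylogenetic_diversity",
    "disparity_profile",
    "cgs",
    "cgs_significance",
    "diet_counts",
    "convex_hull_areas",
]


# ----------------------------------------------------------- membership

@dataclass
class BinMembership:
    members: dict  # bin name -> set of taxon names
    excluded: list = field(default_factory=list)

    def counts(self) -> dict:
        return {b: len(m) for b, m in self.members.items()}


def assign_bins(taxa: list[TaxonRecord], bins: TimeBinSet) -> BinMembership:
    """Overlap-based bin membership; a range-through taxon joins every bin
    it spans, and a point occurrence on a boundary joins the older bin."""
    members = {b.name: set() for b in bins}
    excluded = []
    for rec in taxa:
        hit = False
        for b in bins:
            if b.overlaps_range(rec.fad, rec.lad):
                members[b.name].add(rec.name)
                hit = True
        if not hit:
            excluded.append(rec.name)
    return BinMembership(members=members, excluded=excluded)


# -------------------------------------------------------------- metrics

def _rows(scores: OrdinationResult, members, axes) -> np.ndarray:
    idx = {t: i for i, t in enumerate(scores.taxa)}
    rows = [idx[t] for t in sorted(members)]
    cols = _axis_selection(scores, axes)
    return scores.scores[np.ix_(rows, cols)]


def _axis_selection(scores: OrdinationResult, axes) -> np.ndarray:
    if axes is None:
        return np.arange(scores.n_positive_axes)
    if np.isscalar(axes):
        return np.arange(int(axes))
    return np.asarray(list(axes), dtype=int)


def _sov(arr: np.ndarray) -> float:
    if arr.shape[0] < 2:
        return np.nan
    return float(arr.var(axis=0, ddof=1).sum())


def _sor(arr: np.ndarray) -> float:
    if arr.shape[0] < 1:
        return np.nan
    return float((arr.max(axis=0) - arr.min(axis=0)).sum())


_METRICS = {"sov": _sov, "sor": _sor}


def sum_of_variances(scores: OrdinationResult, members, axes=None) -> float:
    """Sum over axes of the n-1 sample variance of member scores.
    NaN (flagged undefined) for fewer than two members."""
    return _sov(_rows(scores, members, axes))


def sum_of_ranges(scores: OrdinationResult, members, axes=None) -> float:
    """Sum over axes of max-minus-min of member scores."""
    return _sor(_rows(scores, members, axes))


def bootstrap_disparity(
    scores: OrdinationResult,
    members,
    metric: str = "sov",
    n_boot: int = 1000,
    seed: int | None = None,
    axes=None,
) -> tuple[float, float, float]:
    """Taxon bootstrap percentile CI for one bin.

    Returns (point estimate, 2.5% bound, 97.5% bound); members are
    resampled with replacement within the bin.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    arr = _rows(scores, members, axes)
    fn = _METRICS[metric]
    point = fn(arr)
    rng = np.random.default_rng(seed)
    n = arr.shape[0]
    reps = np.array([fn(arr[rng.integers(n, size=n)]) for _ in range(n_boot)])
    reps = reps[~np.isnan(reps)]
    if reps.size == 0:
        return point, np.nan, np.nan
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, float(lo), float(hi)


# ---------------------------------------------- ghost-lineage imputation

def estimate_ancestral_states(tree: Phylogeny, tip_values: dict) -> dict:
    """Maximum-likelihood Brownian-motion ancestral values at internal nodes.

    ``tip_values`` maps tip label -> scalar or 1-D array (axes treated
    independently).  The ML states minimize the sum over edges of
    (difference)^2 / branch length, i.e. they solve the linear system in
    which every internal value is the branch-length-weighted harmonic
    average of its neighbors.  Requires positive branch lengths.
    """
    internal = [n for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    index = {n: i for i, n in enumerate(internal)}
    k = len(internal)
    first = next(iter(tip_values.values()))
    naxes = np.atleast_1d(np.asarray(first, float)).shape[0]
    A = np.zeros((k, k))
    B = np.zeros((k, naxes))

    def wlen(node) -> float:
        L = node.edge.length
        if L is None or L <= 0:
            raise ValueError("ancestral-state estimation requires positive branch lengths")
        return L

    for node in internal:
        i = index[node]
        neighbors = list(node.child_nodes())
        if node.parent_node is not None:
            neighbors.append(node.parent_node)
        for nb in neighbors:
            w = 1.0 / wlen(nb if nb is not node.parent_node else node)
            A[i, i] += w
            if nb.is_leaf():
                B[i] += w * np.atleast_1d(np.asarray(tip_values[nb.taxon.label], float))
            else:
                A[i, index[nb]] -= w
    x = np.linalg.solve(A, B)
    out = {}
    for node, i in index.items():
        out[node] = x[i] if naxes > 1 else float(x[i, 0])
    return out


@dataclass
class AugmentedBin:
    """Real members plus ghost pseudo-taxa of one time bin."""

    names: list[str]
    scores: np.ndarray  # (n, axes)
    is_ghost: np.ndarray  # bool flags, parallel to names

    @property
    def n_real(self) -> int:
        return int((~self.is_ghost).sum())


def ghost_lineage_scores(
    dated_tree: Phylogeny,
    scores: OrdinationResult,
    bins: TimeBinSet,
    taxa: list[TaxonRecord] | None = None,
    axes=None,
) -> dict:
    """Per-bin score sets augmented with ghost-lineage pseudo-taxa.

    A branch contributes a pseudo-taxon to a bin when it spans the bin
    midpoint and carries no taxon sampled in that bin; its score vector is
    the linear time interpolation between the BM estimates (or tip values)
    at its two ends.  Pseudo-taxa are flagged and never counted as real
    diversity.  Returns {bin name: AugmentedBin}.
    """
    if not dated_tree.has_ages():
        raise ValueError("tree must be dated (node ages set)")
    cols = _axis_selection(scores, axes)
    idx = {t: i for i, t in enumerate(scores.taxa)}
    tip_vals = {t: scores.scores[idx[t], cols] for t in dated_tree.taxon_labels}
    work = dated_tree.clone()
    work.branch_lengths_from_ages()
    work.perturb_zero_branches()
    anc = estimate_ancestral_states(work, tip_vals)

    records = taxa or [
        TaxonRecord(name=t, fad=getattr_leaf_age(work, t), lad=getattr_leaf_age(work, t))
        for t in work.taxon_labels
    ]
    membership = assign_bins(records, bins)

    out = {}
    for b in bins:
        mid = b.midpoint
        names, vecs, flags = [], [], []
        for t in sorted(membership.members[b.name]):
            names.append(t)
            vecs.append(np.atleast_1d(tip_vals[t]))
            flags.append(False)
        gi = 0
        for node in work.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            ap = node.parent_node.age_ma
            ac = node.age_ma
            if not (ap > mid >= ac):
                continue
            if node.is_leaf():
                label = node.taxon.label
                if label in membership.members[b.name]:
                    continue  # sampled in this bin: real score already in
                end_val = np.atleast_1d(tip_vals[label])
            else:
                end_val = np.atleast_1d(anc[node])
            start_val = np.atleast_1d(anc[node.parent_node])
            frac = (ap - mid) / (ap - ac) if ap > ac else 0.0
            names.append(f"ghost_{b.name}_{gi}")
            vecs.append(start_val + frac * (end_val - start_val))
            flags.append(True)
            gi += 1
        out[b.name] = AugmentedBin(
            names=names,
            scores=np.array(vecs) if vecs else np.empty((0, len(cols))),
            is_ghost=np.array(flags, dtype=bool),
        )
    return out


def getattr_leaf_age(tree: Phylogeny, label: str) -> float:
    for leaf in tree.tree.leaf_node_iter():
        if leaf.taxon.label == label:
            return leaf.age_ma
    raise KeyError(label)


def phylogenetic_diversity(
    dated_tree: Phylogeny, bins: TimeBinSet, taxa: list[TaxonRecord] | None = None
) -> dict:
    """Lineage count (sampled + ghost) crossing each bin midpoint.

    Tip lineages persist to their LAD when ranges are supplied, otherwise
    to the tip age.  Midpoints older than the root count the single stem
    lineage.
    """
    if not dated_tree.has_ages():
        raise ValueError("tree must be dated (node ages set)")
    lads = {r.name: r.lad for r in (taxa or [])}
    root_age = dated_tree.tree.seed_node.age_ma
    out = {}
    for b in bins:
        mid = b.midpoint
        if mid >= root_age:
            out[b.name] = 1
            continue
        n = 0
        for node in dated_tree.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            ap = node.parent_node.age_ma
            if node.is_leaf():
                end = min(node.age_ma, lads.get(node.taxon.label, node.age_ma))
            else:
                end = node.age_ma
            if ap > mid >= end:
                n += 1
        out[b.name] = n
    return out


# -------------------------------------------------------------- profile

@dataclass
class DisparityProfile:
    bins: TimeBinSet
    metric: str
    values: np.ndarray  # per bin; NaN where undefined
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_taxa: np.ndarray
    includes_ghosts: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bins.names,
                "start_ma": [b.start for b in self.bins],
                "end_ma": [b.end for b in self.bins],
                "metric": self.metric,
                "value": self.values,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "n": self.n_taxa,
                "ghosts": self.includes_ghosts,
            }
        )


def disparity_profile(
    scores: OrdinationResult,
    taxa: list[TaxonRecord],
    bins: TimeBinSet,
    metric: str = "sov",
    axes=None,
    ghost_sets: dict | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DisparityProfile:
    """Per-bin disparity with bootstrap CIs, optionally ghost-augmented."""
    fn = _METRICS[metric]
    rng = np.random.default_rng(seed)
    vals, los, his, ns = [], [], [], []
    membership = assign_bins(taxa, bins)
    for b in bins:
        if ghost_sets is not None:
            aug = ghost_sets[b.name]
            arr = aug.scores
            n_taxa = len(aug.names)
        else:
            mem = membership.members[b.name]
            arr = _rows(scores, mem, axes)
            n_taxa = len(mem)
        v = fn(arr) if arr.shape[0] else np.nan
        if arr.shape[0]:
            reps = np.array(
                [
                    fn(arr[rng.integers(arr.shape[0], size=arr.shape[0])])
                    for _ in range(n_boot)
                ]
            )
            reps = reps[~np.isnan(reps)]
            lo, hi = (np.percentile(reps, [2.5, 97.5]) if reps.size else (np.nan, np.nan))
        else:
            lo = hi = np.nan
        vals.append(v)
        los.append(lo)
        his.append(hi)
        ns.append(n_taxa)
    return DisparityProfile(
        bins=bins,
        metric=metric,
        values=np.array(vals),
        ci_lower=np.array(los, dtype=float),
        ci_upper=np.array(his, dtype=float),
        n_taxa=np.array(ns),
        includes_ghosts=ghost_sets is not None,
    )


# ------------------------------------------------------------------ CGS

@dataclass
class CgsResult:
    cgs: float
    null_expectation: float
    p_value: float | None = None
    n_boot: int = 0
    boot_values: np.ndarray | None = None


def _scaled_midpoints(bins: TimeBinSet, occupied: np.ndarray) -> np.ndarray:
    occ = [b for b, o in zip(bins, occupied) if o]
    t0 = occ[0].start
    t1 = occ[-1].end
    span = t0 - t1
    if span <= 0:
        raise ValueError("degenerate clade time axis")
    return np.array([(t0 - b.midpoint) / span for b in occ])


def cgs(values, bins: TimeBinSet) -> CgsResult:
    """Scaled center of gravity of a disparity profile.

    The clade time axis runs 0 (start of the oldest bin with defined
    disparity) to 1 (end of the youngest); CG = sum(d*t)/sum(d) at bin
    midpoints.  The null expectation is the CG of a flat profile over the
    same bins, exactly 0.5 for equal-length bins.
    """
    values = np.asarray(values, float)
    occupied = ~np.isnan(values)
    if occupied.sum() < 3:
        raise ValueError("CGS needs at least 3 bins with defined disparity")
    d = values[occupied]
    if np.all(d == 0):
        raise ValueError("all-zero disparity profile")
    t = _scaled_midpoints(bins, occupied)
    cg = float((d * t).sum() / d.sum())
    null = float(t.mean())
    return CgsResult(cgs=cg, null_expectation=null)


def cgs_significance(
    scores: OrdinationResult,
    taxa: list[TaxonRecord],
    bins: TimeBinSet,
    metric: str = "sov",
    axes=None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> CgsResult:
    """Taxon-bootstrap two-tailed test of CGS against the flat-profile null.

    Taxa are resampled with replacement within each bin, the profile and
    its CGS recomputed per replicate, and the p-value is the two-tailed
    percentile position of the null expectation in the bootstrap CGS
    distribution.
    """
    fn = _METRICS[metric]
    membership = assign_bins(taxa, bins)
    base_arrays = []
    for b in bins:
        arr = _rows(scores, membership.members[b.name], axes)
        base_arrays.append(arr)
    base_vals = np.array([fn(a) if a.shape[0] else np.nan for a in base_arrays])
    point = cgs(base_vals, bins)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        vals = []
        for arr in base_arrays:
            n = arr.shape[0]
            vals.append(fn(arr[rng.integers(n, size=n)]) if n else np.nan)
        try:
            boots.append(cgs(np.array(vals), bins).cgs)
        except ValueError:
            continue
    boots = np.array(boots)
    if boots.size == 0:
        p = None
    else:
        frac_le = float((boots <= point.null_expectation).mean())
        frac_ge = float((boots >= point.null_expectation).mean())
        p = min(1.0, 2.0 * min(frac_le, frac_ge))
    return CgsResult(
        cgs=point.cgs,
        null_expectation=point.null_expectation,
        p_value=p,
        n_boot=n_boot,
        boot_values=boots,
    )


# ----------------------------------------------------- diets and hulls

def diet_counts(taxa: list[TaxonRecord], bins: TimeBinSet) -> pd.DataFrame:
    """Contingency table bins x diet categories (row order = bin order)."""
    membership = assign_bins(taxa, bins)
    diets = {r.name: r.diet for r in taxa}
    cats = ["carnivore", "omnivore", "herbivore", "unknown"]
    data = {c: [] for c in cats}
    for b in bins:
        mem = membership.members[b.name]
        for c in cats:
            data[c].append(sum(1 for t in mem if diets[t] == c))
    df = pd.DataFrame(data, index=bins.names)
    if df["unknown"].sum() == 0:
        df = df.drop(columns=["unknown"])
    return df


def convex_hull_areas(
    scores: OrdinationResult, groups: dict, axes=(0, 1)
) -> tuple[dict, dict]:
    """2-D convex hull area per group and pairwise overlap areas.

    ``groups`` maps taxon name -> group label.  Groups with fewer than 3
    distinct points yield degenerate hulls of area 0.  Returns
    (areas, overlaps) with overlaps keyed by sorted label pairs.
    """
    idx = {t: i for i, t in enumerate(scores.taxa)}
    ax = list(axes)
    hulls = {}
    for label in sorted(set(groups.values())):
        pts = [
            tuple(scores.scores[idx[t], ax])
            for t, g in groups.items()
            if g == label and t in idx
        ]
        hulls[label] = MultiPoint(pts).convex_hull if pts else MultiPoint([]).convex_hull
    areas = {g: float(h.area) for g, h in hulls.items()}
    overlaps = {}
    labels = sorted(hulls)
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            overlaps[(g1, g2)] = float(hulls[g1].intersection(hulls[g2]).area)
    return areas, overlaps
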