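"""Parsimony: Fitch and Farris tree lengths, ensemble fit indices,
random-addition heuristic search with branch swapping, and symmetric
resampling node support.

Unordered discrete characters are optimized with Fitch's set-intersection
downpass; cells are state sets, so polymorphism and missing data enter as
set-valued tips (missing = the universal set).  Continuous characters are
treated as additive and optimized with the Farris interval downpass: the
minimal total change is the sum of interval gaps accumulated while merging
children ranges.  Both downpasses are vectorized across characters, which
keeps full-matrix tree evaluation cheap enough for swap-based searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .datamodel import ContinuousMatrix, DiscreteMatrix, Phylogeny

__all__ = [
    "ParsimonyFit",
    "SupportTable",
    "SearchResult",
    "fitch_length",
    "fitch_steps_per_character",
    "farris_length",
    "fit_indices",
    "heuristic_search",
    "symmetric_resampling",
]


# ------------------------------------------------------------------
# internal light-weight tree used for scoring and search
# ------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "parent", "tip")

    def __init__(self, tip: int | None = None):
        self.children: list[_Node] = []
        self.parent: _Node | None = None
        self.tip = tip

    def add(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)


def _postorder(root: _Node) -> list[_Node]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    out.reverse()
    return out


def _phylo_to_nodes(tree: Phylogeny, taxon_index: dict[str, int]) -> _Node:
    def build(dnode):
        kids = dnode.child_nodes()
        if not kids:
            label = dnode.taxon.label
            if label not in taxon_index:
                raise KeyError(f"tip {label!r} absent from matrix")
            return _Node(tip=taxon_index[label])
        node = _Node()
        for k in kids:
            node.add(build(k))
        return node

    root = build(tree.tree.seed_node)
    # a trifurcating root is a rooting artifact of an unrooted newick:
    # binarize it (the unrooted topology, hence the length, is unchanged)
    while len(root.children) > 2:
        a = root.children.pop()
        b = root.children.pop()
        inner = _Node()
        inner.add(a)
        inner.add(b)
        root.add(inner)
    for node in _postorder(root):
        if node.children and len(node.children) != 2:
            raise ValueError("tree must be binary (apart from the root trifurcation)")
    return root


def _nodes_to_newick(root: _Node, labels: list[str]) -> str:
    def rec(n: _Node) -> str:
        if n.tip is not None:
            return labels[n.tip]
        return "(" + ",".join(rec(c) for c in n.children) + ")"

    return rec(root) + ";"


def _canonical_topology(root: _Node, labels: list[str]) -> str:
    def rec(n: _Node) -> str:
        if n.tip is not None:
            return labels[n.tip]
        parts = sorted(rec(c) for c in n.children)
        return "(" + ",".join(parts) + ")"

    return rec(root)


# ------------------------------------------------------------------
# character encodings
# ------------------------------------------------------------------

def _encode_discrete(m: DiscreteMatrix) -> np.ndarray:
    """ntax x nchar uint64 bitmasks; missing cells get the universal mask."""
    masks = np.zeros((m.ntax, m.nchar), dtype=np.uint64)
    full = np.zeros(m.nchar, dtype=np.uint64)
    for j in range(m.nchar):
        obs = m.observed_states(j)
        bits = 0
        for s in obs:
            if s >= 63:
                raise ValueError("more than 63 states are not supported")
            bits |= 1 << s
        full[j] = bits if bits else 1
    for i, row in enumerate(m.states):
        for j, cell in enumerate(row):
            if cell is None:
                masks[i, j] = full[j]
            else:
                bits = 0
                for s in cell:
                    bits |= 1 << s
                masks[i, j] = bits
    return masks


def _encode_continuous(m: ContinuousMatrix) -> tuple[np.ndarray, np.ndarray]:
    lo = np.where(np.isnan(m.values), -np.inf, m.values)
    hi = np.where(np.isnan(m.values), np.inf, m.values)
    return lo, hi


# ------------------------------------------------------------------
# downpass scoring
# ------------------------------------------------------------------

def _fitch_downpass(root: _Node, tipmasks: np.ndarray, per_char: bool = False):
    """Fitch steps; returns (steps, node->mask dict).  ``steps`` is the
    per-character vector if ``per_char`` else the weighted-sum-ready vector
    summed to a scalar by the caller."""
    nchar = tipmasks.shape[1]
    steps = np.zeros(nchar, dtype=np.int64)
    masks: dict[_Node, np.ndarray] = {}
    for node in _postorder(root):
        if node.tip is not None:
            masks[node] = tipmasks[node.tip]
        else:
            a, b = (masks[c] for c in node.children)
            inter = a & b
            union = a | b
            nz = inter == 0
            steps += nz
            masks[node] = np.where(nz, union, inter)
    return (steps, masks)


def _farris_downpass(root: _Node, lo: np.ndarray, hi: np.ndarray):
    """Farris interval downpass for additive continuous characters.

    Returns (per-character cost vector, node interval dicts)."""
    nchar = lo.shape[1]
    cost = np.zeros(nchar, dtype=float)
    ivlo: dict[_Node, np.ndarray] = {}
    ivhi: dict[_Node, np.ndarray] = {}
    for node in _postorder(root):
        if node.tip is not None:
            ivlo[node] = lo[node.tip]
            ivhi[node] = hi[node.tip]
        else:
            c1, c2 = node.children
            a = np.maximum(ivlo[c1], ivlo[c2])
            b = np.minimum(ivhi[c1], ivhi[c2])
            gap = a - b
            cost += np.where(gap > 0, gap, 0.0)
            ivlo[node] = np.minimum(a, b)
            ivhi[node] = np.maximum(a, b)
    return cost, (ivlo, ivhi)


# ------------------------------------------------------------------
# public scoring API
# ------------------------------------------------------------------

def fitch_steps_per_character(tree: Phylogeny, m: DiscreteMatrix) -> np.ndarray:
    """Per-character Fitch step counts of ``tree`` on ``m``."""
    taxon_index = {t: i for i, t in enumerate(m.taxa)}
    root = _phylo_to_nodes(tree, taxon_index)
    steps, _ = _fitch_downpass(root, _encode_discrete(m))
    return steps


def fitch_length(tree: Phylogeny, m: DiscreteMatrix) -> int:
    """Total unordered-parsimony length of ``tree`` on ``m``."""
    return int(fitch_steps_per_character(tree, m).sum())


def farris_length(tree: Phylogeny, m: ContinuousMatrix) -> float:
    """Total additive length for continuous characters (Farris intervals)."""
    taxon_index = {t: i for i, t in enumerate(m.taxa)}
    root = _phylo_to_nodes(tree, taxon_index)
    lo, hi = _encode_continuous(m)
    cost, _ = _farris_downpass(root, lo, hi)
    return float(cost.sum())


# ------------------------------------------------------------------
# ensemble fit indices
# ------------------------------------------------------------------

@dataclass
class ParsimonyFit:
    length: float
    s: np.ndarray  # observed steps per character
    m: np.ndarray  # minimum possible steps
    g: np.ndarray  # maximum (star-tree) steps
    ci: float | None
    hi: float | None
    ri: float | None
    ri_defined: bool = True


def _min_steps(cells: list[frozenset]) -> int:
    """Minimum steps over any tree: (size of the smallest state set hitting
    every scored cell) - 1.  Polymorphic cells are satisfied by any of
    their states."""
    if not cells:
        return 0
    forced = {next(iter(c)) for c in cells if len(c) == 1}
    rest = [c for c in cells if not (c & forced)]
    if not rest:
        return max(0, len(forced) - 1)
    candidates = sorted(set().union(*rest))
    for k in range(1, len(candidates) + 1):
        for extra in combinations(candidates, k):
            es = set(extra)
            if all(c & es for c in rest):
                return len(forced) + k - 1
    raise AssertionError("unreachable")  # pragma: no cover


def _max_steps(cells: list[frozenset]) -> int:
    """Star-tree maximum for an unordered character: scored tips minus the
    largest single-state class, counting each polymorphic tip toward its
    most favorable state."""
    if not cells:
        return 0
    states = set().union(*cells)
    best = max(sum(1 for c in cells if s in c) for s in states)
    return len(cells) - best


def fit_indices(tree: Phylogeny, discrete: DiscreteMatrix) -> ParsimonyFit:
    """Tree length and ensemble CI/HI/RI for a discrete matrix.

    CI = sum(m)/sum(s); HI = 1 - CI; RI = (sum(g)-sum(s))/(sum(g)-sum(m)).
    RI is undefined (flagged) when every character is constant or
    autapomorphic, i.e. sum(g) == sum(m).
    """
    s = fitch_steps_per_character(tree, discrete)
    m = np.zeros(discrete.nchar, dtype=np.int64)
    g = np.zeros(discrete.nchar, dtype=np.int64)
    for j in range(discrete.nchar):
        cells = [row[j] for row in discrete.states if row[j] is not None]
        m[j] = _min_steps(cells)
        g[j] = _max_steps(cells)
    length = int(s.sum())
    ci = hi_ = ri = None
    if length > 0:
        ci = float(m.sum() / s.sum())
        hi_ = 1.0 - ci
    ri_defined = bool(g.sum() > m.sum())
    if ri_defined:
        ri = float((g.sum() - s.sum()) / (g.sum() - m.sum()))
    return ParsimonyFit(
        length=length, s=s, m=m, g=g, ci=ci, hi=hi_, ri=ri, ri_defined=ri_defined
    )


# ------------------------------------------------------------------
# heuristic search
# ------------------------------------------------------------------

@dataclass
class SearchResult:
    trees: list[Phylogeny]
    length: float
    n_replicates: int
    swap: str


class _Scorer:
    """Weighted tree length over a discrete and an optional continuous
    partition, with tips addressed by matrix row index."""

    def __init__(
        self,
        discrete: DiscreteMatrix,
        continuous: ContinuousMatrix | None = None,
        disc_weights: np.ndarray | None = None,
        cont_weights: np.ndarray | None = None,
    ):
        self.taxa = list(discrete.taxa)
        if continuous is not None and list(continuous.taxa) != self.taxa:
            raise ValueError("discrete and continuous matrices must share taxa order")
        self.masks = _encode_discrete(discrete)
        self.wd = (
            np.ones(discrete.nchar) if disc_weights is None else np.asarray(disc_weights, float)
        )
        if continuous is not None and continuous.nchar > 0:
            self.clo, self.chi = _encode_continuous(continuous)
            self.wc = (
                np.ones(continuous.nchar)
                if cont_weights is None
                else np.asarray(cont_weights, float)
            )
        else:
            self.clo = self.chi = self.wc = None

    def length(self, root: _Node) -> float:
        steps, _ = _fitch_downpass(root, self.masks)
        total = float(self.wd @ steps)
        if self.clo is not None:
            cost, _ = _farris_downpass(root, self.clo, self.chi)
            total += float(self.wc @ cost)
        return total


def _edges_below(node: _Node) -> list[_Node]:
    """All nodes in the subtree rooted at ``node`` (each stands for its
    parent edge), including ``node`` itself."""
    return _postorder(node)


def _insert_on_edge(edge_child: _Node, new_tip: _Node) -> _Node:
    """Subdivide the edge above ``edge_child`` and attach ``new_tip``.
    Returns the new internal node."""
    parent = edge_child.parent
    joint = _Node()
    idx = parent.children.index(edge_child)
    parent.children[idx] = joint
    joint.parent = parent
    joint.add(edge_child)
    joint.add(new_tip)
    return joint


def _remove_joint(joint: _Node) -> _Node:
    """Undo an insertion: splice the surviving child of ``joint`` into its
    grandparent.  The surviving child is ``joint.children[0]``."""
    child = joint.children[0]
    parent = joint.parent
    idx = parent.children.index(joint)
    parent.children[idx] = child
    child.parent = parent
    return child


def _stepwise_addition(
    scorer: _Scorer, order: list[int], outgroup_idx: int, rng: np.random.Generator
) -> _Node:
    root = _Node()
    root.add(_Node(tip=outgroup_idx))
    ingroup = [i for i in order if i != outgroup_idx]
    core = _Node()
    core.add(_Node(tip=ingroup[0]))
    core.add(_Node(tip=ingroup[1]))
    root.add(core)
    for tip_idx in ingroup[2:]:
        core = root.children[1]
        candidates = _edges_below(core)
        best, best_len = [], np.inf
        tip = _Node(tip=tip_idx)
        for edge_child in candidates:
            joint = _insert_on_edge(edge_child, tip)
            L = scorer.length(root)
            # undo
            joint.children.remove(tip)
            _remove_joint(joint)
            if L < best_len - 1e-12:
                best, best_len = [edge_child], L
            elif L <= best_len + 1e-12:
                best.append(edge_child)
        choice = best[rng.integers(len(best))]
        _insert_on_edge(choice, tip)
    return root


def _spr_moves(root: _Node):
    """Yield (prune_node, regraft_edge_child) pairs for the current tree.
    The outgroup tip (root child 0) and the core root are never pruned."""
    core = root.children[1]
    prunable = [n for n in _postorder(core) if n is not core]
    for v in prunable:
        p = v.parent
        if p is root:
            continue
        yield v


def _apply_spr(root: _Node, v: _Node, target: _Node) -> None:
    """Prune subtree ``v`` and regraft it on the edge above ``target``."""
    p = v.parent
    sib = p.children[0] if p.children[1] is v else p.children[1]
    gp = p.parent
    idx = gp.children.index(p)
    gp.children[idx] = sib
    sib.parent = gp
    _insert_on_edge(target, v)
    # v's parent is the fresh joint created by _insert_on_edge


def _collect_spr_targets(root: _Node, v: _Node) -> list[_Node]:
    core = root.children[1]
    in_v = set(_postorder(v))
    sib = None
    p = v.parent
    sib = p.children[0] if p.children[1] is v else p.children[1]
    targets = []
    for n in _postorder(core):
        if n in in_v or n is p:
            continue
        if n is sib:  # regrafting on the sibling edge rebuilds the same tree
            continue
        targets.append(n)
    return targets


def _swap_to_optimum(
    scorer: _Scorer, root: _Node, swap: str, rng: np.random.Generator
) -> float:
    """First-improvement SPR (or NNI) until no move shortens the tree."""
    current = scorer.length(root)
    improved = True
    while improved:
        improved = False
        prunable = list(_spr_moves(root))
        rng.shuffle(prunable)
        # apply/undo cycles replace the pruned node's parent with a fresh
        # joint; the replaced originals must not be revisited this pass
        dead: set = set()
        for v in prunable:
            if v in dead or v.parent is None or v.parent.parent is None:
                continue
            orig_parent = v.parent
            if swap == "NNI":
                targets = _nni_targets(root, v)
            else:
                targets = _collect_spr_targets(root, v)
            p = v.parent
            sib = p.children[0] if p.children[1] is v else p.children[1]
            for t in targets:
                _apply_spr(root, v, t)
                L = scorer.length(root)
                if L < current - 1e-12:
                    current = L
                    improved = True
                    break
                # undo: prune v again and regraft on the original sibling edge
                dead.add(v.parent)
                _apply_spr(root, v, sib)
                sib = v.parent.children[0] if v.parent.children[1] is v else v.parent.children[1]
            dead.add(orig_parent)
            if improved:
                break
    return current


def _nni_targets(root: _Node, v: _Node) -> list[_Node]:
    """NNI as the subset of SPR moves that regraft ``v`` one edge away:
    onto its 'uncle' edge or its grandparent's sibling edges."""
    p = v.parent
    gp = p.parent
    if gp is None or gp is root:
        return []
    uncle = gp.children[0] if gp.children[1] is p else gp.children[1]
    out = []
    if uncle.children:
        out.extend(uncle.children)
    else:
        out.append(uncle)
    return out


def heuristic_search(
    discrete: DiscreteMatrix,
    continuous: ContinuousMatrix | None = None,
    *,
    outgroup: str,
    n_replicates: int = 10,
    swap: str = "SPR",
    seed: int | None = None,
    disc_weights: np.ndarray | None = None,
    cont_weights: np.ndarray | None = None,
) -> SearchResult:
    """Random-addition-sequence heuristic search with branch swapping.

    Each replicate builds a starting tree by stepwise addition in a random
    taxon order and swaps (SPR or NNI) to a local optimum; all distinct
    topologies at the overall best length are returned, rooted on
    ``outgroup``.  Deterministic for a fixed ``seed``.
    """
    if swap not in ("SPR", "NNI"):
        raise ValueError("swap must be 'SPR' or 'NNI'")
    if outgroup not in discrete.taxa:
        raise KeyError(f"outgroup {outgroup!r} not found in matrix")
    if discrete.ntax < 4:
        raise ValueError("need at least 4 taxa to search")
    scorer = _Scorer(discrete, continuous, disc_weights, cont_weights)
    og_idx = discrete.taxa.index(outgroup)
    rng = np.random.default_rng(seed)

    best_len = np.inf
    best: dict[str, _Node] = {}
    n = discrete.ntax
    for _ in range(n_replicates):
        order = list(rng.permutation(n))
        root = _stepwise_addition(scorer, order, og_idx, rng)
        L = _swap_to_optimum(scorer, root, swap, rng)
        if L < best_len - 1e-12:
            best_len = L
            best = {}
        if L <= best_len + 1e-12:
            key = _collapsed_topology_key(scorer, root)
            if key not in best:
                best[key] = _clone(root)

    trees = [
        Phylogeny.from_newick(_nodes_to_newick(r, scorer.taxa)) for r in best.values()
    ]
    return SearchResult(trees=trees, length=float(best_len), n_replicates=n_replicates, swap=swap)


def _clone(node: _Node) -> _Node:
    new = _Node(tip=node.tip)
    for c in node.children:
        new.add(_clone(c))
    return new


def _collapsed_topology_key(scorer: _Scorer, root: _Node) -> str:
    """Canonical topology string after collapsing internal edges that admit
    zero changes under some most-parsimonious reconstruction (Fitch final
    state sets intersect on every character)."""
    work = _clone(root)
    _, down = _fitch_downpass(work, scorer.masks)
    final: dict[_Node, np.ndarray] = {}
    for node in reversed(_postorder(work)):  # preorder
        if node.parent is None:
            final[node] = down[node]
            continue
        fp = final[node.parent]
        b = down[node]
        if node.tip is not None:
            final[node] = b
            continue
        c1, c2 = node.children
        inter_fp = b & fp
        cond_full = inter_fp == fp
        union_children = down[c1] | down[c2]
        inter_children = down[c1] & down[c2]
        # Fitch uppass rules
        f = np.where(
            cond_full,
            fp,
            np.where(inter_children != 0, b | (fp & union_children), b | fp),
        )
        final[node] = f
    # collapse internal edges whose endpoint final sets always intersect
    changed = True
    while changed:
        changed = False
        for node in _postorder(work):
            if node.tip is not None or node.parent is None or node.parent.parent is None:
                continue
            if np.all((final[node] & final[node.parent]) != 0):
                parent = node.parent
                parent.children.remove(node)
                for c in node.children:
                    parent.children.append(c)
                    c.parent = parent
                changed = True
                break
    return _canonical_topology(work, scorer.taxa)


# ------------------------------------------------------------------
# symmetric resampling
# ------------------------------------------------------------------

@dataclass
class SupportTable:
    """Bipartition recovery frequencies over resampling replicates.

    Splits are stored in the same canonical form produced by
    :meth:`Phylogeny.bipartitions` (the side not containing the
    alphabetically first taxon)."""

    frequencies: dict[frozenset, float]
    n_reps: int
    taxa: frozenset = field(default_factory=frozenset)

    def support_for(self, tip_labels) -> float:
        """Frequency of the split isolating ``tip_labels`` (either side)."""
        want = frozenset(tip_labels)
        anchor = min(self.taxa) if self.taxa else None
        if anchor is not None and anchor in want:
            want = frozenset(self.taxa - want)
        return self.frequencies.get(want, 0.0)


def symmetric_resampling(
    discrete: DiscreteMatrix,
    continuous: ContinuousMatrix | None,
    reference_tree: Phylogeny,
    *,
    outgroup: str,
    n_reps: int = 100,
    p_change: float = 1.0 / 3.0,
    seed: int | None = None,
    n_addition_replicates: int = 2,
    swap: str = "NNI",
) -> SupportTable:
    """Symmetric character-weight resampling support.

    Per replicate each character's weight is doubled with probability
    ``p_change/2``, halved with probability ``p_change/2`` and left at 1
    otherwise; a (reduced-effort) search is run and each reference split is
    scored as recovered if present in the strict consensus of that
    replicate's best trees.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0.0 <= p_change < 1.0):
        raise ValueError("p_change must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ref_splits = reference_tree.bipartitions()
    counts = {s: 0 for s in ref_splits}
    nd = discrete.nchar
    nc = continuous.nchar if continuous is not None else 0
    for _ in range(n_reps):
        u = rng.random(nd + nc)
        w = np.ones(nd + nc)
        w[u < p_change / 2] = 2.0
        w[(u >= p_change / 2) & (u < p_change)] = 0.5
        res = heuristic_search(
            discrete,
            continuous,
            outgroup=outgroup,
            n_replicates=n_addition_replicates,
            swap=swap,
            seed=int(rng.integers(2**31 - 1)),
            disc_weights=w[:nd],
            cont_weights=w[nd:] if nc else None,
        )
        splits_per_tree = [t.bipartitions() for t in res.trees]
        strict = set.intersection(*splits_per_tree) if splits_per_tree else set()
        for s in ref_splits:
            if s in strict:
                counts[s] += 1
    freqs = {s: c / n_reps for s, c in counts.items()}
    return SupportTable(
        frequencies=freqs,
        n_reps=n_reps,
        taxa=frozenset(reference_tree.taxon_labels),
    )
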