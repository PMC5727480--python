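"""Core containers for character matrices, taxon records and dated trees.

Discrete characters are stored as per-cell *state sets*: a singleton set is
an ordinary scoring, a multi-element set a polymorphic scoring, and ``None``
a missing/inapplicable cell (the two are not distinguished).  Continuous
characters are strictly positive ratios with NaN marking missing values.
All ages are in Ma before present (larger = older).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "DiscreteMatrix",
    "ContinuousMatrix",
    "TaxonRecord",
    "TimeBin",
    "TimeBinSet",
    "Phylogeny",
]

StateSet = frozenset  # frozenset[int] | None (missing)

DIETS = ("carnivore", "omnivore", "herbivore", "unknown")


def _check_unique(taxa: Sequence[str]) -> None:
    seen = set()
    for t in taxa:
        if t in seen:
            raise ValueError(f"duplicate taxon name: {t!r}")
        seen.add(t)


@dataclass
class DiscreteMatrix:
    """Taxa x characters matrix of integer state sets (0-based).

    ``states[i][j]`` is a frozenset of states for taxon i, character j, or
    ``None`` if the cell is missing.  ``ordering[j]`` is ``"unordered"`` or
    ``"ordered"``.
    """

    taxa: list[str]
    states: list[list[StateSet | None]]
    ordering: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.taxa)
        if len(self.states) != len(self.taxa):
            raise ValueError("one row of states per taxon required")
        nchar = self.nchar
        for name, row in zip(self.taxa, self.states):
            if len(row) != nchar:
                raise ValueError(f"row for {name!r} has {len(row)} cells, expected {nchar}")
            for cell in row:
                if cell is not None and len(cell) == 0:
                    raise ValueError(f"empty state set for {name!r}")
        if not self.ordering:
            self.ordering = ["unordered"] * nchar
        if len(self.ordering) != nchar:
            raise ValueError("ordering length must equal nchar")
        for o in self.ordering:
            if o not in ("unordered", "ordered"):
                raise ValueError(f"unknown ordering {o!r}")

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.states[0]) if self.states else 0

    def row(self, taxon: str) -> list[StateSet | None]:
        return self.states[self.taxa.index(taxon)]

    def missing_fraction(self) -> float:
        cells = self.ntax * self.nchar
        if cells == 0:
            return 0.0
        miss = sum(cell is None for row in self.states for cell in row)
        return miss / cells

    def observed_states(self, j: int) -> frozenset:
        """Union of states seen in character j across all scored cells."""
        out: set[int] = set()
        for row in self.states:
            if row[j] is not None:
                out |= row[j]
        return frozenset(out)

    def subset_taxa(self, keep: Iterable[str]) -> "DiscreteMatrix":
        keep = list(keep)
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in keep if t not in idx]
        if missing:
            raise KeyError(f"taxa not in matrix: {missing}")
        return DiscreteMatrix(
            taxa=keep,
            states=[list(self.states[idx[t]]) for t in keep],
            ordering=list(self.ordering),
        )


@dataclass
class ContinuousMatrix:
    """Taxa x characters matrix of positive ratios; NaN = missing."""

    taxa: list[str]
    values: np.ndarray
    char_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.taxa)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(len(self.taxa), -1)
        if self.values.shape[0] != len(self.taxa):
            raise ValueError("one row of values per taxon required")
        finite = self.values[~np.isnan(self.values)]
        if np.any(finite <= 0):
            raise ValueError("continuous ratios must be strictly positive")
        if not self.char_names:
            self.char_names = [f"c{j + 1}" for j in range(self.nchar)]
        if len(self.char_names) != self.nchar:
            raise ValueError("char_names length must equal nchar")

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return self.values.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.values[self.taxa.index(taxon)]

    def missing_fraction(self) -> float:
        if self.values.size == 0:
            return 0.0
        return float(np.isnan(self.values).mean())


@dataclass(frozen=True)
class TaxonRecord:
    """Stratigraphic range (Ma) and diet of one taxon."""

    name: str
    fad: float
    lad: float
    diet: str = "unknown"

    def __post_init__(self) -> None:
        if not (self.fad >= self.lad > 0):
            raise ValueError(
                f"{self.name}: require fad >= lad > 0, got fad={self.fad}, lad={self.lad}"
            )
        if self.diet not in DIETS:
            raise ValueError(f"{self.name}: unknown diet {self.diet!r}")


@dataclass(frozen=True)
class TimeBin:
    name: str
    start: float  # older bound, Ma
    end: float  # younger bound, Ma

    def __post_init__(self) -> None:
        if not self.start > self.end:
            raise ValueError(f"bin {self.name}: start must be > end (Ma)")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def duration(self) -> float:
        return self.start - self.end

    def contains_age(self, age: float) -> bool:
        # half-open [end, start): an age exactly on a boundary belongs to
        # the older of the two adjoining bins
        return self.end <= age < self.start

    def overlaps_range(self, fad: float, lad: float) -> bool:
        """Does [lad, fad] overlap this bin (boundary point -> older bin)?"""
        if fad == lad:
            return self.contains_age(fad) or (fad == self.end)
        return fad > self.end and lad < self.start


@dataclass
class TimeBinSet:
    """Ordered, non-overlapping stratigraphic bins, oldest first."""

    bins: list[TimeBin]

    def __post_init__(self) -> None:
        for a, b in zip(self.bins, self.bins[1:]):
            if b.start > a.end:
                raise ValueError(f"bins {a.name} and {b.name} overlap or are out of order")

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __getitem__(self, i):
        return self.bins[i]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bins]

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.bins])


class Phylogeny:
    """A rooted tree with optional branch lengths (Myr) and node ages (Ma).

    Thin wrapper over a :class:`dendropy.Tree`; node ages live in the
    ``age_ma`` attribute of each node.  When ages are set, every parent is
    at least as old as each of its children.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    # -- constructors -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        return cls(tree)

    # -- basic accessors ----------------------------------------------
    @property
    def taxon_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def is_binary(self) -> bool:
        for node in self.tree.preorder_node_iter():
            n = len(node.child_nodes())
            if n not in (0, 2):
                return False
        return True

    def has_ages(self) -> bool:
        return all(
            getattr(n, "age_ma", None) is not None for n in self.tree.preorder_node_iter()
        )

    def node_ages(self) -> dict:
        return {n: n.age_ma for n in self.tree.preorder_node_iter()}

    # -- ages / branch lengths ----------------------------------------
    def set_tip_ages(self, ages: dict[str, float]) -> None:
        for leaf in self.tree.leaf_node_iter():
            leaf.age_ma = float(ages[leaf.taxon.label])

    def validate_ages(self) -> None:
        for node in self.tree.preorder_node_iter():
            age = getattr(node, "age_ma", None)
            if age is None:
                raise ValueError("node without an age")
            for child in node.child_nodes():
                cage = getattr(child, "age_ma", None)
                if cage is None:
                    raise ValueError("node without an age")
                if age < cage - 1e-9:
                    raise ValueError(
                        f"parent age {age} Ma younger than child age {cage} Ma"
                    )

    def branch_lengths_from_ages(self) -> None:
        """Set every edge length to (parent age - child age) in Myr."""
        self.validate_ages()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = max(0.0, node.parent_node.age_ma - node.age_ma)

    def perturb_zero_branches(self, epsilon: float = 1e-4) -> int:
        """Lengthen zero-length branches by ``epsilon`` Myr; return count."""
        n = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node.parent_node is None:
                continue
            if edge.length is None or edge.length <= 0:
                edge.length = epsilon
                n += 1
        return n

    # -- serialization ------------------------------------------------
    def to_newick(self, include_branch_lengths: bool = True) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_edge_lengths=not include_branch_lengths,
            suppress_rooting=True,
        )
        return s.strip()

    def clone(self) -> "Phylogeny":
        t2 = dendropy.Tree(self.tree)
        # dendropy's copy keeps custom attributes only on a deep clone path;
        # re-attach ages explicitly by matching traversal order
        for n_old, n_new in zip(
            self.tree.preorder_node_iter(), t2.preorder_node_iter()
        ):
            if getattr(n_old, "age_ma", None) is not None:
                n_new.age_ma = n_old.age_ma
        return Phylogeny(t2)

    # -- splits --------------------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted splits, each as the frozenset of tip labels
        on the side not containing the first taxon (canonical form)."""
        all_tips = frozenset(self.taxon_labels)
        anchor = min(all_tips)
        out: set[frozenset] = set()
        for node in self.tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(side) < 2 or len(all_tips - side) < 2:
                continue
            if anchor in side:
                side = all_tips - side
            out.add(side)
        return out
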