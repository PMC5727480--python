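"""Morphospace construction.

Two parallel tracks mirror the two character types: continuous ratio
characters are log-transformed, mean-imputed and ordinated by a covariance
PCA; discrete characters yield a maximum observable rescaled distance
(MORD) matrix ordinated by principal coordinates without negative-eigenvalue
correction (the count of positive-variance axes is itself a quantity of
interest downstream, so eigenvalues are reported raw and sign-flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ContinuousMatrix, DiscreteMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "logratio_transform",
    "mean_impute",
    "pca",
    "mord",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    n_comparable: np.ndarray  # characters scored in both members of each pair
    incomparable_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.taxa):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v


@dataclass
class OrdinationResult:
    taxa: list[str]
    scores: np.ndarray  # taxa x axes, ordered by non-increasing eigenvalue
    axis_variances: np.ndarray  # eigenvalues
    method: str  # "PCA" | "PCoA"
    negative_axes: int = 0  # count of negative eigenvalues (PCoA only)
    eigenvalues: np.ndarray | None = None  # raw Gram eigenvalues (PCoA)

    @property
    def n_positive_axes(self) -> int:
        return int(np.sum(self.axis_variances > 1e-10))

    def positive_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_positive_axes]


# ---------------------------------------------------------- continuous

def logratio_transform(m: ContinuousMatrix) -> ContinuousMatrix:
    """Elementwise natural log of the ratio characters (missing preserved).

    The variables are already a-dimensional ratios, so the log alone
    removes the spurious correlation structure of ratio data; a centered
    variant is available via ``center_rows=True`` on :func:`clr_transform`.
    """
    with np.errstate(invalid="ignore"):
        logged = np.log(m.values)
    out = ContinuousMatrix.__new__(ContinuousMatrix)
    out.taxa = list(m.taxa)
    out.values = logged
    out.char_names = list(m.char_names)
    return out


def clr_transform(m: ContinuousMatrix) -> ContinuousMatrix:
    """Centered log-ratio: log values minus each taxon's mean log value."""
    lm = logratio_transform(m)
    row_means = np.nanmean(lm.values, axis=1, keepdims=True)
    lm.values = lm.values - row_means
    return lm


def mean_impute(m: ContinuousMatrix) -> ContinuousMatrix:
    """Replace each missing cell by its character's mean over scored taxa."""
    vals = m.values.copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        miss = np.isnan(col)
        if miss.all():
            raise ValueError(f"character {m.char_names[j]!r} has no scored values")
        col[miss] = col[~miss].mean()
    out = ContinuousMatrix.__new__(ContinuousMatrix)
    out.taxa = list(m.taxa)
    out.values = vals
    out.char_names = list(m.char_names)
    return out


def pca(m: ContinuousMatrix) -> OrdinationResult:
    """Covariance-matrix PCA of a complete continuous matrix.

    Axis variances are the eigenvalues of the character covariance matrix
    (n-1 denominator); their sum equals the total variance of the input.
    """
    x = np.asarray(m.values, float)
    if np.isnan(x).any():
        raise ValueError("PCA input must be complete (impute first)")
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 taxa")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals[np.abs(evals) < 1e-12] = 0.0
    scores = centered @ evecs
    return OrdinationResult(
        taxa=list(m.taxa), scores=scores, axis_variances=evals, method="PCA"
    )


# ------------------------------------------------------------ discrete

def _cell_to_set(cell):
    return cell  # cells already are frozensets or None


def mord(
    m: DiscreteMatrix,
    incomparable: str = "max_observed",
    polymorphism_distance: str = "min",
) -> DistanceMatrix:
    """Maximum observable rescaled distance between all taxon pairs.

    For each pair the distance is the summed per-character difference
    divided by the summed maximum possible difference, both over characters
    scored in both taxa.  Unordered characters differ by 0 when the state
    sets intersect, else 1 (maximum 1); ordered characters differ by the
    minimum |x - y| over the two state sets rescaled by the character's
    observed range (maximum 1).  Pairs with no mutually scored character
    are flagged and, under the default policy, filled with the maximum
    observed distance (``incomparable="trim"`` leaves them as NaN).
    """
    n = m.ntax
    d = np.zeros((n, n))
    ncomp = np.zeros((n, n), dtype=int)
    ranges = np.array(
        [
            (max(obs) - min(obs)) if (obs := m.observed_states(j)) and len(obs) > 1 else 0
            for j in range(m.nchar)
        ],
        dtype=float,
    )
    incomparable_pairs = []
    for i in range(n):
        for k in range(i + 1, n):
            num = den = 0.0
            comp = 0
            for j in range(m.nchar):
                a, b = m.states[i][j], m.states[k][j]
                if a is None or b is None:
                    continue
                comp += 1
                if m.ordering[j] == "ordered" and ranges[j] > 0:
                    diff = min(abs(x - y) for x in a for y in b) / ranges[j]
                else:
                    diff = 0.0 if (a & b) else 1.0
                num += diff
                den += 1.0
            ncomp[i, k] = ncomp[k, i] = comp
            if comp == 0:
                d[i, k] = d[k, i] = np.nan
                incomparable_pairs.append((m.taxa[i], m.taxa[k]))
            else:
                d[i, k] = d[k, i] = num / den
    if incomparable_pairs:
        if incomparable == "max_observed":
            fill = np.nanmax(d) if np.isfinite(np.nanmax(d)) else 1.0
            warnings.warn(
                f"{len(incomparable_pairs)} taxon pair(s) share no scored "
                f"characters; filled with the maximum observed distance {fill:.4f}"
            )
            d[np.isnan(d)] = fill
        elif incomparable != "trim":
            raise ValueError("incomparable must be 'max_observed' or 'trim'")
    return DistanceMatrix(
        taxa=list(m.taxa), values=d, n_comparable=ncomp, incomparable_pairs=incomparable_pairs
    )


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis of a complete distance matrix.

    Double-centers -D**2/2 and eigendecomposes; all axes are returned with
    raw (possibly negative) eigenvalues and no correction, scores scaled by
    sqrt(eigenvalue) on positive axes (zero elsewhere).
    """
    D = np.asarray(d.values, float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains unresolved incomparable pairs")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals[np.abs(evals) < 1e-10] = 0.0
    scores = np.zeros((n, n))
    pos = evals > 0
    scores[:, pos] = evecs[:, pos] * np.sqrt(evals[pos])
    # eigenvalues scale with n; report as variances comparable to PCA axes
    axis_var = evals / (n - 1)
    return OrdinationResult(
        taxa=list(d.taxa),
        scores=scores,
        axis_variances=axis_var,
        method="PCoA",
        negative_axes=int(np.sum(evals < 0)),
        eigenvalues=evals,
    )
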