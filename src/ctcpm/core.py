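"""Core data model: edge indexing, connectome cohorts, connectome computation.

A subject's connectome is the symmetric matrix of Fisher-z transformed
Pearson correlations between every pair of ROI time series. Only the strict
upper triangle carries information; a cohort stores it vectorized as an
``N x E`` matrix with ``E = P(P-1)/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasDefinition
from .errors import DomainError, ValidationError

#: |r| is clipped to this before atanh so perfect correlations stay finite.
_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class EdgeIndex:
    """Bijection between edge ids ``0..E-1`` and unordered node pairs.

    Node ids are 1-based; pairs are ordered ``node_i < node_j`` and
    enumerated row-major along the strict upper triangle.
    """

    n_nodes: int
    pairs: np.ndarray = field(repr=False)  # (E, 2) int64, 1-based

    @property
    def n_edges(self) -> int:
        return self.pairs.shape[0]

    def edge_id(self, node_i: int, node_j: int) -> int:
        """Edge id of the unordered pair (node_i, node_j)."""
        i, j = sorted((node_i, node_j))
        if not (1 <= i < j <= self.n_nodes):
            raise DomainError(f"invalid node pair ({node_i}, {node_j}) for P={self.n_nodes}")
        i0, j0 = i - 1, j - 1
        p = self.n_nodes
        return i0 * p - i0 * (i0 + 1) // 2 + (j0 - i0 - 1)

    def vectorize(self, matrix: np.ndarray) -> np.ndarray:
        """Extract the strict upper triangle of a P x P matrix, row-major."""
        matrix = np.asarray(matrix)
        if matrix.shape != (self.n_nodes, self.n_nodes):
            raise DomainError(f"expected {self.n_nodes}x{self.n_nodes} matrix, got {matrix.shape}")
        iu = np.triu_indices(self.n_nodes, k=1)
        return matrix[iu]

    def devectorize(self, values: np.ndarray, diag: float = 0.0) -> np.ndarray:
        """Rebuild the symmetric P x P matrix from edge values."""
        values = np.asarray(values)
        if values.shape != (self.n_edges,):
            raise DomainError(f"expected {self.n_edges} edge values, got {values.shape}")
        m = np.full((self.n_nodes, self.n_nodes), diag, dtype=float)
        iu = np.triu_indices(self.n_nodes, k=1)
        m[iu] = values
        m[iu[1], iu[0]] = values
        return m


def edge_index_for(n_nodes: int) -> EdgeIndex:
    """Edge index over the strict upper triangle of a ``n_nodes`` parcellation."""
    if n_nodes < 2:
        raise DomainError(f"need at least 2 nodes, got {n_nodes}")
    iu = np.triu_indices(n_nodes, k=1)
    pairs = np.column_stack([iu[0] + 1, iu[1] + 1]).astype(np.int64)
    return EdgeIndex(n_nodes=n_nodes, pairs=pairs)


@dataclass
class ConnectomeCohort:
    """A cohort of vectorized connectomes with one trait score per subject.

    Attributes
    ----------
    subjects
        Subject identifiers, one per row of ``X``.
    X
        ``N x E`` matrix of Fisher-z edge values.
    y
        ``N`` trait scores (e.g. BIS-11 totals), same row order as ``X``.
    edge_index
        Edge id <-> node pair bijection for the columns of ``X``.
    atlas
        Node metadata; ``atlas.n_nodes`` must match ``edge_index.n_nodes``.
    """

    subjects: list[str]
    X: np.ndarray
    y: np.ndarray
    edge_index: EdgeIndex
    atlas: AtlasDefinition

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, e = self.X.shape
        if len(self.subjects) != n or self.y.shape != (n,):
            raise ValidationError("subjects, X rows and y must align")
        if n < 3:
            raise ValidationError(f"need at least 3 subjects, got {n}")
        if e != self.edge_index.n_edges:
            raise ValidationError(
                f"X has {e} columns but edge index defines {self.edge_index.n_edges} edges"
            )
        if self.atlas.n_nodes != self.edge_index.n_nodes:
            raise ValidationError("atlas and edge index disagree on node count")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("non-finite values in edge matrix X")
        if not np.all(np.isfinite(self.y)):
            raise ValidationError("non-finite trait scores")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]


def validate_trait_scores(y: np.ndarray, bounds: tuple[float, float] | None = (30.0, 120.0)) -> None:
    """Check trait scores against declared instrument bounds.

    The default bounds are the BIS-11 total range (30 items scored 1..4).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite trait scores")
    if bounds is not None:
        lo, hi = bounds
        if np.any(y < lo) or np.any(y > hi):
            bad = y[(y < lo) | (y > hi)]
            raise ValidationError(f"trait scores outside instrument bounds [{lo}, {hi}]: {bad[:5]}")


def compute_connectome(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z connectome from a ``T x P`` ROI time-series table.

    Each off-diagonal entry is ``atanh(r)`` for the Pearson correlation ``r``
    between the two ROI columns. Correlations with ``|r| = 1`` are clipped to
    ``1 - 1e-7`` (with a warning) so the transform stays finite. The diagonal
    is set to zero and carries no meaning.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise DomainError("time series must be a 2-D T x P array")
    t, p = ts.shape
    if t < 3:
        raise DomainError(f"need at least 3 time points, got {t}")
    if not np.all(np.isfinite(ts)):
        raise ValidationError("non-finite values in time series")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValidationError(f"zero-variance ROI column(s): {(dead + 1).tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) > _R_CLIP):
        warnings.warn(
            "correlation(s) with |r| ~ 1 clipped before Fisher transform", RuntimeWarning
        )
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z
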