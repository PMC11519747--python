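"""Three-stage edge selection: significance screen, collinearity pruning,
repeated K-fold mutual-information consensus.

Stage 1 keeps edges whose across-subject Pearson correlation with the trait
is significant at ``p < alpha`` (two-tailed, t distribution with N-2 df);
positive and negative passers form a single feature vector, with the
association sign recorded for later network characterization.

Stage 2 treats feature pairs with ``|r| >= threshold`` as collinear and,
within each collinear group, keeps only the member with the highest mutual
information with the trait.

Stage 3 runs repeated K-fold cross-validation (default K=6, 4 repeats) and,
on each of the K*R training portions, ranks the surviving features by mutual
information with the trait; the consensus set is the intersection of every
ranking's top fraction (default 60%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from .core import ConnectomeCohort
from .errors import DomainError, ValidationError


@dataclass
class ScreenResult:
    """Edge-wise trait-association screen.

    ``r``, ``p`` and ``sign`` cover every edge; ``passing_edges`` holds the
    edge ids with ``p < alpha``, ascending.
    """

    passing_edges: np.ndarray
    r: np.ndarray
    p: np.ndarray
    sign: np.ndarray
    alpha: float

    def sign_of(self, edge_ids: np.ndarray) -> np.ndarray:
        return self.sign[np.asarray(edge_ids, dtype=int)]


@dataclass
class SelectionResult:
    """Outcome of the full three-stage selection."""

    screen: ScreenResult
    retained_after_collinearity: np.ndarray
    rankings: list[np.ndarray] = field(repr=False)  # K*R arrays of edge ids, best first
    consensus_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    parameters: dict = field(default_factory=dict)

    @property
    def n_consensus(self) -> int:
        return len(self.consensus_edges)


def screen_edges(cohort: ConnectomeCohort, alpha: float = 0.01) -> ScreenResult:
    """Pearson screen of every edge against the trait score.

    Constant edges are assigned ``r = 0, p = 1`` and never pass. A constant
    trait is a validation error.
    """
    x, y = cohort.X, cohort.y
    n = x.shape[0]
    if n < 4:
        raise ValidationError(f"screen needs at least 4 subjects, got {n}")
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    if sy == 0:
        raise ValidationError("trait scores are constant; correlation screen undefined")
    xc = x - x.mean(axis=0)
    sx = np.sqrt(np.sum(xc**2, axis=0))
    ok = sx > 0
    r = np.zeros(x.shape[1])
    r[ok] = (xc[:, ok].T @ yc) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    t[np.abs(r) == 1.0] = np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~ok] = 1.0
    passing = np.flatnonzero(p < alpha)
    return ScreenResult(
        passing_edges=passing,
        r=r,
        p=p,
        sign=np.sign(r).astype(int),
        alpha=alpha,
    )


def _equal_freq_bins(a: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency (quantile) bin labels by average rank.

    Works column-wise on 2-D input. Tied values share a rank and therefore a
    bin, which makes the labels exactly invariant under strictly monotone
    transforms.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    ranks = stats.rankdata(a, method="average", axis=0)
    b = np.ceil(ranks * n_bins / n).astype(np.int64) - 1
    return np.clip(b, 0, n_bins - 1)


def _mi_from_labels(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    n = bx.shape[0]
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    val = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    return max(val, 0.0)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> float:
    """Plug-in mutual information after equal-frequency discretization.

    Both variables are discretized into ``n_bins`` quantile bins; the
    estimate is the discrete double sum
    ``sum_xy P(x,y) log[P(x,y) / (P(x) P(y))]`` in nats. Nonnegative up to
    float error (clipped at zero).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DomainError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise DomainError("need at least 2 observations")
    if n_bins < 2:
        raise DomainError("need at least 2 bins")
    return _mi_from_labels(_equal_freq_bins(x, n_bins), _equal_freq_bins(y, n_bins), n_bins)


def mi_profile(x: np.ndarray, y: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Mutual information of each column of ``x`` with ``y``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    bx = _equal_freq_bins(x, n_bins)
    by = _equal_freq_bins(np.asarray(y, dtype=float).ravel(), n_bins)
    return np.array([_mi_from_labels(bx[:, j], by, n_bins) for j in range(x.shape[1])])


def prune_collinear(
    x_screened: np.ndarray,
    y: np.ndarray,
    edge_ids: np.ndarray | None = None,
    threshold: float = 0.8,
    n_bins: int = 8,
) -> np.ndarray:
    """Greedy collinearity pruning keeping the highest-MI member of each group.

    Features are visited in descending MI(feature, trait) order (ties broken
    by lower edge id); a feature is kept iff its |correlation| with every
    already-kept feature is below ``threshold``. Returns the retained edge
    ids in ascending order.
    """
    x = np.atleast_2d(np.asarray(x_screened, dtype=float))
    n, f = x.shape
    if f == 0:
        return np.array([], dtype=int)
    if edge_ids is None:
        edge_ids = np.arange(f)
    edge_ids = np.asarray(edge_ids, dtype=int)
    mi = mi_profile(x, y, n_bins)
    order = np.lexsort((edge_ids, -mi))  # MI desc, then edge id asc
    sd = x.std(axis=0)
    z = np.where(sd > 0, (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    kept_cols: list[int] = []
    for col in order:
        if kept_cols:
            corr = np.abs(z[:, kept_cols].T @ z[:, col]) / n
            if np.any(corr >= threshold):
                continue
        kept_cols.append(int(col))
    return np.sort(edge_ids[kept_cols])


def consensus_select(
    x_pruned: np.ndarray,
    y: np.ndarray,
    edge_ids: np.ndarray | None = None,
    k_folds: int = 6,
    repeats: int = 4,
    top_fraction: float = 0.6,
    n_bins: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Repeated K-fold MI-ranking consensus.

    For each of the ``k_folds * repeats`` training portions the features are
    ranked by MI with the trait (computed on the training subjects only);
    the consensus is the intersection of every ranking's top
    ``ceil(top_fraction * F)`` features. Returns (consensus edge ids
    ascending, list of full rankings as edge-id arrays, best first).
    """
    x = np.atleast_2d(np.asarray(x_pruned, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, f = x.shape
    if edge_ids is None:
        edge_ids = np.arange(f)
    edge_ids = np.asarray(edge_ids, dtype=int)
    if f < 2:
        return np.sort(edge_ids.copy()), []
    if k_folds > n:
        raise DomainError(f"k_folds={k_folds} exceeds n={n}")
    if not (0.0 < top_fraction <= 1.0):
        raise DomainError("top_fraction must lie in (0, 1]")
    m = int(np.ceil(top_fraction * f))
    rankings: list[np.ndarray] = []
    consensus: set[int] | None = None
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for train_idx, _test in splitter.split(x):
            mi = mi_profile(x[train_idx], y[train_idx], n_bins)
            order = np.lexsort((edge_ids, -mi))
            ranking = edge_ids[order]
            rankings.append(ranking)
            top = set(ranking[:m].tolist())
            consensus = top if consensus is None else (consensus & top)
    return np.array(sorted(consensus or ()), dtype=int), rankings


def select_features(
    cohort: ConnectomeCohort,
    alpha: float = 0.01,
    collinearity_threshold: float = 0.8,
    k_folds: int = 6,
    repeats: int = 4,
    top_fraction: float = 0.6,
    n_bins: int = 8,
    seed: int = 0,
) -> SelectionResult:
    """Run the full screen -> prune -> consensus selection on a cohort."""
    screen = screen_edges(cohort, alpha=alpha)
    params = dict(
        alpha=alpha,
        collinearity_threshold=collinearity_threshold,
        k_folds=k_folds,
        repeats=repeats,
        top_fraction=top_fraction,
        n_bins=n_bins,
        seed=seed,
    )
    if screen.passing_edges.size == 0:
        return SelectionResult(
            screen=screen,
            retained_after_collinearity=np.array([], dtype=int),
            rankings=[],
            consensus_edges=np.array([], dtype=int),
            parameters=params,
        )
    retained = prune_collinear(
        cohort.X[:, screen.passing_edges],
        cohort.y,
        edge_ids=screen.passing_edges,
        threshold=collinearity_threshold,
        n_bins=n_bins,
    )
    consensus, rankings = consensus_select(
        cohort.X[:, retained],
        cohort.y,
        edge_ids=retained,
        k_folds=k_folds,
        repeats=repeats,
        top_fraction=top_fraction,
        n_bins=n_bins,
        seed=seed,
    )
    return SelectionResult(
        screen=screen,
        retained_after_collinearity=retained,
        rankings=rankings,
        consensus_edges=consensus,
        parameters=params,
    )
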