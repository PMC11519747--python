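"""Characterization of the selected trait network.

Feature importance is the across-fold mean of each edge's OLS t-statistic;
node degree counts consensus edges incident to each node; macroscale counts
tally edges between each pair of the ten coarse brain regions, split by the
sign of the edge-trait association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition
from .core import EdgeIndex
from .errors import DomainError, ValidationError
from .model import CVResult
from .selection import SelectionResult


@dataclass
class NetworkSummary:
    """Per-edge importance, node degrees and macroscale pair counts."""

    edge_ids: np.ndarray
    edge_pairs: np.ndarray  # (M, 2) 1-based node ids
    edge_importance: np.ndarray  # mean t per consensus edge
    edge_sign: np.ndarray  # +-1 per consensus edge
    node_degree: np.ndarray  # length P
    macro_counts_pos: pd.DataFrame = field(repr=False)
    macro_counts_neg: pd.DataFrame = field(repr=False)

    def edge_table(self, atlas: AtlasDefinition) -> pd.DataFrame:
        """Per-edge table with both endpoints' atlas metadata, |t|-ranked."""
        return _edge_table(self, atlas)

    def top_edges(self, atlas: AtlasDefinition, k: int = 20, signed: bool = False) -> pd.DataFrame:
        return top_k_report(self, atlas, k=k, signed=signed)


def aggregate_importance(cv: CVResult) -> np.ndarray:
    """Across-fold mean of per-feature t-statistics (intercept excluded).

    All folds must have been fitted on the same feature set. Infinite
    sentinels from exact fits propagate as +-inf with a warning.
    """
    if not cv.fold_fits:
        raise ValidationError("no fold fits to aggregate")
    ref = cv.fold_fits[0].feature_ids
    for ff in cv.fold_fits[1:]:
        if not np.array_equal(ff.feature_ids, ref):
            raise ValidationError("fold fits use inconsistent feature sets")
    t = np.vstack([ff.t[1:] for ff in cv.fold_fits])
    if np.any(~np.isfinite(t)):
        warnings.warn("infinite t sentinel present; mean importance is +-inf there", RuntimeWarning)
    return t.mean(axis=0)


def node_degrees(edge_pairs: np.ndarray, n_nodes: int) -> np.ndarray:
    """Degree of every node 1..P in the selected edge set (zeros included)."""
    pairs = np.asarray(edge_pairs, dtype=int).reshape(-1, 2)
    if pairs.size and (pairs.min() < 1 or pairs.max() > n_nodes):
        raise ValidationError("edge references node outside 1..P")
    deg = np.zeros(n_nodes, dtype=int)
    for col in (0, 1):
        deg += np.bincount(pairs[:, col] - 1, minlength=n_nodes)
    return deg


def macroscale_counts(
    edge_pairs: np.ndarray,
    edge_sign: np.ndarray,
    atlas: AtlasDefinition,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric region-pair edge counts, one matrix per association sign.

    Within-region edges land on the diagonal and are counted once, so each
    matrix's total (upper triangle + diagonal) equals its edge count.
    """
    pairs = np.asarray(edge_pairs, dtype=int).reshape(-1, 2)
    signs = np.asarray(edge_sign, dtype=int).ravel()
    if pairs.shape[0] != signs.shape[0]:
        raise DomainError("edge_pairs and edge_sign lengths differ")
    labels = atlas.region_labels
    index = {r: i for i, r in enumerate(labels)}
    regions = atlas.regions
    mats = {s: np.zeros((len(labels), len(labels)), dtype=int) for s in (1, -1)}
    for (i, j), s in zip(pairs, signs):
        if s == 0:
            raise ValidationError("edge with zero association sign")
        a = index[regions[i - 1]]
        b = index[regions[j - 1]]
        a, b = min(a, b), max(a, b)
        mats[s][a, b] += 1
        if a != b:
            mats[s][b, a] += 1
    pos = pd.DataFrame(mats[1], index=labels, columns=labels)
    neg = pd.DataFrame(mats[-1], index=labels, columns=labels)
    return pos, neg


def _count_total(m: pd.DataFrame) -> int:
    a = m.to_numpy()
    return int(np.triu(a).sum())


def build_network_summary(
    cv: CVResult,
    selection: SelectionResult,
    atlas: AtlasDefinition,
    edge_index: EdgeIndex,
) -> NetworkSummary:
    """Assemble the full network summary from a CV run and its selection."""
    edge_ids = selection.consensus_edges
    pairs = edge_index.pairs[edge_ids] if len(edge_ids) else np.empty((0, 2), dtype=int)
    importance = aggregate_importance(cv) if len(edge_ids) else np.array([])
    if len(importance) != len(edge_ids):
        raise ValidationError("CV feature count does not match consensus edge count")
    signs = selection.screen.sign_of(edge_ids) if len(edge_ids) else np.array([], dtype=int)
    pos, neg = macroscale_counts(pairs, signs, atlas)
    return NetworkSummary(
        edge_ids=np.asarray(edge_ids, dtype=int),
        edge_pairs=pairs,
        edge_importance=importance,
        edge_sign=signs,
        node_degree=node_degrees(pairs, atlas.n_nodes),
        macro_counts_pos=pos,
        macro_counts_neg=neg,
    )


def _edge_table(summary: NetworkSummary, atlas: AtlasDefinition) -> pd.DataFrame:
    at = atlas.table.set_index("node_id")
    rows = []
    for eid, (i, j), t, s in zip(
        summary.edge_ids, summary.edge_pairs, summary.edge_importance, summary.edge_sign
    ):
        ri, rj = at.loc[i], at.loc[j]
        rows.append(
            {
                "edge_id": int(eid),
                "node_i": int(i),
                "node_j": int(j),
                "region_i": ri.region,
                "region_j": rj.region,
                "hemi_i": ri.hemisphere,
                "hemi_j": rj.hemisphere,
                "network_i": ri.network_name,
                "network_j": rj.network_name,
                "mni_i": f"{ri.mni_x}, {ri.mni_y}, {ri.mni_z}",
                "mni_j": f"{rj.mni_x}, {rj.mni_y}, {rj.mni_z}",
                "sign": "pos" if s > 0 else "neg",
                "mean_t": float(t),
                "degree_i": int(summary.node_degree[i - 1]),
                "degree_j": int(summary.node_degree[j - 1]),
            }
        )
    cols = [
        "edge_id", "node_i", "node_j", "region_i", "region_j", "hemi_i", "hemi_j",
        "network_i", "network_j", "mni_i", "mni_j", "sign", "mean_t", "degree_i", "degree_j",
    ]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        order = np.lexsort((df["edge_id"].to_numpy(), -np.abs(df["mean_t"].to_numpy())))
        df = df.iloc[order].reset_index(drop=True)
    return df


def top_k_report(
    summary: NetworkSummary,
    atlas: AtlasDefinition,
    k: int = 20,
    signed: bool = False,
) -> pd.DataFrame:
    """Top-k edges by feature importance with full atlas annotation.

    Default ranking is by |mean t| descending (signed ranking by flag); ties
    break toward the lower edge id. Asking for more edges than exist
    truncates with a warning.
    """
    df = _edge_table(summary, atlas)
    if signed:
        order = np.lexsort((df["edge_id"].to_numpy(), -df["mean_t"].to_numpy()))
        df = df.iloc[order].reset_index(drop=True)
    if k > len(df):
        warnings.warn(f"requested top {k} but only {len(df)} edges available", RuntimeWarning)
        k = len(df)
    return df.head(k).reset_index(drop=True)
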