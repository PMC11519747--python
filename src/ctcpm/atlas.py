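"""Node atlas: macroscale region membership and coordinates.

An atlas maps each node (ROI) of a parcellation to one of ten macroscale
brain regions, a hemisphere, a finer network label and an MNI coordinate.
The reference layout follows the Shen 268-node parcellation's macroscale
grouping: prefrontal (46), motor (21), insula (7), parietal (27),
temporal (39), occipital (25), limbic (36), cerebellum (41),
subcortical (17), brainstem (9).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical macroscale region labels, in the order used for 10x10 count matrices.
REGION_ORDER: tuple[str, ...] = (
    "prefrontal",
    "motor",
    "insula",
    "parietal",
    "temporal",
    "occipital",
    "limbic",
    "cerebellum",
    "subcortical",
    "brainstem",
)

#: Node counts per macroscale region in the 268-node reference layout.
SHEN268_REGION_SIZES: dict[str, int] = {
    "prefrontal": 46,
    "motor": 21,
    "insula": 7,
    "parietal": 27,
    "temporal": 39,
    "occipital": 25,
    "limbic": 36,
    "cerebellum": 41,
    "subcortical": 17,
    "brainstem": 9,
}

_REQUIRED_COLUMNS = (
    "node_id",
    "region",
    "hemisphere",
    "network_name",
    "mni_x",
    "mni_y",
    "mni_z",
)


class AtlasDefinition:
    """Validated per-node atlas table.

    Parameters
    ----------
    table
        DataFrame with columns ``node_id, region, hemisphere, network_name,
        mni_x, mni_y, mni_z``. ``node_id`` must be unique and contiguous
        ``1..P``. Region labels are lower-cased on input.
    strict
        If True, every region label must belong to the canonical ten-label
        macroscale set (:data:`REGION_ORDER`). Strictness is implied when
        ``P == 268``.
    """

    def __init__(self, table: pd.DataFrame, *, strict: bool = False):
        missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"atlas table missing columns: {missing}")
        table = table.loc[:, list(_REQUIRED_COLUMNS)].copy()
        table["node_id"] = table["node_id"].astype(int)
        if table["node_id"].duplicated().any():
            dup = table.loc[table["node_id"].duplicated(), "node_id"].tolist()
            raise ValidationError(f"duplicate node_id values: {dup}")
        table = table.sort_values("node_id").reset_index(drop=True)
        n = len(table)
        if n == 0:
            raise ValidationError("atlas table is empty")
        if not np.array_equal(table["node_id"].to_numpy(), np.arange(1, n + 1)):
            raise ValidationError("node_id values must be contiguous 1..P")
        table["region"] = table["region"].astype(str).str.strip().str.lower()
        table["hemisphere"] = table["hemisphere"].astype(str).str.strip().str.lower()
        bad_hemi = set(table["hemisphere"]) - {"l", "r", "left", "right"}
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        table["hemisphere"] = table["hemisphere"].str[0]
        if strict or n == 268:
            unknown = set(table["region"]) - set(REGION_ORDER)
            if unknown:
                raise ValidationError(f"unknown macroscale region labels: {sorted(unknown)}")
        for c in ("mni_x", "mni_y", "mni_z"):
            table[c] = table[c].astype(float)
        self.table = table

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def regions(self) -> np.ndarray:
        """Region label of every node, index 0 == node 1."""
        return self.table["region"].to_numpy()

    @property
    def region_labels(self) -> tuple[str, ...]:
        """Region labels present, canonical order first, extras alphabetical."""
        present = set(self.table["region"])
        ordered = [r for r in REGION_ORDER if r in present]
        ordered += sorted(present - set(REGION_ORDER))
        return tuple(ordered)

    def region_sizes(self) -> dict[str, int]:
        counts = self.table["region"].value_counts()
        return {r: int(counts[r]) for r in self.region_labels}

    def __eq__(self, other) -> bool:
        return isinstance(other, AtlasDefinition) and self.table.equals(other.table)

    def __repr__(self) -> str:
        return f"AtlasDefinition(P={self.n_nodes}, regions={len(self.region_labels)})"


def _allocate_region_sizes(n_nodes: int) -> dict[str, int]:
    """Split ``n_nodes`` over the ten regions proportionally to the 268-node
    layout (largest-remainder rounding)."""
    total = sum(SHEN268_REGION_SIZES.values())
    quotas = {r: n_nodes * s / total for r, s in SHEN268_REGION_SIZES.items()}
    sizes = {r: int(q) for r, q in quotas.items()}
    short = n_nodes - sum(sizes.values())
    for r in sorted(quotas, key=lambda r: quotas[r] - int(quotas[r]), reverse=True)[:short]:
        sizes[r] += 1
    return sizes


def synthetic_atlas(n_nodes: int, seed: int = 268) -> AtlasDefinition:
    """Build a synthetic atlas with the reference macroscale layout.

    This is a synthetic stand-in for the Shen 268-node parcellation: the
    macroscale region sizes are exact for ``n_nodes == 268`` and proportional
    otherwise, but the MNI coordinates and network labels are generated, not
    the parcellation's real ones. Hemispheres alternate within each region;
    coordinates are drawn deterministically from ``seed`` with the x-sign
    tied to hemisphere.
    """
    if n_nodes == 268:
        sizes = dict(SHEN268_REGION_SIZES)
    else:
        sizes = _allocate_region_sizes(n_nodes)
    rng = np.random.default_rng(seed)
    rows = []
    node = 1
    for region in REGION_ORDER:
        for i in range(sizes[region]):
            hemi = "r" if i % 2 == 0 else "l"
            x = float(rng.uniform(5, 65)) * (1 if hemi == "r" else -1)
            y = float(rng.uniform(-100, 65))
            z = float(rng.uniform(-60, 75))
            rows.append(
                {
                    "node_id": node,
                    "region": region,
                    "hemisphere": hemi,
                    "network_name": f"{region}_{i // 4 + 1}",
                    "mni_x": round(x, 2),
                    "mni_y": round(y, 2),
                    "mni_z": round(z, 2),
                }
            )
            node += 1
    return AtlasDefinition(pd.DataFrame(rows))


def shen268_synthetic() -> AtlasDefinition:
    """The bundled 268-node reference fixture (synthetic coordinates)."""
    return synthetic_atlas(268)
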