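"""Reading and writing the pipeline's file formats.

Atlas and manifest are CSV with headers; connectivity matrices are one
``P x P`` delimited text file per subject (comma or whitespace, auto
detected); outputs are CSV tables plus a two-file plain-text node/edge
export loadable by external connectome viewers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition
from .core import ConnectomeCohort, EdgeIndex, edge_index_for
from .errors import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .summary import NetworkSummary

#: Maximum |X - X.T| tolerated; within it, the matrix is symmetrized by averaging.
SYMMETRY_TOL = 1e-6


def read_atlas(path: str | Path, *, strict: bool = False) -> AtlasDefinition:
    """Read an atlas CSV (node_id,region,hemisphere,network_name,mni_x,mni_y,mni_z)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse atlas file {path}: {exc}") from exc
    return AtlasDefinition(df, strict=strict)


def write_atlas(atlas: AtlasDefinition, path: str | Path) -> None:
    atlas.table.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the subject manifest CSV (subject_id,score[,covariate...])."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse manifest {path}: {exc}") from exc
    for col in ("subject_id", "score"):
        if col not in df.columns:
            raise FormatError(f"manifest missing required column '{col}'")
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        raise FormatError("duplicate subject_id in manifest")
    if df["score"].isna().any():
        missing = df.loc[df["score"].isna(), "subject_id"].tolist()
        raise ValidationError(f"missing score for subject(s): {missing}")
    return df


def _read_matrix(path: str | Path) -> np.ndarray:
    """Read a square delimited numeric matrix; delimiter auto-detected."""
    text = Path(path).read_text()
    delim = "," if "," in text.splitlines()[0] else None
    try:
        m = np.loadtxt(_io.StringIO(text), delimiter=delim)
    except ValueError as exc:
        raise FormatError(f"cannot parse matrix file {path}: {exc}") from exc
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"matrix in {path} is not square: shape {m.shape}")
    return m


def read_cohort(
    matrix_paths: Sequence[str | Path],
    manifest: str | Path | pd.DataFrame,
    atlas: AtlasDefinition,
) -> ConnectomeCohort:
    """Assemble a cohort from per-subject matrix files and a manifest.

    Matrix files are matched to manifest rows by filename stem == subject_id.
    Each matrix must be symmetric within :data:`SYMMETRY_TOL` (it is then
    averaged with its transpose); the strict upper triangle is kept and the
    diagonal discarded.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    by_stem = {Path(p).stem: Path(p) for p in matrix_paths}
    missing = [s for s in manifest["subject_id"] if s not in by_stem]
    if missing:
        raise ValidationError(f"no matrix file for subject(s): {missing}")
    p = atlas.n_nodes
    ei = edge_index_for(p)
    rows, subjects = [], []
    for sid in manifest["subject_id"]:
        m = _read_matrix(by_stem[sid])
        if m.shape[0] != p:
            raise ValidationError(
                f"subject {sid}: matrix is {m.shape[0]}x{m.shape[0]} but atlas has {p} nodes"
            )
        if not np.all(np.isfinite(m)):
            raise ValidationError(f"subject {sid}: non-finite entries in connectivity matrix")
        asym = np.max(np.abs(m - m.T))
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"subject {sid}: matrix asymmetric beyond tolerance ({asym:.2e} > {SYMMETRY_TOL})"
            )
        m = 0.5 * (m + m.T)
        rows.append(ei.vectorize(m))
        subjects.append(sid)
    x = np.vstack(rows)
    y = manifest["score"].to_numpy(dtype=float)
    return ConnectomeCohort(subjects=subjects, X=x, y=y, edge_index=ei, atlas=atlas)


def write_cohort(cohort: ConnectomeCohort, outdir: str | Path, fmt: str = "%.8g") -> Path:
    """Write a cohort as the standard layout: matrices/<sid>.csv + manifest.csv + atlas.csv."""
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(cohort.subjects):
        m = cohort.edge_index.devectorize(cohort.X[i])
        np.savetxt(outdir / "matrices" / f"{sid}.csv", m, delimiter=",", fmt=fmt)
    pd.DataFrame({"subject_id": cohort.subjects, "score": cohort.y}).to_csv(
        outdir / "manifest.csv", index=False
    )
    write_atlas(cohort.atlas, outdir / "atlas.csv")
    return outdir


def load_cohort_dir(path: str | Path) -> ConnectomeCohort:
    """Load a cohort written by :func:`write_cohort`."""
    path = Path(path)
    atlas = read_atlas(path / "atlas.csv")
    matrices = sorted((path / "matrices").glob("*"))
    return read_cohort(matrices, path / "manifest.csv", atlas)


def write_edge_report(summary: "NetworkSummary", atlas: AtlasDefinition, outdir: str | Path) -> dict[str, Path]:
    """Write the network characterization tables.

    Produces: per-edge table with both endpoints' metadata, sign and
    importance; node-degree table sorted descending; positive and negative
    10x10 macroscale count matrices; and a node/edge plain-text pair for
    connectome viewers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.csv",
        "degree": outdir / "node_degree.csv",
        "macro_pos": outdir / "macro_counts_pos.csv",
        "macro_neg": outdir / "macro_counts_neg.csv",
        "viewer_nodes": outdir / "network_nodes.txt",
        "viewer_edges": outdir / "network_edges.txt",
    }
    summary.edge_table(atlas).to_csv(paths["edges"], index=False)
    deg = pd.DataFrame(
        {"node_id": np.arange(1, atlas.n_nodes + 1), "degree": summary.node_degree}
    )
    deg = deg.sort_values(["degree", "node_id"], ascending=[False, True])
    deg.to_csv(paths["degree"], index=False)
    summary.macro_counts_pos.to_csv(paths["macro_pos"])
    summary.macro_counts_neg.to_csv(paths["macro_neg"])

    nodes = atlas.table
    with open(paths["viewer_nodes"], "w") as fh:
        for _, row in nodes.iterrows():
            fh.write(
                f"{row.node_id},{row.mni_x},{row.mni_y},{row.mni_z},{row.region}\n"
            )
    with open(paths["viewer_edges"], "w") as fh:
        for (i, j), t in zip(summary.edge_pairs, summary.edge_importance):
            fh.write(f"{i},{j},{t:.6g}\n")
    return paths
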