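"""Clustering of FBF binding frequencies into RNA blocks.

Target RNAs (genes with a significant peak) are represented by their
control-subtracted, log2-scaled reads-per-million across FBF iCLIP samples.
Average-linkage agglomerative clustering on Euclidean row distances, cut to
k flat clusters (default 5: four blocks of interest plus a residual),
yields the blocks; labels I-IV are assigned in order of decreasing
spermatogenic-to-oogenic binding ratio, so block I is sperm-enriched and
block IV oocyte-enriched. PCA over the same matrix gives the companion
projection in which the first component tracks overall binding frequency
and the second the gender ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

ROMAN = ("I", "II", "III", "IV")


@dataclass
class BindingMatrix:
    """log2(control-subtracted RPM + 1) per target RNA x FBF sample."""

    values: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    @property
    def n_rnas(self) -> int:
        return len(self.values)


def build_binding_matrix(
    rpm: pd.DataFrame,
    control_rpm_mean: pd.Series,
    targets: Sequence[str],
) -> BindingMatrix:
    """Control-subtract and log2-transform target-RNA RPM rows.

    value(g, s) = log2(max(rpm(g, s) - control_mean(g), 0) + 1); the clamp
    keeps zero binding at zero after the control subtraction. Rows that are
    all zero across samples (no reads-per-gene) are dropped and reported.
    """
    missing = [g for g in targets if g not in rpm.index]
    if missing:
        raise ValueError(f"targets absent from the RPM matrix: {missing[:5]}")
    sub = rpm.loc[list(targets)].sub(control_rpm_mean.loc[list(targets)], axis=0)
    values = np.log2(sub.clip(lower=0.0) + 1.0)
    zero_rows = values.index[(values == 0).all(axis=1)]
    kept = values.drop(index=zero_rows)
    return BindingMatrix(values=kept, dropped=list(zero_rows))


@dataclass
class BlockAssignment:
    """Per-RNA block labels plus the dendrogram they came from."""

    blocks: pd.Series  # values in {"I","II","III","IV","none"}
    linkage: np.ndarray
    ratio_by_block: dict[str, float]
    manual: set[str] = field(default_factory=set)

    def members(self, block: str) -> list[str]:
        return list(self.blocks.index[self.blocks == block])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.blocks.index,
            "block": self.blocks.values,
            "provenance": ["manual" if g in self.manual else "clustered"
                           for g in self.blocks.index],
        })


def _gender_split(columns: Sequence[str]) -> tuple[list[int], list[int]]:
    sperm = [i for i, c in enumerate(columns) if "sperm" in c.lower()]
    oocyte = [i for i, c in enumerate(columns) if
              "oocyte" in c.lower() or "oogenic" in c.lower()]
    if not sperm or not oocyte:
        raise ValueError(
            "could not infer genders from column names; need 'sperm' and "
            "'oocyte'/'oogenic' substrings"
        )
    return sperm, oocyte


def cluster_rnas(
    matrix: BindingMatrix,
    k: int = 5,
    method: str = "average",
) -> BlockAssignment:
    """Average-linkage Euclidean clustering cut to ``k`` flat clusters.

    The largest flat cluster is the residual ("none"); the remaining
    clusters are labeled I-IV by decreasing mean (sperm - oocyte) value, so
    the roman numerals order spermatogenic-to-oogenic binding ratio. Extra
    clusters beyond four also become "none".
    """
    X = matrix.values.to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError(f"need >= {k} rows to cut {k} clusters")
    Z = hierarchy.linkage(X, method=method, metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    sperm_idx, oocyte_idx = _gender_split(matrix.values.columns)
    ratio = X[:, sperm_idx].mean(axis=1) - X[:, oocyte_idx].mean(axis=1)

    sizes = {c: int((flat == c).sum()) for c in np.unique(flat)}
    residual = max(sizes, key=lambda c: (sizes[c], -c))
    others = [c for c in sizes if c != residual]
    mean_ratio = {c: float(ratio[flat == c].mean()) for c in others}
    ordered = sorted(others, key=lambda c: -mean_ratio[c])
    label_of = {residual: "none"}
    for name, c in zip(ROMAN, ordered):
        label_of[c] = name
    for c in ordered[len(ROMAN):]:
        label_of[c] = "none"
    labels = pd.Series(
        [label_of[c] for c in flat], index=matrix.values.index, name="block"
    )
    ratio_by_block = {
        name: float(ratio[labels.values == name].mean())
        for name in ROMAN if (labels == name).any()
    }
    return BlockAssignment(blocks=labels, linkage=Z, ratio_by_block=ratio_by_block)


def override_block(
    assignment: BlockAssignment, gene_id: str, block: str
) -> BlockAssignment:
    """Manually reassign one RNA's block; provenance is recorded."""
    if gene_id not in assignment.blocks.index:
        raise KeyError(f"unknown gene {gene_id}")
    if block not in ROMAN + ("none",):
        raise ValueError(f"invalid block {block!r}")
    assignment.blocks.loc[gene_id] = block
    assignment.manual.add(gene_id)
    return assignment


def pca_projection(
    matrix: BindingMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA over RNAs; deterministic sign convention.

    Each component's loading vector is flipped so its sum is >= 0. Returns
    (scores indexed by RNA, explained-variance fractions).
    """
    X = matrix.values.to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("need >= 3 rows for PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: principal components undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.where(Vt.sum(axis=1) < 0, -1.0, 1.0)
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U[:, :n_components] * S[:n_components]
    evr = (S**2 / (S**2).sum())[:n_components]
    cols = [f"PC{i+1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=matrix.values.index, columns=cols), evr


def filter_block_candidates(
    block_rnas: Sequence[str],
    peaks: Sequence,
    min_rpm: float = 25.0,
) -> list[str]:
    """The block-I paring rule: highest peak >= 25 RPM and FBE-containing.

    For each RNA, its highest peak (by per-million height) must reach
    ``min_rpm`` and hold >=1 canonical FBE in the peak window. RNAs without
    peaks are excluded.
    """
    best: dict[str, object] = {}
    for p in peaks:
        g = p.gene_id
        if g not in best or p.height_rpm > best[g].height_rpm:
            best[g] = p
    keep = []
    for g in block_rnas:
        p = best.get(g)
        if p is not None and p.height_rpm >= min_rpm and p.fbe:
            keep.append(g)
    return keep


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """The merge tree in Newick form, branch lengths from merge heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def write_block_tables(
    matrix: BindingMatrix,
    assignment: BlockAssignment,
    outdir: str | Path,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "binding_matrix": outdir / "binding_matrix.tsv",
        "blocks": outdir / "blocks.tsv",
        "dendrogram": outdir / "dendrogram.nwk",
    }
    matrix.values.to_csv(paths["binding_matrix"], sep="\t", index_label="gene_id")
    assignment.to_frame().to_csv(paths["blocks"], sep="\t", index=False)
    paths["dendrogram"].write_text(
        linkage_to_newick(assignment.linkage, list(matrix.values.index))
    )
    return paths
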