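"""Z-scoring, hierarchical clustering and the four sample-comparison layouts.

A clustered heatmap is built as: variability filter → sample ordering →
per-gene z-scoring → agglomerative clustering (average linkage, Euclidean
distance on the z-scored rows by default).  Genes are always clustered;
the sample axis is clustered only in ``free`` mode — the four comparison
types define a meaningful sample order that clustering would destroy:

* **Type I** — all samples of a single patient, in chronological order
  (evolution of one patient under treatment).
* **Type II** — the first (basal) sample of every patient.
* **Type III** — the second sample of every patient (post-treatment
  comparison).
* **Type IV** — first samples of all patients, then second samples, with
  the same patient order in both halves.

Z-scores are computed per gene across the *selected* samples only, so the
color scale always reflects the comparison actually shown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree

from .exceptions import ValidationError
from .filtering import FilterSpec, apply_filter
from .matrix import ExpressionMatrix

ANALYSIS_TYPES = ("I", "II", "III", "IV", "free")


@dataclass(frozen=True)
class Dendrogram:
    """A SciPy linkage matrix plus the labels it clusters."""

    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: tuple[str, ...]

    @property
    def leaf_order(self) -> list[int]:
        return list(leaves_list(self.merges))

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (1..n_clusters) per input item."""
        return fcluster(self.merges, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        root = to_tree(self.merges)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            parts = ",".join(
                f"{walk(child)}:{max(node.dist - child.dist, 0.0):.6g}"
                for child in (node.left, node.right)
            )
            return f"({parts})"

        return walk(root) + ";"


@dataclass(frozen=True)
class ClusteredHeatmap:
    zmatrix: ExpressionMatrix  # stage "zscored", rows/cols in original order
    gene_order: list[int]
    sample_order: list[int]
    gene_dendrogram: Dendrogram
    sample_dendrogram: Dendrogram | None
    analysis_type: str

    @property
    def ordered_values(self) -> pd.DataFrame:
        v = self.zmatrix.values
        return v.iloc[self.gene_order, self.sample_order]


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene to mean 0, SD 1 (sample SD) across samples.

    Genes with zero variance become all-zero rows, with a warning: they
    carry no contrast, but dropping them silently would desynchronize the
    filter's gene count from the heatmap.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("z-scores need >= 2 samples")
    values = matrix.values.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        names = [matrix.gene_ids[i] for i in np.flatnonzero(flat)[:5]]
        warnings.warn(
            f"{int(flat.sum())} constant gene(s) z-scored to zero (e.g. {names})",
            stacklevel=2,
        )
    z = np.where(sd == 0, 0.0, (values - mean) / np.where(sd == 0, 1.0, sd))
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns),
        code_class=matrix.code_class,
        stage="zscored",
    )


def hcluster(
    values: pd.DataFrame,
    axis: str = "genes",
    method: str = "average",
    metric: str = "euclidean",
) -> Dendrogram:
    """Agglomerative clustering of rows (``genes``) or columns (``samples``)."""
    if axis not in ("genes", "samples"):
        raise ValidationError(f"axis must be 'genes' or 'samples', got {axis!r}")
    data = values if axis == "genes" else values.T
    if data.shape[0] < 2:
        raise ValidationError(f"clustering needs >= 2 {axis}")
    merges = linkage(data.to_numpy(dtype=float), method=method, metric=metric)
    return Dendrogram(merges=merges, labels=tuple(data.index))


def order_samples(meta: pd.DataFrame, analysis_type: str) -> list[str]:
    """Sample ids in the order a comparison type prescribes.

    *meta* needs columns ``sample_id``, ``patient_id``, ``sample_order``
    (``collection_date`` is used as a chronology fallback).  Patients keep
    their order of first appearance in the table.
    """
    if analysis_type not in ("I", "II", "III", "IV"):
        raise ValidationError(f"unknown analysis type {analysis_type!r}")
    meta = meta.reset_index(drop=True)

    def chronology(group: pd.DataFrame) -> pd.DataFrame:
        if group["sample_order"].notna().all():
            return group.sort_values("sample_order", kind="stable")
        if "collection_date" in group and group["collection_date"].notna().all():
            return group.sort_values("collection_date", kind="stable")
        return group

    patients = list(dict.fromkeys(meta["patient_id"]))
    by_patient = {p: chronology(meta[meta["patient_id"] == p]) for p in patients}

    if analysis_type == "I":
        if len(patients) != 1:
            raise ValidationError(
                f"Type I compares samples of a single patient; got {len(patients)} patients"
            )
        return list(by_patient[patients[0]]["sample_id"])

    def nth_sample(position: int) -> list[str]:
        out = []
        for p in patients:
            group = by_patient[p]
            if len(group) <= position:
                raise ValidationError(
                    f"patient '{p}' has no sample #{position + 1}, "
                    f"required by Type {analysis_type}"
                )
            out.append(group["sample_id"].iloc[position])
        return out

    if analysis_type == "II":
        return nth_sample(0)
    if analysis_type == "III":
        return nth_sample(1)
    # Type IV: all first samples, then all second samples, same patient order
    return nth_sample(0) + nth_sample(1)


def build_heatmap(
    matrix: ExpressionMatrix,
    filter_spec: FilterSpec | None = None,
    analysis_type: str = "free",
    sample_meta: pd.DataFrame | None = None,
    linkage_method: str = "average",
    metric: str = "euclidean",
) -> ClusteredHeatmap:
    """Filter → order samples → z-score → cluster.

    In ``free`` mode both axes are clustered; for Types I–IV the sample
    axis keeps the type-defined order and only genes are clustered.
    """
    if analysis_type not in ANALYSIS_TYPES:
        raise ValidationError(f"unknown analysis type {analysis_type!r}")
    selected = matrix if filter_spec is None else apply_filter(matrix, filter_spec)

    if analysis_type == "free":
        ordered_ids = selected.sample_ids
    else:
        if sample_meta is None:
            raise ValidationError(f"Type {analysis_type} needs sample metadata")
        ordered_ids = order_samples(sample_meta, analysis_type)
        missing = [s for s in ordered_ids if s not in selected.sample_ids]
        if missing:
            raise ValidationError(f"ordered samples absent from matrix: {missing}")
        selected = selected.subset_samples(ordered_ids)

    z = zscore_rows(selected)
    gene_dend = hcluster(z.values, "genes", linkage_method, metric)
    if analysis_type == "free":
        sample_dend = hcluster(z.values, "samples", linkage_method, metric)
        sample_order = sample_dend.leaf_order
    else:
        sample_dend = None
        sample_order = list(range(len(ordered_ids)))
    return ClusteredHeatmap(
        zmatrix=z,
        gene_order=gene_dend.leaf_order,
        sample_order=sample_order,
        gene_dendrogram=gene_dend,
        sample_dendrogram=sample_dend,
        analysis_type=analysis_type,
    )


def export_heatmap(hm: ClusteredHeatmap, out_dir: str | Path, prefix: str = "heatmap") -> None:
    """Write the reordered z-matrix, axis orders and Newick dendrograms."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = hm.ordered_values
    ordered.to_csv(out / f"{prefix}_zmatrix.tsv", sep="\t", index_label="gene")
    (out / f"{prefix}_gene_order.txt").write_text("\n".join(ordered.index) + "\n")
    (out / f"{prefix}_sample_order.txt").write_text("\n".join(ordered.columns) + "\n")
    (out / f"{prefix}_genes.nwk").write_text(hm.gene_dendrogram.to_newick() + "\n")
    if hm.sample_dendrogram is not None:
        (out / f"{prefix}_samples.nwk").write_text(hm.sample_dendrogram.to_newick() + "\n")


def render_heatmap(hm: ClusteredHeatmap, path: str | Path) -> None:
    """Optional image rendering: diverging scale symmetric about 0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = hm.ordered_values
    limit = float(np.abs(ordered.to_numpy()).max() or 1.0)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * ordered.shape[1] + 2), max(4, 0.12 * ordered.shape[0] + 1))
    )
    im = ax.imshow(ordered.to_numpy(), cmap="RdBu_r", vmin=-limit, vmax=limit, aspect="auto")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=7)
    if ordered.shape[0] <= 60:
        ax.set_yticks(range(ordered.shape[0]), ordered.index, fontsize=6)
    else:
        ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
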