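"""Stage-specific expression profiling of proneuropeptide genes.

Raw per-stage read counts are normalized for library size (reads per
million, rpm) and optionally for transcript length (RPKM). Genes below 2
rpm in every stage are discarded, profiles are clustered hierarchically
under a Pearson correlation distance (d = 1 - r), and per-stage totals and
fraction-of-1 transforms reproduce the summary views of the study design
(13 life-cycle stages from fertilized egg to mature male/female).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

RAW, RPM, RPKM, FRACTION = "raw", "rpm", "rpkm", "fraction"


@dataclass(frozen=True)
class CountMatrix:
    """A gene x stage count matrix with its normalization state.

    ``data`` is indexed by gene id with one column per stage;
    ``library_sizes`` holds the per-stage total mapped reads and
    ``lengths`` the optional per-gene transcript length in bases.
    """

    data: pd.DataFrame
    library_sizes: Optional[pd.Series] = None
    lengths: Optional[pd.Series] = None
    normalization: str = RAW

    def __post_init__(self) -> None:
        if self.normalization not in (RAW, RPM, RPKM, FRACTION):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if (self.data.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is not None:
            missing = [s for s in self.data.columns if s not in self.library_sizes.index]
            if missing:
                raise ValueError(f"library sizes missing for stages {missing}")
        if self.lengths is not None:
            missing = [g for g in self.data.index if g not in self.lengths.index]
            if missing:
                raise ValueError(f"lengths missing for genes {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def stage_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of expression profiles.

    ``merge_tree`` is a scipy-style linkage matrix over the lexicographically
    sorted gene ids in ``gene_ids``; ``leaf_order`` is the dendrogram leaf
    permutation.
    """

    merge_tree: np.ndarray
    gene_ids: tuple[str, ...]
    leaf_order: tuple[str, ...]
    distance_metric: str
    linkage: str

    def cut(self, k: int) -> dict[str, int]:
        """Cut the tree into ``k`` flat clusters; labels keyed by gene id."""
        labels = hierarchy.fcluster(self.merge_tree, t=k, criterion="maxclust")
        return dict(zip(self.gene_ids, (int(x) for x in labels)))


def read_counts(
    counts_path, library_path, lengths_path=None
) -> CountMatrix:
    """Load a raw count matrix from TSV files.

    ``counts_path``: gene id column followed by one column per stage, with a
    header line of stage names. ``library_path``: two columns (stage, total
    reads). ``lengths_path``: optional two columns (gene, length in bases).
    """
    data = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    libs = pd.read_csv(
        library_path, sep="\t", comment="#", header=None, index_col=0
    ).iloc[:, 0]
    libs.index = libs.index.astype(str)
    libs = pd.to_numeric(libs, errors="coerce").dropna()  # tolerates a header line
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(
            lengths_path, sep="\t", comment="#", header=None, index_col=0
        ).iloc[:, 0]
        lengths.index = lengths.index.astype(str)
    return CountMatrix(
        data=data.astype(float),
        library_sizes=libs.astype(float),
        lengths=lengths.astype(float) if lengths is not None else None,
        normalization=RAW,
    )


def normalize_counts(m: CountMatrix, mode: str) -> CountMatrix:
    """Normalize raw counts to rpm or RPKM.

    rpm[g,s] = raw[g,s] / library_size[s] * 1e6;
    rpkm[g,s] = rpm[g,s] * 1e3 / length[g].
    """
    if mode not in (RPM, RPKM):
        raise ValueError(f"mode must be 'rpm' or 'rpkm', got {mode!r}")
    if m.library_sizes is None:
        raise ValueError("normalization requires library sizes")
    libs = m.library_sizes.reindex(m.data.columns).astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    rpm = m.data.astype(float).div(libs, axis=1) * 1e6
    if mode == RPM:
        return replace(m, data=rpm, normalization=RPM)
    if m.lengths is None:
        raise ValueError("RPKM normalization requires per-gene lengths")
    lengths = m.lengths.reindex(m.data.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpkm = rpm.mul(1e3 / lengths, axis=0)
    return replace(m, data=rpkm, normalization=RPKM)


def filter_min_expression(m: CountMatrix, min_rpm: float = 2.0) -> CountMatrix:
    """Keep genes with at least ``min_rpm`` in at least one stage (inclusive)."""
    if m.normalization != RPM:
        raise ValueError("filter_min_expression expects an rpm-normalized matrix")
    if min_rpm < 0:
        raise ValueError("min_rpm must be >= 0")
    keep = m.data.max(axis=1) >= min_rpm
    data = m.data.loc[keep]
    lengths = m.lengths.reindex(data.index) if m.lengths is not None else None
    return replace(m, data=data, lengths=lengths)


def pearson_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - Pearson r between rows.

    Rows with zero variance are uncorrelatable; they get distance 1 to every
    other row (diagonal stays 0) rather than raising, so constant
    low-expressors remain clusterable.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[flat, :] = 1.0
    dist[:, flat] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return (dist + dist.T) / 2.0


def cluster_profiles(m: CountMatrix, linkage: str = "average") -> ClusterResult:
    """Hierarchically cluster gene profiles under Pearson distance.

    Genes are sorted lexicographically first so the result does not depend
    on input row order (the documented tie-break).
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if len(m.data) < 2:
        raise ValueError("clustering needs at least 2 genes")
    if m.data.shape[1] < 2:
        raise ValueError("clustering needs at least 2 stages")
    data = m.data.sort_index()
    dist = pearson_distance_matrix(data.values)
    condensed = squareform(dist, checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(tree)
    ids = tuple(data.index)
    return ClusterResult(
        merge_tree=tree,
        gene_ids=ids,
        leaf_order=tuple(ids[i] for i in leaves),
        distance_metric="pearson",
        linkage=linkage,
    )


def stage_totals(m: CountMatrix, gene_subset: Optional[Sequence[str]] = None) -> pd.Series:
    """Per-stage sum of normalized values over a gene subset."""
    if m.normalization not in (RPM, RPKM):
        raise ValueError("stage_totals expects a normalized matrix")
    data = m.data
    if gene_subset is not None:
        unknown = [g for g in gene_subset if g not in data.index]
        if unknown:
            raise KeyError(f"unknown gene ids in subset: {unknown}")
        data = data.loc[list(gene_subset)]
    return data.sum(axis=0)


def fraction_transform(m: CountMatrix, mode: str = "sum") -> CountMatrix:
    """Transform each gene's profile to a fraction of 1.

    ``sum`` divides each row by its row sum (all-zero rows stay zero);
    ``max`` divides by the row maximum instead, an alternative reading of
    "normalized reads transformed to 1".
    """
    if mode not in ("sum", "max"):
        raise ValueError(f"mode must be 'sum' or 'max', got {mode!r}")
    denom = m.data.sum(axis=1) if mode == "sum" else m.data.max(axis=1)
    safe = denom.replace(0, np.nan)
    data = m.data.div(safe, axis=0).fillna(0.0)
    return replace(m, data=data, normalization=FRACTION)
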