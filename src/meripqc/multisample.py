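"""Multi-sample comparison: normalization, clustering, PCA,
gene-level heterogeneity and replicate consistency.

Sequencing-depth differences are removed with median-of-ratios-style
size factors computed from bin totals: s_j = y_j / geometric-mean(y),
so every normalized sample sums to the geometric mean of the raw
totals.  Sample relationships (hierarchical clustering on Euclidean
distance, PCA) then reflect signal shape rather than depth; outliers
and swapped samples separate from their replicate group.

Gene-specific coverage heterogeneity is the per-gene (mean, SD) of bin
counts; replicate consistency is the per-bin cross-replicate (mean, SD)
of normalized counts.  Both relationships are summarized with a
tri-cube-weighted local linear regression (lowess, span 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .annotation import BinIndex
from .counting import SampleCounts
from .errors import (
    EmptySampleError,
    GroupSizeError,
    InsufficientGenesError,
    MeripQCError,
)

__all__ = [
    "NormalizedMatrix",
    "Dendrogram",
    "PCAResult",
    "MeanSDCurve",
    "ConsistencyCurve",
    "normalize_matrix",
    "cluster_samples",
    "pca_samples",
    "gene_mean_sd",
    "replicate_consistency",
]

LOWESS_SPAN = 0.75
GRID_POINTS = 100


def _lowess_grid(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tri-cube weighted degree-1 local regression of y on x evaluated
    on a 100-point grid over the observed range."""
    lo, hi = float(np.min(x)), float(np.max(x))
    grid = np.linspace(lo, hi, GRID_POINTS)
    if lo == hi:  # degenerate abscissa: constant fit
        return grid, np.full(GRID_POINTS, float(np.mean(y)))
    fitted = lowess(y, x, frac=LOWESS_SPAN, it=0, xvals=grid)
    return grid, np.asarray(fitted, dtype=float)


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized bin x sample matrix.

    Rows are the bins with at least one read in some sample (all-zero
    rows carry no information and destabilize distances); ``bin_rows``
    maps rows back to BinIndex positions.
    """

    values: np.ndarray            # kept-bins x samples
    sample_ids: list[str]
    size_factors: np.ndarray
    raw_totals: np.ndarray
    bin_rows: np.ndarray          # indices into the BinIndex
    bin_index: BinIndex

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


def normalize_matrix(counts: list[SampleCounts]) -> NormalizedMatrix:
    """Divide each sample's bin counts by its size factor
    s_j = y_j / exp(mean log y), y_j the sample's bin total."""
    if len(counts) < 2:
        raise MeripQCError("normalization requires >= 2 samples")
    X = np.column_stack([c.bin_counts for c in counts]).astype(float)
    totals = X.sum(axis=0)
    if np.any(totals == 0):
        empty = [c.sample_id for c, t in zip(counts, totals) if t == 0]
        raise EmptySampleError(f"samples with zero bin reads: {empty}")
    gm = np.exp(np.mean(np.log(totals)))
    sf = totals / gm
    keep = X.sum(axis=1) > 0
    return NormalizedMatrix(
        values=X[keep] / sf,
        sample_ids=[c.sample_id for c in counts],
        size_factors=sf,
        raw_totals=totals,
        bin_rows=np.flatnonzero(keep),
        bin_index=counts[0].bin_index,
    )


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray
    sample_ids: list[str]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{parent_height - 0.0:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def cluster_samples(norm: NormalizedMatrix) -> Dendrogram:
    """Agglomerative clustering of samples, complete linkage on
    Euclidean distances between normalized bin-count columns."""
    if len(norm.sample_ids) < 2:
        raise MeripQCError("clustering requires >= 2 samples")
    D = pdist(norm.values.T, metric="euclidean")
    Z = linkage(D, method="complete")
    return Dendrogram(linkage_matrix=Z, sample_ids=list(norm.sample_ids))


@dataclass
class PCAResult:
    scores: np.ndarray            # samples x components
    explained_variance_ratio: np.ndarray
    sample_ids: list[str]
    degenerate: bool              # True when total variance is zero


def pca_samples(norm: NormalizedMatrix) -> PCAResult:
    """Column-centered (not variance-scaled) PCA of samples as
    observations over bins; explained-variance fractions sum to 1."""
    X = norm.values.T
    J = X.shape[0]
    if J < 2:
        raise MeripQCError("PCA requires >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc**2).sum())
    if total_var == 0.0:
        k = min(J, X.shape[1])
        return PCAResult(
            scores=np.zeros((J, k)),
            explained_variance_ratio=np.zeros(k),
            sample_ids=list(norm.sample_ids),
            degenerate=True,
        )
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        sample_ids=list(norm.sample_ids),
        degenerate=False,
    )


@dataclass
class MeanSDCurve:
    sample_id: str
    gene_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    grid: np.ndarray
    fitted: np.ndarray
    span: float


def gene_mean_sd(
    counts: SampleCounts,
    bin_index: BinIndex | None = None,
    min_genes: int = 10,
) -> MeanSDCurve:
    """Per-gene mean and SD of bin counts, with a local-regression
    summary of SD against mean.

    Heterogeneous coverage (enrichment peaks, PCR artifacts) raises the
    curve; an Input sample's curve should sit below its IP's.
    """
    bin_index = bin_index or counts.bin_index
    gene_ids, means, sds = [], [], []
    for gene in sorted(bin_index.gene_offsets):
        _, n = bin_index.gene_offsets[gene]
        if n < 2:
            continue
        vals = counts.gene_bin_counts(gene).astype(float)
        gene_ids.append(gene)
        means.append(vals.mean())
        sds.append(vals.std(ddof=1))
    if len(gene_ids) < min_genes:
        raise InsufficientGenesError(
            f"{counts.sample_id}: only {len(gene_ids)} genes with >= 2 bins"
        )
    means = np.array(means)
    sds = np.array(sds)
    grid, fitted = _lowess_grid(means, sds)
    return MeanSDCurve(
        sample_id=counts.sample_id,
        gene_ids=gene_ids,
        means=means,
        sds=sds,
        grid=grid,
        fitted=fitted,
        span=LOWESS_SPAN,
    )


@dataclass
class ConsistencyCurve:
    sample_ids: list[str]
    mu: np.ndarray                # per-bin cross-replicate mean
    s: np.ndarray                 # per-bin cross-replicate SD (ddof=1)
    grid: np.ndarray
    fitted: np.ndarray
    span: float


def replicate_consistency(
    norm: NormalizedMatrix, group: list[str]
) -> ConsistencyCurve:
    """Cross-replicate per-bin mean and SD of normalized counts for a
    replicate group, with a local-regression consistency curve."""
    if len(group) < 2:
        raise GroupSizeError(f"replicate group needs >= 2 samples, got {len(group)}")
    idx = [norm.sample_ids.index(s) for s in group]
    sub = norm.values[:, idx]
    mu = sub.mean(axis=1)
    s = sub.std(axis=1, ddof=1)
    grid, fitted = _lowess_grid(mu, s)
    return ConsistencyCurve(
        sample_ids=list(group), mu=mu, s=s, grid=grid, fitted=fitted, span=LOWESS_SPAN
    )
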