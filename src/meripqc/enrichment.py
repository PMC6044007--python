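"""Immunoprecipitation-efficiency metrics: ESES and the C-test.

ESES (exome signal extraction scaling) adapts signal extraction scaling
from ChIP-seq QC to the exome.  Per gene g and bin i, IP and Input bin
counts y_{t,g,i}, y_{c,g,i} are divided by their per-gene bin means
(removing expression-level differences), pooled, and the normalized IP
values sorted ascending.  With p_j and q_j the cumulative IP and Input
signal fractions along that order, the background cut is

    k = argmax_j |q_j - p_j|        (largest j on ties)

splitting the N bins into background (first k) and signal-enriched
(rest).  Reported metrics: scale factor max_j |q_j - p_j|, enriched
fraction (N - k)/N, and signal-read fraction 1 - p_k (share of the
cumulated IP signal falling in enriched bins).

The C-test is the exact conditional test of two Poisson means: under
H0: lambda_ip <= c * d * lambda_in (d the depth ratio), conditional on
the total T = x_ip + x_in, x_ip ~ Binomial(T, c*d/(1 + c*d)); the
p-value is the upper binomial tail.  The enrichment profile reports the
fraction of well-covered bins significant at each fold threshold c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .annotation import BinIndex
from .counting import SampleCounts
from .errors import DegenerateSignalError, FilterError, MeripQCError

__all__ = [
    "NormalizedGeneBins",
    "ESESResult",
    "CTestProfile",
    "normalize_gene_bins",
    "compute_eses",
    "c_test",
    "ctest_profile",
    "DEFAULT_FOLD_GRID",
]

DEFAULT_FOLD_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class NormalizedGeneBins:
    """Expression-normalized IP/Input bin signals for retained genes.

    ``keys[r] = (gene_id, bin_i)`` identifies the bin behind row r of
    the aligned vectors ``yhat_ip`` / ``yhat_input``; per retained gene
    the mean of each vector over its bins is exactly 1.
    """

    keys: list[tuple[str, int]]
    yhat_ip: np.ndarray
    yhat_input: np.ndarray
    gene_mean_ip: dict[str, float]
    gene_mean_input: dict[str, float]

    @property
    def n_bins(self) -> int:
        return len(self.keys)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_mean_ip)


@dataclass
class ESESResult:
    N: int
    p_curve: np.ndarray
    q_curve: np.ndarray
    k: int                       # 1-based background cut index
    scale_factor: float
    enriched_fraction: float
    signal_read_fraction: float
    sort_order: list[tuple[str, int]]  # rank -> (gene_id, bin_i)


@dataclass
class CTestProfile:
    fold_grid: tuple[float, ...]
    proportions: np.ndarray
    alpha: float
    n_bins_tested: int


def normalize_gene_bins(
    ip: SampleCounts,
    merged_input: SampleCounts,
    bin_index: BinIndex | None = None,
    min_gene_reads: int = 10,
) -> NormalizedGeneBins:
    """Divide each retained gene's bin counts by their per-gene mean.

    Genes with fewer than ``min_gene_reads`` exonic reads in either the
    IP sample or the merged Input are considered not readily detected
    and excluded (the Input-side filter also guarantees a nonzero
    normalizing mean).
    """
    bin_index = bin_index or ip.bin_index
    keys: list[tuple[str, int]] = []
    yt, yc = [], []
    mean_t: dict[str, float] = {}
    mean_c: dict[str, float] = {}
    for gene in sorted(bin_index.gene_offsets):
        t = ip.gene_bin_counts(gene).astype(float)
        c = merged_input.gene_bin_counts(gene).astype(float)
        if t.sum() < min_gene_reads or c.sum() < min_gene_reads:
            continue
        mt, mc = t.mean(), c.mean()
        mean_t[gene] = float(mt)
        mean_c[gene] = float(mc)
        yt.append(t / mt)
        yc.append(c / mc)
        keys.extend((gene, i) for i in range(len(t)))
    if not keys:
        raise FilterError(
            f"no gene retains >= {min_gene_reads} reads in both IP and Input"
        )
    return NormalizedGeneBins(
        keys=keys,
        yhat_ip=np.concatenate(yt),
        yhat_input=np.concatenate(yc),
        gene_mean_ip=mean_t,
        gene_mean_input=mean_c,
    )


def compute_eses(norm: NormalizedGeneBins) -> ESESResult:
    """ESES metrics from pooled normalized bin signals.

    Sorts the normalized IP signal ascending (ties broken by
    (gene_id, bin_i) for determinism), reorders the Input signal by the
    same permutation, forms cumulative fraction curves and locates the
    background cut at the largest gap between them.
    """
    N = norm.n_bins
    if N < 2:
        raise MeripQCError("ESES needs at least 2 bins")
    yt, yc = norm.yhat_ip, norm.yhat_input
    if not np.any(yt > 0):
        raise DegenerateSignalError("IP signal is identically zero")
    order = sorted(range(N), key=lambda r: (yt[r],) + norm.keys[r])
    yt_s, yc_s = yt[order], yc[order]
    p = np.cumsum(yt_s)
    q = np.cumsum(yc_s)
    p /= p[-1]
    q /= q[-1]
    gap = np.abs(q - p)
    m = gap.max()
    k = int(np.flatnonzero(gap == m)[-1]) + 1  # largest index on ties, 1-based
    return ESESResult(
        N=N,
        p_curve=p,
        q_curve=q,
        k=k,
        scale_factor=float(m),
        enriched_fraction=(N - k) / N,
        signal_read_fraction=float(1.0 - p[k - 1]),
        sort_order=[norm.keys[r] for r in order],
    )


def c_test(
    x_ip: int, x_in: int, depth_ratio: float = 1.0, fold: float = 1.0
) -> float:
    """Exact conditional test of two Poisson means.

    One-sided p-value for enrichment of the IP count ``x_ip`` over the
    Input count ``x_in`` beyond ``fold`` at depth ratio ``d`` (IP total
    over Input total): with T = x_ip + x_in and
    pi0 = fold*d / (1 + fold*d), p = P(Binomial(T, pi0) >= x_ip).
    """
    if x_ip < 0 or x_in < 0:
        raise MeripQCError("counts must be nonnegative")
    if x_ip + x_in == 0:
        raise MeripQCError("x_ip + x_in must be positive")
    if depth_ratio <= 0 or fold <= 0:
        raise MeripQCError("depth_ratio and fold must be positive")
    pi0 = fold * depth_ratio / (1.0 + fold * depth_ratio)
    return float(binom.sf(x_ip - 1, x_ip + x_in, pi0))


def ctest_profile(
    ip: SampleCounts,
    merged_input: SampleCounts,
    fold_grid: tuple[float, ...] = DEFAULT_FOLD_GRID,
    alpha: float = 0.05,
    min_bin_reads: int = 10,
) -> CTestProfile:
    """Fraction of well-covered bins significantly enriched at each fold.

    Only bins with strictly more than ``min_bin_reads`` combined reads
    are tested; the depth ratio is total IP reads over total Input
    reads.  Proportions are nonincreasing in the fold threshold.
    """
    x_ip = ip.bin_counts
    x_in = merged_input.bin_counts
    mask = (x_ip + x_in) > min_bin_reads
    if not mask.any():
        raise FilterError(f"no bin exceeds {min_bin_reads} combined reads")
    xi = x_ip[mask].astype(np.int64)
    xc = x_in[mask].astype(np.int64)
    T = xi + xc
    d = ip.total_reads / merged_input.total_reads
    props = []
    for c in fold_grid:
        pi0 = c * d / (1.0 + c * d)
        p = binom.sf(xi - 1, T, pi0)
        props.append(float(np.mean(p < alpha)))
    return CTestProfile(
        fold_grid=tuple(float(c) for c in fold_grid),
        proportions=np.array(props),
        alpha=alpha,
        n_bins_tested=int(mask.sum()),
    )
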