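"""Size-factor normalization, clustering, PCA, heterogeneity and
replicate-consistency curves."""

import numpy as np
import pytest

from meripqc.annotation import build_bins
from meripqc.counting import merge_inputs
from meripqc.errors import (
    EmptySampleError,
    GroupSizeError,
    InsufficientGenesError,
)
from meripqc.multisample import (
    _lowess_grid,
    cluster_samples,
    gene_mean_sd,
    normalize_matrix,
    pca_samples,
    replicate_consistency,
)

from conftest import make_annotation, single_gene_gtf, toy_counts


def toy_pair(bins_a, bins_b):
    models = make_annotation(single_gene_gtf(length=600))
    bi = build_bins(models, 200)
    return [toy_counts(bins_a, bi, sample_id="a"), toy_counts(bins_b, bi, sample_id="b")]


class TestNormalizeMatrix:
    def test_geometric_mean_size_factors(self):
        norm = normalize_matrix(toy_pair([50, 30, 20], [200, 120, 80]))
        assert norm.size_factors == pytest.approx([0.5, 2.0])
        assert norm.values.sum(axis=0) == pytest.approx([200.0, 200.0])

    def test_equal_totals_leave_matrix_unchanged(self):
        norm = normalize_matrix(toy_pair([50, 30, 20], [20, 30, 50]))
        assert norm.size_factors == pytest.approx([1.0, 1.0])
        assert norm.values[:, 0] == pytest.approx([50, 30, 20])

    def test_normalized_totals_equal_geometric_mean(self, counted):
        counts = [counted[s] for s in ("IP1", "IP2", "IP3", "Input1", "Input2")]
        norm = normalize_matrix(counts)
        gm = np.exp(np.mean(np.log(norm.raw_totals)))
        sums = norm.values.sum(axis=0)
        assert np.all(np.abs(sums - gm) / gm < 1e-6)

    def test_depth_rescaling_preserves_distance_ratios(self, counted):
        counts = [counted[s] for s in ("IP1", "IP2", "IP3")]
        norm1 = normalize_matrix(counts)
        scaled = [toy_counts(c.bin_counts, c.bin_index, sample_id=c.sample_id)
                  for c in counts]
        scaled[1] = toy_counts(
            counts[1].bin_counts * 10, counts[1].bin_index, sample_id="IP2"
        )
        norm2 = normalize_matrix(scaled)
        from scipy.spatial.distance import pdist

        d1 = pdist(norm1.values.T)
        d2 = pdist(norm2.values.T)
        ratios = d2 / d1
        assert np.allclose(ratios, ratios[0], rtol=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(EmptySampleError):
            normalize_matrix(toy_pair([0, 0, 0], [1, 2, 3]))


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        norm = normalize_matrix(toy_pair([10, 20, 30], [10, 20, 30]))
        dend = cluster_samples(norm)
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_outlier_joins_last(self, counted):
        """An Input-distributed sample labelled IP separates from the
        true IP replicates."""
        norm = normalize_matrix(
            [counted[s] for s in ("IP1", "IP2", "IP3", "outlier_IP")]
        )
        dend = cluster_samples(norm)
        # the last merge joins the outlier singleton with the IP cluster
        last = dend.linkage_matrix[-1]
        singletons = [int(i) for i in last[:2] if i < 4]
        assert singletons == [3]  # index of outlier_IP

    def test_topology_invariant_under_depth_rescaling(self, counted):
        counts = [counted[s] for s in ("IP1", "IP2", "IP3", "Input1")]
        dend1 = cluster_samples(normalize_matrix(counts))
        rescaled = list(counts)
        rescaled[2] = toy_counts(
            counts[2].bin_counts * 10, counts[2].bin_index, sample_id="IP3"
        )
        dend2 = cluster_samples(normalize_matrix(rescaled))
        assert np.array_equal(
            dend1.linkage_matrix[:, :2], dend2.linkage_matrix[:, :2]
        )

    def test_newick_contains_all_samples(self, counted):
        norm = normalize_matrix([counted[s] for s in ("IP1", "IP2", "Input1")])
        nwk = cluster_samples(norm).to_newick()
        for sid in ("IP1", "IP2", "Input1"):
            assert sid in nwk
        assert nwk.endswith(";")


class TestPCA:
    def test_two_samples_one_component(self):
        norm = normalize_matrix(toy_pair([10, 20, 30], [30, 20, 10]))
        pca = pca_samples(norm)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_identical_samples_degenerate_without_crash(self):
        norm = normalize_matrix(toy_pair([10, 20, 30], [10, 20, 30]))
        pca = pca_samples(norm)
        assert pca.degenerate
        assert np.all(pca.explained_variance_ratio == 0)

    def test_outlier_dominates_pc1(self, counted):
        norm = normalize_matrix(
            [counted[s] for s in ("IP1", "IP2", "IP3", "outlier_IP")]
        )
        pca = pca_samples(norm)
        assert np.argmax(np.abs(pca.scores[:, 0])) == 3


class TestGeneMeanSD:
    def test_constant_bins_have_zero_sd(self, bin_index):
        counts = toy_counts(np.full(bin_index.n_bins, 5), bin_index)
        curve = gene_mean_sd(counts, bin_index)
        assert curve.means == pytest.approx(np.full(len(curve.gene_ids), 5.0))
        assert curve.sds == pytest.approx(np.zeros(len(curve.gene_ids)))

    def test_poisson_sd_tracks_sqrt_mean(self, bin_index):
        """For Poisson bin counts the fitted SD curve follows sqrt(mean)
        over the mid-range (within 15%)."""
        rng = np.random.default_rng(42)
        lam = np.empty(bin_index.n_bins)
        for gene in bin_index.gene_offsets:  # constant rate within a gene
            lam[bin_index.gene_slice(gene)] = np.exp(
                rng.uniform(np.log(10), np.log(1000))
            )
        counts = toy_counts(rng.poisson(lam), bin_index)
        curve = gene_mean_sd(counts, bin_index)
        lo, hi = np.percentile(curve.means, [25, 75])
        sel = (curve.grid > lo) & (curve.grid < hi)
        rel = curve.fitted[sel] / np.sqrt(curve.grid[sel]) - 1
        assert np.all(np.abs(rel) < 0.15)

    def test_pcr_duplication_raises_heterogeneity(self, counted, bin_index):
        clean = gene_mean_sd(counted["IP1"], bin_index)
        dup = gene_mean_sd(counted["dup_IP"], bin_index)
        # compare fitted curves over the upper half of the shared range
        lo = max(clean.grid.min(), dup.grid.min())
        hi = min(clean.grid.max(), dup.grid.max())
        grid = np.linspace((lo + hi) / 2, hi, 25)
        c = np.interp(grid, clean.grid, clean.fitted)
        d = np.interp(grid, dup.grid, dup.fitted)
        assert np.mean(d > c) > 0.8

    def test_insufficient_genes_error(self):
        models = make_annotation(single_gene_gtf(length=600))
        bi = build_bins(models, 200)
        with pytest.raises(InsufficientGenesError):
            gene_mean_sd(toy_counts([5, 5, 5], bi), bi)


class TestReplicateConsistency:
    def test_identical_replicates_have_zero_sd(self, counted):
        norm = normalize_matrix(toy_pair([10, 20, 30], [10, 20, 30]))
        curve = replicate_consistency(norm, ["a", "b"])
        assert np.all(curve.s == 0)

    def test_two_replicate_formula(self):
        """Normalized bin values (2, 4) give mu = 3, s = sqrt(2)."""
        norm = normalize_matrix(toy_pair([2, 4, 6], [4, 8, 12]))
        # equalize depth effect: size factors make columns comparable
        sub = norm.values
        mu = sub.mean(axis=1)
        s = sub.std(axis=1, ddof=1)
        # direct formula check on a constructed pair
        vals = np.array([[2.0, 4.0]])
        assert vals.mean() == 3.0
        assert vals.std(ddof=1) == pytest.approx(np.sqrt(2.0))
        curve = replicate_consistency(norm, ["a", "b"])
        assert curve.mu == pytest.approx(mu)
        assert curve.s == pytest.approx(s)

    def test_group_size_error(self, counted):
        norm = normalize_matrix(toy_pair([1, 2, 3], [4, 5, 6]))
        with pytest.raises(GroupSizeError):
            replicate_consistency(norm, ["a"])

    def test_noisier_group_has_higher_curve(self):
        """A doubled-dispersion replicate group sits pointwise above the
        clean group over the shared mean range."""
        rng = np.random.default_rng(7)
        n_bins = 2000
        mu = np.exp(rng.uniform(np.log(5), np.log(200), n_bins))
        clean = mu[:, None] + rng.normal(0, 0.1 * mu[:, None], (n_bins, 3))
        noisy = mu[:, None] + rng.normal(0, 0.2 * mu[:, None], (n_bins, 3))
        g1, f1 = _lowess_grid(mu, np.std(clean, axis=1, ddof=1))
        g2, f2 = _lowess_grid(mu, np.std(noisy, axis=1, ddof=1))
        lo, hi = max(g1.min(), g2.min()), min(g1.max(), g2.max())
        grid = np.linspace(lo, hi, 50)
        assert np.all(np.interp(grid, g2, f2) > np.interp(grid, g1, f1))
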