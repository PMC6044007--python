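"""ESES metrics and the exact conditional Poisson-mean (C-) test."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meripqc.annotation import build_bins
from meripqc.counting import merge_inputs
from meripqc.enrichment import (
    NormalizedGeneBins,
    c_test,
    compute_eses,
    ctest_profile,
    normalize_gene_bins,
)
from meripqc.errors import FilterError, MeripQCError
from meripqc.simulate import SimulationSpec, make_transcriptome, simulate_counts

from conftest import make_annotation, single_gene_gtf, toy_counts


def binom_tail_exact(x, T, pi0: Fraction) -> Fraction:
    """Independent oracle: P(Binomial(T, pi0) >= x) by exact enumeration."""
    return sum(
        Fraction(comb(T, j)) * pi0**j * (1 - pi0) ** (T - j) for j in range(x, T + 1)
    )


def make_norm(yt, yc):
    yt = np.asarray(yt, dtype=float)
    return NormalizedGeneBins(
        keys=[("g", i) for i in range(len(yt))],
        yhat_ip=yt,
        yhat_input=np.asarray(yc, dtype=float),
        gene_mean_ip={"g": 1.0},
        gene_mean_input={"g": 1.0},
    )


class TestNormalizeGeneBins:
    def test_per_gene_mean_division(self):
        models = make_annotation(single_gene_gtf(length=600))
        bi = build_bins(models, 200)
        ip = toy_counts([2, 4, 6], bi)
        inp = toy_counts([10, 10, 10], bi, role="Input")
        norm = normalize_gene_bins(ip, merge_inputs([inp]), bi, min_gene_reads=10)
        assert norm.yhat_ip.tolist() == [0.5, 1.0, 1.5]
        assert norm.gene_mean_ip["g1"] == pytest.approx(4.0)

    def test_genes_below_ten_reads_excluded(self):
        models = make_annotation(single_gene_gtf(length=600))
        bi = build_bins(models, 200)
        ip = toy_counts([3, 3, 3], bi)  # 9 reads
        inp = toy_counts([10, 10, 10], bi, role="Input")
        with pytest.raises(FilterError):
            normalize_gene_bins(ip, merge_inputs([inp]), bi)

    def test_retained_gene_means_are_one(self, counted, merged_input, bin_index):
        norm = normalize_gene_bins(counted["IP1"], merged_input, bin_index)
        for gene in norm.gene_ids:
            rows = [i for i, (g, _) in enumerate(norm.keys) if g == gene]
            assert np.mean(norm.yhat_ip[rows]) == pytest.approx(1.0, abs=1e-9)
            assert np.mean(norm.yhat_input[rows]) == pytest.approx(1.0, abs=1e-9)


class TestESES:
    def test_worked_example(self):
        r = compute_eses(make_norm([0.5, 0.8, 1.2, 1.5], [1, 1, 1, 1]))
        assert np.allclose(r.p_curve, [0.125, 0.325, 0.625, 1.0])
        assert np.allclose(r.q_curve, [0.25, 0.5, 0.75, 1.0])
        assert r.k == 2
        assert r.scale_factor == pytest.approx(0.175)
        assert r.enriched_fraction == pytest.approx(0.5)
        assert r.signal_read_fraction == pytest.approx(0.675)

    def test_identical_ip_and_input_is_degenerate(self):
        y = np.array([0.2, 0.9, 1.4, 1.5])
        r = compute_eses(make_norm(y, y))
        assert r.scale_factor == 0.0
        assert r.k == 4
        assert r.enriched_fraction == 0.0
        assert r.signal_read_fraction == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_curve_invariants_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        yt = rng.gamma(1.0, 1.0, size=n)
        yc = rng.gamma(1.0, 1.0, size=n) + 1e-9
        r = compute_eses(make_norm(yt, yc))
        for curve in (r.p_curve, r.q_curve):
            assert np.all(np.diff(curve) >= -1e-12)
            assert curve[0] >= 0
            assert curve[-1] == pytest.approx(1.0)
        assert 0 <= r.scale_factor <= 1
        assert 0 <= r.enriched_fraction <= 1
        assert 1 <= r.k <= r.N
        assert r.scale_factor == pytest.approx(
            abs(r.q_curve[r.k - 1] - r.p_curve[r.k - 1])
        )

    def test_invariant_to_per_gene_expression_scaling(
        self, counted, merged_input, bin_index
    ):
        """Multiplying one gene's IP and Input counts by constants does
        not change ESES (the normalization divides expression out)."""
        ip = counted["IP1"]
        inp = merged_input
        gene = sorted(bin_index.gene_offsets)[3]
        sl = bin_index.gene_slice(gene)
        ip2 = toy_counts(ip.bin_counts.copy(), bin_index)
        in2 = toy_counts(inp.bin_counts.copy(), bin_index, role="Input")
        ip2.bin_counts[sl] *= 3
        in2.bin_counts[sl] *= 5
        r1 = compute_eses(normalize_gene_bins(ip, inp, bin_index))
        r2 = compute_eses(normalize_gene_bins(ip2, in2, bin_index))
        assert r1.k == r2.k
        assert r1.scale_factor == pytest.approx(r2.scale_factor)
        assert r1.enriched_fraction == r2.enriched_fraction


class TestCTest:
    def test_zero_ip_count_gives_p_one(self):
        assert c_test(0, 5) == 1.0
        assert c_test(0, 17, depth_ratio=2.0, fold=3.0) == 1.0

    def test_worked_value(self):
        assert c_test(10, 1) == pytest.approx(12 / 2048, abs=1e-15)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("c", [1.0, 2.0, 4.0])
    def test_matches_exact_enumeration_small_totals(self, d, c):
        pi0 = Fraction(c * d).limit_denominator(10**6)
        pi0 = pi0 / (1 + pi0)
        for T in range(1, 13):
            for x_ip in range(0, T + 1):
                exact = float(binom_tail_exact(x_ip, T, pi0))
                assert c_test(x_ip, T - x_ip, d, c) == pytest.approx(
                    exact, abs=1e-12
                )

    def test_monotone_in_ip_count_and_fold(self):
        T = 20
        ps = [c_test(x, T - x) for x in range(T + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        pcs = [c_test(15, 5, 1.0, c) for c in (1, 1.5, 2, 3, 4)]
        assert all(a <= b + 1e-15 for a, b in zip(pcs, pcs[1:]))

    def test_domain_errors(self):
        with pytest.raises(MeripQCError):
            c_test(-1, 5)
        with pytest.raises(MeripQCError):
            c_test(0, 0)


class TestCTestProfile:
    def test_nonincreasing_in_fold(self, counted, merged_input):
        for sid in ("IP1", "IP2", "IP3", "swap_IP"):
            prof = ctest_profile(counted[sid], merged_input)
            assert np.all(np.diff(prof.proportions) <= 1e-12)

    def test_min_bin_reads_filter(self, counted, merged_input):
        with pytest.raises(FilterError):
            ctest_profile(counted["IP1"], merged_input, min_bin_reads=10**9)

    def test_enrichment_raises_significant_fraction(self):
        """An 8x-enrichment sample shows more significant bins at fold 2
        than a matched no-enrichment twin."""
        spec = SimulationSpec(n_genes=15, seed=5)
        null_spec = SimulationSpec(n_genes=15, seed=5, peak_fold=1.0)
        ss = np.random.SeedSequence(5)
        s1, s2, s3 = ss.spawn(3)
        tr = make_transcriptome(spec, np.random.default_rng(s1))
        tr0 = make_transcriptome(null_spec, np.random.default_rng(s1))
        at_fold2 = {}
        for name, t, sp in (("enriched", tr, spec), ("null", tr0, null_spec)):
            ip = simulate_counts(t, sp, "IP", np.random.default_rng(s2))
            inp = simulate_counts(t, sp, "Input", np.random.default_rng(s3))
            inp.role = "Input"
            prof = ctest_profile(ip, merge_inputs([inp]))
            at_fold2[name] = prof.proportions[prof.fold_grid.index(2.0)]
        assert at_fold2["enriched"] > at_fold2["null"]
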