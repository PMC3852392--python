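"""Two-locus EM, D' confidence intervals and Gabriel-style block calling."""

import numpy as np
import pytest

from sweepscan.haploblocks import (
    HaploBlock,
    call_blocks,
    d_prime,
    dprime_ci,
    filter_large_blocks,
    two_locus_em,
)
from sweepscan.panel import MISSING

from conftest import make_map, make_panel


def genotypes_from_haplotypes(hap_a, hap_b):
    """Unphased two-marker genotypes from each individual's two haplotypes.

    ``hap_a[i]`` and ``hap_b[i]`` are individual i's haplotypes as
    (allele at marker 1, allele at marker 2).
    """
    hap_a, hap_b = np.asarray(hap_a), np.asarray(hap_b)
    return hap_a[:, 0] + hap_b[:, 0], hap_a[:, 1] + hap_b[:, 1]


class TestTwoLocusEM:
    def test_perfectly_correlated_markers(self):
        g = np.array([0, 0, 1, 1, 2, 2, 0, 2])
        f = two_locus_em(g, g)
        assert f is not None
        assert f.sum() == pytest.approx(1.0)
        assert d_prime(f) == pytest.approx(1.0)

    def test_equilibrium_markers(self):
        # haplotype counts exactly balanced (24 each of 00,01,10,11, paired
        # into unambiguous homozygote-pair individuals): D' = 0 exactly
        g1 = np.array([0] * 24 + [0] * 24 + [2] * 24 + [2] * 24)
        g2 = np.array([0] * 24 + [2] * 24 + [0] * 24 + [2] * 24)
        f = two_locus_em(g1, g2)
        assert np.allclose(f, 0.25)
        assert d_prime(f) == pytest.approx(0.0)

    def test_recovers_known_haplotype_frequencies(self):
        truth = np.array([0.4, 0.1, 0.2, 0.3])
        rng = np.random.default_rng(5)
        haps = rng.choice(4, size=400, p=truth)
        hap_alleles = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])[haps]
        g1, g2 = genotypes_from_haplotypes(hap_alleles[0::2], hap_alleles[1::2])
        f = two_locus_em(g1, g2)
        assert np.max(np.abs(f - truth)) < 0.05

    def test_marginal_frequencies_preserved(self):
        rng = np.random.default_rng(9)
        g1 = rng.integers(0, 3, 60)
        g2 = rng.integers(0, 3, 60)
        f = two_locus_em(g1, g2)
        assert f[2] + f[3] == pytest.approx(g1.mean() / 2, abs=1e-6)
        assert f[1] + f[3] == pytest.approx(g2.mean() / 2, abs=1e-6)

    def test_insufficient_data(self):
        assert two_locus_em(np.array([1, MISSING]), np.array([MISSING, 1])) is None


class TestDprimeCI:
    def test_complete_ld_large_n_is_strong(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 200)
        pair = dprime_ci(g, g)
        assert pair.klass == "strong_LD"
        assert pair.ci_high >= 0.98 and pair.ci_low >= 0.70

    def test_equilibrium_large_n_is_recombination(self):
        rng = np.random.default_rng(2)
        haps1 = rng.integers(0, 2, (300, 2))
        haps2 = rng.integers(0, 2, (300, 2))
        pair = dprime_ci(haps1.sum(axis=1), haps2.sum(axis=1))
        assert pair.klass == "recombination"
        assert pair.ci_high < 0.90

    def test_small_sample_is_uninformative(self):
        # perfect correlation but only 8 individuals: the likelihood profile
        # stays wide (ci_low < 0.70), so the pair is not called strong LD
        g = np.tile([0, 1, 2], 3)[:8]
        pair = dprime_ci(g, g)
        assert pair.klass == "uninformative"
        assert pair.ci_low < 0.70 and pair.ci_high >= 0.90

    def test_low_maf_is_uninformative(self):
        g1 = np.zeros(100, dtype=int)
        g1[:2] = 1
        g2 = np.ones(100, dtype=int)
        pair = dprime_ci(g1, g2)
        assert pair.klass == "uninformative"


def _block_panel(seed=0):
    """Three-chromosome panel: chr1 = one shared haplotype block (6 Mb),
    chr2 = independent markers, chr3 = short perfect block."""
    rng = np.random.default_rng(seed)
    n = 40
    # chr1: 7 markers spanning 6 Mb in two founder haplotypes
    hapA = np.array([0, 1, 0, 1, 1, 0, 1])
    hapB = 1 - hapA
    chr1 = np.array([
        rng.choice([hapA, hapB], p=[0.6, 0.4]) + rng.choice([hapA, hapB], p=[0.6, 0.4])
        for _ in range(n)
    ])
    chr2 = rng.integers(0, 2, (n, 5)) + rng.integers(0, 2, (n, 5))
    hapC = np.array([1, 0, 1])
    chr3 = np.array([
        rng.choice([hapC, 1 - hapC]) + rng.choice([hapC, 1 - hapC])
        for _ in range(n)
    ])
    calls = np.hstack([chr1, chr2, chr3]).astype(np.int8)
    chroms = ["chr1"] * 7 + ["chr2"] * 5 + ["chr3"] * 3
    pos = list(range(1_000_000, 7_000_001, 1_000_000)) + \
          list(range(1_000_000, 5_000_001, 1_000_000)) + \
          [1_000_000, 1_500_000, 2_000_000]
    markers = make_map(15, chrom=chroms)
    markers = type(markers)(markers.marker_id, markers.chromosome,
                            np.array(pos), markers.allele_ref, markers.allele_alt)
    return make_panel(calls, "P", markers)


class TestCallBlocks:
    def test_planted_blocks_recovered(self):
        panel = _block_panel()
        blocks = call_blocks(panel)
        by_chrom = {b.chromosome: b for b in blocks}
        assert "chr1" in by_chrom and by_chrom["chr1"].n_markers == 7
        assert by_chrom["chr1"].span_bp == 6_000_000
        assert "chr3" in by_chrom
        assert "chr2" not in by_chrom  # markers in equilibrium: no block

    def test_blocks_disjoint_and_outermost_strong(self):
        blocks = call_blocks(_block_panel(3))
        spans = {}
        for b in blocks:
            for i in range(b.first_index, b.last_index + 1):
                assert i not in spans
                spans[i] = b

    def test_distant_pairs_never_evaluated(self):
        # with max_pair_bp below the plant's span the full block cannot form
        blocks = call_blocks(_block_panel(), max_pair_bp=2_000_000)
        chr1_blocks = [b for b in blocks if b.chromosome == "chr1"]
        assert all(b.span_bp <= 2_000_000 for b in chr1_blocks)


class TestFilterLargeBlocks:
    def _mk(self, span_mb):
        return HaploBlock("chr1", 1_000_000, 1_000_000 + int(span_mb * 1e6), 0, 5, 6)

    def test_exact_5mb_excluded(self):
        assert filter_large_blocks([self._mk(5.0)]) == []

    def test_larger_included(self):
        # e.g. a 6.37 Mb block (95.48-101.85 Mb scale) passes the cut
        assert len(filter_large_blocks([self._mk(6.37)])) == 1

    def test_empty_input(self):
        assert filter_large_blocks([]) == []

    def test_sorted_output(self):
        blocks = [
            HaploBlock("chr2", 1, 7_000_000, 0, 1, 2),
            HaploBlock("chr1", 10_000_000, 17_000_000, 0, 1, 2),
            HaploBlock("chr1", 1, 7_000_000, 0, 1, 2),
        ]
        out = filter_large_blocks(blocks)
        assert [(b.chromosome, b.start_bp) for b in out] == [
            ("chr1", 1), ("chr1", 10_000_000), ("chr2", 1)]
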