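"""Distance arithmetic, exact Spearman permutation p-values, and cis pair calling."""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hepalnc.cis_pairing import (
    correlation,
    find_cis_pairs,
    format_distance_kb,
    genomic_distance,
)
from hepalnc.errors import ConfigurationError, ValidationError
from hepalnc.io_models import GeneLocus

from conftest import gene_loci, make_matrix


def locus(gid, chrom, start, end):
    return GeneLocus(gid, chrom, ".", start, end)


def bruteforce_exact_p(x, y):
    """Independent enumeration oracle: permute y, Spearman via corrcoef of ranks."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    count = 0
    for perm in permutations(range(n)):
        if abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / factorial(n)


class TestGenomicDistance:
    def test_published_separations(self):
        # mm9 loci of reported liver cis pairs
        lnc1 = locus("lnc1", "chr1", 195107465, 195110037)
        g0s2 = locus("G0s2", "chr1", 195098354, 195099382)
        assert genomic_distance(lnc1, g0s2) == 8083
        lnc3 = locus("lnc3", "chr3", 129227397, 129235123)
        elovl6 = locus("Elovl6", "chr3", 129235304, 129341411)
        assert genomic_distance(lnc3, elovl6) == 181

    def test_overlap_and_cross_chromosome(self):
        a = locus("a", "chr1", 100, 500)
        assert genomic_distance(a, a) == 0
        assert genomic_distance(a, locus("b", "chr1", 400, 900)) == 0
        assert genomic_distance(a, locus("c", "chr2", 100, 500)) is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=gene_loci(chrom="chr1"), b=gene_loci(chrom="chr1"))
    def test_symmetry(self, a, b):
        assert genomic_distance(a, b) == genomic_distance(b, a)

    def test_disjoint_ordered_loci_distances_increase(self):
        a = locus("a", "chr1", 100, 200)
        b = locus("b", "chr1", 500, 600)
        c = locus("c", "chr1", 5_000, 6_000)
        assert genomic_distance(a, c) >= genomic_distance(a, b)
        assert genomic_distance(a, c) >= genomic_distance(b, c)


class TestFormatDistanceKb:
    @pytest.mark.parametrize(
        "bp, expected",
        [
            (8083, "8.0"),
            (18151, "18.1"),
            (181, "0.18"),
            (2206, "2.2"),
            (86376, "86.3"),  # truncation: rounding would print 86.4
            (65487, "65.4"),  # truncation: rounding would print 65.5
            (999, "0.99"),
            (0, "0.00"),
            (1000, "1.0"),
        ],
    )
    def test_truncated_display(self, bp, expected):
        assert format_distance_kb(bp) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            format_distance_kb(-1)


class TestCorrelation:
    def test_perfect_monotone(self):
        rho, p = correlation([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 720)

    def test_perfect_antitone(self):
        rho, p = correlation([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 720)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            x = rng.uniform(0, 10, 6)
            y = rng.uniform(0, 10, 6)
            rho, p = correlation(x, y)
            assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
            assert p == pytest.approx(bruteforce_exact_p(x, y))

    def test_exact_p_with_ties_matches_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 3, 6).astype(float)  # heavy ties
            y = rng.uniform(0, 10, 6)
            if np.ptp(x) == 0:
                continue
            _, p = correlation(x, y)
            assert p == pytest.approx(bruteforce_exact_p(x, y))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        transform=st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_rho_invariant_under_increasing_transforms(self, seed, transform):
        g = np.random.default_rng(seed)
        x, y = g.uniform(0, 10, 6), g.uniform(0, 10, 6)
        f = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 0.1 * v + 7}[transform]
        rho1, p1 = correlation(x, y)
        rho2, p2 = correlation(f(x), y)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_vector_gives_nan(self, caplog):
        with caplog.at_level("WARNING"):
            rho, p = correlation([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert np.isnan(rho) and np.isnan(p)

    def test_large_n_uses_t_approximation(self, rng):
        x, y = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        rho, p = correlation(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_pearson_method(self, rng):
        x, y = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
        rho, p = correlation(x, y, method="pearson")
        ref = stats.pearsonr(x, y)
        assert rho == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestFindCisPairs:
    def planted_dataset(self, rng, n_pairs=10, n_null=50, gap=10_000):
        """Planted pairs (shared profile, zero noise) plus null genes far away."""
        loci, lnc_ids, cod_ids = [], [], []
        values, gene_ids = [], []
        pos = 1
        for i in range(n_pairs):
            lnc, cod = f"L{i}", f"C{i}"
            loci.append(locus(lnc, "chr1", pos, pos + 999))
            loci.append(locus(cod, "chr1", pos + 999 + gap, pos + 1998 + gap))
            pos += 500_000
            profile = np.sort(rng.uniform(1, 50, 6))
            for gid, scale in ((lnc, 1.0), (cod, 3.0)):
                gene_ids.append(gid)
                values.append(scale * profile)
            lnc_ids.append(lnc)
            cod_ids.append(cod)
        for j in range(n_null):
            gid = f"N{j}"
            loci.append(locus(gid, "chr2", 1 + j * 500_000, 1000 + j * 500_000))
            gene_ids.append(gid)
            values.append(rng.uniform(1, 50, 6))
            (lnc_ids if j % 2 else cod_ids).append(gid)
        matrix = make_matrix(np.array(values), gene_ids=gene_ids)
        return lnc_ids, cod_ids, matrix, loci

    def test_planted_pairs_recovered_exactly(self, rng):
        lnc_ids, cod_ids, matrix, loci = self.planted_dataset(rng)
        pairs = find_cis_pairs(lnc_ids, cod_ids, matrix, loci)
        assert {(p.lncrna_id, p.coding_id) for p in pairs} == {(f"L{i}", f"C{i}") for i in range(10)}
        assert all(p.rho == pytest.approx(1.0) and p.strength == "strong" for p in pairs)
        assert all(p.distance_bp == 10_000 for p in pairs)

    def test_cross_chromosome_pair_excluded(self):
        loci = [locus("L0", "chr1", 100, 200), locus("C0", "chr2", 100, 200)]
        profile = np.arange(1.0, 7.0)
        matrix = make_matrix(np.array([profile, profile * 2]), gene_ids=["L0", "C0"])
        assert find_cis_pairs(["L0"], ["C0"], matrix, loci) == []

    def test_distance_and_rho_threshold_monotonicity(self, rng):
        values = rng.lognormal(1, 1, size=(40, 6))
        gene_ids = [f"g{i}" for i in range(40)]
        matrix = make_matrix(values, gene_ids=gene_ids)
        loci = [locus(g, "chr1", 1 + i * 30_000, 1000 + i * 30_000) for i, g in enumerate(gene_ids)]
        lnc = gene_ids[::2]
        cod = gene_ids[1::2]

        def keys(**kw):
            return {(p.lncrna_id, p.coding_id) for p in
                    find_cis_pairs(lnc, cod, matrix, loci, alpha=0.5, **kw)}

        assert keys(max_distance=50_000) <= keys(max_distance=100_000)
        assert keys(r_coexpressed=0.9) <= keys(r_coexpressed=0.8)

    def test_strength_classes(self, rng):
        # rho >= 0.9 -> strong; 0.8 <= rho < 0.9 -> coexpressed
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([2, 1, 4, 3, 5, 6], dtype=float)  # two swaps: rho = 0.8857
        loci = [locus("L0", "chr1", 100, 200), locus("C0", "chr1", 300, 400)]
        matrix = make_matrix(np.array([x, y]), gene_ids=["L0", "C0"])
        (pair,) = find_cis_pairs(["L0"], ["C0"], matrix, loci)
        assert pair.rho == pytest.approx(0.8857, abs=1e-3)
        assert pair.strength == "coexpressed"

    def test_empty_de_lists_and_missing_locus(self, rng):
        matrix = make_matrix(rng.uniform(1, 2, (2, 6)), gene_ids=["a", "b"])
        loci = [locus("a", "chr1", 1, 10)]
        assert find_cis_pairs([], ["a"], matrix, loci) == []
        with pytest.raises(ConfigurationError, match="no locus"):
            find_cis_pairs(["b"], ["a"], matrix, loci)

    def test_constant_gene_skipped_with_warning(self, caplog):
        loci = [locus("L0", "chr1", 100, 200), locus("C0", "chr1", 300, 400)]
        matrix = make_matrix(np.array([[5.0] * 6, np.arange(1.0, 7.0)]), gene_ids=["L0", "C0"])
        with caplog.at_level("WARNING"):
            assert find_cis_pairs(["L0"], ["C0"], matrix, loci) == []
        assert any("constant expression" in r.message for r in caplog.records)
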