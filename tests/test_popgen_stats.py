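"""Diversity, differentiation and summary-vector estimators against
independent brute-force oracles."""

import numpy as np
import pytest

from conftest import matrix_from_arrays, random_matrix
from weedyrice.popgen_stats import (
    STAT_NAMES,
    abc_summary_vector,
    mfh_share,
    pi_theta,
    site_partition,
    summary_vector_from_arrays,
    tajimas_d,
    watterson_theta,
    weir_cockerham_fst,
)

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def brute_pi_per_site(column, idx):
    """Mean pairwise difference by explicit enumeration of all pairs."""
    vals = [column[i] for i in idx if column[i] >= 0]
    diffs = pairs = 0
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            pairs += 1
            diffs += int(vals[i] != vals[j])
    return diffs / pairs if pairs else 0.0


def brute_wc_fst(counts1, n1, counts2, n2):
    """Weir & Cockerham (1984) two-sample haploid estimator, written from
    the ANOVA mean squares."""
    p1, p2 = counts1 / n1, counts2 / n2
    n_tot = n1 + n2
    p_bar = (counts1 + counts2) / n_tot
    n_c = n_tot - (n1**2 + n2**2) / n_tot
    msp = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2)
    denom = msp + (n_c - 1) * msg
    return np.nan if denom == 0 else (msp - msg) / denom


# ---------------------------------------------------------------------------


class TestWattersonTheta:
    def test_matches_harmonic_formula(self):
        # 4 haplotypes, 2 segregating sites, locus length 100
        g = np.zeros((2, 4), dtype=np.int8)
        g[0, 0] = 1
        g[1, :2] = 1
        m = matrix_from_arrays(g, ["p"] * 4, {"L0": (2, 100)})
        a3 = 1 + 1 / 2 + 1 / 3
        assert watterson_theta(m, "p") == pytest.approx(2 / (100 * a3) * 1000)

    def test_monomorphic_locus_is_zero(self):
        g = np.zeros((1, 4), dtype=np.int8)   # minor allele count 0 -> no S
        m = matrix_from_arrays(g, ["p"] * 4, {"L0": (1, 100)})
        assert watterson_theta(m, "p") == 0.0

    def test_missing_data_uses_per_site_effective_n(self):
        g = np.array([[1, 0, 0, -1]], dtype=np.int8)   # effective n = 3
        m = matrix_from_arrays(g, ["p"] * 4, {"L0": (1, 100)})
        assert watterson_theta(m, "p") == pytest.approx(
            (1 / (1 + 1 / 2)) / 100 * 1000)


class TestPiTheta:
    def test_two_two_split(self):
        g = np.array([[1, 1, 0, 0]], dtype=np.int8)
        m = matrix_from_arrays(g, ["p"] * 4, {"L0": (1, 100)})
        assert pi_theta(m, "p") == pytest.approx((4 / 6) / 100 * 1000)

    def test_maximally_different_pair(self):
        g = np.ones((5, 2), dtype=np.int8)
        g[:, 1] = 0
        m = matrix_from_arrays(g, ["p"] * 2, {"L0": (5, 5)})
        assert pi_theta(m, "p") == pytest.approx(1000.0)

    def test_pi_invariant_to_label_partition_of_the_union(self, rng):
        g = rng.integers(0, 2, size=(6, 8)).astype(np.int8)
        m1 = matrix_from_arrays(g, ["a"] * 8)
        m2 = matrix_from_arrays(g, ["a"] * 4 + ["b"] * 4)
        # pi over the pooled sample ignores how labels split it
        assert pi_theta(m2, ["a", "b"]) == pi_theta(m1, "a")


class TestTajimasD:
    def test_undefined_without_segregating_sites(self):
        g = np.zeros((1, 6), dtype=np.int8)
        m = matrix_from_arrays(g, ["p"] * 6)
        assert np.isnan(tajimas_d(m, "p"))

    def test_excess_singletons_negative(self):
        g = np.zeros((5, 10), dtype=np.int8)
        for i in range(5):
            g[i, i] = 1
        m = matrix_from_arrays(g, ["p"] * 10)
        assert tajimas_d(m, "p") < 0

    def test_intermediate_frequencies_positive(self):
        g = np.zeros((3, 4), dtype=np.int8)
        g[:, :2] = 1
        m = matrix_from_arrays(g, ["p"] * 4)
        assert tajimas_d(m, "p") > 0

    def test_zero_when_pi_equals_watterson(self):
        # n=4: 3 sites at frequency 2/4 and 8 singletons give
        # k_hat = 6 = S/a1 exactly (a1 = 11/6, S = 11)
        g = np.zeros((11, 4), dtype=np.int8)
        g[:3, :2] = 1
        for i in range(8):
            g[3 + i, i % 4] = 1
        m = matrix_from_arrays(g, ["p"] * 4)
        assert tajimas_d(m, "p") == pytest.approx(0.0, abs=1e-12)


class TestSitePartition:
    @pytest.mark.parametrize("col1,col2,field", [
        ([0, 1], [0, 1], "shared"),
        ([0, 1], [0, 0], "private1"),
        ([0, 0], [0, 1], "private2"),
        ([0, 0], [1, 1], "fixed"),
    ])
    def test_single_site_classification(self, col1, col2, field):
        g = np.array([col1 + col2], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 2 + ["b"] * 2)
        part = site_partition(m, "a", "b")
        assert getattr(part, field) == 1
        assert part.total == 1

    def test_components_sum_to_union_total(self, rng):
        for _ in range(500):
            m, n1, n2 = random_matrix(rng, missing=True)
            part = site_partition(m, "pop1", "pop2")
            total = 0
            for row in m.genotypes:
                a = [x for x in row[:n1] if x >= 0]
                b = [x for x in row[n1:] if x >= 0]
                if not a or not b:
                    continue
                u = a + b
                if len(set(u)) == 2:
                    total += 1
            assert part.total == total

    def test_excluding_singletons_never_increases_counts(self, rng):
        for _ in range(100):
            m, _, _ = random_matrix(rng)
            p = site_partition(m, "pop1", "pop2")
            assert p.shared_nosingle <= p.shared
            assert p.private1_nosingle <= p.private1
            assert p.private2_nosingle <= p.private2


class TestWeirCockerhamFst:
    def test_complete_fixation_is_one(self):
        g = np.array([[0, 0, 1, 1]], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 2 + ["b"] * 2)
        fst = weir_cockerham_fst(m, "a", "b")
        assert fst.per_snp["fst"].iloc[0] == pytest.approx(1.0)

    def test_identical_allele_counts_clamp_to_zero(self):
        g = np.array([[0, 1, 0, 1]], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 2 + ["b"] * 2)
        fst = weir_cockerham_fst(m, "a", "b")
        assert fst.per_snp["raw"].iloc[0] < 0
        assert fst.per_snp["fst"].iloc[0] == 0.0

    def test_singleton_snps_never_enter(self):
        g = np.array([[1, 0, 0, 0, 0, 0]], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 3 + ["b"] * 3)
        fst = weir_cockerham_fst(m, "a", "b")
        assert fst.per_snp.empty

    def test_grand_mean_zero_pads_nonpolymorphic_loci(self):
        # three loci; the third has no polymorphism at all
        g = np.array([
            [0, 0, 1, 1],     # locus A: fst 1
            [0, 0, 1, 1],     # locus B: fst 1
            [0, 0, 0, 0],     # locus C: monomorphic
        ], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 2 + ["b"] * 2,
                               {"A": (1, 100), "B": (1, 100), "C": (1, 100)})
        fst = weir_cockerham_fst(m, "a", "b")
        assert fst.grand_mean == pytest.approx((1 + 1 + 0) / 3)
        assert fst.per_locus["C"] == 0.0

    def test_matches_textbook_formula_on_random_snps(self, rng):
        checked = 0
        while checked < 500:
            m, n1, n2 = random_matrix(rng, n_sites=1)
            row = m.genotypes[0]
            c1, c2 = int(row[:n1].sum()), int(row[n1:].sum())
            pooled_minor = min(c1 + c2, n1 + n2 - c1 - c2)
            if pooled_minor <= 1:
                continue
            expected = brute_wc_fst(c1, n1, c2, n2)
            fst = weir_cockerham_fst(m, "pop1", "pop2")
            assert fst.per_snp["raw"].iloc[0] == pytest.approx(
                expected, abs=1e-12)
            checked += 1


class TestMfhShare:
    def test_identical_populations_share_everywhere(self):
        g = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 2 + ["b"] * 2)
        assert mfh_share(m, "a", "b") == 1.0

    def test_disjoint_haplotypes_share_nothing(self):
        g = np.array([[1, 1, 0, 0]], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 2 + ["b"] * 2)
        assert mfh_share(m, "a", "b") == 0.0

    def test_fraction_counts_matching_loci(self):
        # 2 loci, MFH equal at exactly one
        g = np.array([[1, 1, 0, 0], [0, 0, 0, 0]], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 2 + ["b"] * 2,
                               {"A": (1, 50), "B": (1, 50)})
        assert mfh_share(m, "a", "b") == 0.5

    def test_ties_resolved_lexicographically(self):
        # pop1 split 1/1 between '0' and '1' haplotypes: MFH is '0'
        g = np.array([[0, 1, 0, 0]], dtype=np.int8)
        m = matrix_from_arrays(g, ["a"] * 2 + ["b"] * 2)
        assert mfh_share(m, "a", "b") == 1.0


class TestSummaryVector:
    def test_nested_weed_has_no_private_variants(self):
        # weed haplotypes are a subset of progenitor haplotypes
        g = np.array([[0, 0, 0, 1, 0, 0],
                      [0, 0, 1, 0, 0, 1]], dtype=np.int8)
        m = matrix_from_arrays(g, ["w"] * 2 + ["p"] * 4)
        sv = abc_summary_vector(m, "w", "p")
        assert sv.private_weed == 0

    def test_identical_monomorphic_panels_are_all_zero(self):
        g = np.zeros((0, 8), dtype=np.int8)
        m = matrix_from_arrays(g, ["w"] * 4 + ["p"] * 4)
        sv = abc_summary_vector(m, "w", "p")
        assert all(v == 0 for v in sv.as_dict().values())

    def test_matrix_and_array_paths_agree(self, rng):
        """The pandas-backed and the fast numpy summary paths are
        independent routes to the same eight numbers."""
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            g = rng.integers(0, 2, size=(int(rng.integers(1, 15)),
                                         n1 + n2)).astype(np.int8)
            m = matrix_from_arrays(g, ["w"] * n1 + ["p"] * n2,
                                   {"L0": (len(g), 800)})
            sv = abc_summary_vector(m, "w", "p").to_array()
            fast = summary_vector_from_arrays([g], n1, 800)
            np.testing.assert_allclose(sv, fast, atol=1e-12)

    def test_matches_per_site_enumeration(self, rng):
        for _ in range(30):
            g = rng.integers(0, 2, size=(10, 12)).astype(np.int8)
            m = matrix_from_arrays(g, ["w"] * 6 + ["p"] * 6,
                                   {"L0": (10, 1000)})
            sv = abc_summary_vector(m, "w", "p")
            s_w = s_p = fixed = pw = pp = sh = s_u = 0
            pi = 0.0
            for row in g:
                a, b, u = set(row[:6]), set(row[6:]), set(row)
                s_w += len(a) == 2
                s_p += len(b) == 2
                s_u += len(u) == 2
                sh += len(a) == 2 and len(b) == 2
                pw += len(a) == 2 and len(b) == 1
                pp += len(a) == 1 and len(b) == 2
                fixed += len(a) == 1 and len(b) == 1 and a != b
                pi += brute_pi_per_site(row, range(12))
            assert (sv.s_weed, sv.s_progenitor, sv.fixed, sv.private_weed,
                    sv.private_progenitor, sv.shared, sv.s_union) == \
                (s_w, s_p, fixed, pw, pp, sh, s_u)
            assert sv.pi_combined == pytest.approx(pi / 1000 * 1000)

    def test_stat_names_match_dataclass_order(self):
        sv = abc_summary_vector(
            matrix_from_arrays(np.zeros((0, 4), dtype=np.int8),
                               ["w"] * 2 + ["p"] * 2), "w", "p")
        assert tuple(sv.as_dict()) == STAT_NAMES


class TestDiversityOracles:
    def test_theta_and_pi_match_brute_force(self, rng):
        """Watterson and pi equal naive per-site recomputation on 500
        random matrices with missing data."""
        for _ in range(500):
            m, n1, _ = random_matrix(rng, missing=True)
            L = 1000
            w = pi = 0.0
            for row in m.genotypes:
                vals = [x for x in row[:n1] if x >= 0]
                n = len(vals)
                if n >= 2 and len(set(vals)) == 2:
                    w += 1.0 / sum(1.0 / i for i in range(1, n))
                pi += brute_pi_per_site(row, range(n1))
            assert watterson_theta(m, "pop1") == pytest.approx(
                w / L * 1000, abs=1e-12)
            assert pi_theta(m, "pop1") == pytest.approx(
                pi / L * 1000, abs=1e-12)


class TestPartitionPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_components_conserve_union_total(self, data):
        from hypothesis import strategies as st

        n1 = data.draw(st.integers(2, 5), label="n1")
        n2 = data.draw(st.integers(2, 5), label="n2")
        n_sites = data.draw(st.integers(1, 8), label="sites")
        rows = data.draw(st.lists(
            st.lists(st.integers(-1, 1), min_size=n1 + n2, max_size=n1 + n2),
            min_size=n_sites, max_size=n_sites), label="matrix")
        g = np.array(rows, dtype=np.int8)
        m = matrix_from_arrays(g, ["pop1"] * n1 + ["pop2"] * n2)
        part = site_partition(m, "pop1", "pop2")
        expected = 0
        for row in g:
            a = [x for x in row[:n1] if x >= 0]
            b = [x for x in row[n1:] if x >= 0]
            if a and b and len(set(a + b)) == 2:
                expected += 1
        assert part.total == expected
        assert (part.shared_nosingle + part.private1_nosingle
                + part.private2_nosingle + part.fixed_nosingle) <= expected


class TestEighthStatisticSlot:
    def test_singleton_alternative_counts_pooled_singletons(self):
        g = np.array([[1, 0, 0, 0, 0, 0],     # pooled singleton
                      [1, 1, 0, 0, 0, 0],     # doubleton
                      [1, 1, 1, 0, 0, 0]], dtype=np.int8)
        m = matrix_from_arrays(g, ["w"] * 3 + ["p"] * 3)
        default = abc_summary_vector(m, "w", "p")
        assert default.s_union == 3
        with pytest.warns(UserWarning, match="singletons_union"):
            alt = abc_summary_vector(m, "w", "p", eighth="singletons_union")
        assert alt.s_union == 1
        assert alt.to_array()[:7].tolist() == default.to_array()[:7].tolist()

    def test_unknown_slot_rejected(self):
        m = matrix_from_arrays(np.zeros((0, 4), dtype=np.int8),
                               ["w"] * 2 + ["p"] * 2)
        with pytest.raises(ValueError):
            abc_summary_vector(m, "w", "p", eighth="entropy")
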