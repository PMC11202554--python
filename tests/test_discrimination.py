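"""Contingency tests, count reconstruction, and fixed-difference screens."""

from math import comb

import numpy as np
import pytest
from scipy import stats

from snppanel import (
    chi_square_test,
    genotype_counts_from_frequencies,
    inbred_distinguishers,
    population_specific_loci,
)
from snppanel.reference_data import (
    INBRED_DISTINGUISHING_LOCI,
    OUTBRED_COHORT_SIZES,
    inbred_reference_matrix,
    seven_locus_count_tables,
    seven_locus_reference_matrix,
)
from snppanel.synthetic_data import (
    ColonyScenario,
    plant_line_distinguishers,
    simulate_colonies,
)
from tests.conftest import make_matrix


class TestCountReconstruction:
    def test_published_row_sums_to_cohort(self):
        assert list(genotype_counts_from_frequencies([0.08, 0.35, 0.57], 37)) == [3, 13, 21]

    def test_single_class(self):
        assert list(genotype_counts_from_frequencies([1.0], 32)) == [32]

    def test_largest_remainder_tiebreak_in_input_order(self):
        assert list(genotype_counts_from_frequencies([0.5, 0.5], 31)) == [16, 15]

    def test_sum_outside_tolerance_rejected(self):
        with pytest.raises(ValueError, match="outside tolerance"):
            genotype_counts_from_frequencies([0.5, 0.4], 30)

    def test_all_published_tables_sum_to_cohort_sizes(self):
        for locus, (counts, pops, _classes) in seven_locus_count_tables().items():
            for row, pop in zip(counts, pops):
                assert row.sum() == OUTBRED_COHORT_SIZES[pop], locus


def exact_permutation_pvalues(table: np.ndarray) -> tuple[float, float, float]:
    """Exhaustive label-permutation null of the Pearson statistic (2x2).

    Permuting sample labels with both margins fixed is the conditional
    (hypergeometric) null; returns (p_exact, mid_p, observed statistic).
    Independent of the implementation under test.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pearson(a_):
        cells = [a_, r1 - a_, c1 - a_, r2 - (c1 - a_)]
        expected = [r1 * c1 / n, r1 * (n - c1) / n, r2 * c1 / n, r2 * (n - c1) / n]
        return sum((o - e) ** 2 / e for o, e in zip(cells, expected) if e > 0)

    obs = pearson(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    p = mid = 0.0
    for a_ in range(lo, hi + 1):
        w = comb(r1, a_) * comb(r2, c1 - a_) / denom
        s = pearson(a_)
        if s > obs + 1e-9:
            p += w
            mid += w
        elif abs(s - obs) <= 1e-9:
            p += w
            mid += 0.5 * w
    return p, mid, obs


def small_2x2_tables(min_margin=3, n_max=12):
    from itertools import product

    for a, b, c, d in product(range(n_max + 1), repeat=4):
        n = a + b + c + d
        if not (2 * min_margin <= n <= n_max):
            continue
        if min(a + b, c + d, a + c, b + d) < min_margin:
            continue
        yield np.array([[a, b], [c, d]])


class TestChiSquare:
    def test_identical_rows_give_p_one(self):
        r = chi_square_test(np.array([[10, 5, 2], [10, 5, 2]]), ["X", "Y"], ["AA", "AB", "BB"])
        assert r.chi2 == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_zero_column_dropped_without_changing_statistic(self):
        base = np.array([[8, 2], [3, 7]])
        padded = np.array([[8, 0, 2], [3, 0, 7]])
        r1 = chi_square_test(base, ["X", "Y"], ["AA", "BB"])
        r2 = chi_square_test(padded, ["X", "Y"], ["AA", "AB", "BB"])
        assert r1.chi2 == pytest.approx(r2.chi2) and r1.df == r2.df

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 20, size=(3, 3))
        r = chi_square_test(t, list("XYZ"), list("abc"))
        rp = chi_square_test(t[[2, 0, 1]][:, [1, 2, 0]], list("ZXY"), list("bca"))
        assert r.chi2 == pytest.approx(rp.chi2) and r.p == pytest.approx(rp.p)

    def test_degenerate_table_has_undefined_p(self):
        r = chi_square_test(np.array([[5, 5], [0, 0]]), ["X", "Y"], ["AA", "BB"])
        assert r.p is None and r.chi2 is None

    def test_statistic_exact_on_full_permutation_support(self):
        """Our Pearson statistic equals the independent hand formula on
        every table of the exhaustive permutation support."""
        rng = np.random.default_rng(6)
        tables = [t for t in small_2x2_tables()]
        for t in [tables[k] for k in rng.choice(len(tables), 25, replace=False)]:
            (a, b), (c, d) = t
            r1, c1 = a + b, a + c
            for a_ in range(max(0, c1 - (c + d)), min(r1, c1) + 1):
                perm = np.array([[a_, r1 - a_], [c1 - a_, (c + d) - (c1 - a_)]])
                if perm.min(axis=0).sum() == 0 or perm.min(axis=1).sum() == 0:
                    continue
                _, mid, obs = exact_permutation_pvalues(perm)
                ours = chi_square_test(perm, ["X", "Y"], ["A", "B"])
                if ours.chi2 is not None:
                    assert ours.chi2 == pytest.approx(obs, abs=1e-9)
                    assert ours.df == 1

    def test_p_within_small_sample_gap_of_permutation_null(self):
        """Asymptotic p tracks the exhaustive permutation mid-p within the
        analytic worst-case gap of the chi-square approximation on this
        table family (computed here by exhaustive scan, not assumed)."""
        family = list(small_2x2_tables())
        gap = 0.0
        for t in family:
            _, mid, obs = exact_permutation_pvalues(t)
            p_asym = float(stats.chi2.sf(obs, 1))
            gap = max(gap, abs(p_asym - mid))
        rng = np.random.default_rng(10)
        for t in [family[k] for k in rng.choice(len(family), 50, replace=False)]:
            r = chi_square_test(t, ["X", "Y"], ["A", "B"])
            _, mid, _ = exact_permutation_pvalues(t)
            assert abs(r.p - mid) <= gap + 1e-12


class TestPopulationSpecificLoci:
    def test_monomorphic_pattern_flagged(self):
        m = make_matrix(
            {
                "CMU": [["GG"]] * 8,
                "Dalian": [["AA"], ["AG"], ["AG"], ["GG"], ["GG"], ["AA"], ["AG"], ["GG"]],
            },
            ["MG15x"],
        )
        flagged, _ = population_specific_loci(m, alpha=0.05)
        assert [r.locus for r in flagged] == ["MG15x"]
        assert flagged[0].monomorphic_in == ["CMU"]

    def test_identical_distributions_not_flagged(self):
        rows = [["AA"], ["AG"], ["GG"], ["AG"]]
        m = make_matrix({"X": rows, "Y": rows}, ["L"])
        flagged, results = population_specific_loci(m, alpha=0.05)
        assert flagged == [] and results[0].p == pytest.approx(1.0)

    def test_all_seven_published_loci_flagged(self):
        m = seven_locus_reference_matrix()
        flagged, results = population_specific_loci(m, alpha=0.001)
        assert len(flagged) == 7
        assert all(r.p < 0.001 for r in results)

    def test_require_pattern_gate(self):
        """The categorical gate keeps only loci with monomorphic or
        fixed-different patterns (four of the seven published loci)."""
        m = seven_locus_reference_matrix()
        flagged, _ = population_specific_loci(m, alpha=0.001, require_pattern=True)
        assert {r.locus for r in flagged} == {"MG15", "MG89", "MG126", "MG215"}

    def test_fixed_different_pattern(self):
        m = make_matrix({"X": [["CC"]] * 5, "Y": [["TT"]] * 5}, ["L"])
        _, results = population_specific_loci(m, alpha=0.05)
        assert results[0].fixed_different


class TestInbredDistinguishers:
    def test_all_fifteen_published_loci_reported(self):
        m = inbred_reference_matrix()
        cmp = inbred_distinguishers(m, "CerebralIschemia", "Diabetes")
        assert cmp.n_distinguishing == 15
        published = {
            (row[0], row[6], row[7]) for row in INBRED_DISTINGUISHING_LOCI
        }
        got = {
            (locus, "/".join(sorted(ga.split("/"))), "/".join(sorted(gb.split("/"))))
            for locus, ga, gb in cmp.distinguishing
        }
        normalized = {
            (l, "/".join(sorted(a.split("/"))), "/".join(sorted(b.split("/"))))
            for l, a, b in published
        }
        assert got == normalized

    def test_same_fixed_allele_not_reported(self):
        m = make_matrix({"A": [["CC"]] * 3, "B": [["CC"]] * 3}, ["L"])
        assert inbred_distinguishers(m, "A", "B").n_distinguishing == 0

    def test_fixed_heterozygote_not_reported(self):
        m = make_matrix({"A": [["CT"]] * 3, "B": [["CC"]] * 3}, ["L"])
        cmp = inbred_distinguishers(m, "A", "B")
        assert cmp.n_distinguishing == 0
        assert cmp.monomorphic_both == 1  # uniform, just not a fixed difference

    def test_segregating_line_not_reported(self):
        m = make_matrix({"A": [["CC"], ["TT"], ["CC"]], "B": [["TT"]] * 3}, ["L"])
        cmp = inbred_distinguishers(m, "A", "B")
        assert cmp.n_distinguishing == 0 and cmp.monomorphic_a == 0

    def test_planted_recovery(self):
        sim = simulate_colonies(ColonyScenario(n_loci=60, seed=19))
        planted = plant_line_distinguishers(sim, "CerebralIschemia", "Diabetes", k=9, seed=3)
        cmp = inbred_distinguishers(
            sim.matrix, "CerebralIschemia", "Diabetes"
        )
        got = {locus for locus, _, _ in cmp.distinguishing}
        # all planted loci recovered; extras can only be naturally co-fixed
        assert set(planted) <= got
        for locus in got - set(planted):
            counts_a = sim.matrix.genotype_counts(locus, "CerebralIschemia")
            counts_b = sim.matrix.genotype_counts(locus, "Diabetes")
            assert len(counts_a) == 1 and len(counts_b) == 1
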