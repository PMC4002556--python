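import numpy as np
import pytest

from oracles import (
    augmented_ranks_bruteforce,
    disorder_bruteforce,
    expand_table,
    random_table,
    rp_bruteforce,
    rv_uniform_closed_form,
)
from ordagree import (
    ContingencyTable,
    MeasureValue,
    PairedAssessments,
    augmented_mean_ranks,
    contingency_from_pairs,
    disorder_measure,
    percentage_agreement,
    relative_position,
    relative_rank_variance,
    spearman_rho,
)


class TestPercentageAgreement:
    def test_diagonal_only_is_one(self):
        t = ContingencyTable(np.diag([3, 1, 4, 1, 5]))
        assert percentage_agreement(t).estimate == 1.0

    def test_uniform_5x5(self, uniform5):
        assert percentage_agreement(uniform5).estimate == pytest.approx(0.2)

    def test_off_diagonal_single_cell_is_zero(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 3] = 7
        assert percentage_agreement(ContingencyTable(counts)).estimate == 0.0


class TestRelativePosition:
    def test_fully_polarized_is_one(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 4] = 12
        t = ContingencyTable(counts)
        assert relative_position(t).estimate == 1.0
        assert relative_position(t.transpose()).estimate == -1.0

    def test_single_diagonal_cell_is_zero(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[2, 2] = 9
        assert relative_position(ContingencyTable(counts)).estimate == 0.0

    def test_hand_enumeration(self):
        p = PairedAssessments.from_tuples([(1, 2), (1, 2), (2, 2)])
        rp = relative_position(contingency_from_pairs(p))
        assert rp.estimate == pytest.approx(2 / 3, abs=1e-12)


class TestAugmentedRanks:
    def test_single_subject(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 1
        ar = augmented_mean_ranks(ContingencyTable(counts))
        assert ar.rx[0, 0] == ar.ry[0, 0] == 1.0

    def test_uniform_2x2_hand_ordering(self, uniform2):
        ar = augmented_mean_ranks(uniform2)
        assert np.array_equal(ar.rx, [[1, 2], [3, 4]])
        assert np.array_equal(ar.ry, [[1, 3], [2, 4]])

    def test_weighted_rank_sums_complete(self, rng):
        for _ in range(20):
            counts = random_table(rng)
            t = ContingencyTable(counts)
            ar = augmented_mean_ranks(t)
            total = t.n * (t.n + 1) / 2
            assert (counts * ar.rx).sum() == pytest.approx(total)
            assert (counts * ar.ry).sum() == pytest.approx(total)

    def test_occupied_ranks_within_bounds(self, rng):
        counts = random_table(rng, m=5, n=30)
        ar = augmented_mean_ranks(ContingencyTable(counts))
        occ = counts > 0
        for r in (ar.rx, ar.ry):
            assert (r[occ] >= 1).all() and (r[occ] <= counts.sum()).all()

    def test_matches_explicit_sorting(self, rng):
        for _ in range(30):
            counts = random_table(rng)
            ar = augmented_mean_ranks(ContingencyTable(counts))
            bx, by = augmented_ranks_bruteforce(counts)
            occ = counts > 0
            assert np.allclose(ar.rx[occ], bx[occ])
            assert np.allclose(ar.ry[occ], by[occ])


class TestRelativeRankVariance:
    def test_uniform_5x5_maximum(self, uniform5):
        rv = relative_rank_variance(uniform5).estimate
        assert rv == pytest.approx(0.6144, abs=1e-12)
        assert round(rv, 2) == 0.61

    def test_diagonal_only_is_zero(self):
        t = ContingencyTable(np.diag([2, 0, 5, 1, 3]))
        assert relative_rank_variance(t).estimate == 0.0

    def test_uniform_2x2(self, uniform2):
        assert relative_rank_variance(uniform2).estimate == pytest.approx(0.1875)

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("per_cell", [1, 3])
    def test_uniform_closed_form(self, m, per_cell):
        t = ContingencyTable(np.full((m, m), per_cell))
        assert relative_rank_variance(t).estimate == pytest.approx(
            rv_uniform_closed_form(m), abs=1e-12)

    def test_small_n_reversal_exceeds_one_unclipped(self):
        # documented behaviour: the [0, 1] range is asymptotic
        t = ContingencyTable([[0, 1], [1, 0]])
        assert relative_rank_variance(t).estimate == pytest.approx(1.5)


class TestDisorder:
    def test_single_disordered_pair(self):
        p = PairedAssessments.from_tuples([(1, 3), (2, 2)])
        assert disorder_measure(p).estimate == 1.0

    def test_concordant_pair(self):
        p = PairedAssessments.from_tuples([(1, 3), (3, 4)])
        assert disorder_measure(p).estimate == 0.0

    def test_one_of_three(self):
        p = PairedAssessments.from_tuples([(1, 3), (2, 2), (3, 4)])
        assert disorder_measure(p).estimate == pytest.approx(1 / 3)

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            disorder_measure(PairedAssessments.from_tuples([(1, 1)]))

    def test_table_route_equals_pairs_route(self, rng):
        for _ in range(20):
            counts = random_table(rng)
            t = ContingencyTable(counts)
            assert disorder_measure(t).estimate == pytest.approx(
                disorder_measure(t.to_pairs()).estimate, abs=1e-12)

    def test_ties_not_disordered(self):
        p = PairedAssessments.from_tuples([(2, 2), (2, 3), (3, 2)])
        # pairs tied on either coordinate: only {(2,3),(3,2)} is disordered
        assert disorder_measure(p).estimate == pytest.approx(1 / 3)


class TestSpearman:
    def test_perfect_monotone(self):
        p = PairedAssessments.from_tuples([(1, 1), (2, 2), (3, 3)])
        assert spearman_rho(p).estimate == pytest.approx(1.0)

    def test_perfect_reversal(self):
        p = PairedAssessments.from_tuples([(1, 3), (2, 2), (3, 1)])
        assert spearman_rho(p).estimate == pytest.approx(-1.0)

    def test_classic_formula_no_ties(self):
        p = PairedAssessments.from_tuples([(1, 2), (2, 1), (3, 3)])
        assert spearman_rho(p).estimate == pytest.approx(0.5)

    def test_constant_column_rejected(self):
        p = PairedAssessments.from_tuples([(2, 1), (2, 3), (2, 2)])
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman_rho(p)


class TestOracleEquivalence:
    """Dual-route checks against naive enumeration on random tables."""

    def test_rp_marginal_formula_vs_cross_pairs(self, rng):
        for _ in range(60):
            counts = random_table(rng)
            got = relative_position(ContingencyTable(counts)).estimate
            assert got == pytest.approx(rp_bruteforce(counts), abs=1e-12)

    def test_disorder_cell_formula_vs_enumeration(self, rng):
        for _ in range(60):
            counts = random_table(rng)
            a, b = expand_table(counts)
            got = disorder_measure(ContingencyTable(counts)).estimate
            assert got == pytest.approx(disorder_bruteforce(a, b), abs=0)


class TestStructuralProperties:
    def _tables(self, rng, k=30):
        return [random_table(rng) for _ in range(k)]

    def test_rp_antisymmetric_under_transpose(self, rng):
        for counts in self._tables(rng):
            t = ContingencyTable(counts)
            assert relative_position(t.transpose()).estimate == pytest.approx(
                -relative_position(t).estimate, abs=1e-12)

    def test_rv_d_pa_symmetric_under_transpose(self, rng):
        for counts in self._tables(rng):
            t, tt = ContingencyTable(counts), ContingencyTable(counts).transpose()
            assert relative_rank_variance(tt).estimate == pytest.approx(
                relative_rank_variance(t).estimate, abs=1e-12)
            assert disorder_measure(tt).estimate == pytest.approx(
                disorder_measure(t).estimate, abs=1e-12)
            assert percentage_agreement(tt).estimate == pytest.approx(
                percentage_agreement(t).estimate, abs=1e-12)

    def test_rank_invariance_under_relabeling(self, rng):
        # embed each m×m table into a larger grid via a strictly increasing
        # relabeling of the shared category scale; all measures unchanged
        for _ in range(20):
            counts = random_table(rng, m=3, n=25)
            t = ContingencyTable(counts)
            big = np.zeros((6, 6), dtype=int)
            new = np.sort(rng.choice(6, size=3, replace=False))
            big[np.ix_(new, new)] = counts
            tb = ContingencyTable(big)
            for f in (percentage_agreement, relative_position,
                      relative_rank_variance, disorder_measure):
                assert f(tb).estimate == pytest.approx(f(t).estimate, abs=1e-12)

    def test_perfect_agreement_implies_null_disagreement(self, rng):
        diag = np.diag(rng.integers(1, 6, size=5))
        t = ContingencyTable(diag)
        assert percentage_agreement(t).estimate == 1.0
        assert relative_position(t).estimate == 0.0
        assert relative_rank_variance(t).estimate == 0.0
        assert disorder_measure(t).estimate == 0.0


class TestMeasureValue:
    def test_range_validation(self):
        with pytest.raises(ValueError):
            MeasureValue("PA", 1.5)
        with pytest.raises(ValueError):
            MeasureValue("RP", 0.2, lower=0.5, upper=0.1)
        with pytest.raises(ValueError):
            MeasureValue("XX", 0.0)

    def test_rv_above_one_allowed(self):
        MeasureValue("RV", 1.5)  # small-n pathological tables
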