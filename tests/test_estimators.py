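"""Unit and property tests for the plug-in information estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scanpath_ais.estimators import (
    DistributionTable,
    EmptyTableError,
    bias_correction,
    conditional_entropy,
    conditional_mutual_information,
    entropy,
    entropy_of_codes,
    joint_code,
    mutual_information,
)

from oracles import (
    conditional_entropy_oracle,
    conditional_mutual_information_oracle,
    entropy_oracle,
    mutual_information_oracle,
    probs_from_counts,
)

TOL = 1e-10


def random_table(rng, arity, n_symbols=3, n_cells=6, max_count=9):
    cells = rng.integers(0, n_symbols, size=(n_cells, arity))
    counts = {}
    for cell in map(tuple, cells):
        counts[cell] = counts.get(cell, 0) + int(rng.integers(1, max_count))
    return DistributionTable.from_counts(counts)


class TestEntropy:
    def test_uniform_over_four(self):
        t = DistributionTable.from_counts({(0,): 5, (1,): 5, (2,): 5, (3,): 5})
        assert entropy(t).value == pytest.approx(2.0, abs=TOL)

    def test_degenerate_single_symbol(self):
        t = DistributionTable.from_counts({(0,): 10})
        assert entropy(t).value == pytest.approx(0.0, abs=TOL)

    def test_dyadic_distribution(self):
        t = DistributionTable.from_counts({(0,): 2, (1,): 1, (2,): 1})
        assert entropy(t).value == pytest.approx(1.5, abs=TOL)

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyTableError):
            DistributionTable.from_counts({})

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = random_table(rng, arity=1)
            expect = entropy_oracle(probs_from_counts(t.counts))
            assert entropy(t).value == pytest.approx(expect, abs=TOL)


class TestConditionalEntropy:
    def test_independent_variables(self):
        # product table: counts(x, y) = cx * cy
        cx, cy = [3, 1], [2, 2, 4]
        counts = {(i, j): a * b for i, a in enumerate(cx) for j, b in enumerate(cy)}
        t = DistributionTable.from_counts(counts)
        hx = entropy(t.marginal((0,))).value
        assert conditional_entropy(t, (0,), (1,)).value == pytest.approx(hx, abs=TOL)

    def test_deterministic_function_of_condition(self):
        counts = {(0, 0): 4, (1, 1): 3, (0, 2): 2}  # x fully determined by y
        t = DistributionTable.from_counts(counts)
        assert conditional_entropy(t, (0,), (1,)).value == pytest.approx(0.0, abs=TOL)

    def test_matches_double_sum_oracle_3x3(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            counts = {
                (i, j): int(c)
                for (i, j), c in np.ndenumerate(rng.integers(0, 8, size=(3, 3)))
                if c > 0
            }
            if not counts:
                continue
            t = DistributionTable.from_counts(counts)
            expect = conditional_entropy_oracle(probs_from_counts(counts), (0,), (1,))
            assert conditional_entropy(t, (0,), (1,)).value == pytest.approx(
                expect, abs=TOL
            )


class TestMutualInformation:
    def test_identity_coupling(self):
        counts = {(0, 0): 3, (1, 1): 5, (2, 2): 2}
        t = DistributionTable.from_counts(counts)
        hx = entropy(t.marginal((0,))).value
        assert mutual_information(t, (0,), (1,)).value == pytest.approx(hx, abs=TOL)

    def test_product_table_gives_zero(self):
        counts = {(i, j): (i + 1) * (j + 2) for i in range(2) for j in range(3)}
        t = DistributionTable.from_counts(counts)
        assert mutual_information(t, (0,), (1,)).value == pytest.approx(0.0, abs=TOL)

    def test_2x2_against_direct_evaluation(self):
        counts = {(0, 0): 4, (0, 1): 1, (1, 0): 1, (1, 1): 4}
        t = DistributionTable.from_counts(counts)
        expect = mutual_information_oracle(probs_from_counts(counts), (0,), (1,))
        assert mutual_information(t, (0,), (1,)).value == pytest.approx(expect, abs=TOL)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            t = random_table(rng, arity=2)
            mi_xy = mutual_information(t, (0,), (1,)).value
            mi_yx = mutual_information(t, (1,), (0,)).value
            assert mi_xy == pytest.approx(mi_yx, abs=TOL)
            assert mi_xy >= -1e-12
            assert mi_xy <= entropy(t.marginal((0,))).value + 1e-12
            assert mi_xy <= entropy(t.marginal((1,))).value + 1e-12


class TestConditionalMutualInformation:
    def test_empty_condition_reduces_to_mi(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, arity=2)
        cmi = conditional_mutual_information(t, (0,), (1,), ()).value
        mi = mutual_information(t, (0,), (1,)).value
        assert cmi == pytest.approx(mi, abs=TOL)

    def test_conditionally_independent_copies(self):
        # X and Y both exact copies of Z -> I(X;Y|Z) = 0
        counts = {(z, z, z): c for z, c in [(0, 3), (1, 5), (2, 2)]}
        t = DistributionTable.from_counts(counts)
        assert conditional_mutual_information(t, (0,), (1,), (2,)).value == pytest.approx(
            0.0, abs=TOL
        )

    def test_random_2x2x2_against_chain_rule_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            counts = {
                (i, j, k): int(c)
                for (i, j, k), c in np.ndenumerate(rng.integers(0, 6, size=(2, 2, 2)))
                if c > 0
            }
            if len(counts) < 2:
                continue
            t = DistributionTable.from_counts(counts)
            expect = conditional_mutual_information_oracle(
                probs_from_counts(counts), (0,), (1,), (2,)
            )
            got = conditional_mutual_information(t, (0,), (1,), (2,)).value
            assert got == pytest.approx(expect, abs=TOL)
            assert got >= -1e-12


class TestChainRulesAndDPI:
    def test_chain_rules_hold_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            t = random_table(rng, arity=2)
            h_joint = entropy(t).value
            h_y = entropy(t.marginal((1,))).value
            h_x_given_y = conditional_entropy(t, (0,), (1,)).value
            assert h_joint == pytest.approx(h_y + h_x_given_y, abs=TOL)
            h_x = entropy(t.marginal((0,))).value
            mi = mutual_information(t, (0,), (1,)).value
            assert mi == pytest.approx(h_x - h_x_given_y, abs=TOL)

    def test_data_processing_inequality_on_markov_triples(self):
        # exact population tables with X -> Z -> Y structure:
        # counts(x,z,y) = a(x) b(x,z) d(z,y) makes Y independent of X given Z
        rng = np.random.default_rng(6)
        for _ in range(25):
            a = rng.integers(1, 5, size=2)
            b = rng.integers(1, 4, size=(2, 2))
            d = rng.integers(1, 4, size=(2, 2))
            counts = {
                (x, z, y): int(a[x] * b[x, z] * d[z, y])
                for x in range(2)
                for z in range(2)
                for y in range(2)
            }
            t = DistributionTable.from_counts(counts)
            i_xy = mutual_information(t.marginal((0, 2)), (0,), (1,)).value
            i_xz = mutual_information(t.marginal((0, 1)), (0,), (1,)).value
            assert i_xy <= i_xz + 1e-10


class TestBiasCorrection:
    def test_single_symbol_support_zero_correction(self):
        t = DistributionTable.from_counts({(0,): 10})
        assert bias_correction(t, "entropy", method="mm") == 0.0
        assert bias_correction(t, "entropy", method="pt") == 0.0

    def test_first_order_term_halves_when_n_doubles(self):
        counts = {(0,): 6, (1,): 3, (2,): 1}
        doubled = {k: 2 * v for k, v in counts.items()}
        c1 = bias_correction(DistributionTable.from_counts(counts), "entropy", method="mm")
        c2 = bias_correction(DistributionTable.from_counts(doubled), "entropy", method="mm")
        assert c2 == pytest.approx(c1 / 2, rel=1e-12)

    def test_unknown_quantity_rejected(self):
        t = DistributionTable.from_counts({(0,): 1, (1,): 1})
        with pytest.raises(ValueError):
            bias_correction(t, "free_energy")

    @pytest.mark.parametrize("method", ["mm", "pt"])
    def test_corrected_entropy_closer_to_truth(self, method):
        """Monte-Carlo: corrected mean entropy beats the raw plug-in at n=50."""
        p = np.array([0.4, 0.3, 0.2, 0.1])
        true_h = float(-(p * np.log2(p)).sum())
        rng = np.random.default_rng(7)
        raw, corrected = [], []
        for _ in range(1000):
            sample = rng.choice(4, size=50, p=p)
            t = DistributionTable.from_samples(sample[:, None])
            est = entropy(t, correct_bias=True, method=method)
            corrected.append(est.value)
            raw.append(est.uncorrected)
        assert abs(np.mean(corrected) - true_h) < abs(np.mean(raw) - true_h)

    def test_pt_correction_at_least_mm(self):
        # the support-size estimate can only grow the correction
        rng = np.random.default_rng(8)
        for _ in range(20):
            sample = rng.choice(6, size=25)
            t = DistributionTable.from_samples(sample[:, None])
            mm = bias_correction(t, "entropy", method="mm")
            pt = bias_correction(t, "entropy", method="pt")
            assert pt >= mm - 1e-12


class TestFastCodePaths:
    def test_entropy_of_codes_matches_table_route(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            codes = rng.integers(0, 5, size=40)
            t = DistributionTable.from_samples(codes[:, None])
            assert entropy_of_codes(codes) == pytest.approx(entropy(t).value, abs=TOL)

    def test_joint_code_is_injective_on_pairs(self):
        rng = np.random.default_rng(10)
        a = rng.integers(0, 7, size=100)
        b = rng.integers(0, 4, size=100)
        codes = joint_code(a, b)
        pairs = {(x, y) for x, y in zip(a, b)}
        assert len(np.unique(codes)) == len(pairs)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=10), min_size=4, max_size=4).filter(
        lambda c: sum(c) > 0
    )
)
def test_entropy_bounds_property(counts):
    """0 <= H <= log2(observed support) for any 4-cell count vector."""
    table = {(i,): c for i, c in enumerate(counts) if c > 0}
    t = DistributionTable.from_counts(table)
    h = entropy(t).value
    assert -1e-12 <= h <= np.log2(t.support_size()) + 1e-12
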