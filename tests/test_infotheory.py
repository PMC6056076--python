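"""Count tables and the six information measures against independent oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from conftest import dataset_from_rows
from pkdb.infotheory import (
    InfoConfig,
    conditional_local_mutual_information,
    conditional_mutual_information,
    count_tables,
    local_mutual_information,
    mutual_information,
    pointwise_conditional_mutual_information,
    pointwise_mutual_information,
)

BITS = InfoConfig(log_base=2.0)
NATS = InfoConfig(log_base=math.e)


# --- independent oracles over raw rows ------------------------------------


def _joint(rows, cols):
    """Empirical distribution of the tuple of the given columns."""
    c = Counter(tuple(r[j] for j in cols) for r in rows)
    n = len(rows)
    return {k: v / n for k, v in c.items()}


def _mi_sets(rows, a_cols, b_cols):
    """I(A; B) over column sets, plain summation in bits."""
    pab = _joint(rows, a_cols + b_cols)
    pa = _joint(rows, a_cols)
    pb = _joint(rows, b_cols)
    total = 0.0
    for k, p in pab.items():
        ka, kb = k[: len(a_cols)], k[len(a_cols):]
        total += p * math.log2(p / (pa[ka] * pb[kb]))
    return total


def _cmi_sets(rows, a_cols, b_cols, c_cols):
    """I(A; B | C) over column sets in bits."""
    pabc = _joint(rows, a_cols + b_cols + c_cols)
    pac = _joint(rows, a_cols + c_cols)
    pbc = _joint(rows, b_cols + c_cols)
    pc = _joint(rows, c_cols)
    na, nb = len(a_cols), len(b_cols)
    total = 0.0
    for k, p in pabc.items():
        ka, kb, kc = k[:na], k[na:na + nb], k[na + nb:]
        total += p * math.log2(p * pc[kc] / (pac[ka + kc] * pbc[kb + kc]))
    return total


def _rows_with_class(ds):
    return [tuple(r) + (y,) for r, y in zip(ds.X.tolist(), ds.y.tolist())]


# --- counting --------------------------------------------------------------


class TestCountTables:
    def test_table3_frequencies(self, table3, table3_counts):
        c = table3_counts
        assert c.n_total == 6
        assert c.pair_count(0, 1, 1, 1) == 3  # (Xi=b, Xj=d)
        assert c.value_count(1, 1) == 4  # Xj=d
        assert c.triple_count(0, 1, 1, 1, 2, 0) == 3  # (b, d, e)

    def test_single_instance(self):
        ds = dataset_from_rows([[0, 1]], [0], [2, 2], 1)
        c = count_tables(ds)
        assert c.pair_count(0, 0, 1, 1) == 1
        assert c.pair_count(0, 1, 1, 0) == 0
        assert c.value_count(0, 0) == 1

    def test_matches_nested_loop_recount(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=5, n_instances=50, seed=7)
        c = count_tables(ds)
        rows = list(zip(ds.X.tolist(), ds.y.tolist()))
        for i, j in itertools.combinations(range(5), 2):
            for vi in range(ds.arities[i]):
                for vj in range(ds.arities[j]):
                    naive = sum(1 for r, _ in rows if r[i] == vi and r[j] == vj)
                    assert c.pair_count(i, vi, j, vj) == naive
        for i, j, k in itertools.combinations(range(5), 3):
            vi, vj, vk = ds.X[0, i], ds.X[0, j], ds.X[0, k]
            naive = sum(
                1 for r, _ in rows if (r[i], r[j], r[k]) == (vi, vj, vk)
            )
            assert c.triple_count(i, vi, j, vj, k, vk) == naive

    def test_marginalisation_consistency(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=4, n_instances=80, seed=3)
        c = count_tables(ds)
        for (i, j), t in c.pair_class.items():
            assert np.array_equal(t.sum(axis=(1, 2)), c.value_class[i].sum(axis=1))
            assert np.array_equal(t.sum(axis=(0, 2)), c.value_class[j].sum(axis=1))
            assert np.array_equal(t.sum(axis=(0, 1)), c.class_counts)
        for (i, j, k), t in c.triple.items():
            assert np.array_equal(t.sum(axis=2), c.pair_class[(i, j)].sum(axis=2))
        assert c.class_counts.sum() == c.n_total

    def test_decrement_equals_recount(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=4, n_instances=30, seed=11)
        full = count_tables(ds)
        dec = full.decremented(ds.X[5], int(ds.y[5]))
        ref = count_tables(ds.without_row(5))
        assert dec.n_total == ref.n_total
        assert np.array_equal(dec.class_counts, ref.class_counts)
        for a, b in zip(dec.value_class, ref.value_class):
            assert np.array_equal(a, b)
        for key in full.pair_class:
            assert np.array_equal(dec.pair_class[key], ref.pair_class[key])
        for key in full.triple:
            assert np.array_equal(dec.triple[key], ref.triple[key])


# --- averaged measures ------------------------------------------------------


class TestAveragedMeasures:
    def test_mi_zero_under_independence(self):
        rows = [[x] for x in (0, 0, 1, 1)]
        y = [0, 1, 0, 1]  # product table: X independent of Y
        c = count_tables(dataset_from_rows(rows, y, [2], 2))
        assert mutual_information(c, 0, BITS) == pytest.approx(0.0, abs=1e-12)

    def test_mi_one_bit_for_identical_binary(self):
        rows = [[0], [1]]
        c = count_tables(dataset_from_rows(rows, [0, 1], [2], 2))
        assert mutual_information(c, 0, BITS) == pytest.approx(1.0)

    def test_mi_matches_direct_summation(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=3, n_instances=20, seed=5,
                                 arity_range=(3, 3))
        c = count_tables(ds)
        rows = _rows_with_class(ds)
        ycol = ds.n_attributes
        for i in range(3):
            assert mutual_information(c, i, BITS) == pytest.approx(
                _mi_sets(rows, [i], [ycol])
            )

    def test_mi_invalid_index(self, table3_counts):
        with pytest.raises(ValueError):
            mutual_information(table3_counts, 99)

    def test_cmi_zero_when_conditionally_independent(self):
        # X0 and X1 independent within each class
        rows = [[a, b] for a in (0, 1) for b in (0, 1)]
        c = count_tables(dataset_from_rows(rows * 2, [0] * 4 + [1] * 4, [2, 2], 2))
        assert conditional_mutual_information(c, 0, 1, BITS) == pytest.approx(0.0, abs=1e-12)

    def test_cmi_one_bit_for_copy_attribute(self):
        rows = [[x, x] for x in (0, 1)] * 2
        y = [0, 0, 1, 1]
        c = count_tables(dataset_from_rows(rows, y, [2, 2], 2))
        assert conditional_mutual_information(c, 0, 1, BITS) == pytest.approx(1.0)

    def test_cmi_symmetry_and_clmi_sum(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=3, n_instances=40, seed=9)
        c = count_tables(ds)
        cmi = conditional_mutual_information(c, 0, 1, BITS)
        assert conditional_mutual_information(c, 1, 0, BITS) == pytest.approx(cmi)
        total = sum(
            conditional_local_mutual_information(c, 0, vi, 1, vj, BITS)
            for vi in range(ds.arities[0])
            for vj in range(ds.arities[1])
        )
        assert total == pytest.approx(cmi)

    def test_cmi_equal_indices_rejected(self, table3_counts):
        with pytest.raises(ValueError):
            conditional_mutual_information(table3_counts, 1, 1)

    def test_lmi_sums_to_mi(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=2, n_instances=30, seed=2,
                                 arity_range=(3, 3))
        c = count_tables(ds)
        total = sum(
            local_mutual_information(c, 0, v, BITS) for v in range(ds.arities[0])
        )
        assert total == pytest.approx(mutual_information(c, 0, BITS))

    def test_lmi_matches_direct_summation(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=2, n_instances=25, seed=8,
                                 arity_range=(3, 3))
        c = count_tables(ds)
        rows = _rows_with_class(ds)
        for v in range(ds.arities[0]):
            direct = sum(
                p * math.log2(p / (sum(q for kk, q in _joint(rows, [0, 2]).items()
                                       if kk[0] == v)
                                   * _joint(rows, [2])[(k[1],)]))
                for k, p in _joint(rows, [0, 2]).items() if k[0] == v
            )
            assert local_mutual_information(c, 0, v, BITS) == pytest.approx(direct)

    def test_lmi_zero_when_value_uninformative(self):
        rows = [[x] for x in (0, 0, 1, 1)]
        c = count_tables(dataset_from_rows(rows, [0, 1, 0, 1], [2], 2))
        assert local_mutual_information(c, 0, 0, BITS) == pytest.approx(0.0, abs=1e-12)

    def test_clmi_symmetry(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=3, n_instances=40, seed=4)
        c = count_tables(ds)
        a = conditional_local_mutual_information(c, 0, 0, 1, 0, BITS)
        b = conditional_local_mutual_information(c, 1, 0, 0, 0, BITS)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("seed", range(10))
    def test_nonnegativity_sweep(self, make_random_dataset, seed):
        """MI, CMI and LMI are true (conditional) divergences, hence >= 0."""
        ds = make_random_dataset(n_attributes=3, n_instances=30, seed=seed,
                                 class_count=3)
        c = count_tables(ds)
        for i in range(3):
            assert mutual_information(c, i, BITS) >= -1e-12
            for v in range(ds.arities[i]):
                assert local_mutual_information(c, i, v, BITS) >= -1e-12
        for i, j in itertools.combinations(range(3), 2):
            assert conditional_mutual_information(c, i, j, BITS) >= -1e-12

    def test_log_base_rescaling(self, make_random_dataset):
        ds = make_random_dataset(n_attributes=3, n_instances=50, seed=6)
        c = count_tables(ds)
        for fn, args in [
            (mutual_information, (0,)),
            (conditional_mutual_information, (0, 1)),
            (local_mutual_information, (0, 0)),
            (conditional_local_mutual_information, (0, 0, 1, 0)),
        ]:
            assert fn(c, *args, NATS) == pytest.approx(fn(c, *args, BITS) * math.log(2))


# --- pointwise measures -----------------------------------------------------


class TestPointwiseMeasures:
    def test_worked_example_pmi(self, table3_counts):
        # P(b,d)/(P(b)P(d)) = (1/2)/((1/2)(4/6)) = 6/4
        val = pointwise_mutual_information(table3_counts, 0, 1, 1, 1, BITS)
        assert val == pytest.approx(math.log2(6 / 4))

    def test_worked_example_pcmi_exact_zero(self, table3_counts):
        # P(b,e|d) = P(b|d) * P(e|d) exactly on the six printed rows
        val = pointwise_conditional_mutual_information(
            table3_counts, 0, 1, 2, 0, 1, 1, BITS
        )
        assert val == 0.0

    def test_hand_frequency_a_d(self, table3_counts):
        val = pointwise_mutual_information(table3_counts, 0, 0, 1, 1, BITS)
        assert val == pytest.approx(math.log2((1 / 6) / ((1 / 2) * (4 / 6))))

    def test_hand_frequency_b_bt_given_d(self, table3_counts):
        val = pointwise_conditional_mutual_information(
            table3_counts, 0, 1, 3, 0, 1, 1, BITS
        )
        assert val == pytest.approx(math.log2(4 / 3))

    def test_pmi_zero_under_independence(self):
        rows = [[a, b] for a in (0, 1) for b in (0, 1)]
        c = count_tables(dataset_from_rows(rows, [0] * 4, [2, 2], 1))
        assert pointwise_mutual_information(c, 0, 0, 1, 0, BITS) == pytest.approx(0.0)

    def test_pmi_flagged_zero_on_zero_joint(self, table3_counts):
        # (Xi=a, Xk=f) occurs, (Xi=b, Xk=f) never does
        val, defined = pointwise_mutual_information(
            table3_counts, 0, 1, 2, 1, BITS, return_flag=True
        )
        assert (val, defined) == (0.0, False)

    def test_pcmi_zero_conditioning_count_raises(self, table3_counts):
        with pytest.raises(ValueError, match="conditioning"):
            pointwise_conditional_mutual_information(
                table3_counts, 0, 1, 2, 0, 1, 5, BITS
            )

    def test_pmi_chain_rule_on_all_table3_triples(self, table3_counts):
        """I(x_i; x_j, x_k) = I(x_i; x_j) + I(x_i; x_k | x_j) wherever defined."""
        c = table3_counts
        for i, j, k in itertools.permutations(range(4), 3):
            for vi in range(c.arities[i]):
                for vj in range(c.arities[j]):
                    for vk in range(c.arities[k]):
                        cjk = c.pair_count(j, vj, k, vk)
                        cijk = c.triple_count(i, vi, j, vj, k, vk)
                        ci = c.value_count(i, vi)
                        if cijk == 0 or c.pair_count(i, vi, j, vj) == 0:
                            continue
                        lhs = math.log2(
                            (cijk / c.n_total) / ((ci / c.n_total) * (cjk / c.n_total))
                        )
                        rhs = pointwise_mutual_information(
                            c, i, vi, j, vj, BITS
                        ) + pointwise_conditional_mutual_information(
                            c, i, vi, k, vk, j, vj, BITS
                        )
                        assert rhs == pytest.approx(lhs)

    def test_pointwise_log_base_rescaling(self, table3_counts):
        b = pointwise_mutual_information(table3_counts, 0, 1, 1, 1, BITS)
        e = pointwise_mutual_information(table3_counts, 0, 1, 1, 1, NATS)
        assert e == pytest.approx(b * math.log(2))


class TestChainRule:
    def test_mi_chain_rule_against_joint_oracle(self, make_random_dataset):
        """I(X_i; Pi, Y) = I(X_i; Y) + I(X_i; X_a | Y) + I(X_i; X_b | X_a, Y)."""
        ds = make_random_dataset(n_attributes=4, n_instances=60, seed=13)
        c = count_tables(ds)
        rows = _rows_with_class(ds)
        ycol = ds.n_attributes
        i, a, b = 3, 0, 1
        lhs = _mi_sets(rows, [i], [a, b, ycol])
        rhs = (
            mutual_information(c, i, BITS)
            + conditional_mutual_information(c, i, a, BITS)
            + _cmi_sets(rows, [i], [b], [a, ycol])
        )
        assert rhs == pytest.approx(lhs)
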