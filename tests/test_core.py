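"""Unit and property tests for the register and the three memory operations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from weam.core import (
    UNDEFINED,
    AMRegister,
    DiscreteFunction,
    RecognitionParams,
    capacity_log2,
    column_distribution,
    column_entropy,
    emerging_objects,
    entropy,
    exact_capacity,
    load_amr,
    recognize,
    register,
    retrieve,
    save_amr,
)


def stored(cues, n, m, max_weight=65535):
    amr = AMRegister(n, m, max_weight)
    for c in cues:
        register(amr, DiscreteFunction(c, n=n) if isinstance(c, dict)
                 else DiscreteFunction(c))
    return amr


# ---------------------------------------------------------------- register

class TestRegister:
    def test_single_cue_marks_exactly_its_cells(self):
        # one cell per column: {(a1,v3), (a2,v1), (a3,v6), (a4,v7)}
        amr = stored([[3, 1, 6, 7]], n=4, m=8)
        w = amr.weights
        assert w.sum() == 4
        assert w[0, 3] == w[1, 1] == w[2, 6] == w[3, 7] == 1

    def test_repeated_registration_accumulates(self):
        amr = stored([[2, 0, 1]] * 5, n=3, m=3)
        assert amr.weights[0, 2] == amr.weights[1, 0] == amr.weights[2, 1] == 5

    def test_cues_differing_in_one_column(self):
        amr = stored([[0, 1, 1], [2, 1, 1]], n=3, m=3)
        col0 = amr.weights[0]
        assert sorted(col0.tolist()) == [0, 1, 1]
        assert (amr.weights[1:] == [[0, 2, 0], [0, 2, 0]]).all()

    def test_partial_cue_touches_only_defined_columns(self):
        amr = stored([{0: 1, 2: 2}], n=3, m=3)
        assert amr.weights.sum() == 2
        assert (amr.weights[1] == 0).all()

    def test_saturation_at_max_weight(self):
        amr = stored([[0]] * 5, n=1, m=2, max_weight=3)
        assert amr.weights[0, 0] == 3

    def test_arity_and_range_errors(self):
        amr = AMRegister(3, 4)
        with pytest.raises(ValueError, match="arity"):
            register(amr, DiscreteFunction([0, 1]))
        with pytest.raises(ValueError, match="out of range"):
            register(amr, DiscreteFunction([0, 1, 4]))


# --------------------------------------------------------------- recognize

class TestRecognize:
    def test_stored_cue_accepted_with_unit_cue_weight(self):
        f = DiscreteFunction([1, 0, 2])
        amr = stored([[1, 0, 2]], n=3, m=3)
        rep = recognize(amr, f)
        assert rep.accepted and rep.failing_columns == () and rep.rho == 1.0

    def test_empty_register_rejects_everything(self):
        amr = AMRegister(4, 4)
        rep = recognize(amr, DiscreteFunction([0, 1, 2, 3]))
        assert not rep.accepted
        assert len(rep.failing_columns) == 4
        assert rep.rho == 0.0 and rep.Omega == 0.0

    def test_xi_relaxes_one_failing_column(self):
        amr = stored([[0, 0, 0, 0]], n=4, m=2)
        g = DiscreteFunction([1, 0, 0, 0])  # differs at column 0 only
        assert not recognize(amr, g, RecognitionParams(xi=0)).accepted
        assert recognize(amr, g, RecognitionParams(xi=1)).accepted

    def test_iota_turns_weak_cells_off(self):
        # column 0 weights {3,1}: omega_0 = 2, so iota=1 needs weight >= 2
        amr = stored([[0, 0]] * 3 + [[1, 0]], n=2, m=2)
        weak = DiscreteFunction([1, 0])
        assert recognize(amr, weak).accepted
        assert not recognize(amr, weak, RecognitionParams(iota=1.0)).accepted

    def test_kappa_thresholds_cue_weight(self):
        # cue hits cells of weight 1 while Omega = 2
        amr = stored([[0, 0]] * 3 + [[1, 1]], n=2, m=2)
        weak = DiscreteFunction([1, 1])
        assert recognize(amr, weak).accepted
        rep = recognize(amr, weak, RecognitionParams(kappa=1.0))
        assert rep.rho == 1.0 and rep.Omega == 2.0 and not rep.accepted

    def test_partial_cue_scores_defined_arguments_only(self):
        amr = stored([[0, 1, 1]] * 2, n=3, m=2)
        rep = recognize(amr, DiscreteFunction({0: 0, 2: 1}, n=3))
        assert rep.accepted and rep.rho == 2.0


# ---------------------------------------------------------------- retrieve

class TestRetrieve:
    def test_sigma_zero_is_reproductive(self, rng):
        cues = [[0, 3, 1], [2, 2, 2], [1, 0, 3]]
        amr = stored(cues, n=3, m=4)
        for c in cues:
            assert retrieve(amr, DiscreteFunction(c), 0.0, rng=rng) == \
                DiscreteFunction(c)

    def test_single_support_column_is_forced(self, rng):
        amr = stored([[2, 1]] * 4, n=2, m=4)
        for sigma in (0.0, 0.3, 2.0):
            out = retrieve(amr, DiscreteFunction([2, 1]), sigma, rng=rng)
            assert out == DiscreteFunction([2, 1])

    def test_rejection_yields_undefined(self, rng):
        amr = AMRegister(3, 3)
        assert retrieve(amr, DiscreteFunction([0, 1, 2]), 0.1, rng=rng) is None

    def test_negative_sigma_raises(self, rng):
        amr = stored([[0]], n=1, m=2)
        with pytest.raises(ValueError, match="sigma"):
            retrieve(amr, DiscreteFunction([0]), -0.1, rng=rng)

    def test_undefined_arguments_sampled_from_prior(self, rng):
        # column 1 never seen by the partial cue; its only support is level 2
        amr = stored([[0, 2, 1]], n=3, m=3)
        out = retrieve(amr, DiscreteFunction({0: 0, 2: 1}, n=3), 0.0, rng=rng)
        assert out == DiscreteFunction([0, 2, 1])

    def test_xi_relaxed_zero_cell_falls_back_to_prior(self, rng):
        amr = stored([[0, 0]], n=2, m=2)
        cue = DiscreteFunction([1, 0])  # column 0 unsupported at level 1
        out = retrieve(amr, cue, 0.0, RecognitionParams(xi=1), rng=rng)
        assert out == DiscreteFunction([0, 0])

    def test_sampling_matches_product_distribution(self):
        # weights {3,1}, cue at level 0, wide kernel: Phi computed by hand
        amr = stored([[0]] * 3 + [[1]], n=1, m=2)
        sigma, m = 1.0, 2
        z = [math.exp(-0.5 * (j / (sigma * m)) ** 2) for j in (0, 1)]
        phi = np.array([3 * z[0], 1 * z[1]])
        phi /= phi.sum()
        rng = np.random.default_rng(12345)
        draws = np.array([
            retrieve(amr, DiscreteFunction([0]), sigma, rng=rng).levels[0]
            for _ in range(10_000)
        ])
        counts = np.bincount(draws, minlength=2)
        p = stats.chisquare(counts, 10_000 * phi).pvalue
        assert p > 0.01


# ----------------------------------------------------------------- entropy

class TestEntropy:
    def test_empty_column_has_zero_entropy(self):
        assert column_entropy(AMRegister(2, 4), 0) == 0.0

    def test_two_equal_cells_give_one_bit(self):
        amr = stored([[0, 0], [1, 1]], n=2, m=2)
        assert column_entropy(amr, 0) == pytest.approx(1.0)

    def test_three_one_split(self):
        amr = stored([[0]] * 3 + [[1]], n=1, m=2)
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert column_entropy(amr, 0) == pytest.approx(expected, abs=1e-12)
        assert column_entropy(amr, 0) == pytest.approx(0.8113, abs=5e-5)

    def test_memory_entropy_is_column_mean(self):
        # one uniform 2-level column, one empty column
        amr = stored([{0: 0}, {0: 1}], n=2, m=2)
        assert entropy(amr) == pytest.approx(0.5)
        assert entropy(AMRegister(5, 5)) == 0.0

    def test_column_index_out_of_range(self):
        with pytest.raises(IndexError):
            column_entropy(AMRegister(2, 2), 2)


# ---------------------------------------------------------------- capacity

class TestCapacity:
    def test_empty_register_holds_one_trivial_function(self):
        assert capacity_log2(AMRegister(8, 4)) == 0.0
        assert exact_capacity(0.0) == 1

    def test_boolean_enumeration_oracle(self):
        # nonzero counts per column (2, 3, 1) -> 6 functions
        amr = stored([[0, 0, 0], [1, 1, 0], [0, 2, 0]], n=3, m=4, max_weight=1)
        supports = [np.nonzero(amr.weights[i])[0] for i in range(3)]
        enumerated = sum(1 for _ in itertools.product(*supports))
        assert enumerated == 6
        assert 2 ** capacity_log2(amr) == pytest.approx(6, rel=1e-9)

    def test_exact_capacity_requires_integral_exponent(self):
        assert exact_capacity(10.0) == 1024
        with pytest.raises(ValueError):
            exact_capacity(10.5)

    def test_emerging_objects_is_exact_big_integer(self):
        assert emerging_objects(8.0, 10) == 246
        assert emerging_objects(300.0, 1) == 2 ** 300 - 1


# ------------------------------------------------------------- persistence

class TestPersistence:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        amr = AMRegister(5, 3, max_weight=7)
        for _ in range(20):
            register(amr, DiscreteFunction(rng.integers(0, 3, size=5)))
        save_amr(amr, tmp_path / "amr")
        assert load_amr(tmp_path / "amr") == amr

    def test_load_rejects_inconsistent_shape(self, tmp_path):
        save_amr(AMRegister(3, 2), tmp_path / "amr")
        (tmp_path / "amr" / "weights.csv").write_text("0,0\n0,0\n")
        with pytest.raises(ValueError, match="shape"):
            load_amr(tmp_path / "amr")


# ------------------------------------------------------- domain-type guards

class TestTypes:
    def test_discrete_function_needs_a_defined_argument(self):
        with pytest.raises(ValueError):
            DiscreteFunction([UNDEFINED, UNDEFINED])
        with pytest.raises(ValueError):
            DiscreteFunction([0, -2])

    def test_mapping_constructor_and_completeness(self):
        f = DiscreteFunction({1: 2}, n=3)
        assert not f.complete and list(f.items()) == [(1, 2)]
        assert DiscreteFunction([0, 1]).complete

    def test_register_shape_immutable_and_weights_read_only(self):
        amr = AMRegister(2, 3)
        with pytest.raises(ValueError):
            AMRegister(0, 3)
        with pytest.raises((ValueError, RuntimeError)):
            amr.weights[0, 0] = 1

    def test_recognition_params_validation(self):
        with pytest.raises(ValueError):
            RecognitionParams(iota=-1)
        with pytest.raises(ValueError):
            RecognitionParams(xi=-2)


# ---------------------------------------------------------------- properties

cue_sets = st.integers(1, 5).flatmap(
    lambda n: st.integers(1, 4).flatmap(
        lambda m: st.lists(
            st.lists(st.integers(0, m - 1), min_size=n, max_size=n),
            min_size=1, max_size=8,
        ).map(lambda cues: (n, m, cues))
    )
)


@given(cue_sets)
def test_register_is_monotone_and_adds_cue_mass(case):
    n, m, cues = case
    amr = AMRegister(n, m)
    for c in cues:
        before = amr.weights.copy()
        register(amr, DiscreteFunction(c))
        assert (amr.weights >= before).all()
        assert amr.weights.sum() == before.sum() + n


@given(cue_sets)
def test_every_registered_cue_is_accepted_by_default(case):
    n, m, cues = case
    amr = stored(cues, n, m)
    for c in cues:
        assert recognize(amr, DiscreteFunction(c)).accepted


@given(cue_sets, st.floats(0.0, 2.0), st.integers(0, 2 ** 31 - 1))
def test_retrieved_levels_lie_in_column_support(case, sigma, seed):
    n, m, cues = case
    amr = stored(cues, n, m)
    out = retrieve(amr, DiscreteFunction(cues[0]), sigma,
                   rng=np.random.default_rng(seed))
    assert out is not None and out.complete
    for i, j in out.items():
        assert amr.weights[i, j] > 0


@given(cue_sets)
def test_entropy_bounds(case):
    n, m, cues = case
    amr = stored(cues, n, m)
    assert 0.0 <= entropy(amr) <= math.log2(m) + 1e-12
    psi = column_distribution(amr, 0)
    if not psi.empty:
        assert psi.probs.sum() == pytest.approx(1.0)


def test_entropy_nondecreasing_in_expectation():
    """Mean entropy over many seeds grows as random cues accumulate."""
    checkpoints = [1, 2, 4, 8, 16, 32]
    traj = np.zeros(len(checkpoints))
    for seed in range(100):
        rng = np.random.default_rng(seed)
        amr = AMRegister(4, 4)
        k = 0
        for t in range(1, 33):
            register(amr, DiscreteFunction(rng.integers(0, 4, size=4)))
            if t in checkpoints:
                traj[k] += entropy(amr)
                k += 1
    traj /= 100
    assert (np.diff(traj) >= -1e-3).all()
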