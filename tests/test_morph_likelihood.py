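"""Mk likelihoods, parsimony counts, and among-character rate fits."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import norm

from paleotip.core_io import CharacterMatrix, ModelTree, TreeNode, ValidationError
from paleotip.morph_likelihood import (
    ClockModel,
    branch_expected_change,
    count_parsimony_steps,
    fit_rate_distribution,
    matrix_log_likelihood,
    mk_transition_probability,
    quartile_rate_classes,
)
from tests.conftest import balanced_tree, random_character_matrix


def brute_force_loglik(
    tree: ModelTree,
    cm: CharacterMatrix,
    clock: ClockModel,
    factors: tuple[float, ...],
) -> float:
    """Enumerate all internal-state assignments and rate classes."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    taxon_idx = {t: i for i, t in enumerate(cm.taxa)}
    total = 0.0
    for c in range(cm.n_char):
        k = int(cm.k_per_char[c])
        if k < 2:
            continue
        class_likes = []
        for f in factors:
            like = 0.0
            for assignment in itertools.product(range(k), repeat=len(internals)):
                states = {id(n): s for n, s in zip(internals, assignment)}
                for leaf in tree.leaves():
                    states[id(leaf)] = cm.states[taxon_idx[leaf.label], c]
                p = 1.0 / k  # uniform root frequency
                for parent, child in tree.branches():
                    s_child = states[id(child)]
                    nu = f * branch_expected_change(parent.age, child.age, clock)
                    P = mk_transition_probability(nu, k)
                    if s_child < 0:  # missing: marginalize
                        p_row = P[states[id(parent)]].sum()
                    else:
                        p_row = P[states[id(parent)], s_child]
                    p *= p_row
                like += p
            class_likes.append(like)
        total += math.log(np.mean(class_likes))
    return total


class TestTransitionMatrix:
    def test_zero_change_is_identity(self):
        assert np.allclose(mk_transition_probability(0.0, 4), np.eye(4))

    def test_stationary_limit_binary(self):
        P = mk_transition_probability(50.0, 2)
        assert np.allclose(P, 0.5, atol=1e-12)

    @pytest.mark.parametrize("nu,k", [(0.3, 3), (0.05, 2), (1.7, 5)])
    def test_matches_matrix_exponential(self, nu, k):
        Q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Q, -1.0)  # one expected change per unit nu
        assert np.allclose(
            mk_transition_probability(nu, k), expm(Q * nu), atol=1e-12
        )

    def test_rows_sum_to_one(self):
        P = mk_transition_probability(0.8, 6)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            mk_transition_probability(0.1, 1)


class TestBranchExpectedChange:
    def test_strict_is_rate_times_duration(self):
        clock = ClockModel.strict(0.02)
        assert branch_expected_change(470, 460, clock) == pytest.approx(0.2)

    def test_equal_rates_reduce_to_strict(self):
        eb = ClockModel.early_burst(0.02, 0.02, tau=465.0)
        strict = ClockModel.strict(0.02)
        for older, younger in [(470, 460), (466, 465.5), (463, 461)]:
            assert branch_expected_change(older, younger, eb) == pytest.approx(
                branch_expected_change(older, younger, strict)
            )

    def test_branch_entirely_before_breakpoint(self):
        clock = ClockModel.early_burst(0.03, 0.01, tau=462.0)
        assert branch_expected_change(466.0, 462.0, clock) == pytest.approx(0.12)

    def test_straddling_branch_matches_quadrature(self):
        clock = ClockModel.early_burst(0.032, 0.01, tau=462.0)

        def rate(t):
            return clock.alpha_early if t > clock.tau else clock.alpha_late

        for older, younger in [(468.0, 455.0), (462.5, 461.5), (470, 462.01)]:
            target, _ = quad(rate, younger, older, points=[clock.tau])
            assert branch_expected_change(older, younger, clock) == pytest.approx(
                target, abs=1e-9
            )

    def test_reversed_ages_error(self):
        with pytest.raises(ValidationError, match="reversed"):
            branch_expected_change(460.0, 470.0, ClockModel.strict(0.01))


class TestRateClasses:
    def test_sigma_zero_gives_unit_factors(self):
        rc = quartile_rate_classes(0.0)
        assert rc.factors == (1.0, 1.0, 1.0, 1.0)

    def test_log_symmetry(self):
        rc = quartile_rate_classes(0.8)
        f = rc.factors
        assert f[0] * f[3] == pytest.approx(1.0, abs=1e-12)
        assert f[1] * f[2] == pytest.approx(1.0, abs=1e-12)

    def test_quantile_oracle(self):
        rc = quartile_rate_classes(1.0)
        expected = np.exp(norm.ppf([0.125, 0.375, 0.625, 0.875]))
        assert np.allclose(rc.factors, expected, atol=1e-9)


class TestMatrixLogLikelihood:
    def test_two_identical_tips_no_change(self):
        a = TreeNode("A", age=469.999999)
        b = TreeNode("B", age=469.999999)
        tree = ModelTree(TreeNode(age=470.0, children=[a, b]))
        cm = CharacterMatrix(
            ["A", "B"], np.array([[1], [1]]), k_per_char=np.array([2])
        )
        clock = ClockModel.strict(1e-9)
        # with no change the likelihood is the root-state marginal 1/k
        lnl = matrix_log_likelihood(tree, cm, clock)
        assert lnl == pytest.approx(math.log(0.5), abs=1e-5)

    def test_brute_force_four_tips(self, four_tip_tree):
        rng = np.random.default_rng(12)
        cm = random_character_matrix(rng, ["A", "B", "C", "D"], 3, k=2)
        clock = ClockModel.strict(0.05, sigma=0.7)
        rc = quartile_rate_classes(0.7)
        ours = matrix_log_likelihood(four_tip_tree, cm, clock, rc)
        ref = brute_force_loglik(four_tip_tree, cm, clock, rc.factors)
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_brute_force_with_missing_and_multistate(self, four_tip_tree):
        rng = np.random.default_rng(13)
        cm = random_character_matrix(
            rng, ["A", "B", "C", "D"], 4, k=3, missing_fraction=0.25
        )
        clock = ClockModel.early_burst(0.06, 0.02, tau=463.0, sigma=0.5)
        rc = quartile_rate_classes(0.5)
        ours = matrix_log_likelihood(four_tip_tree, cm, clock, rc)
        ref = brute_force_loglik(four_tip_tree, cm, clock, rc.factors)
        assert ours == pytest.approx(ref, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_property_pruning_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(2, 6))
        taxa = [f"t{i}" for i in range(n_tips)]

        def grow(labels, older):
            if len(labels) == 1:
                return TreeNode(labels[0], age=older - rng.uniform(0.5, 3.0))
            split = int(rng.integers(1, len(labels)))
            node = TreeNode(age=older)
            node.add_child(grow(labels[:split], older - rng.uniform(0.2, 2.0)))
            node.add_child(grow(labels[split:], older - rng.uniform(0.2, 2.0)))
            return node

        tree = ModelTree(grow(taxa, 470.0))
        k = int(rng.integers(2, 5))
        cm = random_character_matrix(rng, taxa, 2, k=k, missing_fraction=0.2)
        sigma = float(rng.uniform(0, 1))
        clock = ClockModel.strict(float(rng.uniform(0.005, 0.1)), sigma)
        rc = quartile_rate_classes(sigma)
        ours = matrix_log_likelihood(tree, cm, clock, rc)
        ref = brute_force_loglik(tree, cm, clock, rc.factors)
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_tip_order_permutation_invariance(self, four_tip_tree):
        rng = np.random.default_rng(14)
        cm = random_character_matrix(rng, ["A", "B", "C", "D"], 6, k=2)
        clock = ClockModel.strict(0.04, sigma=0.4)
        base = matrix_log_likelihood(four_tip_tree, cm, clock)
        order = [2, 0, 3, 1]
        cm_perm = CharacterMatrix(
            [cm.taxa[i] for i in order],
            cm.states[order],
            k_per_char=cm.k_per_char,
        )
        assert matrix_log_likelihood(
            four_tip_tree, cm_perm, clock
        ) == pytest.approx(base, abs=1e-12)

    def test_early_burst_equal_rates_bitwise_strict(self, four_tip_tree):
        rng = np.random.default_rng(15)
        cm = random_character_matrix(rng, ["A", "B", "C", "D"], 8, k=2)
        rc = quartile_rate_classes(0.6)
        strict = matrix_log_likelihood(
            four_tip_tree, cm, ClockModel.strict(0.03, 0.6), rc
        )
        burst = matrix_log_likelihood(
            four_tip_tree, cm,
            ClockModel.early_burst(0.03, 0.03, tau=463.0, sigma=0.6), rc,
        )
        assert burst == strict  # identical floats, not merely close

    def test_sigma_zero_collapses_classes(self, four_tip_tree):
        rng = np.random.default_rng(16)
        cm = random_character_matrix(rng, ["A", "B", "C", "D"], 5, k=2)
        clock = ClockModel.strict(0.05, sigma=0.0)
        one_class = matrix_log_likelihood(
            four_tip_tree, cm, clock, quartile_rate_classes(0.0, n_classes=1)
        )
        four_class = matrix_log_likelihood(
            four_tip_tree, cm, clock, quartile_rate_classes(0.0, n_classes=4)
        )
        assert four_class == pytest.approx(one_class, abs=1e-12)
        # spreading the classes changes the likelihood
        spread = matrix_log_likelihood(
            four_tip_tree, cm,
            ClockModel.strict(0.05, sigma=1.0), quartile_rate_classes(1.0),
        )
        assert spread != pytest.approx(four_class, abs=1e-9)

    def test_ascertainment_changes_loglik_with_invariant_chars(
        self, four_tip_tree
    ):
        states = np.array(
            [[0, 0, 1], [0, 1, 0], [0, 1, 1], [0, 0, 0]]
        )  # first character invariant
        cm = CharacterMatrix(
            ["A", "B", "C", "D"], states, k_per_char=np.array([2, 2, 2])
        )
        clock = ClockModel.strict(0.05)
        plain = matrix_log_likelihood(four_tip_tree, cm, clock)
        corrected = matrix_log_likelihood(
            four_tip_tree, cm, clock, ascertainment=True
        )
        assert corrected > plain  # conditioning on variability raises lnL

    def test_ordered_characters_change_multistate_likelihood(
        self, four_tip_tree
    ):
        cm = CharacterMatrix(
            ["A", "B", "C", "D"],
            np.array([[0, 2], [2, 1], [1, 0], [0, 2]]),
            k_per_char=np.array([3, 3]),
        )
        clock = ClockModel.strict(0.05, 0.5)
        unordered = matrix_log_likelihood(four_tip_tree, cm, clock)
        ordered = matrix_log_likelihood(
            four_tip_tree, cm, clock, ordered={0, 1}
        )
        # stepwise transitions make 0 <-> 2 jumps harder
        assert ordered < unordered
        # binary characters have no ordering to distinguish
        cm2 = CharacterMatrix(
            ["A", "B", "C", "D"],
            np.array([[0], [1], [1], [0]]),
            k_per_char=np.array([2]),
        )
        assert matrix_log_likelihood(
            four_tip_tree, cm2, clock, ordered={0}
        ) == pytest.approx(
            matrix_log_likelihood(four_tip_tree, cm2, clock), abs=1e-9
        )

    def test_taxon_mismatch_lists_difference(self, four_tip_tree):
        cm = CharacterMatrix(
            ["A", "B", "C", "E"], np.zeros((4, 2)), k_per_char=np.array([2, 2])
        )
        with pytest.raises(ValidationError, match="E"):
            matrix_log_likelihood(four_tip_tree, cm, ClockModel.strict(0.01))


def brute_force_parsimony(tree: ModelTree, states_by_taxon, k: int) -> int:
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = None
    for assignment in itertools.product(range(k), repeat=len(internals)):
        labels = {id(n): s for n, s in zip(internals, assignment)}
        for leaf in tree.leaves():
            labels[id(leaf)] = states_by_taxon[leaf.label]
        cost = 0
        for parent, child in tree.branches():
            s_c = labels[id(child)]
            if s_c < 0:
                continue  # missing: choose freely, zero cost contribution
            if s_c != labels[id(parent)]:
                cost += 1
        if best is None or cost < best:
            best = cost
    return best


class TestParsimony:
    def test_invariant_character_zero_steps(self, four_tip_tree):
        cm = CharacterMatrix(
            ["A", "B", "C", "D"], np.ones((4, 1)), k_per_char=np.array([2])
        )
        assert count_parsimony_steps(four_tip_tree, cm).counts.tolist() == [0]

    def test_single_derived_tip_one_step(self, four_tip_tree):
        cm = CharacterMatrix(
            ["A", "B", "C", "D"],
            np.array([[1], [0], [0], [0]]),
            k_per_char=np.array([2]),
        )
        assert count_parsimony_steps(four_tip_tree, cm).counts.tolist() == [1]

    def test_missing_contributes_no_constraint(self, four_tip_tree):
        cm = CharacterMatrix(
            ["A", "B", "C", "D"],
            np.array([[1], [-1], [0], [0]]),
            k_per_char=np.array([2]),
        )
        assert count_parsimony_steps(four_tip_tree, cm).counts.tolist() == [1]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_trees_match_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(3, 9))
        taxa = [f"t{i}" for i in range(n_tips)]

        def grow(labels, older):
            if len(labels) == 1:
                return TreeNode(labels[0], age=older - 1.0)
            split = int(rng.integers(1, len(labels)))
            node = TreeNode(age=older)
            node.add_child(grow(labels[:split], older - 1.0))
            node.add_child(grow(labels[split:], older - 1.0))
            return node

        tree = ModelTree(grow(taxa, 470.0))
        k = 4
        cm = random_character_matrix(rng, taxa, 2, k=k, missing_fraction=0.2)
        ours = count_parsimony_steps(tree, cm).counts
        for c in range(cm.n_char):
            ref = brute_force_parsimony(
                tree, {t: int(cm.states[i, c]) for i, t in enumerate(cm.taxa)}, k
            )
            assert ours[c] == ref


class TestRateDistributionFit:
    def test_equal_counts_near_zero_spread(self):
        fit = fit_rate_distribution(np.full(40, 5))
        assert abs(fit.delta_loglik) < 0.2
        assert fit.lognormal_sigma < 0.1

    def test_lognormal_preferred_on_lognormal_data(self):
        wins = 0
        for rep in range(50):
            rng = np.random.default_rng(rep)
            factors = np.exp(1.0 * rng.standard_normal(200))
            counts = rng.poisson(3.0 * factors)
            fit = fit_rate_distribution(counts)
            wins += fit.preferred == "lognormal"
        assert wins >= 40  # >= 80% of replicates

    def test_predicted_invariant_count(self):
        # matrix-sized regime: 65 characters with a handful invariant, as
        # in morphological matrices where the fitted spread is checked
        # against the observed number of unchanged characters
        deltas = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            factors = np.exp(1.0 * rng.standard_normal(65))
            counts = rng.poisson(6.0 * factors)
            fit = fit_rate_distribution(counts)
            deltas.append(
                abs(fit.expected_invariant_lognormal - (counts == 0).sum())
            )
        assert np.median(deltas) <= 2.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            fit_rate_distribution(np.zeros(20, dtype=int))

    def test_too_few_characters_rejected(self):
        with pytest.raises(ValidationError, match="10"):
            fit_rate_distribution(np.arange(5))
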