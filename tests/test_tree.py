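"""Pseudo-item decomposition, node/category probabilities, and their oracles."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from drsm.tree import (
    MISSING,
    ItemParameters,
    PersonParameters,
    ResponseData,
    category_probabilities,
    decompose_responses,
    four_point_tree,
    five_point_tree,
    node_probability,
    pointwise_loglik,
    recompose_responses,
)

from conftest import random_item, random_person


class TestDecomposition:
    @pytest.mark.parametrize(
        "x, expected",
        [(1, (0, 1)), (2, (0, 0)), (3, (1, 0)), (4, (1, 1))],
    )
    def test_four_point_map(self, tree4, x, expected):
        data = ResponseData(np.array([[x, x]]), tree4)
        pseudo = decompose_responses(data)
        assert tuple(pseudo[0, 0]) == expected

    @pytest.mark.parametrize(
        "x, expected",
        [
            (1, (0, 0, 1)),
            (2, (0, 0, 0)),
            (3, (1, MISSING, MISSING)),
            (4, (0, 1, 0)),
            (5, (0, 1, 1)),
        ],
    )
    def test_five_point_map(self, tree5, x, expected):
        data = ResponseData(np.array([[x, x]]), tree5)
        assert tuple(decompose_responses(data)[0, 0]) == expected

    def test_missing_response_expands_to_all_missing(self, tree4):
        data = ResponseData(np.array([[0, 2]]), tree4)
        assert tuple(decompose_responses(data)[0, 0]) == (MISSING, MISSING)

    def test_roundtrip_is_invertible(self, tree4, tree5, rng):
        for tree in (tree4, tree5):
            resp = rng.integers(1, tree.n_categories + 1, size=(40, 9))
            data = ResponseData(resp, tree)
            back = recompose_responses(decompose_responses(data), tree)
            assert np.array_equal(back, resp)

    def test_out_of_range_category_names_cell(self, tree4):
        resp = np.ones((3, 4), dtype=int)
        resp[2, 1] = 7
        with pytest.raises(ValueError, match="person 2, item 1"):
            ResponseData(resp, tree4)


class TestNodeProbability:
    def test_all_zero_parameters_give_half(self, tree4):
        person = PersonParameters(theta=np.zeros(3), eta=np.zeros(3))
        item = ItemParameters(
            beta=np.zeros((2, 4)),
            loadings={"agree_trait": 1.0, "extreme_trait": 0.5, "extreme_ers": 0.5},
        )
        for node in tree4.nodes:
            ctx = "agree" if node.branch_rule else None
            p = node_probability(node, person, item, 0, tree4, branch_context=ctx)
            assert np.allclose(p, 0.5)

    def test_branch_probabilities_sum_to_one_under_sign_flip(self, tree4):
        person = PersonParameters(theta=np.array([1.0]), eta=np.array([0.0]))
        item = ItemParameters(
            beta=np.zeros((2, 1)),
            loadings={"agree_trait": 1.0, "extreme_trait": 0.5, "extreme_ers": 1.0},
        )
        node = tree4.nodes[1]
        p_agree = node_probability(node, person, item, 0, tree4, branch_context="agree")
        p_disagree = node_probability(node, person, item, 0, tree4, branch_context="disagree")
        assert p_agree[0] == pytest.approx(expit(0.5))
        assert p_disagree[0] == pytest.approx(expit(-0.5))
        assert p_agree[0] + p_disagree[0] == pytest.approx(1.0)

    def test_ers_only_linear_predictor(self, tree4):
        # eta=0.3 with unit ERS loading and beta=0.1 gives logistic(0.2)
        person = PersonParameters(theta=np.array([0.7]), eta=np.array([0.3]))
        item = ItemParameters(
            beta=np.array([[0.0], [0.1]]),
            loadings={"agree_trait": 1.0, "extreme_trait": 0.0, "extreme_ers": 1.0},
        )
        p = node_probability(tree4.nodes[1], person, item, 0, tree4, branch_context="agree")
        assert p[0] == pytest.approx(0.549833997312478, abs=1e-12)

    def test_extreme_node_requires_branch_context(self, tree4, rng):
        person = random_person(rng)
        item = random_item(rng)
        with pytest.raises(ValueError, match="branch context"):
            node_probability(tree4.nodes[1], person, item, 0, tree4)


def _oracle_category_probs(person, item, i, tree):
    """Enumerate pseudo-item outcome combinations consistent with each category."""
    H = tree.n_nodes
    K = tree.n_categories
    out = np.zeros((person.n_persons, K))
    for x in range(1, K + 1):
        vec = tree.category_map[x]
        prob = np.ones(person.n_persons)
        for combo in itertools.product([0, 1], repeat=H):
            if any(v != MISSING and combo[j] != v for j, v in enumerate(vec)):
                continue
            # probability of this full outcome combination along the tree
            p = np.ones(person.n_persons)
            for j, node in enumerate(tree.nodes):
                if vec[j] == MISSING:
                    continue
                if node.branch_rule:
                    ctx = "agree" if combo[tree.node_index(1)] == 1 else "disagree"
                else:
                    ctx = None
                pj = node_probability(node, person, item, i, tree, branch_context=ctx)
                p = p * np.where(vec[j] == 1, pj, 1 - pj)
            prob = p
        out[:, x - 1] = prob
    return out


class TestCategoryProbabilities:
    def test_all_zero_gives_uniform_quarter(self, tree4):
        person = PersonParameters(theta=np.zeros(2), eta=np.zeros(2))
        item = ItemParameters(
            beta=np.zeros((2, 3)),
            loadings={"agree_trait": 1.0, "extreme_trait": 1.0, "extreme_ers": 0.0},
        )
        p = category_probabilities(person, item, 0, tree4)
        assert np.allclose(p, 0.25)

    def test_midpoint_probability_is_moderate_node_probability(self, tree5, rng):
        person = random_person(rng, kappa=True)
        item = random_item(rng, H=3, kappa=True)
        p = category_probabilities(person, item, 2, tree5)
        q = node_probability(tree5.nodes[0], person, item, 2, tree5)
        assert np.allclose(p[:, 2], q)

    def test_normalization_over_random_draws(self, tree4, tree5):
        rng = np.random.default_rng(42)
        for tree in (tree4, tree5):
            H = tree.n_nodes
            for _ in range(500):
                person = random_person(rng, N=3, kappa=tree.n_categories == 5)
                item = random_item(rng, I=4, H=H, kappa=tree.n_categories == 5)
                p = category_probabilities(person, item, 1, tree)
                assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-10

    def test_matches_enumeration_oracle(self, tree4, tree5):
        rng = np.random.default_rng(7)
        for tree in (tree4, tree5):
            person = random_person(rng, N=5, kappa=tree.n_categories == 5)
            item = random_item(rng, I=4, H=tree.n_nodes, kappa=tree.n_categories == 5)
            for i in range(4):
                got = category_probabilities(person, item, i, tree)
                want = _oracle_category_probs(person, item, i, tree)
                np.testing.assert_allclose(got, want, atol=1e-12)


class TestModelNesting:
    def test_unit_ers_zero_trait_reduces_to_rasch_tree(self, tree4, rng):
        """With loadings (0, 1) the extreme node is the classic ERS Rasch node."""
        person = random_person(rng, N=6)
        beta = rng.standard_normal((2, 3))
        item = ItemParameters(
            beta=beta,
            loadings={"agree_trait": 1.0, "extreme_trait": 0.0, "extreme_ers": 1.0},
        )
        p = category_probabilities(person, item, 1, tree4)
        p1 = expit(person.theta[:, 0] - beta[0, 1])
        pe = expit(person.eta - beta[1, 1])
        want = np.column_stack(
            [(1 - p1) * pe, (1 - p1) * (1 - pe), p1 * (1 - pe), p1 * pe]
        )
        np.testing.assert_allclose(p, want, atol=1e-14)

    def test_zero_ers_unit_trait_reduces_to_ordinal_structure(self, tree4, rng):
        person = random_person(rng, N=6)
        beta = rng.standard_normal((2, 3))
        item = ItemParameters(
            beta=beta,
            loadings={"agree_trait": 1.0, "extreme_trait": 1.0, "extreme_ers": 0.0},
        )
        p = category_probabilities(person, item, 0, tree4)
        th = person.theta[:, 0]
        p1 = expit(th - beta[0, 0])
        pe_a = expit(th - beta[1, 0])
        pe_d = expit(-th - beta[1, 0])
        want = np.column_stack(
            [(1 - p1) * pe_d, (1 - p1) * (1 - pe_d), p1 * (1 - pe_a), p1 * pe_a]
        )
        np.testing.assert_allclose(p, want, atol=1e-14)


class TestBranchSymmetryAndMonotonicity:
    def test_branch_symmetry_without_ers(self, tree4):
        """With eta=0 and beta2=0: P(extreme|agree; th) = P(non-extreme|disagree; th)."""
        thetas = np.linspace(-3, 3, 13)
        person = PersonParameters(theta=thetas, eta=np.zeros(13))
        item = ItemParameters(
            beta=np.zeros((2, 1)),
            loadings={"agree_trait": 1.0, "extreme_trait": 0.8, "extreme_ers": 1.0},
        )
        node = tree4.nodes[1]
        pa = node_probability(node, person, item, 0, tree4, branch_context="agree")
        pd = node_probability(node, person, item, 0, tree4, branch_context="disagree")
        np.testing.assert_allclose(pa, 1 - pd, atol=1e-14)

    def test_monotone_in_theta_and_eta(self, tree4):
        thetas = np.linspace(-2, 2, 9)
        person = PersonParameters(theta=thetas, eta=np.zeros(9))
        item = ItemParameters(
            beta=np.ones((2, 1)) * 0.3,
            loadings={"agree_trait": 1.0, "extreme_trait": 0.6, "extreme_ers": 0.7},
        )
        node = tree4.nodes[1]
        pa = node_probability(node, person, item, 0, tree4, branch_context="agree")
        pd = node_probability(node, person, item, 0, tree4, branch_context="disagree")
        assert np.all(np.diff(pa) > 0)
        assert np.all(np.diff(pd) < 0)
        person2 = PersonParameters(theta=np.zeros(9), eta=np.linspace(-2, 2, 9))
        for ctx in ("agree", "disagree"):
            pe = node_probability(node, person2, item, 0, tree4, branch_context=ctx)
            assert np.all(np.diff(pe) > 0)


class TestPointwiseLoglik:
    def test_single_cell_uniform(self, tree4):
        person = PersonParameters(theta=np.zeros(1), eta=np.zeros(1))
        item = ItemParameters(
            beta=np.zeros((2, 2)),
            loadings={"agree_trait": 1.0, "extreme_trait": 1.0, "extreme_ers": 0.0},
        )
        data = ResponseData(np.array([[2, 3]]), tree4)
        ll = pointwise_loglik(data, person, item)
        np.testing.assert_allclose(ll, np.log(0.25))

    def test_equals_category_probability_log(self, tree4, tree5, rng):
        """Brute-force oracle: log of the product of node factors."""
        for tree in (tree4, tree5):
            K = tree.n_categories
            person = random_person(rng, N=8, kappa=K == 5)
            item = random_item(rng, I=5, H=tree.n_nodes, kappa=K == 5)
            resp = rng.integers(1, K + 1, size=(8, 5))
            data = ResponseData(resp, tree)
            ll = pointwise_loglik(data, person, item)
            for i in range(5):
                probs = category_probabilities(person, item, i, tree)
                want = np.log(probs[np.arange(8), resp[:, i] - 1])
                np.testing.assert_allclose(ll[:, i], want, atol=1e-12)

    def test_missing_cells_contribute_zero_and_sum_is_exchangeable(self, tree4, rng):
        person = random_person(rng, N=6)
        item = random_item(rng, I=4)
        resp = rng.integers(1, 5, size=(6, 4))
        resp[1, 2] = 0
        data = ResponseData(resp, tree4)
        ll = pointwise_loglik(data, person, item)
        assert ll[1, 2] == 0.0
        perm = rng.permutation(6)
        data_p = ResponseData(resp[perm], tree4)
        person_p = PersonParameters(person.theta[perm], eta=person.eta[perm])
        assert pointwise_loglik(data_p, person_p, item).sum() == pytest.approx(ll.sum())


class TestInvertedItems:
    def test_inversion_flips_trait_direction_everywhere(self, tree4):
        person = PersonParameters(theta=np.array([1.3]), eta=np.array([0.4]))
        base = dict(loadings={"agree_trait": 1.0, "extreme_trait": 0.6, "extreme_ers": 0.7})
        item = ItemParameters(beta=np.zeros((2, 1)), **base)
        item_inv = ItemParameters(beta=np.zeros((2, 1)), item_inverted=[True], **base)
        p = category_probabilities(person, item, 0, tree4)[0]
        p_inv = category_probabilities(person, item_inv, 0, tree4)[0]
        person_neg = PersonParameters(theta=np.array([-1.3]), eta=np.array([0.4]))
        p_neg = category_probabilities(person_neg, item, 0, tree4)[0]
        np.testing.assert_allclose(p_inv, p_neg, atol=1e-14)
        assert not np.allclose(p, p_inv)
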