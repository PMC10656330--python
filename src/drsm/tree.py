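"""IRTree structures for Likert-type rating data.

An IRTree decomposes each ordinal response into a sequence of binary
pseudo-decisions (pseudo-items).  Two tree shapes are supported:

* **Four-point scales** (categories 1..4): an *agreement* node (agree vs.
  disagree, driven by the substantive trait) followed by an *extreme* node
  (extreme vs. moderate category, driven by extreme response style and --
  in the multidimensional parameterization -- by the trait as well).
* **Five-point scales** (categories 1..5): an additional *moderate* node
  (midpoint vs. non-midpoint, driven by midpoint response style) is visited
  first; choosing the midpoint terminates the tree, so the agreement and
  extreme pseudo-items are missing by design for category 3.

The extreme node is split between the agreement branches: conditional on
agreeing, higher trait levels push toward the extreme category, while
conditional on disagreeing the trait loading enters with a negative sign,
so that high trait levels favour *moderate* disagreement.  ERS pushes
toward the extremes on both branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "NodeSpec",
    "TreeSpec",
    "PersonParameters",
    "ItemParameters",
    "ResponseData",
    "four_point_tree",
    "five_point_tree",
    "make_tree",
    "decompose_responses",
    "recompose_responses",
    "node_probability",
    "category_probabilities",
    "pointwise_loglik",
    "AGREE_TRAIT",
    "EXTREME_TRAIT",
    "EXTREME_ERS",
    "MODERATE_MRS",
]

MISSING = -1

# canonical loading-slot names: (node, latent process)
AGREE_TRAIT = "agree_trait"
EXTREME_TRAIT = "extreme_trait"
EXTREME_ERS = "extreme_ers"
MODERATE_MRS = "moderate_mrs"

SIGN_FLIP = "sign-flip-trait-when-disagree"


@dataclass(frozen=True)
class NodeSpec:
    """One binary decision node of the tree.

    ``node_id`` follows the convention 0 = moderate, 1 = agreement,
    2 = extreme.  ``processes`` names the latent variables entering the
    node's linear predictor.  ``branch_rule`` marks the extreme node's
    conditional sign flip of the trait term.  ``parameterization`` is
    informational: "rasch" nodes carry unit loadings, "loaded" nodes have
    item-specific loadings.
    """

    node_id: int
    processes: tuple[str, ...]
    branch_rule: str | None = None
    parameterization: str = "loaded"

    def __post_init__(self) -> None:
        if self.node_id not in (0, 1, 2):
            raise ValueError(f"node_id must be 0, 1 or 2, got {self.node_id}")
        if self.branch_rule not in (None, SIGN_FLIP):
            raise ValueError(f"unknown branch_rule {self.branch_rule!r}")
        if self.branch_rule == SIGN_FLIP and self.node_id != 2:
            raise ValueError("sign-flip branch rule is only defined for the extreme node")


@dataclass(frozen=True)
class TreeSpec:
    """Tree shape: nodes plus the category -> pseudo-item outcome map.

    ``category_map[x]`` is a tuple with one entry per node (in ``nodes``
    order): 0, 1, or ``MISSING`` (-1) for pseudo-items that are missing by
    design for that category.
    """

    n_categories: int
    nodes: tuple[NodeSpec, ...]
    category_map: Mapping[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        K = self.n_categories
        if K not in (4, 5):
            raise ValueError(f"n_categories must be 4 or 5, got {K}")
        if set(self.category_map) != set(range(1, K + 1)):
            raise ValueError("category_map must cover exactly the categories 1..K")
        H = len(self.nodes)
        vectors = []
        for x, vec in self.category_map.items():
            if len(vec) != H:
                raise ValueError(f"outcome vector for category {x} has wrong length")
            if any(v not in (0, 1, MISSING) for v in vec):
                raise ValueError(f"outcome vector for category {x} has entries outside {{0,1,missing}}")
            vectors.append(tuple(vec))
        if len(set(vectors)) != K:
            raise ValueError("category_map is not injective")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def has_moderate_node(self) -> bool:
        return any(n.node_id == 0 for n in self.nodes)

    def node_index(self, node_id: int) -> int:
        for j, n in enumerate(self.nodes):
            if n.node_id == node_id:
                return j
        raise KeyError(f"tree has no node with id {node_id}")

    def outcome_array(self) -> np.ndarray:
        """(K, H) int8 array of pseudo-item outcomes, rows ordered by category."""
        K = self.n_categories
        arr = np.empty((K, self.n_nodes), dtype=np.int8)
        for x in range(1, K + 1):
            arr[x - 1] = self.category_map[x]
        return arr


def four_point_tree() -> TreeSpec:
    """Agreement + extreme nodes for categories 1..4 (no missing by design)."""
    nodes = (
        NodeSpec(1, ("trait",), parameterization="rasch"),
        NodeSpec(2, ("trait", "ERS"), branch_rule=SIGN_FLIP),
    )
    category_map = {
        1: (0, 1),  # strongly disagree = disagree & extreme
        2: (0, 0),  # disagree          = disagree & non-extreme
        3: (1, 0),  # agree             = agree & non-extreme
        4: (1, 1),  # strongly agree    = agree & extreme
    }
    return TreeSpec(4, nodes, category_map)


def five_point_tree() -> TreeSpec:
    """Moderate + agreement + extreme nodes for categories 1..5.

    Choosing the midpoint (category 3) terminates the tree, so the
    agreement and extreme pseudo-items are missing by design there.
    """
    nodes = (
        NodeSpec(0, ("MRS",)),
        NodeSpec(1, ("trait",), parameterization="rasch"),
        NodeSpec(2, ("trait", "ERS"), branch_rule=SIGN_FLIP),
    )
    category_map = {
        1: (0, 0, 1),
        2: (0, 0, 0),
        3: (1, MISSING, MISSING),
        4: (0, 1, 0),
        5: (0, 1, 1),
    }
    return TreeSpec(5, nodes, category_map)


def make_tree(n_categories: int) -> TreeSpec:
    if n_categories == 4:
        return four_point_tree()
    if n_categories == 5:
        return five_point_tree()
    raise ValueError(f"no tree defined for {n_categories} categories")


@dataclass
class PersonParameters:
    """Latent person parameters on the logit scale.

    ``theta`` is (N, D) with one column per trait dimension; ``eta`` the
    ERS level; ``kappa`` the MRS level (five-point trees only).
    """

    theta: np.ndarray
    eta: np.ndarray | None = None
    kappa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.theta.ndim == 1:
            self.theta = self.theta[:, None]
        if self.eta is not None:
            self.eta = np.asarray(self.eta, dtype=float)
            if self.eta.shape != (self.n_persons,):
                raise ValueError("eta must have one entry per person")
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)
            if self.kappa.shape != (self.n_persons,):
                raise ValueError("kappa must have one entry per person")

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    @property
    def n_dimensions(self) -> int:
        return self.theta.shape[1]


@dataclass
class ItemParameters:
    """Item difficulties and loadings.

    ``beta`` is (H, I), rows aligned with the tree's node order.
    ``loadings`` maps slot names (``agree_trait``, ``extreme_trait``,
    ``extreme_ers``, ``moderate_mrs``) to per-item loading vectors; all
    loadings are constrained nonnegative.  ``item_inverted`` flips the sign
    of every trait term of an item.  ``item_dimension`` assigns each item
    to one trait dimension; ``item_group`` is an optional covariate label
    (e.g. item wording) selecting a trajectory group.
    """

    beta: np.ndarray
    loadings: dict[str, np.ndarray]
    item_dimension: np.ndarray | None = None
    item_inverted: np.ndarray | None = None
    item_group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2:
            raise ValueError("beta must be a (n_nodes, n_items) array")
        I = self.n_items
        self.loadings = {k: np.broadcast_to(np.asarray(v, dtype=float), (I,)).copy()
                         for k, v in self.loadings.items()}
        for name, alpha in self.loadings.items():
            if np.any(alpha < 0):
                raise ValueError(f"loadings {name!r} must be nonnegative")
        if self.item_dimension is None:
            self.item_dimension = np.zeros(I, dtype=int)
        else:
            self.item_dimension = np.asarray(self.item_dimension, dtype=int)
        if self.item_inverted is None:
            self.item_inverted = np.zeros(I, dtype=bool)
        else:
            self.item_inverted = np.asarray(self.item_inverted, dtype=bool)
        for name in ("item_dimension", "item_inverted"):
            if getattr(self, name).shape != (I,):
                raise ValueError(f"{name} must have one entry per item")
        if self.item_group is not None:
            self.item_group = np.asarray(self.item_group)
            if self.item_group.shape != (I,):
                raise ValueError("item_group must have one entry per item")

    @property
    def n_items(self) -> int:
        return self.beta.shape[1]

    def trait_sign(self) -> np.ndarray:
        """Per-item sign of trait terms: -1 for inverted items, else +1."""
        return np.where(self.item_inverted, -1.0, 1.0)


@dataclass
class ResponseData:
    """An N x I matrix of ordinal categories with its tree.

    Missing responses are encoded as 0 (or NaN on input); item order is
    presentation order.
    """

    responses: np.ndarray
    tree: TreeSpec

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses)
        if resp.dtype.kind == "f":
            out = np.where(np.isnan(resp), 0, resp).astype(int)
        else:
            out = resp.astype(int)
        if out.ndim != 2:
            raise ValueError("responses must be a 2-D person-by-item matrix")
        N, I = out.shape
        if N < 1 or I < 2:
            raise ValueError("need at least one person and two items")
        K = self.tree.n_categories
        bad = (out < 0) | (out > K)
        if np.any(bad):
            p, i = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"response {out[p, i]} at person {p}, item {i} outside 1..{K}"
            )
        self.responses = out

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.responses == 0


def decompose_responses(data: ResponseData) -> np.ndarray:
    """Expand ordinal responses into binary pseudo-item outcomes.

    Returns an (N, I, H) int8 array with entries 0/1 and -1 for missing
    (either missing by design under the tree, or a missing ordinal
    response, which expands to all-missing).
    """
    tree = data.tree
    out_map = np.vstack([np.full((1, tree.n_nodes), MISSING, dtype=np.int8),
                         tree.outcome_array()])
    return out_map[data.responses]


def recompose_responses(pseudo: np.ndarray, tree: TreeSpec) -> np.ndarray:
    """Inverse of :func:`decompose_responses` on observed cells (0 = missing)."""
    arr = tree.outcome_array()
    N, I, H = pseudo.shape
    out = np.zeros((N, I), dtype=int)
    for x in range(tree.n_categories):
        match = np.all(pseudo == arr[x], axis=2)
        out[match] = x + 1
    return out


def _theta_items(person: PersonParameters, item: ItemParameters) -> np.ndarray:
    """(N, I) trait values gathered per item dimension, with inversion sign."""
    th = person.theta[:, item.item_dimension]  # (N, I)
    return th * item.trait_sign()


def _node_linpreds(person: PersonParameters, item: ItemParameters, tree: TreeSpec):
    """Linear predictors of every node/branch, each (N, I).

    Returns a dict with keys ``agree``, ``extreme_agree``,
    ``extreme_disagree`` and, for five-point trees, ``moderate``.
    """
    th = _theta_items(person, item)
    out = {}
    b1 = item.beta[tree.node_index(1)]
    out["agree"] = item.loadings[AGREE_TRAIT] * th - b1
    b2 = item.beta[tree.node_index(2)]
    a_th = item.loadings[EXTREME_TRAIT] * th
    a_ers = 0.0
    if person.eta is not None:
        a_ers = item.loadings[EXTREME_ERS] * person.eta[:, None]
    out["extreme_agree"] = a_ers + a_th - b2
    out["extreme_disagree"] = a_ers - a_th - b2
    if tree.has_moderate_node:
        b0 = item.beta[tree.node_index(0)]
        a_mrs = 0.0
        if person.kappa is not None:
            a_mrs = item.loadings[MODERATE_MRS] * person.kappa[:, None]
        out["moderate"] = a_mrs - b0
    return out


def node_probability(
    node: NodeSpec,
    person: PersonParameters,
    item: ItemParameters,
    item_index: int,
    tree: TreeSpec | None = None,
    branch_context: str | int | None = None,
) -> np.ndarray:
    """P(pseudo-item outcome = 1) at one item, for every person.

    ``branch_context`` ("agree"/1 or "disagree"/0) is required for the
    extreme node, whose trait term flips sign on the disagree branch.
    """
    if tree is None:
        tree = five_point_tree() if node.node_id == 0 else four_point_tree()
    if node.branch_rule == SIGN_FLIP:
        if branch_context is None:
            raise ValueError("extreme node requires the agreement outcome as branch context")
        agree = branch_context in (1, "agree")
    elif branch_context is not None:
        raise ValueError(f"node {node.node_id} takes no branch context")
    lp = _node_linpreds(person, item, tree)
    i = item_index
    if not 0 <= i < item.n_items:
        raise IndexError(f"item_index {i} out of range")
    if node.node_id == 1:
        return expit(lp["agree"][:, i])
    if node.node_id == 2:
        key = "extreme_agree" if agree else "extreme_disagree"
        return expit(lp[key][:, i])
    return expit(lp["moderate"][:, i])


def category_probabilities(
    person: PersonParameters,
    item: ItemParameters,
    item_index: int,
    tree: TreeSpec,
) -> np.ndarray:
    """(N, K) matrix of ordinal category probabilities at one item."""
    probs = _all_category_probabilities(person, item, tree)
    return probs[:, item_index, :]


def _all_category_probabilities(
    person: PersonParameters, item: ItemParameters, tree: TreeSpec
) -> np.ndarray:
    """(N, I, K) category probabilities, product of node factors per branch."""
    lp = _node_linpreds(person, item, tree)
    p1 = expit(lp["agree"])
    pe_a = expit(lp["extreme_agree"])
    pe_d = expit(lp["extreme_disagree"])
    if tree.n_categories == 4:
        return np.stack(
            [
                (1 - p1) * pe_d,
                (1 - p1) * (1 - pe_d),
                p1 * (1 - pe_a),
                p1 * pe_a,
            ],
            axis=-1,
        )
    q = expit(lp["moderate"])
    rest = 1 - q
    return np.stack(
        [
            rest * (1 - p1) * pe_d,
            rest * (1 - p1) * (1 - pe_d),
            q,
            rest * p1 * (1 - pe_a),
            rest * p1 * pe_a,
        ],
        axis=-1,
    )


def _bernoulli_loglik(y: np.ndarray, lp: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Sum over nothing: elementwise log Bernoulli(y | logistic(lp)), 0 where unobserved."""
    ll = y * lp - np.logaddexp(0.0, lp)
    return np.where(observed, ll, 0.0)


def pointwise_loglik(
    data: ResponseData,
    person: PersonParameters,
    item: ItemParameters,
    tree: TreeSpec | None = None,
) -> np.ndarray:
    """(N, I) log probability of each observed response; missing cells give 0.

    Equals the sum of the Bernoulli pseudo-item log likelihoods along the
    branch selected by each category, which is the log of the product of
    node factors.
    """
    tree = tree or data.tree
    pseudo = decompose_responses(data)
    lp = _node_linpreds(person, item, tree)
    j1, j2 = tree.node_index(1), tree.node_index(2)
    y1 = pseudo[:, :, j1].astype(float)
    y2 = pseudo[:, :, j2].astype(float)
    obs1 = pseudo[:, :, j1] != MISSING
    obs2 = pseudo[:, :, j2] != MISSING
    ll = _bernoulli_loglik(np.where(obs1, y1, 0.0), lp["agree"], obs1)
    z = np.where(y1 == 1, lp["extreme_agree"], lp["extreme_disagree"])
    ll += _bernoulli_loglik(np.where(obs2, y2, 0.0), z, obs2)
    if tree.has_moderate_node:
        j0 = tree.node_index(0)
        y0 = pseudo[:, :, j0].astype(float)
        obs0 = pseudo[:, :, j0] != MISSING
        ll += _bernoulli_loglik(np.where(obs0, y0, 0.0), lp["moderate"], obs0)
    return ll
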