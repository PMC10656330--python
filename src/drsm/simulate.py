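"""Synthetic rating-scale data under every model variant.

Data generation mirrors the two simulation designs the models were built
for: person parameters and pseudo-item difficulties are i.i.d. standard
normal, loadings follow the variant's constraints (unit, constant,
trajectory-valued, or trajectory plus item noise), and binary pseudo-item
responses are Bernoulli draws with the model-implied branch probabilities,
reassembled into ordinal categories through the tree's category map.

Seed policy: replication ``r`` of a condition uses the counter-based
stream ``default_rng([base_seed, r])``, so each replication is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .tree import (
    AGREE_TRAIT,
    EXTREME_ERS,
    EXTREME_TRAIT,
    MISSING,
    MODERATE_MRS,
    ItemParameters,
    PersonParameters,
    ResponseData,
    TreeSpec,
    _node_linpreds,
    make_tree,
    recompose_responses,
)
from .trajectory import FDRSMSpec, TrajectorySpec, draw_noisy_loadings, trajectory_loading

__all__ = [
    "VARIANTS",
    "SimulationCondition",
    "SimulatedDataset",
    "simulate_persons",
    "simulate_items",
    "simulate_dataset",
    "study1_conditions",
    "study2_conditions",
]

# generating variants: free-loading (2PL) generation is not part of either
# study design, so the simulator covers the five process-structured variants
VARIANTS = ("ordinal", "ers", "static", "drsm", "fdrsm")

# Study-1 trajectory grid: trait loadings decrease, ERS loadings increase,
# paired into large / medium / small total strategy change.  Within each
# change size both orderings (trait steeper / ERS steeper) occur.
STUDY1_TRAIT_GRID = [(0.8, 0.2), (0.7, 0.3), (0.6, 0.4), (0.5, 0.5)]
STUDY1_ERS_GRID = [(0.2, 0.8), (0.3, 0.7), (0.4, 0.6), (0.5, 0.5)]
STUDY1_PAIRINGS = {  # change size -> [(|trait slope|, |ERS slope|), ...]
    "large": [(0.6, 0.4), (0.4, 0.6)],
    "medium": [(0.4, 0.2), (0.2, 0.4)],
    "small": [(0.2, 0.0), (0.0, 0.2)],
}
STUDY1_LAMBDAS = (2.0, 0.5)
STUDY1_STATIC = [(0.3, 0.7), (0.7, 0.3)]  # (trait, ERS) constant loadings


@dataclass
class SimulationCondition:
    """One cell of a simulation design."""

    variant: str
    N: int = 1000
    I: int = 40
    n_categories: int = 4
    trait_trajectory: tuple[float, float] | None = None
    ers_trajectory: tuple[float, float] | None = None
    agree_trajectory: tuple[float, float] | None = None
    mrs_trajectory: tuple[float, float] | None = None
    static_loadings: tuple[float, float] | None = None  # (trait, ERS) constants
    lam: float = 2.0
    noise_sd: float = 0.0
    n_replications: int = 100
    base_seed: int = 20230206
    label: str = ""

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.variant == "fdrsm" and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.variant == "static" and self.static_loadings is None:
            raise ValueError("static variant requires static_loadings")
        if self.variant in ("drsm", "fdrsm") and (
            self.trait_trajectory is None or self.ers_trajectory is None
        ):
            raise ValueError(f"{self.variant} variant requires trait and ERS trajectories")

    @property
    def tree(self) -> TreeSpec:
        return make_tree(self.n_categories)


@dataclass
class SimulatedDataset:
    """A generated data set together with the truth that produced it."""

    data: ResponseData
    person: PersonParameters
    item: ItemParameters
    trajectories: dict[str, TrajectorySpec]
    condition: SimulationCondition
    replication_index: int
    seed: tuple[int, int]


def simulate_persons(
    N: int,
    D: int = 1,
    include_ers: bool = True,
    include_mrs: bool = False,
    rng: np.random.Generator | int | None = None,
) -> PersonParameters:
    """Draw i.i.d. standard-normal, mutually uncorrelated person parameters."""
    if N < 1:
        raise ValueError("need at least one person")
    rng = np.random.default_rng(rng)
    theta = rng.standard_normal((N, D))
    eta = rng.standard_normal(N) if include_ers else None
    kappa = rng.standard_normal(N) if include_mrs else None
    return PersonParameters(theta=theta, eta=eta, kappa=kappa)


def simulate_items(
    I: int, tree: TreeSpec, rng: np.random.Generator | int | None = None
) -> ItemParameters:
    """Draw i.i.d. standard-normal pseudo-item difficulties (loadings unset)."""
    if I < 2:
        raise ValueError("need at least two items")
    rng = np.random.default_rng(rng)
    beta = rng.standard_normal((tree.n_nodes, I))
    loadings = {AGREE_TRAIT: np.ones(I), EXTREME_TRAIT: np.ones(I), EXTREME_ERS: np.ones(I)}
    if tree.has_moderate_node:
        loadings[MODERATE_MRS] = np.ones(I)
    return ItemParameters(beta=beta, loadings=loadings)


def _condition_loadings(
    cond: SimulationCondition, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, TrajectorySpec]]:
    """Per-item loading vectors and the trajectory truth for a condition."""
    I = cond.I
    ones, zeros = np.ones(I), np.zeros(I)
    trajectories: dict[str, TrajectorySpec] = {}

    def from_traj(endpoints, process):
        spec = TrajectorySpec(endpoints[0], endpoints[1], cond.lam, process=process)
        trajectories[process] = spec
        mu = trajectory_loading(spec, np.arange(1, I + 1), I)
        if cond.variant == "fdrsm":
            fd = draw_noisy_loadings(FDRSMSpec(spec, cond.noise_sd), I, rng)
            return fd.item_loadings
        return mu

    if cond.variant == "ordinal":
        loadings = {AGREE_TRAIT: ones, EXTREME_TRAIT: ones, EXTREME_ERS: zeros}
    elif cond.variant == "ers":
        loadings = {AGREE_TRAIT: ones, EXTREME_TRAIT: zeros, EXTREME_ERS: ones}
    elif cond.variant == "static":
        a_th, a_ers = cond.static_loadings
        loadings = {
            AGREE_TRAIT: ones,
            EXTREME_TRAIT: np.full(I, a_th),
            EXTREME_ERS: np.full(I, a_ers),
        }
    else:  # drsm / fdrsm
        loadings = {
            EXTREME_TRAIT: from_traj(cond.trait_trajectory, "trait"),
            EXTREME_ERS: from_traj(cond.ers_trajectory, "ERS"),
        }
        if cond.agree_trajectory is not None:
            loadings[AGREE_TRAIT] = from_traj(cond.agree_trajectory, "agree_trait")
        else:
            loadings[AGREE_TRAIT] = ones
    if cond.n_categories == 5:
        if cond.mrs_trajectory is not None:
            loadings[MODERATE_MRS] = from_traj(cond.mrs_trajectory, "MRS")
        else:
            loadings[MODERATE_MRS] = ones
    return loadings, trajectories


def simulate_dataset(cond: SimulationCondition, replication_index: int = 0) -> SimulatedDataset:
    """Generate one replication of a condition (deterministic in its seed)."""
    rng = np.random.default_rng([cond.base_seed, replication_index])
    tree = cond.tree
    include_ers = cond.variant != "ordinal"
    person = simulate_persons(
        cond.N, include_ers=include_ers, include_mrs=tree.has_moderate_node, rng=rng
    )
    if not include_ers:
        # the extreme node still exists; a zero loading removes the ERS term
        person = PersonParameters(person.theta, eta=np.zeros(cond.N), kappa=person.kappa)
    item = simulate_items(cond.I, tree, rng)
    loadings, trajectories = _condition_loadings(cond, rng)
    item = ItemParameters(
        beta=item.beta,
        loadings=loadings,
        item_dimension=item.item_dimension,
        item_inverted=item.item_inverted,
    )
    lp = _node_linpreds(person, item, tree)
    shape = (cond.N, cond.I)
    y1 = (rng.random(shape) < expit(lp["agree"])).astype(np.int8)
    z = np.where(y1 == 1, lp["extreme_agree"], lp["extreme_disagree"])
    y2 = (rng.random(shape) < expit(z)).astype(np.int8)
    if tree.has_moderate_node:
        y0 = (rng.random(shape) < expit(lp["moderate"])).astype(np.int8)
        pseudo = np.stack([y0, y1, y2], axis=-1)
        pseudo[y0 == 1, 1:] = MISSING
    else:
        pseudo = np.stack([y1, y2], axis=-1)
    responses = recompose_responses(pseudo, tree)
    data = ResponseData(responses=responses, tree=tree)
    return SimulatedDataset(
        data=data,
        person=person,
        item=item,
        trajectories=trajectories,
        condition=cond,
        replication_index=replication_index,
        seed=(cond.base_seed, replication_index),
    )


def _scaled(value: int, scale: float, minimum: int) -> int:
    return max(int(round(value * scale)), minimum)


def study1_conditions(
    scale: float = 1.0,
    base_seed: int = 20230206,
    cross_lambda: bool = True,
    both_orderings: bool = True,
) -> list[SimulationCondition]:
    """The first study's full data-generation grid, optionally shrunk.

    ``scale`` shrinks N, I and the replication count proportionally (with
    floors of 50 persons, 10 items, 1 replication).
    """
    sizes_N = [500, 1000]
    sizes_I = [20, 40]
    lams = STUDY1_LAMBDAS if cross_lambda else STUDY1_LAMBDAS[:1]
    trait_by_slope = {round(g1 - gI, 1): (g1, gI) for g1, gI in STUDY1_TRAIT_GRID}
    ers_by_slope = {round(gI - g1, 1): (g1, gI) for g1, gI in STUDY1_ERS_GRID}
    conds: list[SimulationCondition] = []
    for N in sizes_N:
        for I in sizes_I:
            common = dict(
                N=_scaled(N, scale, 50),
                I=_scaled(I, scale, 10),
                n_replications=_scaled(100, scale, 1),
                base_seed=base_seed,
            )
            for size, pairings in STUDY1_PAIRINGS.items():
                if not both_orderings:
                    pairings = pairings[:1]
                for s_th, s_ers in pairings:
                    for lam in lams:
                        conds.append(
                            SimulationCondition(
                                variant="drsm",
                                trait_trajectory=trait_by_slope[s_th],
                                ers_trajectory=ers_by_slope[s_ers],
                                lam=lam,
                                label=f"drsm-{size}-th{s_th}-ers{s_ers}-lam{lam}-N{N}-I{I}",
                                **common,
                            )
                        )
            for a_th, a_ers in STUDY1_STATIC:
                conds.append(
                    SimulationCondition(
                        variant="static",
                        static_loadings=(a_th, a_ers),
                        label=f"static-{a_th}-{a_ers}-N{N}-I{I}",
                        **common,
                    )
                )
            for uni in ("ordinal", "ers"):
                conds.append(
                    SimulationCondition(variant=uni, label=f"{uni}-N{N}-I{I}", **common)
                )
    return conds


def study2_conditions(
    scale: float = 1.0, base_seed: int = 20230207, lam: float = 2.0
) -> list[SimulationCondition]:
    """The second study's grid: noisy trajectories, loaded agreement node.

    All three process trajectories (trait loadings of agreement and of
    extreme responding decreasing, ERS loadings increasing) share the same
    absolute slope, centred at 0.5, with item noise SD 0.1 or 0.2.
    """
    conds = []
    for s in (0.0, 0.2, 0.4, 0.6):
        down = (0.5 + s / 2, 0.5 - s / 2)
        up = (0.5 - s / 2, 0.5 + s / 2)
        for sd in (0.1, 0.2):
            conds.append(
                SimulationCondition(
                    variant="fdrsm",
                    N=_scaled(1000, scale, 50),
                    I=_scaled(40, scale, 10),
                    trait_trajectory=down,
                    ers_trajectory=up,
                    agree_trajectory=down,
                    lam=lam,
                    noise_sd=sd,
                    n_replications=_scaled(100, scale, 1),
                    base_seed=base_seed,
                    label=f"fdrsm-slope{s}-sd{sd}",
                )
            )
    return conds
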