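"""Dynamic loading trajectories.

The influence of a response process (substantive trait, ERS, MRS) on its
decision node is allowed to change smoothly with item position.  The
loading of item ``i`` (1-based) out of ``I`` is

    alpha_i = (gamma_1 - gamma_I) * (1 - ((i-1)/(I-1)) ** lam) + gamma_I

so ``gamma_1`` and ``gamma_I`` are the loadings at the first and last item
and ``lam`` controls the shape: linear for ``lam = 1``, change concentrated
late for ``lam > 1`` and early for ``lam < 1``.  The *slope*
``gamma_I - gamma_1`` summarises the total change; zero slope means a
static response strategy.  ``lam`` and ``1/lam`` curve the trajectory
symmetrically in opposite directions, so estimation restricts it to
[0.25, 4].

The flexible variant adds item-level noise: realized loadings are drawn
from Normal(alpha_i, sigma) and truncated at zero to respect the global
nonnegativity constraint on loadings.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

__all__ = [
    "LAMBDA_BOUNDS",
    "TrajectorySpec",
    "FDRSMSpec",
    "trajectory_loading",
    "slope",
    "draw_noisy_loadings",
]

LAMBDA_BOUNDS = (0.25, 4.0)


@dataclass
class TrajectorySpec:
    """Endpoints and shape of one process's loading trajectory."""

    gamma_first: float
    gamma_last: float
    shape: float = 1.0
    process: str = "trait"
    group: str | None = None

    def __post_init__(self) -> None:
        if self.gamma_first < 0 or self.gamma_last < 0:
            raise ValueError("endpoint loadings must be nonnegative")
        lo, hi = LAMBDA_BOUNDS
        if not lo <= self.shape <= hi:
            raise ValueError(f"shape must lie in [{lo}, {hi}], got {self.shape}")

    @property
    def slope(self) -> float:
        return self.gamma_last - self.gamma_first

    def to_json(self) -> str:
        return json.dumps(
            {
                "process": self.process,
                "gamma_first": self.gamma_first,
                "gamma_last": self.gamma_last,
                "shape": self.shape,
                "group": self.group,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TrajectorySpec":
        d = json.loads(s)
        return cls(
            gamma_first=d["gamma_first"],
            gamma_last=d["gamma_last"],
            shape=d["shape"],
            process=d.get("process", "trait"),
            group=d.get("group"),
        )


@dataclass
class FDRSMSpec:
    """A trajectory plus item-level Gaussian deviations of SD ``noise_sd``."""

    trajectory: TrajectorySpec
    noise_sd: float = 0.0
    item_loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.item_loadings is not None:
            self.item_loadings = np.asarray(self.item_loadings, dtype=float)


def trajectory_loading(
    spec: TrajectorySpec, item_index: int | np.ndarray, n_items: int
) -> float | np.ndarray:
    """Loading at item position ``item_index`` (1-based) of ``n_items``."""
    if n_items < 2:
        raise ValueError("a trajectory needs at least two items")
    i = np.asarray(item_index)
    if np.any((i < 1) | (i > n_items)):
        raise ValueError(f"item_index must lie in 1..{n_items}")
    t = (i - 1) / (n_items - 1)
    out = (spec.gamma_first - spec.gamma_last) * (1.0 - t ** spec.shape) + spec.gamma_last
    if np.isscalar(item_index):
        return float(out)
    return out


def slope(spec: TrajectorySpec) -> float:
    """Total change of the loading over the questionnaire (last minus first)."""
    return spec.slope


def draw_noisy_loadings(
    fd: FDRSMSpec, n_items: int, rng: np.random.Generator | int | None = None
) -> FDRSMSpec:
    """Realize item loadings around the trajectory; truncated at zero.

    Returns a new spec with ``item_loadings`` filled in; reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(rng)
    mu = trajectory_loading(fd.trajectory, np.arange(1, n_items + 1), n_items)
    alpha = mu + fd.noise_sd * rng.standard_normal(n_items)
    alpha = np.maximum(alpha, 0.0)
    return FDRSMSpec(trajectory=fd.trajectory, noise_sd=fd.noise_sd, item_loadings=alpha)
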