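"""Delimited-text input/output and deterministic fixtures.

Response matrices travel as plain CSV (rows = persons, columns = items,
integer categories, empty cell = missing) with a JSON sidecar declaring
the number of categories and optional per-item metadata (trait dimension,
inverted wording, trajectory group).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimulationCondition, SimulatedDataset, simulate_dataset
from .tree import ResponseData, make_tree

__all__ = ["read_response_csv", "write_response_csv", "write_truth_json", "make_fixture"]


def write_response_csv(data: ResponseData, path, meta_path=None, **meta_extra) -> None:
    """Write a response matrix as CSV plus its JSON sidecar."""
    resp = data.responses.astype(float)
    resp[resp == 0] = np.nan
    df = pd.DataFrame(resp, columns=[f"item_{i+1}" for i in range(data.n_items)])
    df.to_csv(path, index=False, float_format="%.0f")
    if meta_path is not None:
        meta = {"n_categories": data.tree.n_categories}
        for key, val in meta_extra.items():
            if val is not None:
                meta[key] = np.asarray(val).tolist()
        Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_response_csv(path, meta_path) -> tuple[ResponseData, dict]:
    """Read a response CSV and its sidecar; validates categories against K."""
    meta = json.loads(Path(meta_path).read_text())
    if "n_categories" not in meta:
        raise ValueError(f"{meta_path}: sidecar must declare n_categories")
    K = int(meta["n_categories"])
    df = pd.read_csv(path)
    values = df.to_numpy(dtype=float)
    filled = np.where(np.isnan(values), 0, values)
    if not np.allclose(filled, np.round(filled)):
        bad = np.argwhere(filled != np.round(filled))[0]
        raise ValueError(f"{path}: non-integer category at row {bad[0]}, column {df.columns[bad[1]]}")
    ints = filled.astype(int)
    out_of_range = (ints < 0) | (ints > K)
    if np.any(out_of_range):
        p, i = map(int, np.argwhere(out_of_range)[0])
        raise ValueError(
            f"{path}: category {ints[p, i]} at row {p}, column {df.columns[i]} outside 1..{K}"
        )
    data = ResponseData(responses=ints, tree=make_tree(K))
    for key in ("item_dimension", "item_inverted", "item_group"):
        if key in meta and len(meta[key]) != data.n_items:
            raise ValueError(f"{meta_path}: {key} length does not match the item count")
    return data, meta


def write_truth_json(sim: SimulatedDataset, path) -> None:
    """Serialize the generating parameters of a simulated data set."""
    cond = sim.condition
    truth = {
        "condition": {
            "variant": cond.variant,
            "N": cond.N,
            "I": cond.I,
            "n_categories": cond.n_categories,
            "lam": cond.lam,
            "noise_sd": cond.noise_sd,
            "label": cond.label,
        },
        "seed": list(sim.seed),
        "replication_index": sim.replication_index,
        "beta": sim.item.beta.tolist(),
        "loadings": {k: v.tolist() for k, v in sim.item.loadings.items()},
        "theta": sim.person.theta.tolist(),
        "eta": None if sim.person.eta is None else sim.person.eta.tolist(),
        "kappa": None if sim.person.kappa is None else sim.person.kappa.tolist(),
        "trajectories": {
            k: json.loads(t.to_json()) for k, t in sim.trajectories.items()
        },
    }
    Path(path).write_text(json.dumps(truth, indent=1))


_FIXTURES = {
    "tiny": dict(variant="ordinal", N=50, I=10),
    "study1-mini": dict(
        variant="drsm", N=50, I=10,
        trait_trajectory=(0.8, 0.2), ers_trajectory=(0.3, 0.7), lam=2.0,
    ),
    "study2-mini": dict(
        variant="fdrsm", N=50, I=10,
        trait_trajectory=(0.8, 0.2), ers_trajectory=(0.3, 0.7),
        agree_trajectory=(0.8, 0.2), lam=2.0, noise_sd=0.1,
    ),
}


def make_fixture(kind: str, seed: int = 0, out_dir=".") -> dict[str, Path]:
    """Write a small deterministic data set with its truth sidecar."""
    if kind not in _FIXTURES:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_FIXTURES)}")
    cond = SimulationCondition(base_seed=seed, n_replications=1, **_FIXTURES[kind])
    sim = simulate_dataset(cond, 0)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": out_dir / f"{kind}.csv",
        "meta": out_dir / f"{kind}.meta.json",
        "truth": out_dir / f"{kind}.truth.json",
    }
    write_response_csv(sim.data, paths["data"], paths["meta"])
    write_truth_json(sim, paths["truth"])
    return paths
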