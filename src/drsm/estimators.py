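"""Bayesian estimation of the IRTree model variants.

Six variants are exposed as scikit-learn style estimators that differ only
in how the loading slots of the decision nodes are constrained:

===============  =========================  =========================
class            extreme-node trait loading extreme-node ERS loading
===============  =========================  =========================
OrdinalIRTree    fixed at 1                 fixed at 0
ERSIRTree        fixed at 0                 fixed at 1
StaticIRTree     one estimated constant     one estimated constant
DRSM             position trajectory        position trajectory
FlexibleDRSM     trajectory + item noise    trajectory + item noise
TwoPLIRTree      free per item              free per item
===============  =========================  =========================

Estimation is NUTS with the weakly informative prior set used throughout:
standard-normal person parameters, hierarchical normal difficulties with
Cauchy(0, 5) / half-Cauchy(0, 5) hyperpriors, LogNormal(0, 2) loadings and
trajectory endpoints, and a LogNormal(-0.5, 1) shape prior truncated to
[0.25, 4].  Point estimates are expected a posteriori (EAP) means;
convergence is judged by split R-hat below 1.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
from sklearn.base import BaseEstimator

from ._model import BuiltModel, build_model
from ._nuts import nuts_sample
from .tree import ResponseData, make_tree

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "FitResult",
    "OrdinalIRTree",
    "ERSIRTree",
    "StaticIRTree",
    "DRSM",
    "FlexibleDRSM",
    "TwoPLIRTree",
    "MODEL_CLASSES",
    "make_model",
    "fit",
    "eap",
    "credible_interval",
    "check_convergence",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the weakly informative prior set."""

    loading_mu: float = 0.0
    loading_sd: float = 2.0  # LogNormal(0, 2) on loadings and endpoints
    lam_mu: float = -0.5
    lam_sd: float = 1.0  # LogNormal(-0.5, 1) on the shape, truncated
    cauchy_scale: float = 5.0  # difficulty hyperpriors and noise SDs


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; ``draws`` counts post-warmup iterations per chain."""

    chains: int = 4
    warmup: int = 500
    draws: int = 500
    max_treedepth: int = 8
    target_accept: float = 0.8
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("split R-hat needs at least two chains")

    @classmethod
    def simulation_preset(cls) -> "MCMCConfig":
        return cls(chains=4, warmup=500, draws=500)

    @classmethod
    def empirical_preset(cls) -> "MCMCConfig":
        return cls(chains=4, warmup=500, draws=1000)


@dataclass
class FitResult:
    """Posterior draws and summaries of one model fit."""

    variant: str
    draws: dict[str, np.ndarray]  # name -> (chains, draws, ...) natural scale
    rhat: dict[str, np.ndarray]
    max_rhat: float
    converged: bool
    loglik: np.ndarray | None  # (chains, draws, n_obs) over observed cells
    obs_index: np.ndarray | None  # (n_obs, 2) person/item of each cell
    accept_stat: np.ndarray
    divergences: np.ndarray
    n_persons: int
    n_items: int
    config: MCMCConfig

    def eap(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:]).mean(axis=0)

    def posterior_sd(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:]).std(axis=0, ddof=1)

    def credible_interval(self, name: str, level: float = 0.95) -> np.ndarray:
        d = self.draws[name]
        flat = d.reshape(-1, *d.shape[2:])
        lo = (1 - level) / 2
        return np.quantile(flat, [lo, 1 - lo], axis=0)

    def to_inference_data(self) -> az.InferenceData:
        post = {k: v for k, v in self.draws.items() if v.ndim >= 2}
        groups = {"posterior": post}
        if self.loglik is not None:
            groups["log_likelihood"] = {"y": self.loglik}
        return az.from_dict(**groups)


def eap(fit: FitResult, name: str | None = None):
    """EAP point estimate(s); all parameters if ``name`` is None."""
    if name is not None:
        return fit.eap(name)
    return {k: fit.eap(k) for k in fit.draws}


def credible_interval(fit: FitResult, name: str, level: float = 0.95) -> np.ndarray:
    """Equal-tailed posterior interval, rows (lower, upper)."""
    return fit.credible_interval(name, level)


def check_convergence(fit: FitResult, threshold: float = 1.05) -> dict:
    """Split R-hat report: pass iff the largest R-hat is at most ``threshold``."""
    return {
        "max_rhat": fit.max_rhat,
        "threshold": threshold,
        "passed": bool(fit.max_rhat <= threshold),
        "divergences": int(fit.divergences.sum()),
    }


def _as_response_data(X, n_categories: int) -> ResponseData:
    if isinstance(X, ResponseData):
        return X
    X = np.asarray(getattr(X, "values", X))
    return ResponseData(responses=X, tree=make_tree(n_categories))


class BaseIRTree(BaseEstimator):
    """Shared fitting machinery; subclasses pin the model variant."""

    _variant: str = ""

    def __init__(
        self,
        n_categories: int = 4,
        agreement: str = "rasch",
        chains: int = 4,
        warmup: int = 500,
        draws: int = 500,
        target_accept: float = 0.8,
        max_treedepth: int = 8,
        random_state: int | None = None,
        item_dimension=None,
        item_inverted=None,
        item_group=None,
        free_person_sds: tuple = (),
        store_loglik: bool = True,
        rhat_threshold: float = 1.05,
        priors: PriorSpec | None = None,
    ):
        self.n_categories = n_categories
        self.agreement = agreement
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.random_state = random_state
        self.item_dimension = item_dimension
        self.item_inverted = item_inverted
        self.item_group = item_group
        self.free_person_sds = free_person_sds
        self.store_loglik = store_loglik
        self.rhat_threshold = rhat_threshold
        self.priors = priors

    # -- the variant is a class property, not a constructor argument
    @property
    def variant(self) -> str:
        return self._variant

    def _mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            max_treedepth=self.max_treedepth,
            target_accept=self.target_accept,
            rhat_threshold=self.rhat_threshold,
        )

    def fit(self, X, y=None):
        """Sample the posterior given an N x I matrix of categories 1..K."""
        data = _as_response_data(X, self.n_categories)
        if self._variant in ("fdrsm",) and data.n_items < 3:
            raise ValueError("too few items for a trajectory model")
        from ._model import _Priors

        pr = self.priors
        model = build_model(
            data,
            self._variant,
            agreement=self.agreement,
            item_dimension=self.item_dimension,
            item_inverted=self.item_inverted,
            item_group=self.item_group,
            free_person_sds=tuple(self.free_person_sds),
            priors=None if pr is None else _Priors(
                loading_mu=pr.loading_mu, loading_sd=pr.loading_sd,
                lam_mu=pr.lam_mu, lam_sd=pr.lam_sd, cauchy_scale=pr.cauchy_scale,
            ),
        )
        cfg = self._mcmc_config()
        res = nuts_sample(
            model.logp_and_grad,
            model.dim,
            chains=cfg.chains,
            warmup=cfg.warmup,
            draws=cfg.draws,
            seed=self.random_state,
            max_treedepth=cfg.max_treedepth,
            target_accept=cfg.target_accept,
        )
        self.model_ = model
        self.result_ = _summarize(model, res.draws, cfg, self._variant,
                                  store_loglik=self.store_loglik)
        self.result_.accept_stat = res.accept_stat
        self.result_.divergences = res.divergences
        fr = self.result_
        self.theta_ = fr.eap("theta")
        self.eta_ = fr.eap("eta") if "eta" in fr.draws else None
        self.kappa_ = fr.eap("kappa") if "kappa" in fr.draws else None
        self.beta_ = fr.eap("beta")
        self.loadings_ = {
            name: fr.eap(f"alpha.{name}") for name in model.slot_configs
        }
        self.trajectories_ = {}
        for name, cfg_s in model.slot_configs.items():
            if cfg_s.kind in ("trajectory", "noisy"):
                self.trajectories_[name] = {
                    "gamma_first": fr.eap(f"gamma_first.{name}"),
                    "gamma_last": fr.eap(f"gamma_last.{name}"),
                    "shape": fr.eap(f"lam.{name}"),
                    "slope": fr.eap(f"slope.{name}"),
                    "slope_sd": fr.posterior_sd(f"slope.{name}"),
                    "slope_ci": fr.credible_interval(f"slope.{name}"),
                }
        self.max_rhat_ = fr.max_rhat
        self.converged_ = fr.converged
        if not fr.converged:
            warnings.warn(
                f"{self._variant} fit flagged: max split R-hat "
                f"{fr.max_rhat:.3f} > {cfg.rhat_threshold}", stacklevel=2
            )
        return self

    def score(self, X=None, y=None) -> float:
        """Mean posterior pointwise log-likelihood per observed response."""
        fr = self.result_
        if fr.loglik is None:
            raise ValueError("fit with store_loglik=True to score")
        return float(fr.loglik.mean())


def _summarize(model: BuiltModel, draws: np.ndarray, cfg: MCMCConfig,
               variant: str, store_loglik: bool) -> FitResult:
    chains, n_draws, dim = draws.shape
    natural: dict[str, list] = {}
    loglik = None
    if store_loglik:
        obs = np.argwhere(~model.data.missing_mask)
        loglik = np.empty((chains, n_draws, len(obs)), dtype=np.float32)
        rows, cols = obs[:, 0], obs[:, 1]
    for c in range(chains):
        for d in range(n_draws):
            params = model.constrain_draw(draws[c, d])
            for k, v in params.items():
                natural.setdefault(k, []).append(np.asarray(v))
            if store_loglik:
                ll = model.loglik_matrix(draws[c, d])
                loglik[c, d] = ll[rows, cols]
    out = {}
    for k, vals in natural.items():
        arr = np.stack(vals).reshape(chains, n_draws, *np.asarray(vals[0]).shape)
        out[k] = arr
    # convergence on the sampler's own coordinates
    rhat_all = _split_rhat(draws)
    rhat = {"unconstrained": rhat_all}
    max_rhat = float(np.nanmax(rhat_all))
    return FitResult(
        variant=variant,
        draws=out,
        rhat=rhat,
        max_rhat=max_rhat,
        converged=bool(max_rhat <= cfg.rhat_threshold),
        loglik=loglik,
        obs_index=None if not store_loglik else obs,
        accept_stat=np.zeros(chains),
        divergences=np.zeros(chains, dtype=int),
        n_persons=model.N,
        n_items=model.I,
        config=cfg,
    )


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split R-hat per coordinate of (chains, draws, dim) samples."""
    dataset = az.convert_to_dataset(draws)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(dataset, method="split")
    return np.asarray(r["x"])


class OrdinalIRTree(BaseIRTree):
    """Trait-only tree: Rasch agreement and extreme nodes, no response style."""

    _variant = "ordinal"


class ERSIRTree(BaseIRTree):
    """Traditional response-style tree: the extreme node is pure ERS."""

    _variant = "ers"


class StaticIRTree(BaseIRTree):
    """Two-dimensional extreme node with constant trait and ERS loadings."""

    _variant = "static"


class DRSM(BaseIRTree):
    """Dynamic response strategy model: loadings follow position trajectories."""

    _variant = "drsm"


class FlexibleDRSM(BaseIRTree):
    """DRSM with item-level loading noise shrunk toward the trajectory.

    Pass ``agreement="model"`` to also give the agreement node a noisy
    trajectory (the parameterization with a loaded agreement node).
    """

    _variant = "fdrsm"


class TwoPLIRTree(BaseIRTree):
    """Free item-specific loadings on the multidimensional nodes."""

    _variant = "2pl"


MODEL_CLASSES = {
    "ordinal": OrdinalIRTree,
    "ers": ERSIRTree,
    "static": StaticIRTree,
    "drsm": DRSM,
    "fdrsm": FlexibleDRSM,
    "2pl": TwoPLIRTree,
}


def make_model(variant: str, **kwargs) -> BaseIRTree:
    """Instantiate the estimator class for a variant name."""
    try:
        cls = MODEL_CLASSES[variant.lower().replace("-", "").replace("f_", "f")]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None
    return cls(**kwargs)


def fit(variant: str, data, priors: PriorSpec | None = None,
        mcmc: MCMCConfig | None = None, **kwargs) -> FitResult:
    """Functional front-end: fit a variant and return its :class:`FitResult`."""
    mcmc = mcmc or MCMCConfig.simulation_preset()
    est = make_model(
        variant,
        chains=mcmc.chains,
        warmup=mcmc.warmup,
        draws=mcmc.draws,
        max_treedepth=mcmc.max_treedepth,
        target_accept=mcmc.target_accept,
        rhat_threshold=mcmc.rhat_threshold,
        priors=priors,
        **kwargs,
    )
    est.fit(data)
    return est.result_
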