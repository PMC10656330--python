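"""Unconstrained-parameter posterior builders for the IRTree variants.

Each model variant is assembled from *loading slots* -- one per
(node, process) pair -- whose per-item loadings are either fixed, a single
estimated constant, a position trajectory, a trajectory with item-level
noise, or free per item.  The builder lays the free parameters out in one
flat unconstrained vector, and provides the log posterior with its
analytic gradient (the likelihood is a product of Bernoulli-logit node
factors, so all gradients are closed-form).

Constraint transforms:

* nonnegative loadings and scale parameters live on the log scale, so the
  LogNormal loading priors act as normal densities on the unconstrained
  coordinate and the nonnegativity constraint holds by construction;
* the trajectory shape ``lam`` is mapped to [0.25, 4] through a scaled
  logistic on the log scale, with its truncated-LogNormal prior plus the
  transform Jacobian;
* item-noise loadings of the flexible model are non-centered: standard
  normal deviations ``z_i`` give ``alpha_i = max(0, mu_i + sigma * z_i)``,
  which mirrors the generator's truncation at zero and avoids the funnel
  between the noise scale and the deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from .tree import (
    AGREE_TRAIT,
    EXTREME_ERS,
    EXTREME_TRAIT,
    MISSING,
    MODERATE_MRS,
    ItemParameters,
    PersonParameters,
    ResponseData,
    decompose_responses,
    pointwise_loglik,
)
from .trajectory import LAMBDA_BOUNDS
from ._kernels import HAVE_NUMBA, loglik_grad_kernel

__all__ = ["SlotConfig", "BuiltModel", "build_model", "variant_slots"]


@dataclass(frozen=True)
class _Priors:
    """Internal mirror of the prior hyperparameters (see PriorSpec)."""

    loading_mu: float = 0.0
    loading_sd: float = 2.0
    lam_mu: float = -0.5
    lam_sd: float = 1.0
    cauchy_scale: float = 5.0

_LOG_LO = np.log(LAMBDA_BOUNDS[0])
_LOG_RANGE = np.log(LAMBDA_BOUNDS[1]) - np.log(LAMBDA_BOUNDS[0])

SLOT_KINDS = ("fixed", "constant", "trajectory", "noisy", "free")


@dataclass(frozen=True)
class SlotConfig:
    """How one loading slot is parameterized."""

    kind: str
    value: float = 1.0  # used by kind="fixed"

    def __post_init__(self):
        if self.kind not in SLOT_KINDS:
            raise ValueError(f"unknown slot kind {self.kind!r}")


def variant_slots(
    variant: str, agreement: str = "rasch", has_moderate: bool = False
) -> dict[str, SlotConfig]:
    """Loading-slot table of a named model variant.

    ``agreement`` is "rasch" (unit trait loading on the agreement node) or
    "model" (the agreement node gets the same loading structure as the
    variant's extreme node -- the parameterization with an item-specific
    agreement loading).
    """
    kinds = {
        "ordinal": ("fixed", 1.0, "fixed", 0.0),
        "ers": ("fixed", 0.0, "fixed", 1.0),
        "static": ("constant", None, "constant", None),
        "drsm": ("trajectory", None, "trajectory", None),
        "fdrsm": ("noisy", None, "noisy", None),
        "2pl": ("free", None, "free", None),
    }
    if variant not in kinds:
        raise ValueError(f"unknown variant {variant!r}")
    th_kind, th_val, ers_kind, ers_val = kinds[variant]
    slots = {
        EXTREME_TRAIT: SlotConfig(th_kind, th_val if th_val is not None else 1.0),
        EXTREME_ERS: SlotConfig(ers_kind, ers_val if ers_val is not None else 1.0),
    }
    if agreement == "rasch" or variant in ("ordinal", "ers"):
        slots[AGREE_TRAIT] = SlotConfig("fixed", 1.0)
    elif agreement == "model":
        agree_kind = th_kind if th_kind != "fixed" else "fixed"
        slots[AGREE_TRAIT] = SlotConfig(agree_kind, 1.0)
    else:
        raise ValueError("agreement must be 'rasch' or 'model'")
    if has_moderate:
        if variant == "ordinal":
            slots[MODERATE_MRS] = SlotConfig("fixed", 0.0)
        elif variant == "ers":
            slots[MODERATE_MRS] = SlotConfig("fixed", 1.0)
        else:
            slots[MODERATE_MRS] = slots[EXTREME_ERS]
    return slots


def _half_cauchy_logp_grad(x: float, scale: float) -> tuple[float, float]:
    """log density (up to a constant) and d/dx of half-Cauchy(0, scale)."""
    s2 = scale * scale
    return -np.log1p(x * x / s2), -2.0 * x / (s2 + x * x)


class _Slot:
    """Bookkeeping for one loading slot's free parameters."""

    def __init__(self, name: str, config: SlotConfig, I: int,
                 group_idx: np.ndarray, n_groups: int):
        self.name = name
        self.config = config
        self.I = I
        self.group_idx = group_idx
        self.G = n_groups

    def n_params(self) -> dict[str, int]:
        k = self.config.kind
        if k == "fixed":
            return {}
        if k == "constant":
            return {f"{self.name}.u": self.G}
        if k == "trajectory":
            return {f"{self.name}.u1": self.G, f"{self.name}.uI": self.G,
                    f"{self.name}.v": self.G}
        if k == "noisy":
            return {f"{self.name}.u1": self.G, f"{self.name}.uI": self.G,
                    f"{self.name}.v": self.G, f"{self.name}.log_sigma": 1,
                    f"{self.name}.z": self.I}
        return {f"{self.name}.u": self.I}  # free


class BuiltModel:
    """A variant bound to a data set: flat parameter vector <-> posterior."""

    def __init__(
        self,
        data: ResponseData,
        slots: dict[str, SlotConfig],
        item_dimension: np.ndarray | None = None,
        item_inverted: np.ndarray | None = None,
        item_group: np.ndarray | None = None,
        free_person_sds: tuple[str, ...] = (),
        priors: _Priors | None = None,
        use_kernel: bool | None = None,
    ):
        self.priors = priors if priors is not None else _Priors()
        self.use_kernel = HAVE_NUMBA if use_kernel is None else use_kernel
        tree = data.tree
        self.data = data
        self.tree = tree
        N, I = data.n_persons, data.n_items
        self.N, self.I = N, I

        pseudo = decompose_responses(data)
        j1, j2 = tree.node_index(1), tree.node_index(2)
        self.H = tree.n_nodes
        self.j1, self.j2 = j1, j2
        self.O1 = (pseudo[:, :, j1] != MISSING).astype(float)
        self.O2 = (pseudo[:, :, j2] != MISSING).astype(float)
        self.Y1 = np.where(self.O1 > 0, pseudo[:, :, j1], 0).astype(float)
        self.Y2 = np.where(self.O2 > 0, pseudo[:, :, j2], 0).astype(float)
        self.sgn = np.where(self.O1 > 0, 2.0 * self.Y1 - 1.0, 0.0)
        self.has_moderate = tree.has_moderate_node
        if self.has_moderate:
            j0 = tree.node_index(0)
            self.j0 = j0
            self.O0 = (pseudo[:, :, j0] != MISSING).astype(float)
            self.Y0 = np.where(self.O0 > 0, pseudo[:, :, j0], 0).astype(float)

        self.dim_idx = (np.zeros(I, dtype=np.int64) if item_dimension is None
                        else np.ascontiguousarray(item_dimension, dtype=np.int64))
        self._zeros_I = np.zeros(I)
        self._zeros_N = np.zeros(N)
        self.D = int(self.dim_idx.max()) + 1
        self.Mdim = np.zeros((I, self.D))
        self.Mdim[np.arange(I), self.dim_idx] = 1.0
        self.w = np.where(
            np.zeros(I, dtype=bool) if item_inverted is None else np.asarray(item_inverted, bool),
            -1.0, 1.0,
        )
        if item_group is None:
            gidx, G = np.zeros(I, dtype=int), 1
            self.group_labels = [None]
        else:
            labels, gidx = np.unique(np.asarray(item_group), return_inverse=True)
            G = len(labels)
            self.group_labels = list(labels)
        self.gidx, self.G = gidx, G

        # position variable of the trajectory: (i-1)/(I-1) for i = 1..I
        self.t = np.arange(I) / (I - 1)
        self.tlog = np.where(self.t > 0, np.log(np.maximum(self.t, 1e-300)), 0.0)

        self.slot_configs = dict(slots)
        self.include_eta = slots[EXTREME_ERS].kind != "fixed" or slots[EXTREME_ERS].value != 0.0
        self.include_kappa = self.has_moderate and (
            slots[MODERATE_MRS].kind != "fixed" or slots[MODERATE_MRS].value != 0.0
        )
        self.free_person_sds = tuple(free_person_sds)

        self._slots = {
            name: _Slot(name, cfg, I, gidx, G) for name, cfg in slots.items()
        }

        # flat layout
        layout: dict[str, slice] = {}
        pos = 0

        def add(name: str, n: int):
            nonlocal pos
            layout[name] = slice(pos, pos + n)
            pos += n

        add("theta", N * self.D)
        if self.include_eta:
            add("eta", N)
        if self.include_kappa:
            add("kappa", N)
        for sd_name in self.free_person_sds:
            add(f"log_sd.{sd_name}", 1)
        add("beta", self.H * I)
        add("mu_beta", 1)
        add("log_sigma_beta", 1)
        for name in (MODERATE_MRS, AGREE_TRAIT, EXTREME_TRAIT, EXTREME_ERS):
            if name in self._slots:
                for pname, n in self._slots[name].n_params().items():
                    add(pname, n)
        self.layout = layout
        self.dim = pos

    # ------------------------------------------------------------------
    def _get(self, x: np.ndarray, name: str) -> np.ndarray:
        return x[self.layout[name]]

    def _slot_loadings(self, x: np.ndarray, name: str):
        """Loadings alpha (I,) plus a cache for the backward pass."""
        cfg = self.slot_configs[name]
        if cfg.kind == "fixed":
            return np.full(self.I, cfg.value), None
        if cfg.kind == "constant":
            u = self._get(x, f"{name}.u")
            alpha_g = np.exp(u)
            return alpha_g[self.gidx], {"u": u, "alpha_g": alpha_g}
        if cfg.kind == "free":
            u = self._get(x, f"{name}.u")
            return np.exp(u), {"u": u}
        # trajectory / noisy
        u1 = self._get(x, f"{name}.u1")
        uI = self._get(x, f"{name}.uI")
        v = self._get(x, f"{name}.v")
        g1, gI = np.exp(u1), np.exp(uI)
        sv = expit(v)
        loglam = _LOG_LO + _LOG_RANGE * sv
        lam = np.exp(loglam)
        tpow = self.t ** lam[self.gidx]
        mu = (g1[self.gidx] - gI[self.gidx]) * (1.0 - tpow) + gI[self.gidx]
        cache = {"u1": u1, "uI": uI, "v": v, "g1": g1, "gI": gI,
                 "sv": sv, "loglam": loglam, "lam": lam, "tpow": tpow, "mu": mu}
        if cfg.kind == "trajectory":
            return mu, cache
        z = self._get(x, f"{name}.z")
        sigma = np.exp(self._get(x, f"{name}.log_sigma")[0])
        raw = mu + sigma * z
        cache["z"], cache["sigma"], cache["raw"] = z, sigma, raw
        return np.maximum(raw, 0.0), cache

    def _slot_backward(self, name: str, cache, d_alpha: np.ndarray,
                       grad: np.ndarray, logp_add: list[float]) -> None:
        """Chain-rule d logp/d alpha into the slot's parameters + priors."""
        cfg = self.slot_configs[name]
        L = self.layout
        pr = self.priors
        lmu, ls2 = pr.loading_mu, pr.loading_sd**2
        if cfg.kind == "fixed":
            return
        if cfg.kind == "constant":
            u, alpha_g = cache["u"], cache["alpha_g"]
            du = np.bincount(self.gidx, weights=d_alpha, minlength=self.G) * alpha_g
            du += -(u - lmu) / ls2  # LogNormal loading prior on the log scale
            logp_add.append(float(np.sum(-0.5 * (u - lmu) ** 2 / ls2)))
            grad[L[f"{name}.u"]] += du
            return
        if cfg.kind == "free":
            u = cache["u"]
            du = d_alpha * np.exp(u) - (u - lmu) / ls2
            logp_add.append(float(np.sum(-0.5 * (u - lmu) ** 2 / ls2)))
            grad[L[f"{name}.u"]] += du
            return
        # trajectory core (also the mean curve of the noisy slot)
        if cfg.kind == "noisy":
            # non-centered deviations: alpha_i = max(0, mu_i + sigma * z_i)
            z, sigma, raw = cache["z"], cache["sigma"], cache["raw"]
            pos = (raw > 0.0).astype(float)
            logp_add.append(float(np.sum(-0.5 * z * z)))
            grad[L[f"{name}.z"]] += d_alpha * sigma * pos - z
            d_log_sigma = float(np.sum(d_alpha * z * pos)) * sigma
            hc_lp, hc_g = _half_cauchy_logp_grad(sigma, pr.cauchy_scale)
            logp_add.append(hc_lp + np.log(sigma))  # prior + log-scale Jacobian
            grad[L[f"{name}.log_sigma"]] += d_log_sigma + hc_g * sigma + 1.0
            d_traj = d_alpha * pos
        else:
            d_traj = d_alpha
        u1, uI, v = cache["u1"], cache["uI"], cache["v"]
        g1, gI, lam, tpow = cache["g1"], cache["gI"], cache["lam"], cache["tpow"]
        sv, loglam = cache["sv"], cache["loglam"]
        gx = self.gidx
        d_g1 = np.bincount(gx, weights=d_traj * (1.0 - tpow), minlength=self.G)
        d_gI = np.bincount(gx, weights=d_traj * tpow, minlength=self.G)
        dtpow_dlam = tpow * self.tlog
        d_lam = np.bincount(
            gx, weights=d_traj * (gI[gx] - g1[gx]) * dtpow_dlam, minlength=self.G
        )
        # endpoint priors: LogNormal on the log scale
        logp_add.append(float(
            np.sum(-0.5 * ((u1 - lmu) ** 2 + (uI - lmu) ** 2) / ls2)
        ))
        grad[L[f"{name}.u1"]] += d_g1 * g1 - (u1 - lmu) / ls2
        grad[L[f"{name}.uI"]] += d_gI * gI - (uI - lmu) / ls2
        # shape prior: truncated LogNormal via a scaled logistic transform
        zs = (loglam - pr.lam_mu) / pr.lam_sd
        logp_add.append(float(np.sum(-loglam - 0.5 * zs**2)))
        d_loglam = d_lam * lam + (-1.0 - zs / pr.lam_sd)
        jac = _LOG_RANGE * sv * (1.0 - sv)
        # log Jacobian in a saturation-safe form: log sigmoid(v) + log sigmoid(-v)
        log_jac = np.log(_LOG_RANGE) + log_expit(v) + log_expit(-v)
        logp_add.append(float(np.sum(loglam + log_jac)))
        grad[L[f"{name}.v"]] += d_loglam * jac + jac + (1.0 - 2.0 * sv)

    # ------------------------------------------------------------------
    def _person_vectors(self, x: np.ndarray):
        """theta (N,D), eta, kappa on the likelihood scale plus sd caches."""
        theta = self._get(x, "theta").reshape(self.N, self.D)
        eta = self._get(x, "eta") if self.include_eta else None
        kappa = self._get(x, "kappa") if self.include_kappa else None
        sds = {}
        for sd_name in self.free_person_sds:
            sds[sd_name] = np.exp(self._get(x, f"log_sd.{sd_name}")[0])
        return theta, eta, kappa, sds

    def _likelihood(self, theta, eta, kappa, alphas, beta):
        """(ll, d_theta, d_eta, d_kappa, d_beta, d_alpha) of the data term."""
        if self.use_kernel:
            return self._likelihood_numba(theta, eta, kappa, alphas, beta)
        return self._likelihood_numpy(theta, eta, kappa, alphas, beta)

    def _likelihood_numba(self, theta, eta, kappa, alphas, beta):
        zI = self._zeros_I
        zN = self._zeros_N
        (ll, d_theta, d_eta, d_kappa, d_b1, d_b2, d_b0,
         d_a_at, d_a_et, d_a_ers, d_a_mrs) = loglik_grad_kernel(
            np.ascontiguousarray(theta[:, self.dim_idx] * self.w),
            eta if eta is not None else zN,
            kappa if kappa is not None else zN,
            alphas[AGREE_TRAIT], alphas[EXTREME_TRAIT], alphas[EXTREME_ERS],
            alphas.get(MODERATE_MRS, zI),
            beta[self.j1], beta[self.j2],
            beta[self.j0] if self.has_moderate else zI,
            self.Y1, self.Y2, self.Y0 if self.has_moderate else self.Y1,
            self.O1, self.O2, self.O0 if self.has_moderate else self.O1,
            self.sgn, self.dim_idx, self.w, self.D,
            eta is not None, kappa is not None, self.has_moderate,
        )
        d_beta = np.zeros_like(beta)
        d_beta[self.j1] = d_b1
        d_beta[self.j2] = d_b2
        d_alpha = {AGREE_TRAIT: d_a_at, EXTREME_TRAIT: d_a_et, EXTREME_ERS: d_a_ers}
        if self.has_moderate:
            d_beta[self.j0] = d_b0
            d_alpha[MODERATE_MRS] = d_a_mrs
        return (ll, d_theta,
                d_eta if eta is not None else None,
                d_kappa if kappa is not None else None,
                d_beta, d_alpha)

    def _likelihood_numpy(self, theta, eta, kappa, alphas, beta):
        th_items = theta[:, self.dim_idx] * self.w  # (N, I)
        a_at = alphas[AGREE_TRAIT]
        a_et = alphas[EXTREME_TRAIT]
        a_ers = alphas[EXTREME_ERS]

        lp1 = a_at * th_items - beta[self.j1]
        ll = np.sum(self.O1 * (self.Y1 * lp1 - np.logaddexp(0.0, lp1)))
        r1 = self.O1 * (self.Y1 - expit(lp1))

        z = self.sgn * (a_et * th_items) - beta[self.j2]
        if eta is not None:
            z = z + a_ers * eta[:, None]
        ll += np.sum(self.O2 * (self.Y2 * z - np.logaddexp(0.0, z)))
        r2 = self.O2 * (self.Y2 - expit(z))

        d_beta = np.zeros_like(beta)
        d_beta[self.j1] = -r1.sum(axis=0)
        d_beta[self.j2] = -r2.sum(axis=0)
        d_th_items = r1 * a_at + r2 * self.sgn * a_et
        d_alpha = {
            AGREE_TRAIT: (r1 * th_items).sum(axis=0),
            EXTREME_TRAIT: (r2 * self.sgn * th_items).sum(axis=0),
            EXTREME_ERS: (eta @ r2 if eta is not None else np.zeros(self.I)),
        }
        d_eta = r2 @ a_ers if eta is not None else None

        d_kappa = None
        if self.has_moderate:
            a_mrs = alphas[MODERATE_MRS]
            lp0 = -beta[self.j0] + (a_mrs * kappa[:, None] if kappa is not None else 0.0)
            ll += np.sum(self.O0 * (self.Y0 * lp0 - np.logaddexp(0.0, lp0)))
            r0 = self.O0 * (self.Y0 - expit(lp0))
            d_beta[self.j0] = -r0.sum(axis=0)
            if kappa is not None:
                d_alpha[MODERATE_MRS] = kappa @ r0
                d_kappa = r0 @ a_mrs
            else:
                d_alpha[MODERATE_MRS] = np.zeros(self.I)

        d_theta = (d_th_items * self.w) @ self.Mdim  # (N, D)
        return ll, d_theta, d_eta, d_kappa, d_beta, d_alpha

    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        L = self.layout
        grad = np.zeros(self.dim)
        logp_add: list[float] = []

        theta_raw, eta_raw, kappa_raw, sds = self._person_vectors(x)
        theta = theta_raw.copy()
        for d in range(self.D):
            key = f"theta{d}"
            if key in sds:
                theta[:, d] = theta_raw[:, d] * sds[key]
        eta = eta_raw * sds.get("eta", 1.0) if eta_raw is not None else None
        kappa = kappa_raw * sds.get("kappa", 1.0) if kappa_raw is not None else None

        beta = self._get(x, "beta").reshape(self.H, self.I)
        mu_beta = self._get(x, "mu_beta")[0]
        log_sb = self._get(x, "log_sigma_beta")[0]
        sigma_beta = np.exp(log_sb)

        alphas, caches = {}, {}
        for name in self.slot_configs:
            alphas[name], caches[name] = self._slot_loadings(x, name)

        # ---- likelihood ----
        ll, d_theta, d_eta, d_kappa, d_beta, d_alpha = self._likelihood(
            theta, eta, kappa, alphas, beta
        )
        logp = ll

        # ---- person parameters: standard-normal raw scale ----
        d_theta_raw = d_theta.copy()
        for d in range(self.D):
            key = f"theta{d}"
            if key in sds:
                s = sds[key]
                d_theta_raw[:, d] = d_theta[:, d] * s
                d_log_sd = float(np.sum(d_theta[:, d] * theta_raw[:, d])) * s
                hc_lp, hc_g = _half_cauchy_logp_grad(s, self.priors.cauchy_scale)
                logp_add.append(hc_lp + np.log(s))
                grad[L[f"log_sd.theta{d}"]] += d_log_sd + hc_g * s + 1.0
        grad[L["theta"]] += (d_theta_raw - theta_raw).ravel()
        logp += float(np.sum(-0.5 * theta_raw**2))
        if eta_raw is not None:
            d_eta_raw = d_eta * sds.get("eta", 1.0)
            if "eta" in sds:
                s = sds["eta"]
                hc_lp, hc_g = _half_cauchy_logp_grad(s, self.priors.cauchy_scale)
                logp_add.append(hc_lp + np.log(s))
                grad[L["log_sd.eta"]] += float(np.sum(d_eta * eta_raw)) * s + hc_g * s + 1.0
            grad[L["eta"]] += d_eta_raw - eta_raw
            logp += float(np.sum(-0.5 * eta_raw**2))
        if kappa_raw is not None:
            d_kappa = d_kappa if d_kappa is not None else np.zeros(self.N)
            d_kappa_raw = d_kappa * sds.get("kappa", 1.0)
            if "kappa" in sds:
                s = sds["kappa"]
                hc_lp, hc_g = _half_cauchy_logp_grad(s, self.priors.cauchy_scale)
                logp_add.append(hc_lp + np.log(s))
                grad[L["log_sd.kappa"]] += float(np.sum(d_kappa * kappa_raw)) * s + hc_g * s + 1.0
            grad[L["kappa"]] += d_kappa_raw - kappa_raw
            logp += float(np.sum(-0.5 * kappa_raw**2))

        # ---- difficulties: hierarchical normal prior ----
        resid = beta - mu_beta
        logp += float(np.sum(-0.5 * (resid / sigma_beta) ** 2)) \
            - beta.size * np.log(sigma_beta)
        d_beta += -resid / sigma_beta**2
        grad[L["beta"]] += d_beta.ravel()
        d_mu = float(np.sum(resid)) / sigma_beta**2
        c_lp, c_g = _half_cauchy_logp_grad(mu_beta, self.priors.cauchy_scale)  # Cauchy(0,5), symmetric
        logp_add.append(c_lp)
        grad[L["mu_beta"]] += d_mu + c_g
        d_sb = float(np.sum(resid**2)) / sigma_beta**3 - beta.size / sigma_beta
        hc_lp, hc_g = _half_cauchy_logp_grad(sigma_beta, self.priors.cauchy_scale)
        logp_add.append(hc_lp + log_sb)
        grad[L["log_sigma_beta"]] += (d_sb + hc_g) * sigma_beta + 1.0

        # ---- loading slots ----
        for name in self.slot_configs:
            self._slot_backward(name, caches[name], d_alpha[name], grad, logp_add)

        return logp + sum(logp_add), grad

    def logp(self, x: np.ndarray) -> float:
        return self.logp_and_grad(x)[0]

    # ------------------------------------------------------------------
    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = rng.uniform(-0.5, 0.5, self.dim)
        return x

    def constrain_draw(self, x: np.ndarray):
        """Natural-scale parameters of a single draw."""
        theta_raw, eta_raw, kappa_raw, sds = self._person_vectors(x)
        theta = theta_raw.copy()
        for d in range(self.D):
            if f"theta{d}" in sds:
                theta[:, d] *= sds[f"theta{d}"]
        out = {
            "theta": theta,
            "beta": self._get(x, "beta").reshape(self.H, self.I).copy(),
            "mu_beta": self._get(x, "mu_beta")[0],
            "sigma_beta": float(np.exp(self._get(x, "log_sigma_beta")[0])),
        }
        if eta_raw is not None:
            out["eta"] = eta_raw * sds.get("eta", 1.0)
        if kappa_raw is not None:
            out["kappa"] = kappa_raw * sds.get("kappa", 1.0)
        for name, cfg in self.slot_configs.items():
            alpha, cache = self._slot_loadings(x, name)
            out[f"alpha.{name}"] = alpha
            if cfg.kind in ("trajectory", "noisy"):
                out[f"gamma_first.{name}"] = cache["g1"]
                out[f"gamma_last.{name}"] = cache["gI"]
                out[f"lam.{name}"] = cache["lam"]
                out[f"slope.{name}"] = cache["gI"] - cache["g1"]
            if cfg.kind == "noisy":
                out[f"sigma.{name}"] = cache["sigma"]
        return out

    def person_item_from_draw(self, x: np.ndarray) -> tuple[PersonParameters, ItemParameters]:
        c = self.constrain_draw(x)
        person = PersonParameters(theta=c["theta"], eta=c.get("eta"), kappa=c.get("kappa"))
        loadings = {name: c[f"alpha.{name}"] for name in self.slot_configs}
        item = ItemParameters(
            beta=c["beta"], loadings=loadings, item_dimension=self.dim_idx,
            item_inverted=self.w < 0,
            item_group=None if self.G == 1 else np.asarray(self.group_labels)[self.gidx],
        )
        return person, item

    def pointwise_loglik_draw(self, x: np.ndarray) -> np.ndarray:
        person, item = self.person_item_from_draw(x)
        return pointwise_loglik(self.data, person, item, self.tree)

    def loglik_matrix(self, x: np.ndarray) -> np.ndarray:
        """(N, I) pointwise log-likelihood using the cached decomposition."""
        theta_raw, eta_raw, kappa_raw, sds = self._person_vectors(x)
        theta = theta_raw.copy()
        for d in range(self.D):
            if f"theta{d}" in sds:
                theta[:, d] *= sds[f"theta{d}"]
        eta = eta_raw * sds.get("eta", 1.0) if eta_raw is not None else None
        kappa = kappa_raw * sds.get("kappa", 1.0) if kappa_raw is not None else None
        beta = self._get(x, "beta").reshape(self.H, self.I)
        alphas = {name: self._slot_loadings(x, name)[0] for name in self.slot_configs}

        th_items = theta[:, self.dim_idx] * self.w
        lp1 = alphas[AGREE_TRAIT] * th_items - beta[self.j1]
        ll = self.O1 * (self.Y1 * lp1 - np.logaddexp(0.0, lp1))
        z = self.sgn * (alphas[EXTREME_TRAIT] * th_items) - beta[self.j2]
        if eta is not None:
            z = z + alphas[EXTREME_ERS] * eta[:, None]
        ll += self.O2 * (self.Y2 * z - np.logaddexp(0.0, z))
        if self.has_moderate:
            lp0 = -beta[self.j0]
            if kappa is not None:
                lp0 = lp0 + alphas[MODERATE_MRS] * kappa[:, None]
            else:
                lp0 = np.broadcast_to(lp0, ll.shape)
            ll += self.O0 * (self.Y0 * lp0 - np.logaddexp(0.0, lp0))
        return ll


def build_model(
    data: ResponseData,
    variant: str,
    agreement: str = "rasch",
    item_dimension=None,
    item_inverted=None,
    item_group=None,
    free_person_sds: tuple[str, ...] = (),
    priors: _Priors | None = None,
    use_kernel: bool | None = None,
) -> BuiltModel:
    slots = variant_slots(variant, agreement, has_moderate=data.tree.has_moderate_node)
    return BuiltModel(
        data, slots,
        item_dimension=item_dimension,
        item_inverted=item_inverted,
        item_group=item_group,
        free_person_sds=free_person_sds,
        priors=priors,
        use_kernel=use_kernel,
    )
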