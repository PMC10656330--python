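"""Recovery metrics, model comparison, and the replication harness.

``psis_loo`` reports out-of-sample predictive accuracy on the information
criterion scale (-2 * elpd, smaller is better), approximated by
Pareto-smoothed importance sampling over the person-item pointwise log
likelihood.  ``posthoc_trajectory_fit`` recovers a position trajectory
from freely estimated item loadings (the post-hoc analysis used for the
2PL model, which has no trajectory of its own).  ``replication_study``
regenerates the simulation-study tables -- average LOO, selection
proportions, slope recovery, RMSE -- at a configurable scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .estimators import FitResult, MCMCConfig, make_model
from .simulate import SimulatedDataset, SimulationCondition, simulate_dataset
from .trajectory import LAMBDA_BOUNDS
from .tree import AGREE_TRAIT, EXTREME_ERS, EXTREME_TRAIT, MODERATE_MRS

__all__ = [
    "rmse",
    "psis_loo",
    "ComparisonResult",
    "compare_models",
    "TrajectoryFit",
    "posthoc_trajectory_fit",
    "RecoveryReport",
    "recovery_report",
    "replication_study",
]


def rmse(true_values, estimates) -> float:
    """Root mean square error between a truth vector and its estimates."""
    t = np.asarray(true_values, dtype=float).ravel()
    e = np.asarray(estimates, dtype=float).ravel()
    if t.shape != e.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {e.shape}")
    if t.size == 0:
        raise ValueError("need at least one element")
    return float(np.sqrt(np.mean((t - e) ** 2)))


def psis_loo(fit: FitResult) -> dict:
    """PSIS-LOO of one fit on the information-criterion scale.

    Returns ``loo_ic`` (-2 * elpd_loo, smaller is better), ``elpd``, its
    standard error, and the Pareto-k diagnostics; a high-k fraction above
    0.7 is recorded as a warning.
    """
    if fit.loglik is None:
        raise ValueError("fit was run without pointwise log-likelihood storage")
    idata = az.from_dict(
        posterior={"mu_beta": fit.draws["mu_beta"]},
        log_likelihood={"y": fit.loglik.astype(np.float64)},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    pareto_k = np.asarray(res.pareto_k)
    high_k = float(np.mean(pareto_k > 0.7))
    return {
        "loo_ic": float(-2.0 * res.elpd_loo),
        "elpd": float(res.elpd_loo),
        "se": float(res.se),
        "p_loo": float(res.p_loo),
        "pareto_k": pareto_k,
        "high_k_fraction": high_k,
        "warning": high_k > 0.0,
    }


@dataclass
class ComparisonResult:
    """LOO comparison of several fits of the same data."""

    names: list[str]
    loo_ic: np.ndarray
    elpd_se: np.ndarray
    best_index: int
    best_name: str
    tie: bool
    high_k_fractions: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.names,
                "loo_ic": self.loo_ic,
                "elpd_se": self.elpd_se,
                "high_k_fraction": self.high_k_fractions,
                "selected": [i == self.best_index for i in range(len(self.names))],
            }
        )


def compare_models(fits, names=None) -> ComparisonResult:
    """Select the model with the smallest LOO IC; ties go to the first listed."""
    fits = list(fits)
    if names is None:
        names = [f.variant for f in fits]
    loos = [psis_loo(f) for f in fits]
    ic = np.array([l["loo_ic"] for l in loos])
    best = int(np.argmin(ic))
    tie = bool(np.sum(ic == ic[best]) > 1)
    return ComparisonResult(
        names=list(names),
        loo_ic=ic,
        elpd_se=np.array([l["se"] for l in loos]),
        best_index=best,
        best_name=names[best],
        tie=tie,
        high_k_fractions=np.array([l["high_k_fraction"] for l in loos]),
    )


@dataclass
class TrajectoryFit:
    """Least-squares trajectory through a vector of item loadings."""

    gamma_first: float
    gamma_last: float
    shape: float
    residual_sd: float
    shape_identified: bool

    @property
    def slope(self) -> float:
        return self.gamma_last - self.gamma_first


def posthoc_trajectory_fit(loadings, n_items: int | None = None) -> TrajectoryFit:
    """Fit the position trajectory to item-loading estimates.

    Nonlinear least squares over (gamma_1, gamma_I, lam) with the shape
    bounded to [0.25, 4], multi-started over 8 log-spaced shape values to
    avoid local minima.  For a flat trajectory the shape has no effect on
    the curve, so ``shape_identified`` is False there.
    """
    y = np.asarray(loadings, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a vector of at least three loading values")
    if not np.all(np.isfinite(y)):
        raise ValueError("loadings must be finite")
    I = n_items or y.size
    if I != y.size:
        raise ValueError("n_items must match the number of loadings")
    t = np.arange(I) / (I - 1)
    lo, hi = LAMBDA_BOUNDS

    def resid(p):
        g1, gI, lam = p
        return (g1 - gI) * (1.0 - t**lam) + gI - y

    best = None
    g1_0 = max(y[0], 1e-6)
    gI_0 = max(y[-1], 1e-6)
    for lam0 in np.geomspace(lo, hi, 8):
        sol = least_squares(
            resid, x0=[g1_0, gI_0, lam0],
            bounds=([0.0, 0.0, lo], [np.inf, np.inf, hi]),
        )
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    g1, gI, lam = best.x
    res = resid(best.x)
    dof = max(y.size - 3, 1)
    return TrajectoryFit(
        gamma_first=float(g1),
        gamma_last=float(gI),
        shape=float(lam),
        residual_sd=float(np.sqrt(np.sum(res**2) / dof)),
        shape_identified=bool(abs(gI - g1) > 1e-6),
    )


@dataclass
class RecoveryReport:
    """RMSEs and trajectory summaries of one fit against simulation truth."""

    rmse: dict[str, float]
    slopes: dict[str, dict]  # process slot -> {eap, truth, sd}
    converged: bool


_SLOT_PROCESS = {
    EXTREME_TRAIT: "trait",
    EXTREME_ERS: "ERS",
    AGREE_TRAIT: "agree_trait",
    MODERATE_MRS: "MRS",
}


def recovery_report(fit: FitResult, truth: SimulatedDataset) -> RecoveryReport:
    """Compare a fit's EAPs with the generating parameters."""
    out: dict[str, float] = {}
    person, item = truth.person, truth.item
    out["theta"] = rmse(person.theta, fit.eap("theta"))
    if person.eta is not None and "eta" in fit.draws:
        out["eta"] = rmse(person.eta, fit.eap("eta"))
    if person.kappa is not None and "kappa" in fit.draws:
        out["kappa"] = rmse(person.kappa, fit.eap("kappa"))
    out["beta"] = rmse(item.beta, fit.eap("beta"))
    alpha_t, alpha_e = [], []
    for slot, alpha_true in item.loadings.items():
        key = f"alpha.{slot}"
        if key in fit.draws:
            alpha_t.append(alpha_true)
            alpha_e.append(fit.eap(key))
    out["alpha"] = rmse(np.concatenate(alpha_t), np.concatenate(alpha_e))
    slopes = {}
    for slot, process in _SLOT_PROCESS.items():
        key = f"slope.{slot}"
        if key in fit.draws:
            true_slope = None
            if process in truth.trajectories:
                true_slope = truth.trajectories[process].slope
            slopes[slot] = {
                "eap": float(np.mean(fit.draws[key])),
                "sd": float(np.std(fit.draws[key], ddof=1)),
                "truth": true_slope,
            }
    return RecoveryReport(rmse=out, slopes=slopes, converged=fit.converged)


def _scaled_condition(cond: SimulationCondition, scale: float) -> SimulationCondition:
    if scale >= 1.0:
        return cond
    return replace(
        cond,
        N=max(int(round(cond.N * scale)), 50),
        I=max(int(round(cond.I * scale)), 10),
        n_replications=max(int(round(cond.n_replications * scale)), 1),
    )


def replication_study(
    conditions,
    models_to_fit=("static", "drsm"),
    scale: float = 1.0,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    agreement: str = "rasch",
) -> dict[str, pd.DataFrame]:
    """Fit models to replicate data sets and tabulate per-condition results.

    Returns ``{"summary": ..., "records": ...}``: one summary row per
    condition (average LOO and selection proportion per model, slope
    recovery, mean RMSEs) and one record row per (condition, replication,
    model).  Failed or non-converged fits are kept in the records, flagged,
    and excluded from the averages.
    """
    mcmc = mcmc or MCMCConfig.simulation_preset()
    records = []
    for ci, cond0 in enumerate(conditions):
        cond = _scaled_condition(cond0, scale)
        for rep in range(cond.n_replications):
            sim = simulate_dataset(cond, rep)
            for mi, name in enumerate(models_to_fit):
                ss = np.random.SeedSequence([seed, ci, rep, mi])
                rec = {
                    "condition": cond.label or f"cond{ci}",
                    "variant": cond.variant,
                    "replication": rep,
                    "model": name,
                    "failed": False,
                }
                try:
                    est = make_model(
                        name,
                        n_categories=cond.n_categories,
                        agreement=agreement,
                        chains=mcmc.chains,
                        warmup=mcmc.warmup,
                        draws=mcmc.draws,
                        max_treedepth=mcmc.max_treedepth,
                        target_accept=mcmc.target_accept,
                        random_state=ss,
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est.fit(sim.data)
                    fit = est.result_
                    rep_report = recovery_report(fit, sim)
                    rec["loo_ic"] = psis_loo(fit)["loo_ic"]
                    rec["converged"] = fit.converged
                    rec["max_rhat"] = fit.max_rhat
                    for fam, val in rep_report.rmse.items():
                        rec[f"rmse_{fam}"] = val
                    for slot, s in rep_report.slopes.items():
                        proc = _SLOT_PROCESS[slot]
                        rec[f"slope_eap_{proc}"] = s["eap"]
                        rec[f"slope_sd_{proc}"] = s["sd"]
                        rec[f"slope_truth_{proc}"] = s["truth"]
                except Exception as exc:  # noqa: BLE001 - harness must survive
                    rec["failed"] = True
                    rec["error"] = str(exc)
                records.append(rec)
    rec_df = pd.DataFrame(records)
    summaries = []
    ok = rec_df[~rec_df["failed"]]
    for cond_label, grp in ok.groupby("condition", sort=False):
        row = {"condition": cond_label, "variant": grp["variant"].iloc[0]}
        # strict minimum LOO per replication decides the selected model
        for rep, g in grp.groupby("replication"):
            if g["loo_ic"].notna().all() and len(g) == len(models_to_fit):
                best = g.loc[g["loo_ic"].idxmin(), "model"]
                row[f"n_best_{best}"] = row.get(f"n_best_{best}", 0) + 1
        n_reps = grp["replication"].nunique()
        for name in models_to_fit:
            sub = grp[grp["model"] == name]
            row[f"loo_{name}"] = sub["loo_ic"].mean()
            row[f"prop_best_{name}"] = row.get(f"n_best_{name}", 0) / max(n_reps, 1)
        for col in grp.columns:
            if col.startswith(("slope_", "rmse_")):
                for name in models_to_fit:
                    sub = grp[grp["model"] == name]
                    if sub[col].notna().any():
                        row[f"{col}_{name}"] = sub[col].mean()
        row["n_replications"] = n_reps
        row["n_failed"] = int(rec_df[(rec_df["condition"] == cond_label) & rec_df["failed"]].shape[0])
        summaries.append(row)
    return {"summary": pd.DataFrame(summaries), "records": rec_df}
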