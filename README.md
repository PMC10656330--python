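# drsm — dynamic response strategy models for rating-scale data

Self-report questionnaires measure traits with Likert items, but category
choices are also driven by response styles — stable preferences for the
extreme or middle categories irrespective of content.  Classic IRTree
models separate these processes by decomposing each ordinal response into
binary pseudo-decisions (agree vs. disagree; extreme vs. moderate), each
with its own latent variable, and assume the mix of processes is constant
over the questionnaire.  As respondents fatigue, however, effortful
trait-based responding gives way to heuristic, style-driven responding —
the process mix changes *with item position*.

This package implements IRTree models in which the loadings of the
trait (θ), extreme response style (η), and midpoint response style (κ)
processes follow position trajectories

    α_i = (γ₁ − γ_I) · (1 − ((i−1)/(I−1))^λ) + γ_I,      λ ∈ [0.25, 4],

so that γ₁ and γ_I are the loadings at the first and last item and the
slope γ_I − γ₁ quantifies the total strategy change (the dynamic response
strategy model, DRSM).  A flexible extension (F-DRSM) lets item loadings
scatter around the trajectory with estimated noise SD σ, bridging the gap
to a fully free 2PL parameterization.  The package is aimed at
psychometricians and survey methodologists who want to detect, quantify,
or control for position-dependent response-style effects.

It provides:

* **Estimators** (scikit-learn style): `OrdinalIRTree`, `ERSIRTree`,
  `StaticIRTree`, `DRSM`, `FlexibleDRSM`, `TwoPLIRTree` for four- and
  five-point scales, fitted by the No-U-Turn Sampler with analytic
  gradients, weakly informative priors, split-R̂ convergence checks, and
  PSIS-LOO model comparison (via ArviZ).
* **A simulator** reproducing both simulation-study designs (and custom
  conditions) with exact seed control.
* **Evaluation tools**: RMSE recovery reports, LOO comparison tables,
  post-hoc trajectory fits through free loadings, and a replication
  harness that regenerates the study tables at configurable scale.
* **A CLI**: `drsm simulate | fit | compare | recover | fixture`.

## Worked example

Generate data under the dynamic model — trait influence on extreme
decisions falling from 0.8 to 0.2, ERS influence rising from 0.3 to 0.7
— and fit the DRSM:

```python
import numpy as np
from drsm import DRSM, SimulationCondition, simulate_dataset

cond = SimulationCondition(
    variant="drsm", N=400, I=16,
    trait_trajectory=(0.8, 0.2), ers_trajectory=(0.3, 0.7),
    lam=2.0, base_seed=1001,
)
sim = simulate_dataset(cond, replication_index=0)

est = DRSM(chains=4, warmup=250, draws=250, random_state=7)
est.fit(sim.data)

print("converged:", est.converged_, " max split R-hat:", round(est.max_rhat_, 3))
for slot, tr in est.trajectories_.items():
    lo, hi = tr["slope_ci"].ravel()
    print(f"{slot:14s} slope EAP {float(tr['slope'][0]):+.3f} "
          f"95% CI [{lo:+.3f}, {hi:+.3f}]  shape {float(tr['shape'][0]):.2f}")
```

Output:

```
converged: True  max split R-hat: 1.02
extreme_trait  slope EAP -0.597 95% CI [-0.783, -0.394]  shape 2.22
extreme_ers    slope EAP +0.383 95% CI [+0.086, +0.672]  shape 1.18
```

The trait slope EAP −0.60 recovers the generating change of −0.6 (trait
involvement decays over the questionnaire), the ERS slope +0.38 recovers
the generated +0.4 (style involvement grows), and both 95% intervals
exclude zero — the fitted model detects the strategy change.  The shape
estimates scatter around the generating value 2 toward the prior's
center 1, reflecting that λ carries far more posterior uncertainty than
the endpoints.  `est.theta_`, `est.eta_`, `est.beta_`, and `est.loadings_` hold
the EAPs of persons, difficulties, and per-item loadings;
`drsm.evaluate.psis_loo(est.result_)` gives the LOO information
criterion for model comparison (smaller is better).

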