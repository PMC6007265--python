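# socialpref

Social-preference modelling of costly punishment, with simulated prefrontal
fNIRS.

`socialpref` is a tested re-implementation of a decision-neuroscience
analysis chain for a *norm-compliance task*: an ultimatum-game variant in
which a responder, after receiving a transfer `t ∈ {0, 10, 20, 30, 40, 50}`
out of a 100-point pie (both players also hold a 30-point endowment), may
spend up to 30 endowment points on punishment, each point removing five
points from the proposer. Punishment lets the responder create
*advantageous inequality* (AI, responder ahead), *equality* (E), or
tolerate *disadvantageous inequality* (DI). Because no human data are
redistributable for this design, the package ships a first-class synthetic
cohort generator whose agents hold known ("true") preferences — every
downstream stage is therefore testable against ground truth.

## The models

Nine competing social-utility accounts of responder behavior are fitted to
standardized punishment amounts (behavior) and to standardized hemodynamic
responses (neural data), where `X_r`, `X_p` are the post-punishment payoffs
of responder and proposer:

| id | utility |
|---|---|
| `FS_unconstrained` | `P·X_r − α·max(X_p−X_r, 0) − β·max(X_r−X_p, 0)` |
| `FS_standard` | as above with `α ≥ β`, `0 ≤ β < 1` |
| `TotalReward` | `P·(X_r + X_p)` |
| `RewardDifference` | `P·(X_r − X_p)` |
| `ProposerReward` | `P·X_p` |
| `LinearCombination` | `P₁·X_r + P₂·X_p` |
| `CharnessRabin` | `(ρr + σs + θq)·X_p + (1 − ρr − σs − θq)·X_r` |
| `FS_RT` | unconstrained Fehr–Schmidt `− P_RT·RT` |
| `RT_only` | `− P_RT·RT` |

`α` weights aversion to DI, `β` aversion to AI (`β < 0` = AI *seeking*);
the Charness–Rabin indicators are `r = 1` in AI, `s = 1` in DI and `q = −1`
when the proposer misbehaved (any transfer below 50). The RT term treats
response time as a proxy for choice difficulty.

Around the models, the package provides: modified Beer–Lambert conversion
of two-wavelength (760/850 nm) optical densities to O₂Hb/HHb/tHb with
detrending, 60-s baseline correction and 2.5-s/180-ms sliding-window
extraction; multi-start nonlinear least squares (behavior) and fair-weight
robust regression (neural); AIC/MSE model comparison with a uniform null
model and nested F-tests; percentage-bend correlations, Fisher r-to-z
comparison, factorial ANOVA; and linear-SVR prediction of the behavioral
utility series from dlPFC vs dmPFC responses.

## Worked example

```python
import dataclasses
from socialpref import (BEHAVIORAL_MODELS, CohortConfig, FitOptions,
                        compare_models, fit_behavior, simulate_cohort)

cc = dataclasses.replace(CohortConfig(), n_participants=8, with_optics=False)
data = simulate_cohort(cc, seed=42)
fits = [fit_behavior(data.participant_trials(pid), mid, FitOptions(),
                     participant_id=pid)
        for pid in range(8) for mid in BEHAVIORAL_MODELS]
comp = compare_models(fits)
print(comp.mean_aic.sort_values())
```

prints (mean AIC per model, lower = better):

```
FS_RT               -206.35
FS_unconstrained    -109.55
LinearCombination   -106.01
FS_standard          -98.94
RewardDifference     -98.12
ProposerReward       -57.06
TotalReward          -43.07
RT_only              -33.52
CharnessRabin        406.79
```

The RT-enhanced unconstrained Fehr–Schmidt model (`FS_RT`) — the cohort's
generating model — wins by a wide margin; the constrained `FS_standard`
cannot express the agents' AI-seeking (`β < 0`) and fits worse than its
unconstrained counterpart; `CharnessRabin` is penalized by its fixed
payoff-scale offset against a standardized dependent variable. A nested
F-test of `FS_RT` against `FS_unconstrained` on participant 0 gives
`F(1,56) = 591.9, p = 1.9e-31`: response times carry punishment information
beyond the payoff terms.

The full chain — simulate → preprocess → fit → compare → correlate →
predict — is one call (`run_pipeline`) or one command:

```bash
socialpref run-all --seed 1 --n-participants 8 --out run1
```

The `examples/` directory holds one short narrative script per capability.

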