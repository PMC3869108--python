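# primsel — Bayesian model selection for movement-primitive extraction

Motor-control researchers routinely decompose multi-joint kinematic or
muscle recordings into a small number of *movement primitives*: source time
courses `S` combined by weights `W`, optionally entering each trial with a
per-trial delay.  Which decomposition model to use (PCA-like, ICA-like,
delayed/anechoic), how many sources to keep and how smooth the sources
should be are usually decided heuristically.  `primsel` makes these choices
by Bayesian model comparison.

## The models and the criterion

Observed signals `X` (J trials × T time points) are modelled as

    X = W S + ε                      pPCA / ICA / SIM   (instantaneous)
    X_jt = Σ_i W_ji S_i(t − τ_ji) + ε_jt       AMM      (anechoic)

with i.i.d. Gaussian noise ε ~ N(0, σ_n²).  The four families differ only
in their priors: pPCA uses i.i.d. Gaussian sources; ICA tilts the Gaussian
by a contrast term `λ·log cosh(s−μ)`; SIM draws each source row from a
Gaussian process with the wave kernel `k(t,t′) = σ² sinc(2 f₀|t−t′|)`
(band-limited to cutoff f₀); AMM adds per-(trial, source) delays with an
exponential prior of mean γ.

Each candidate model M = (family, I, f₀) is fitted by MAP with
empirical-Bayes hyperparameter updates, and its evidence is approximated by
a Laplace expansion at the optimum Θ*:

    LAP = log p(X|Θ*,Φ,M) + log p(Θ*|Φ,M) + (F/2)·log 2π − ½·log|H|

where `H` is the Hessian of the negative log joint and `F = dim(Θ)`.
Larger LAP is better.  LAP is compared against BIC and AIC, which see only
the parameter count and therefore cannot credit *soft* constraints such as
temporal smoothness.  A synthetic ground-truth benchmark (band-limited
sources, uniform weights, exponential delays, signal-dependent noise
calibrated to a target 1−R²) quantifies how well each criterion recovers
the generating family, the source count and the smoothness cutoff.

## Worked example

```python
import numpy as np
from primsel import FitOptions, ModelSpec, fit_model
from primsel.selection import select_model
from primsel.synthetic_data import make_dataset

# two band-limited (5 Hz) sources, 10 trials, noise level 1-R^2 = 0.15
ds = make_dataset("sim", I_true=2, cutoff_hz=5.0, noise_level=0.15,
                  J=10, seed=42)

res = select_model(ds.X_noisy, families=("ppca", "sim"), I_range=(2,),
                   f0_grid=(3.0, 5.0, 7.0, 10.0, np.inf),
                   opts=FitOptions())
print(res.to_frame()[["family", "f0_hz", "lap", "bic"]])
print("LAP winner:", res.winner_lap.label)
print("BIC winner:", res.winner_bic.label)
```

Output:

```
  family  f0_hz          lap          bic
0   ppca    inf -1821.754718  4083.137997
1    sim    3.0 -2014.221129  4977.883032
2    sim    5.0 -1604.197806  4443.767121
3    sim    7.0 -1619.210735  4435.378438
4    sim   10.0 -1641.578116  4418.671723
LAP winner: sim(I=2, f0=5)
BIC winner: ppca(I=2, f0=inf)
```

LAP peaks at the generating cutoff (5 Hz) and correctly identifies the
smooth instantaneous mixture; BIC prefers plain pPCA because the smoothness
prior lowers the attainable likelihood without changing the parameter
count — exactly the failure mode the LAP criterion is designed to repair.

A command-line interface wraps the same functionality:

```sh
primsel select signals.csv --config experiment.yaml --out results/
primsel generate --config experiment.yaml --out benchmark/
primsel replicate-table3 --seed 1 --out results/
```

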