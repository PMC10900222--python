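# allokin

Energetic and dynamical dissection of a catalyzed torsional isomerization
rate, built around the peptidyl-prolyl *cis–trans* isomerization catalyzed
by the enzyme Pin1.

## The problem

The rate of a diffusive barrier crossing along a 1-D reaction coordinate
ω (here the prolyl amide torsion: *trans* ≈ 180°, *cis* ≈ 0°, transition
state ≈ 90°) is set jointly by an energetic factor — the activation free
energy ΔG‡ — and a dynamical factor — the effective diffusion coefficient
D_eff along ω.  In the overdamped limit of Kramers' theory,

    k = (ω₀ ω_b / 2π) · β · D_eff · exp(−β ΔG‡),

with ω₀, ω_b the square-rooted curvatures of the reactant well and of the
barrier on the free-energy profile A(ω) and β = 1/k_BT.  Allosteric
effectors can shift either factor; separating them requires A(ω), measured
rates at several (scaled-down) barrier heights, and a fixed-slope
regression of ln(k/ω₀ω_b) on ΔG‡ whose intercept yields D_eff.

`allokin` implements this full analysis chain as a reusable, tested
library:

| stage | module |
| --- | --- |
| Brownian (overdamped) torsion dynamics with known ground truth: umbrella windows, escape replicas, pseudo-structure ensembles with a planted collective mode | `allokin.synthetic_data` |
| WHAM free-energy profiles with Monte Carlo bootstrap errors, well/transition-state location, barrier heights and curvatures | `allokin.free_energy` |
| extrapolation of profiles measured at scaled barrier amplitudes α·V₂ to the unscaled potential (first-order cumulant regression of A(ω;α) on 1−α) | `allokin.alpha_extrapolation` |
| first-passage detection, Kaplan–Meier survival with exponential-Greenwood CIs, CI-weighted exponential rate fits | `allokin.kinetics` |
| fixed-slope Kramers regression → D_eff, rate extrapolation to the full barrier, first-order error propagation | `allokin.kramers` |
| multiensemble PCA (functional PC) and PLS functional mode analysis with cross-validated component count | `allokin.functional_modes` |
| per-system summary tables, comparative deltas and fold changes | `allokin.report_cli` |
| quadrature / finite-difference oracles (Boltzmann profiles, mean first-passage times) | `allokin.theory` |
| seeded end-to-end desk experiments | `allokin.pipelines` |

## Worked example

Recover the diffusion coefficient of a synthetic torsional double well
from rates measured at three reduced barriers (4, 5, 6 kcal/mol on a
V₂ = 12 kcal/mol well, D_true = 10⁸ deg²/s):

```python
from allokin.pipelines import kramers_recovery_experiment

res = kramers_recovery_experiment(seed=1)
print(f"D_eff = {res['d_eff'].value:.3g} ± {res['d_eff'].sd:.2g} deg^2/s")
print(f"D_eff / D_true = {res['d_ratio']:.3f}")
print(f"k(V2=12) extrapolated = {res['k_extrapolated'].value:.3g} 1/s"
      f"  (oracle {res['k_oracle']:.3g} 1/s)")
```

prints (seed 1)

```
D_eff = 6.93e+07 ± 1.2e+07 deg^2/s
D_eff / D_true = 0.693
k(V2=12) extrapolated = 0.000195 1/s  (oracle 0.000344 1/s)
```

i.e. the pipeline — umbrella sampling → WHAM → survival kinetics →
fixed-slope regression — recovers the generator's diffusion coefficient
to within ~30% and predicts the unsampleably slow full-barrier rate
within a factor of two of the exact mean-first-passage-time solution.

Comparative reporting over the six reference Pin1 systems reproduces the
published allosteric effects, e.g.:

```python
from allokin.pipelines import comparative_report
rep = comparative_report()
c = rep["ww_addition_deff_fold"]
print(c.value, "->", c.rounded)   # 3.006... -> 3.0  (WW domain enhances D_eff ~3-fold)
```

A `allokin` console command exposes each stage
(`simulate`, `wham`, `extrapolate`, `kinetics`, `kramers`, `modes`,
`report`); see `allokin --help`.

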