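# spherekin

Release-kinetics toolkit for drug-loaded polymer microspheres. It answers a
routine question in controlled-release formulation work: given a cumulative
in-vitro release curve for drug-loaded PLGA/PLA microspheres, what effective
diffusion coefficient *D*<sub>eff</sub> inside the polymer matrix and what
external mass-transfer coefficient *h* (the boundary layer, including any
surrounding hydrogel) explain it?

## Model

Cumulative fractional release from a sphere of radius *R* with internal
diffusivity *D*<sub>eff</sub> and a surface film characterised by *h* follows
the non-steady-state Fickian series

```
M_t/M_inf = 1 - Σ_n  6 L² / (β_n² (β_n² + L² - L)) · exp(-β_n² D_eff t / R²)
```

where `L = h R / D_eff` is the mass-transfer Biot number and the eigenvalues
β<sub>n</sub> are the positive roots of

```
β cot β + L - 1 = 0 .
```

For large *L* (diffusion-controlled release) the roots approach nπ and the
series reduces to the classical film-free form
`1 - (6/π²) Σ exp(-n²π² D_eff t / R²)/n²`. Parameters are estimated per
curve by minimising the residual sum of squares with a genetic algorithm in
log₁₀ space plus a Nelder–Mead polish; replicates are aggregated to
mean ± SD with an *R*² (%) per fit, and the fitter flags *h* when the data
cannot identify it (large-*L* regimes).

The package also provides the gravimetric formulas used to characterise the
hydrogel carrier — mass loss `(W0 − Wd)/W0 × 100` and water uptake
`(Ww − Wd)/Wd × 100` — plus release-profile descriptors (24-h burst
fraction, phase release rate in amount/day), a synthetic-data generator with
known ground truth, a strict CSV dialect, and a CLI.

## Worked example

Simulate the slow aqueous-medium regime (*D*<sub>eff</sub> = 5.58·10⁻¹⁶ m²/s,
*h* = 4.01·10⁻¹⁰ m/s, *R* = 50.7 µm, so *L* ≈ 36) and refit it:

```
$ spherekin simulate --deff 5.58e-16 --h 4.01e-10 --times 1,7,14,28
# D_eff = 5.58e-16 m^2/s, h = 4.01e-10 m/s, R = 5.07e-05 m, L = 36.43
time_day,fraction_released
1,0.352969
7,0.806249
14,0.943470
28,0.995130

$ spherekin synth --scenario sls --seed 3 --replicates 2 --noise-sd 0 --out sls.csv
$ spherekin fit --in sls.csv --seed 1 --out report.json
# spherekin 0.1.0 fit: sls.csv  (R = 5.07e-05 m, seed = 1)
condition	D_eff (m^2/s)	h (m/s)	R^2 (%)
sls	5.58e-16 ± 6.16e-25	4.01e-10 ± 2.34e-18	100.00 ± 0
```

The fit recovers the generating constants to numerical precision on
noise-free data (the ± column is the SD across replicate fits). `report.json`
carries the per-replicate estimates, RSS, *R*² and identifiability flags,
along with the seed, bounds, radius and model variant needed to reproduce
the run. The same workflow applies to laboratory data: put the measurements
in the CSV dialect (`condition,replicate,time,time_unit,value,kind,dose`)
and run `spherekin fit`.

In Python:

```python
from spherekin import ModelParams, solve_eigenvalues, fractional_release

params = ModelParams(d_eff=5.58e-16, h=4.01e-10, radius=50.7e-6)
print(params.biot)                       # 36.43
print(solve_eigenvalues(params.biot, 3).roots)   # [3.056, 6.112, 9.172]
print(fractional_release(params, [86400.0]))     # [0.353] after one day
```

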