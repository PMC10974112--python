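# rheomelt

Melt viscosity governs whether a drug/polymer formulation can be mixed,
extruded, 3D-printed or melt-coated at all, and at what energy cost. This
package implements a unified melt-viscosity model for binary drug/polymer
mixtures and the full analysis pipeline around it: simulating rheometry
sweeps, building time–temperature-superposition master curves, fitting all
model parameters with replicate statistics, separating the plasticizing and
filler effects of a drug, and extracting the drug-in-polymer solubility line
from rheology alone. It is aimed at formulation scientists and process
engineers working on amorphous solid dispersions and other melt-based
pharmaceutical processes.

## The model

Shear thinning of the polymer melt follows the Carreau model,

    η(γ̇) = η₀ / (1 + γ̇/γ̇_c)^c

with zero-shear-rate viscosity η₀ (the low-rate plateau), critical shear
rate γ̇_c (onset of thinning) and flow index c (negative log-log slope of
the thinning branch). Temperature enters through time–temperature
superposition with an Arrhenius shift factor

    a_T(T, T_ref) = η₀(T)/η₀(T_ref) = exp[(E_A/R)(1/T − 1/T_ref)]   (T in K)

and drug content through a *drug shift factor* built on the log-linear
liquid–liquid mixing rule: for a fully dissolved (single-phase) drug

    a_drug(w) = exp(w · s_plast),    s_plast = ln(η_drug/η_polymer) < 0,

while for a partially dissolved drug with dissolved-limit fraction w_s(T)

    a_drug(w, w_s) = exp[w_s · s_plast + (w − w_s) · s_filler],

where s_filler > 0 quantifies the suspension (filler) effect of the
undissolved solid. Both shift factors rescale the effective shear rate in
the global model

    η(γ̇, T, w) = η₀ · a_T · a_drug / (1 + γ̇ · a_T · a_drug / γ̇_c)^c .

Inverting the two-phase factor turns temperature-resolved drug shift
factors of an opaque (two-phase) melt into the solubility line:

    w_s = (ln a_drug − w · s_filler) / (s_plast − s_filler).

Six parameters (η₀, γ̇_c, c, E_A, s_plast, s_filler) plus a tabulated
solubility curve describe viscosity across shear rate, temperature, drug
load and phase state.

## Worked example

Simulate a plasticized drug/polymer series (triplicate 0.628–628 rad/s
sweeps, 130–200 °C, 2 % multiplicative noise) and run the whole pipeline:

```python
from rheomelt import *
from rheomelt.io import RunConfig, run_pipeline, write_curves

polymer = CarreauArrheniusParams.from_values(5146, 2.5, 0.363, 130846, 160.0)
drug = DrugShiftParams(s_plast=-6.0)
design = SweepDesign(noise_sigma=0.02, seed=11)
curves = generate_mixture_series(design, polymer, drug, None,
                                 [0.0, 0.1, 0.2], system="SOL")
write_curves(curves, "curves.csv", seed=11)
print(run_pipeline(RunConfig(curves="curves.csv", outdir="out", seed=11)))
```

which prints (abridged):

```
Carreau-Arrhenius parameters (mean ± sd over replicates):
  drug fraction 0:
    eta0     = 5153.32 ± 2.9  (pooled 5153.34)
    gamma_c  = 2.51071 ± 0.0229  (pooled 2.51058)
    c        = 0.363735 ± 0.000921  (pooled 0.363734)
    EA       = 130913 ± 164  (pooled 130913)
  drug fraction 0.1:
    eta0     = 2825.3 ± 10.9  (pooled 2825.27)
    ...
    eta0 vs pure polymer: t=-356, p=1.86e-06 -> significant at alpha=0.05

Drug shift factors (pooled over temperature):
  w=0.1: a_drug=0.5482
  w=0.2: a_drug=0.301

plasticizing slope s_plast = -6.005 ± 0.00271 (n=2, 0 opaque excluded)
```

The fitted pure-polymer parameters land on the generating values within the
noise (η₀ 5153 vs 5146, E_A 130913 vs 130846); the mixture's zero-shear
viscosity drops by the factor e^(w·s_plast) (0.5482 ≈ e^−0.6), the drop is
statistically significant at α = 0.05, and the through-origin regression
recovers the plasticizing slope −6.

The same stages are available as a CLI:

```
rheomelt simulate --design design.json --params params.json --out curves.csv
rheomelt fit --curves curves.csv --tref 160 --out params.json
rheomelt shift | slope | solubility | predict | mastercurve | run ...
```

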