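# Methods

## Model and assumptions

The package models the melt viscosity of a binary drug/polymer mixture as a
Carreau shear-thinning law whose effective shear rate is rescaled by two
multiplicative shift factors — an Arrhenius factor for temperature and a
drug shift factor for composition:

    η(γ̇, T, w) = η₀ a / (1 + γ̇ a / γ̇_c)^c ,   a = a_T(T) · a_drug(w).

The underlying assumptions, in decreasing order of importance:

* **Cox–Merz equivalence.** Oscillatory complex viscosity η*(ω) and
  rotational dynamic viscosity η(γ̇) are identified one-to-one (ω ↔ γ̇).
  The package treats both measurement modes on a single rate axis and
  provides `cox_merz_deviation` to check the assumption on paired sweeps
  (median relative deviation over the overlapping range, oscillatory curve
  interpolated in log-log space).
* **Thermorheological simplicity, far from T_g.** A single Arrhenius
  activation energy shifts all rates; ln a_T is linear in 1/T_K. This holds
  for melts measured well above the glass transition; near T_g a
  Williams–Landel–Ferry description would be needed and is out of scope.
* **Log-linear mixing.** The dissolved drug acts like a low-viscosity
  liquid mixed log-linearly by weight fraction, giving
  a_drug = exp(w·s_plast) with s_plast = ln(η_drug/η_polymer); the
  suspended (undissolved) drug raises ln a_drug linearly with slope
  s_filler, assumed drug-independent. Both linearities are low-fraction
  approximations (loads ≤ 30 wt% in practice); curvature of ln a_drug in w,
  which some drug/polymer pairs show, is deliberately not modeled — the
  linear slope is reported together with residual diagnostics.
* **Equilibrated phase split.** In the two-phase factor
  a_drug = exp[w_s s_plast + (w−w_s) s_filler] the dissolved fraction w_s
  is taken from an equilibrium solubility line; slow dissolution in highly
  viscous melts biases rheology-derived w_s at low temperatures and no
  kinetic correction is attempted.

Temperatures are °C at every interface (converted to Kelvin only inside the
Arrhenius expression); `E_A` is a bare numeric parameter that only appears
in the ratio E_A/R with R = 8.314 J·mol⁻¹·K⁻¹, so its effective unit is
J·mol⁻¹ regardless of how a source labels it. The filler slope is fitted on
weight fraction even though classical suspension models use volume
fraction; at the small density contrasts and loads involved the distinction
is absorbed into s_filler itself (a density-based conversion hook is left
unimplemented).

## Parameters

| parameter | meaning | unit | default / bounds |
|---|---|---|---|
| η₀ | zero-shear-rate viscosity at T_ref | Pa·s | fit bounds [10⁻¹, 10⁸] |
| γ̇_c | critical shear rate (thinning onset) | s⁻¹ | fit bounds [10⁻³, 10⁴] |
| c | flow index (thinning slope) | – | fit bounds (0, 1) |
| E_A | activation-energy parameter (as E_A/R) | J·mol⁻¹ | fit bounds [10³, 10⁶] |
| T_ref | reference temperature | °C | 160 |
| s_plast | plasticizing slope of ln a_drug on w | – | fitted; < 0 for plasticizers |
| s_filler | filler slope of ln a_drug on w | – | fitted; > 0 |
| w_ref | reference drug fraction | – | fixed 0 |

## Estimation procedure

1. **Master curve.** Sweeps are shifted to T_ref along lines of constant
   shear stress: (γ̇, η) → (γ̇a, η/a), which preserves γ̇·η exactly. Shift
   factors are estimated per temperature by minimizing the squared
   log-viscosity distance to the reference-temperature curve over the
   overlapping reduced-rate range (linear interpolation in log-log space; a
   coarse grid over ln a ∈ [−20, 20] locates the finite-overlap region
   before local refinement). If no sweep sits exactly at T_ref the nearest
   temperature serves as reference, with a warning. The mean per-point
   misfit is used so overlap size does not bias the optimum.
2. **Simultaneous fit.** (η₀, γ̇_c, c, E_A) are fitted by constrained
   least squares on log10 viscosity over all points of all temperatures
   (`scipy.optimize.least_squares`, trust-region reflective, box bounds
   above, internal parameterization ln η₀ / ln γ̇_c / c / ln E_A for
   conditioning). Initialization is graphical: η₀ from the reduced-curve
   plateau, c = 0.4, γ̇_c where the reduced viscosity first falls below
   η₀/2^0.4, E_A from the Arrhenius regression of the step-1 shift
   factors; three seeded, jittered restarts guard against local minima.
   Each replicate is fitted separately and summarized as mean ± sd
   (matching how replicate scatter is reported in practice); a pooled fit
   over all points is reported alongside. Equal point weights in log10
   space weight every decade of rate and viscosity equally.
3. **Drug shift factors.** With the pure-polymer parameters fixed, each
   drug-loaded curve group leaves a single free scalar (the drug shift
   factor multiplying a_T); it is fitted by 1-D least squares in log10
   viscosity, either pooled over temperatures (single-phase mode) or per
   temperature (two-phase, temperature-resolved mode). The slope of
   ln a_drug on w is a through-origin regression — a_drug(0) = 1 by
   construction of the reference — with opaque-flagged (suspected
   two-phase) observations excluded and counted.
4. **Solubility extraction.** For an opaque load w the temperature-resolved
   shift factor is inverted algebraically,
   w_s = (ln a_drug − w·s_filler)/(s_plast − s_filler), clamped to
   [0, w], with out-of-range inputs logged. Geometrically this intersects
   the filler line, translated through the observed shift factor, with the
   plasticizing line. The inversion degenerates when s_plast = s_filler
   (parallel lines) and raises.
5. **Prediction.** A user-supplied solubility table (strictly increasing
   temperatures, non-decreasing w_s, piecewise-linear, extrapolation
   refused because phase boundaries bend sharply near T_g) closes the loop:
   w_s(T) feeds the two-phase factor and the global model predicts the
   viscosity of partially dissolved melts. The prediction is continuous in
   temperature across the full-dissolution boundary because the two-phase
   factor merges into the single-phase one as w_s → w.

Zero-shear viscosities of two fits are compared with Welch's
unequal-variance t-test on the replicate η₀ values (default α = 0.05); two
identical degenerate replicate sets are defined as statistic 0, p = 1.

## Synthetic data

The generator emulates plate–plate melt rheometry of pharmaceutical
polymers: oscillatory frequency sweeps over 0.628–628 rad/s at 10
log-spaced points per decade, temperatures 130–200 °C in 10 K steps,
T_ref = 160 °C, three replicates; rotational sweeps cover 0.1–100 s⁻¹ but
are truncated at 10 s⁻¹, where gap emptying ends the usable range. Noise is
multiplicative log-normal with σ = 0.02 by default — replicate scatter on
published log-log flow curves is barely visible, implying a small constant
relative error — applied independently per point and replicate,
deterministic given the seed. Default generating parameter sets follow
published Carreau–Arrhenius fits of three common carriers (a butylated
methacrylate copolymer, a polyvinyl caprolactam–polyvinyl acetate–PEG graft
copolymer, and copovidone). The default two-phase scenario uses
s_plast = −6 and s_filler = +4 with a dissolved-limit line rising from
10 wt% at 130 °C to 35 wt% at 200 °C, magnitudes typical of a
griseofulvin-in-Soluplus melt with an inorganic-filler reference line.

What the generator does **not** emulate: instrument compliance and inertia,
temperature drift or measurement error, thermal degradation, amplitude
dependence (all sweeps are assumed within the linear viscoelastic region;
the 1 % strain amplitude is metadata only), nonlinear ln a_drug(w) trends,
and dissolution kinetics. Passing round-trip tests therefore demonstrates
the estimators' correctness and noise robustness under the model's own
assumptions, not robustness to real-instrument artifacts.

## Numerical choices

* Fit objective: log10 viscosity, equal weights; rms log residual reported.
* Optimizer tolerances 10⁻¹⁴ (xtol/ftol/gtol); shift-factor refinement
  xatol 10⁻¹⁰. Noise-free round trips recover generating parameters to
  ≈10⁻⁸ relative.
* Shift-factor search range ln a ∈ [−20, 20] (a ∈ [2·10⁻⁹, 5·10⁸]); curves
  whose rate ranges cannot overlap anywhere in that range raise an error
  naming the offending temperature.
* w_s is clamped to w_drug wherever both appear (dissolved drug cannot
  exceed total drug); solubility inversion results are clamped to [0, w].
* Degenerate inputs: single-temperature data raise an identifiability error
  for E_A; all-opaque or all-zero-fraction observation sets raise in the
  slope regression; bound-hitting fit solutions log a warning.
* Problem sizes: default campaigns are 31-point sweeps × 8 temperatures × 3
  replicates (744 points per system), which one constrained fit handles in
  well under a second; the full two-phase pipeline (pure fit, two slope
  series, temperature-resolved shifts) runs in a few seconds.

## Known limitations

* Replicate sd is the only uncertainty measure; no bootstrap or profile
  likelihood, and no covariance-based errors from the optimizer.
* The solubility line is an input, never fitted: no Flory–Huggins, PC-SAFT
  or similar phase modeling.
* Single Arrhenius activation energy (no WLF), single Carreau form (no
  Cross, power-law or Carreau–Yasuda alternatives), no vertical shift
  factors, no storage/loss modulus decomposition.
* The filler slope is treated as drug-independent and linear in weight
  fraction; dense suspensions (≳30 v%) violate both assumptions.
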