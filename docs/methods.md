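# Methods

This note records the models implemented in `twosite`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data tests
do and do not demonstrate about experimental data.

## Two-site exchange and the dispersion model

The core object is a spin exchanging between a major conformation *a* and a
minor conformation *b*. The model assumes: (i) exactly two sites; (ii) equal
intrinsic transverse rates in both sites (one R2,0 per peak per condition —
the dispersion data cannot separate the minor state's intrinsic rate from
exchange at p_b < 0.15); (iii) in-phase single-quantum magnetization with
ideal, instantaneous refocusing pulses. Off-resonance pulse effects,
finite pulse widths, three-site schemes and multiple-quantum dispersion are
out of scope.

`carver_richards_r2eff` implements the equal-rate Carver–Richards closed
form. `bloch_mcconnell_r2eff` propagates the 2×2 complex evolution matrix
(exchange + intrinsic relaxation + inter-state offset, state *a* on
resonance) through the explicit echo train, with each 180° pulse applied as
complex conjugation and n = round(ν_CPMG·T_relax) blocks of two δ–180–δ
echoes, δ = T_relax/(4n). Non-integer ν_CPMG·T_relax is rounded with a
warning; experimental grids are built from integer pulse counts anyway.

The propagator reports the *rate* of signal decay measured over a second
identical echo train, −ln(S(2T)/S(T))/T. The first train's signal also
contains a transient from the equilibration of the two magnetization modes;
measuring across a second train cancels it exactly, which makes the result
independent of T_relax at fixed ν_CPMG. With this convention the closed
form agrees with the numerical propagation to ~1e−12 across the fitted
parameter box (k_ex 10³–10⁴ s⁻¹, p_b 0.05–0.12, Δω 0.5–5 ppm, 600/800 MHz):
the closed form is the exact dominant-eigenvalue rate of the cycle
propagator, and its only approximation is treating the transient amplitude
as unity. Had the single-train quantity −ln(S(T)/S(0))/T been used instead,
the comparison would degrade to ~3% in the deep slow-exchange corner — that
discrepancy is the transient, not an error in either evaluator.

Numerical safeguards: the arccosh argument is clamped at 1 (with a warning
beyond floating-point cancellation) so optimizer objectives stay finite,
and for η₊ beyond cosh overflow (~ν_CPMG → 0) the identity
arccosh(D₊ cosh η) → η + ln D₊ is used.

ppm→rad/s conversion uses Larmor frequencies derived from the nominal ¹H
field through the gyromagnetic ratios |γ_N/γ_H| = 0.10136767 and
|γ_C/γ_H| = 0.25145002, fixed in `twosite.constants`. Δω is fitted and
stored as a magnitude: CPMG dispersion is insensitive to its sign, so
comparisons against phosphorylation-induced shift changes must use
absolute values.

## Thermodynamic tying and temperature analysis

k_ex(T) follows the Eyring equation with transmission coefficient 1 (the
universal default; nothing in the data constrains it) and p_b(T) the
reaction isotherm. Both free energies are treated as temperature
independent over the 5–20 °C window, i.e. constant activation heat
capacity; this is what justifies replacing per-temperature (k_ex, p_b, Δω)
triplets by (Δ‡G, ΔG, per-peak Δω) — 7 parameters instead of 28 for five
peaks at four temperatures. Constants: R = 8.31446 J/(mol·K), 2019-SI exact
k_B and h, °C→K offset 273.15 exactly. Energies are J/mol internally; kJ
only at presentation.

`eyring_fit` and `vant_hoff_fit` are unweighted ordinary least squares on
the linearized forms ln(k·h/(k_B·T)) vs 1/T and ln(p_b/(1−p_b)) vs 1/T,
with uncertainties from the regression covariance. Unweighted OLS was
chosen because per-temperature rate uncertainties are rarely homogeneous
enough to justify a specific weighting and the printed-rate regressions
this package is checked against carry no weights. Note that a rate table
derived from a single temperature-independent Δ‡G regresses to ΔS‡ ≈ 0 by
construction; a fitted |ΔS‡| of a few J/(K·mol) on real data is therefore
within the model's own resolution.

## The global fit

`fit_global` minimizes χ² = Σ[(R2eff_obs − R2eff_model)/σ]² over
(Δ‡G, ΔG, |Δω| per peak) with scipy's bounded trust-region least squares.
Points without a stated uncertainty fall back to σ = 1 (logged). The
intrinsic rates — one per (peak, field, temperature), since R2,0 varies
strongly with both B₀ and temperature — enter the model additively and are
therefore profiled out in closed form (the χ²-optimal weighted offset per
profile). This variable projection shrinks the nonlinear search space from
~47 to 7 dimensions for the default dataset, which is the main reason a
full multistart fit takes seconds.

Bounds and initialization: Δ‡G ∈ [20, 90] kJ/mol, ΔG ∈ [0.1, 30] kJ/mol;
amide |Δω| is restrained to ≥ 1 ppm (the conventional convergence aid for
¹⁵N dispersion data), methyl ¹³C |Δω| only to ≥ 0. Multistart (default 10)
draws Δ‡G from [45, 60] kJ/mol, ΔG from [2, 10] kJ/mol and per-peak Δω
from each peak's Rex through the fast-exchange relation
Δω ≈ √(Rex·k_ex/(p_a p_b)), jittered ±30%; all draws are seeded. The best
start wins by strict χ² comparison, so ties resolve to the lowest start
index and results are reproducible for a fixed seed. Convergence
tolerances: ftol 1e−10, xtol 1e−8. A dataset whose largest Rex is below
0.5 s⁻¹ triggers a degenerate-fit warning — the exchange parameters are
then essentially unconstrained.

Parameter uncertainties come from seeded Monte-Carlo refits of synthetic
replicates built from the best-fit curves plus Gaussian noise at each
point's stated σ (or the RMS residual when no σ is given). Replicate
refits start from the best-fit parameters with a single start.

## Relaxation and tumbling

R1 and R1ρ are monoexponential fits (log-linear start, nonlinear refine);
a series whose fitted decay over the sampled window is below 1e−9 is
flagged as non-decaying rather than reported. R2 follows from R1ρ with the
tilt-angle correction R2 = (R1ρ − R1 cos²θ)/sin²θ, tanθ = ω₁/Ω; with no
offsets supplied the on-resonance approximation is used and noted. The
rotational correlation time uses τ_c ≈ √(6·R2/R1 − 7)/(4π ν_N), valid for
slow nearly isotropic tumbling; ratios below 7/6 are rejected as outside
the approximation.

Residues with enhanced local ps–ns motion bias the mean R2/R1 downward.
The exclusion rule — drop residues whose ratio falls more than 1.5 SD below
the median, in one pass — is a package choice (the criterion is usually
left qualitative); both the multiplier and the rule are configurable, and
the excluded-id list is always returned so the decision is auditable.

## Chemical shifts, RDCs, assays

CSP uses the standard weighted combination √((Δδ_H·1)² + (Δδ_N·0.154)²)
with the 0.3 ppm significance cutoff; residues missing in either state are
skipped, never imputed. Secondary-Cα comparison subtracts a user-supplied
random-coil table and regresses state against state; slope ≈ 1 and r ≈ 1
indicate an unchanged backbone.

RDCs: D = vᵀS v with the dipolar prefactor absorbed into the Saupe tensor
(tensor in Hz, "Da convention"; dividing by the static N–H dipolar constant
recovers the dimensionless order matrix). The tensor is solved by SVD of
the 5-column orientation design matrix over residues matched between the
coupling table and the bond-vector set (≥ 5, non-degenerate); unmatched
entries are reported. Quality is R = √(⟨(D_obs−D_calc)²⟩ / (2⟨D_obs²⟩)).
N→H vectors are read from PDB with gemmi, first model by default, prolines
skipped. Euler angles are reported in z-y-z convention in the input
structure frame.

Melting temperatures are the grid point maximizing |dθ/dT| (central
differences; optional 3-point smoothing, off by default because the
synthetic fixtures are noise-free) — resolution is the grid step, 1 °C on
the default 35–75 °C scan. A second derivative peak above half the maximum
flags multimodality. Initial velocity is minus the OLS slope of
concentration vs time; all supplied points are used, so truncating to the
early (<15% depletion) regime is the caller's responsibility. The
phosphoryl adduct mass is computed from standard atomic masses (HPO₃:
79.98 Da average, 79.966 monoisotopic).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the experimental design of a multi-temperature
dispersion study: 5/10/15/20 °C, 600 and 800 MHz, ten CPMG fields from 50
to 1000 Hz, T_relax 60 ms (¹⁵N) / 30 ms (¹³C), five peaks (four amide,
Δω 1.5–3 ppm; one methyl, 1.2 ppm), Δ‡G = 50,228 J/mol, ΔG = 5,601 J/mol.
Noise is additive Gaussian on R2eff with σ = 0.2 s⁻¹ — per-point R2eff
uncertainties in real studies are spectrum-noise derived and rarely quoted;
0.2 s⁻¹ is a typical value for well-resolved peaks and is the one free
choice of the noise model. Intrinsic rates default to a flat 10 s⁻¹; real
R2,0 grows with B₀ and falls with temperature, but since the fit profiles
one rate per condition the flat default costs no generality in the tests.
Generators are pure functions of their arguments including the seed, and
zero-noise outputs are exact fixed points of the corresponding fits.

What passing these tests shows: the estimators are unbiased and correctly
seeded on data generated under their own model, and the tied 7-parameter
fit neither biases the free energies nor deflates χ². What they do not
show: robustness to model violations present in real spectra — unequal
intrinsic rates, pulse imperfections, peak overlap, temperature
miscalibration, or a third exchanging site. The experimental R-factors
(~27–28%), the experimental τ_c (~11 ns) and the experimental depletion
traces require the original measured data and coordinates, which are not
redistributable here; round-trip and property tests stand in for them.

## Problem sizes

Default test and acceptance runs use the full 40-profile × 10-point
dispersion grid (400 residuals, 7 free + 40 profiled parameters), 20-seed
recovery ensembles for the median-error property, 50-seed ensembles for the
RDC noise/R-factor calibration, and 3–8 Monte-Carlo replicates for error
bars — sizes chosen so the whole suite completes in well under a minute of
optimizer time while keeping Monte-Carlo assertions stable.
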