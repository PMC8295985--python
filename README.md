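# twosite

Quantitative solution-NMR analysis of two-site protein conformational
exchange, built around the thermodynamically tied global fitting of CPMG
relaxation-dispersion data, with the supporting relaxation, chemical-shift,
residual-dipolar-coupling and biophysical-assay computations that accompany
such a study.

The package is aimed at NMR spectroscopists and biophysicists who have
per-peak R2eff dispersion profiles (or want to simulate them), and who need
the kinetics *and* thermodynamics of a microsecond–millisecond equilibrium —
for example the rotamer interconversion of an active-site side chain in an
enzyme domain — from data recorded at several temperatures and static
fields.

## The model

A spin exchanging between a major state *a* and a minor state *b*
(population p_b, shift separation Δω, exchange rate k_ex = k_ab + k_ba)
relaxes during a CPMG train with the effective rate given by the
Carver–Richards closed form

    R2eff(ν_CPMG) = R2,0 + k_ex/2 − ν_CPMG · arccosh[D₊ cosh η₊ − D₋ cos η₋]

with ψ = k_ex² − Δω², ζ = −2Δω k_ex (p_a − p_b), D± = ½[±1 + (ψ+2Δω²)/√(ψ²+ζ²)]
and η± = √(±ψ + √(ψ²+ζ²)) / (2√2 ν_CPMG). A numerical Bloch–McConnell
propagator (ideal 180° pulses as complex conjugation of the 2×2 complex
evolution) serves as an independent oracle for this closed form.

Instead of fitting (k_ex, p_b) separately at every temperature, the global
fit ties them to two free energies via transition-state theory and the
reaction isotherm,

    k_ex(T) = (k_B T/h) · exp(−Δ‡G/RT),     p_b(T) = K/(1+K),  K = exp(−ΔG/RT),

so a dataset of five peaks at four temperatures needs 7 exchange parameters
(Δ‡G, ΔG, five peak-specific |Δω|) instead of 28, plus one intrinsic rate
per (peak, field, temperature) that is profiled out in closed form.
Per-temperature rate constants k_ab = p_b k_ex and k_ba = (1−p_b) k_ex are
then regressed with the Eyring and van't Hoff equations to give activation
and standard enthalpies/entropies.

Supporting operations: R1/R1ρ exponential decay fitting with the tilt-angle
R2 correction and the τ_c ≈ √(6 R2/R1 − 7)/(4π ν_N) tumbling estimate;
weighted ¹H/¹⁵N chemical-shift perturbations √((Δδ_H)² + (0.154 Δδ_N)²);
alignment-tensor determination from ¹D_NH RDCs by SVD with R-factor
scoring; CD melting temperatures from the derivative maximum of θ₂₂₂(T);
and initial velocities from substrate-depletion slopes.

Every input has a seeded synthetic generator with known ground truth
(`twosite.synthetic`), so the whole pipeline is testable end to end without
experimental data.

## Worked example

```python
from twosite.globalfit import GlobalFitConfig, fit_global
from twosite.synthetic import GroundTruth, gen_rd_dataset

dataset = gen_rd_dataset(GroundTruth(noise_sd=0.2, seed=1))   # 40 profiles
result = fit_global(dataset.profiles, GlobalFitConfig(multistart_count=5, seed=2))
print(round(result.tp.dG_act), round(result.tp.dG_eq), round(result.reduced_chi2, 2))
```

prints

```
50236 5591 0.88
```

— the activation free energy (true value 50,228 J/mol) and standard free
energy (true 5,601 J/mol) recovered from 400 noisy R2eff points within a
few J/mol, with a reduced χ² near 1 showing the 7-parameter tying fully
explains data generated under the tied model. `result.rate_table` holds the
derived k_ex, p_b, k_ab, k_ba at each temperature (e.g. k_ex ≈ 2,135 s⁻¹
and p_b ≈ 8.2% at 5 °C for these free energies). The `examples/` directory
has one short script per capability (dispersion fit, Eyring/van't Hoff,
relaxation/τ_c, CSP mapping, RDC SVD, melts/kinetics, full pipeline); each
prints the numbers it computes and what they mean.

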