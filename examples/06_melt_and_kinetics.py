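"""Thermal-melt midpoint extraction and enzymatic initial velocity.

Generates a two-state CD melting trace and a linear substrate-depletion
trace, then reads out the melting temperature (derivative maximum) and the
initial phosphoryl-transfer velocity (OLS slope).
"""

from twosite.assays import extract_tm, initial_velocity, mass_shift_phospho
from twosite.synthetic import gen_kinetics_trace, gen_melt_curve

for tm_true, label in ((54.0, "mesophilic domain"), ((56.5), "stabilized mutant")):
    curve = gen_melt_curve(tm_C=tm_true, T_range=(35.0, 75.0), step_C=1.0)
    res = extract_tm(curve)
    print(f"{label:20s}: true Tm {tm_true:.1f} C -> extracted {res.tm_C:.1f} C")

for v0_true, label in ((25.0, "fast mesophilic enzyme"), (3.0, "slow thermophilic enzyme")):
    trace = gen_kinetics_trace(v0=v0_true, hpr0=600.0, noise_sd=4.0, seed=5)
    res = initial_velocity(trace)
    print(
        f"{label:23s}: true V0 {v0_true:5.1f} uM/min -> fitted "
        f"{res.v0:5.1f} +/- {res.v0_err:.1f} uM/min"
    )

print(f"\nsingle phosphoryl adduct mass : {mass_shift_phospho():.2f} Da (rounds to 80)")
print(
    "\nThe Tm readout resolves half-degree stability differences between\n"
    "constructs; V0 is the early-time depletion slope of the 600 uM substrate."
)
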