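"""R1/R1rho decay fitting and the rotational-correlation-time estimate.

Simulates per-residue relaxation decays (with a few linker-like residues
undergoing extra fast local motion), extracts rates, applies the tilt-angle
R2 correction, trims mobile residues, and estimates tau_c from the mean
R2/R1 ratio.
"""

import numpy as np

from twosite.constants import nucleus_frequency_hz
from twosite.relaxation import fit_exponential_decay, r2_from_r1rho, tau_c_estimate, trimmed_mean_r2_r1
from twosite.synthetic import gen_decay_series

R1_DELAYS = [0.0, 0.12, 0.28, 0.44, 0.64, 0.80, 1.04, 1.20]
R1RHO_DELAYS = [0.0002, 0.0042, 0.0072, 0.015, 0.0234, 0.0324, 0.042, 0.0522, 0.06]

rng = np.random.default_rng(0)
ratios = {}
for i in range(25):
    res = f"res{i}"
    r1_true = 1.1
    ratio_true = 22.0 if i % 8 else 15.0  # every eighth residue sits in a flexible linker
    r1_series = gen_decay_series(r1_true, R1_DELAYS, i0=1e4, noise_sd=0.01, seed=2 * i)
    rr_series = gen_decay_series(
        r1_true * ratio_true, R1RHO_DELAYS, i0=1e4, noise_sd=0.01, seed=2 * i + 1
    )
    r1 = fit_exponential_decay(r1_series).rate
    r1rho = fit_exponential_decay(rr_series).rate
    r2 = r2_from_r1rho(r1rho, r1, spinlock_Hz=1000.0, offset_Hz=0.0)
    ratios[res] = r2 / r1

trimmed = trimmed_mean_r2_r1(ratios)
nu_n = nucleus_frequency_hz(800.0, "15N")
tau_c = tau_c_estimate(trimmed.mean_ratio, nu_n)

print(f"residues analyzed : {len(ratios)}")
print(f"excluded (local ps-ns motion) : {trimmed.excluded}")
print(f"mean R2/R1 after trimming : {trimmed.mean_ratio:.1f}")
print(f"tau_c : {tau_c * 1e9:.1f} ns")
print(
    "\nA ~11 ns correlation time is what a compact ~28 kDa domain tumbles at;\n"
    "the trimmed residues report faster effective motion, not global tumbling."
)
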