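"""Chemical-shift perturbation mapping between two phosphorylation states.

Builds amide shift tables for a protein before and after modification of one
site, computes the weighted combined 1H/15N perturbation per residue, and
classifies the significantly perturbed residues.
"""

import numpy as np

from twosite.csp import classify_significant, compare_secondary_shifts, csp_map

rng = np.random.default_rng(3)
state_a, state_b = {}, {}
site = {188, 189, 190, 191}
for res in range(160, 210):
    h, n = 8.0 + 0.3 * rng.standard_normal(), 118.0 + 3.0 * rng.standard_normal()
    state_a[res] = (h, n)
    if res in site:  # electronic/ring-current effects near the modified histidine
        state_b[res] = (h + rng.uniform(0.3, 0.6), n + rng.uniform(1.0, 3.0))
    else:
        state_b[res] = (h + rng.normal(0, 0.01), n + rng.normal(0, 0.05))

perturbations = csp_map(state_a, state_b)
significant = classify_significant(perturbations, threshold_ppm=0.3)
print(f"residues compared : {len(perturbations)}")
print(f"significant (>0.3 ppm) : {sorted(significant)}")
print(f"largest perturbation : {max(perturbations.values()):.2f} ppm")

# Secondary Calpha shifts: unchanged backbone conformation gives slope ~ 1, r ~ 1
coil = {res: 56.0 for res in range(160, 210)}
sec = rng.uniform(-3, 3, 50)
ca_a = {res: coil[res] + sec[i] for i, res in enumerate(range(160, 210))}
ca_b = {res: v + rng.normal(0, 0.05) for res, v in ca_a.items()}
fit = compare_secondary_shifts(ca_a, ca_b, coil)
print(f"secondary-Ca comparison : slope {fit.slope:.3f}, r {fit.r:.4f} over {fit.n} residues")
print(
    "\nPerturbations confined to the modification site plus an unchanged\n"
    "secondary-shift line indicate a local side-chain event, not a backbone\n"
    "conformational change."
)
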