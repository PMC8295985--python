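"""Alignment-tensor determination from residual dipolar couplings by SVD.

Generates couplings from a known tensor over random bond orientations, fits
the tensor back by singular value decomposition, and scores the agreement
with the R-factor — at two noise levels.
"""

import numpy as np

from twosite.rdc import AlignmentTensor, BondVectorSet, svd_fit
from twosite.synthetic import gen_rdc_set

rng = np.random.default_rng(1)
v = rng.normal(size=(40, 3))
v /= np.linalg.norm(v, axis=1, keepdims=True)
vectors = BondVectorSet({f"r{i}": v[i] for i in range(40)})

truth = AlignmentTensor.axially_symmetric(da_hz=10.0, rhombicity=0.25)
print(f"true tensor : Da = {truth.da_hz:.2f} Hz, R = {truth.rhombicity:.3f}")

for noise in (0.0, 1.0):
    data = gen_rdc_set(truth, vectors, noise_sd=noise, seed=7)
    fit = svd_fit(data, vectors)
    print(
        f"noise {noise:.1f} Hz -> Da = {fit.tensor.da_hz:6.2f} Hz, "
        f"R = {fit.tensor.rhombicity:6.3f}, R-factor = {fit.r_factor:.4f}"
    )

print(
    "\nZero noise recovers the tensor exactly (R-factor 0); the R-factor then\n"
    "grows with the coupling noise. Against an experimental structure, an\n"
    "R-factor around 0.2-0.3 still indicates that the measured couplings are\n"
    "consistent with the coordinates, i.e. unchanged domain orientations."
)
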