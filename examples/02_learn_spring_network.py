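"""Learn spring constants by self-consistent fluctuation matching.

A 12-residue reference network with known, heavy-tailed spring constants
supplies analytic distance-variance targets; the learner starts from a
uniform k0 = 1 network and must recover the reference.  Springs absent in
the reference are driven to zero and removed by connectivity trimming.
"""

import numpy as np

import rigiditygraph as rg
from rigiditygraph import enm

ref = rg.make_reference_enm(n_residues=12, seed=3)
print(f"reference: {len(ref.model.springs)} springs "
      f"({sum(1 for s in ref.model.springs if s.k == 0)} true zeros)")

cg = rg.CGModel(ref.model.sites, ref.model.coords)
model = enm.build_initial_model(cg, ref.spec.lc, k0=1.0, targets=ref.targets)
fit, rep1 = enm.fluctuation_matching_round(model, ref.targets)
trimmed, rep2 = enm.trim_and_refit(fit, ref.targets)

lookup = {s.pair: s.k for s in ref.model.springs}
k_fit = trimmed.stiffnesses()
k_ref = np.array([lookup[s.pair] for s in trimmed.springs])
sel = k_ref > 0.1
rel = np.abs(k_fit[sel] - k_ref[sel]) / k_ref[sel]

print(f"round 1: {rep1.iterations} iterations, converged={rep1.converged}, "
      f"max variance mismatch {rep1.max_rel_mismatch:.1e}")
print(f"after trimming: {len(trimmed.springs)} springs retained")
print(f"zero set recovered exactly: "
      f"{ {s.pair for s in trimmed.springs} == ref.nonzero_pairs }")
print(f"stiffness recovery (k_ref > 0.1): max rel err {rel.max():.2e}, "
      f"median {np.median(rel):.2e}")
print()
print("A max error well below 1% means the inverse-variance iteration found")
print("the reference fixed point; trimming removed exactly the springs the")
print("reference never had.")
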