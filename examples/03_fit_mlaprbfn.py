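"""Fit the multi-Laplacian-regularized RBF network and watch the solver.

Four patient-similarity graphs (Gaussian, cosine, polynomial, sigmoid
kernels) regularize the fit; their weights eta are learned on the
probability simplex while an L2,1 penalty row-sparsifies the readout.
"""

import numpy as np

from mlaprbfn import Hyperparams, fit_mlaprbfn, generate_multiview_fixture

fixture = generate_multiview_fixture(n=60, d=3, noise_sd=0.05, seed=3)
hp = Hyperparams(p=8, tmax=10, lambda1=2**-3, lambda2=2**-3, rho=2.0, seed=3)
model = fit_mlaprbfn(fixture, hp)

print("objective trace (one value per alternating iteration):")
for t, J in enumerate(model.state.objective_trace):
    print(f"  t={t:2d}  J = {J:.6f}")
print("\nlearned view weights (Gaussian, cosine, polynomial, sigmoid):")
print("  eta =", np.round(model.eta, 4), " sum =", float(model.eta.sum()))
rows = np.linalg.norm(model.W, axis=1)
print(f"\nreadout row norms: min {rows.min():.3f}, max {rows.max():.3f}")
print("\nThe objective is non-increasing by construction (closed-form W-step")
print("on a majorizing surrogate, exact simplex eta-step); eta concentrates")
print("on the views whose graphs the fitted predictions vary least over.")
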