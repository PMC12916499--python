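"""Fit and rotate a three-factor model on polychoric correlations.

Estimates the heterogeneous correlation matrix of a simulated battery
(five questionnaires for speed), fits the ML three-factor model, rotates it
obliquely, and prints fit indices and the factor correlations.
"""

import numpy as np

import factorverse as fv

spec = fv.build_default_spec(5, [10, 10, 10, 10, 10], 3, seed=2)
ds = fv.simulate_responses(spec, n=1500, seed=3)

R = fv.heterogeneous_matrix(ds.responses)
print(f"polychoric matrix: {R.matrix.shape[0]} items, "
      f"smallest eigenvalue {R.min_eigenvalue_before:.4f}")

sol = fv.rotate(fv.extract_ml(fv.ensure_psd(R), 3, ds.n), "oblimin")
print(f"chi2 = {sol.chi_square:.1f} on df = {sol.df:.0f}; "
      f"RMSEA = {sol.rmsea:.3f}, TLI = {sol.tli:.3f}")
print("factor correlations (oblimin):")
print(np.round(sol.factor_corr, 3))

# each questionnaire block should load one factor dominantly
top = sol.loadings.groupby(
    sol.loadings.index.str.split("__").str[0]).mean().round(2)
print("mean loadings per questionnaire block:")
print(top)
print("blocks separate onto the planted factors; the factor correlations "
      "reflect the planted oblique structure")
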