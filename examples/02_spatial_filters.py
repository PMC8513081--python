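"""Fit multiclass CSP (joint approximate diagonalization) on a synthetic
session and inspect the mutual-information ranking of the spatial filters.

The projection Z = W E maximizes class-discriminative variance; filters
are ranked by an approximation to the mutual information between the
class label and each filter's output variance.
"""

import numpy as np

from mdeeg import FilterSpec, SynthConfig, apply_csp, apply_filter, fit_csp, generate

epochs = apply_filter(generate(SynthConfig(seed=1)), FilterSpec("bandpass", (4.0, 40.0)))
model = fit_csp(epochs)

print(f"fitted {model.W.shape[0]} spatial filters on {epochs.n_trials} trials")
print("top 5 filters by mutual-information score:")
for rank, j in enumerate(model.order[:5]):
    v = [float(model.W[j] @ r @ model.W[j]) for r in model.class_covs]
    print(f"  filter {j:2d}: MI {model.mi_scores[j]:.4f}, "
          f"per-class variance {np.round(v, 3)}")

z = apply_csp(model, epochs)
print(f"spatial-domain tensor: {z.data.shape}, tag {z.domain!r}")
print("-> the top-ranked filters isolate components whose variance differs "
      "most across the three imagery classes; low-ranked ones are noise.")
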