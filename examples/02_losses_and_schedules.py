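"""The loss terms and schedules, evaluated on hand-checkable inputs.

Shows the supervised / consistency / pseudo-label terms, the adaptive
convex weights, the Gaussian warm-up and the stage totals on tiny arrays
whose values you can verify with a calculator.
"""

import math

import numpy as np

from plmt import (LossWeights, adaptive_weights, cross_entropy, mse_loss,
                  stage_a_total, stage_c_total, warmup_weight)

# cross-entropy: uniform 2-class prediction -> ln 2
probs = np.full((1, 2, 2, 2), 0.5, dtype=np.float32)
target = np.zeros((1, 2, 2), dtype=np.int64)
print(f"CE(uniform, C=2) = {cross_entropy(probs, target).item():.4f} "
      f"(ln 2 = {math.log(2):.4f})")

# consistency MSE: antipodal one-pixel distributions -> 1.0
a = np.array([1.0, 0.0], dtype=np.float32).reshape(1, 2, 1, 1)
b = np.array([0.0, 1.0], dtype=np.float32).reshape(1, 2, 1, 1)
print(f"MSE((1,0),(0,1)) = {mse_loss(a, b).item():.4f}")

# adaptive weights: a single logistic scalar keeps alpha+beta = 1 exactly
for z in (0.0, math.log(3)):
    alpha, beta = adaptive_weights(z)
    print(f"z={z:.4f} -> alpha={alpha:.3f}, beta={beta:.3f} (sum {alpha+beta})")

# Gaussian warm-up: e^-5 at the start, 1 at the end
for t in (0, 500, 1000):
    print(f"warmup(t={t}, t_max=1000) = {warmup_weight(t, 1000):.6f}")

# stage totals reproduce the defining combinations
w = LossWeights(lambda_a=0.1, lambda_c=0.1, K=1000.0, z=0.0)
ba = stage_a_total(1.0, 0.5, w, ramp=1.0)
print(f"stage A total: 1.0 + 0.1*1*0.5 = {ba.total_value:.4f}")
bc = stage_c_total(1.0, 0.001, 0.8, w, ramp=1.0)
print(f"stage C total: 1.0 + 0.1*(0.5*1000*0.001 + 0.5*0.8) = {bc.total_value:.4f}")
print("the temperature K=1000 lifts the numerically tiny consistency MSE to the")
print("magnitude of the pseudo-label cross-entropy, so the trainable convex pair")
print("(alpha, beta) arbitrates between comparably sized terms.")
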