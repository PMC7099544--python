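"""Run the particle-swarm high-pass filter against a convolutional target.

One scalar swarm per pixel: particle velocities are the candidate high-pass
samples and the least-squares cost compares them with the convolutional
filter's response.  The script reports the swarm-mean global-best cost at
start and end and the overall mean squared error reduction.
"""

import numpy as np

from icfilt import PSOConfig, SyntheticSpec, generate, pso_hpf, traditional_hpf

image = generate(SyntheticSpec("sphere", size=(16, 16)))
target = traditional_hpf(image)

cfg = PSOConfig(n_particles=30, n_iterations=200, seed=0)
output, state = pso_hpf(image, target, cfg)

h = state.cost_history
mse = float(np.mean((output - target) ** 2))
print(f"swarm: {cfg.n_particles} particles/pixel, {state.n_iterations_run} iterations")
print(f"mean global-best cost: {h[0]:.4f} (init) -> {h[-1]:.6f} (final)")
print(f"MSE(output, target):   {mse:.6f}  ({100 * (1 - mse / h[0]):.3f}% drop)")
print(f"cost non-increasing at every iteration: {bool(np.all(np.diff(h) <= 0))}")
print("The swarm tracks the target response closely but stochastically -")
print("the convolutional filter it imitates remains the sharper of the two.")
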