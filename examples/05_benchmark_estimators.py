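"""Score demographic estimators on a slice of the simulation design.

Draws a few scenarios from the 540-cell factorial design and compares the
random-guessing baselines and two affine age rules on mean absolute error.
(The Bayesian model can be added to `models` — each scenario then costs a
full MCMC fit.)
"""
from ridgemix import GrowthParams, run_benchmark
from ridgemix.simulate import design_subset, factorial_design

growth = GrowthParams()
design = design_subset(factorial_design(base_seed=3), size=6, seed=3)
models = ["random", "random2", "PM1", "LCmod", "KAmod2"]

per_row, aggregate = run_benchmark(models, design, growth)
print(aggregate.round(2).to_string())
# Cells are mean absolute errors: ages in years, proportions on [0, 1].
# The educated random guesser ('random2', ages ~ N(18, 5)) typically beats
# the per-print affine rules on mean age - pooling beats per-print guessing.
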