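"""Build the balanced multi-level binary replacement calibration design.

Nine circadian-clock rate parameters at 8 equally spaced levels each would
need 8^9 > 134 million full-factorial runs; the binary-replacement design
compresses this to 2^13 = 8192 runs while keeping every factor perfectly
balanced (1024 runs per level).
"""

import numpy as np

from nwaymeta import OMBRSpec, circadian_clock_factors, make_ombr_design

spec = OMBRSpec(circadian_clock_factors(), run_exponent=13)
design = make_ombr_design(spec, optimizer_seed=0)

print(f"design: {design.n_obs} runs x {design.n_params} parameters, "
      f"{len(np.unique(design.values, axis=0))} distinct rows")
for j, name in enumerate(design.param_names):
    levels, counts = np.unique(design.values[:, j], return_counts=True)
    print(f"  {name:8s} levels {levels.min():.2f}..{levels.max():.2f} "
          f"x{counts[0]} each, column variance {np.var(design.values[:, j], ddof=1):.4f}")

# The variances follow d^2 (L^2 - 1) / 12 for level spacing d and L levels:
# they are properties of the ranges alone, so they double as a design check.
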