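"""Sensitivity maps: global and per-cluster loading products, plus the
2-way polynomial follow-up for individual outputs.

The product of second-mode regressor loadings with second-mode response
loadings reads as the standardised effect of each parameter on each state
variable; regional maps expose effects that only act in one behavioural
regime.  (The loadings are not orthogonal, so treat the maps as a
semi-quantitative screen.)
"""

import numpy as np

from nwaymeta import (
    HCConfig,
    fit_hcplsr_classical,
    fit_hcplsr_inverse,
    make_synthetic_trilinear,
    npls_sensitivity,
    poly_hcplsr_2way,
    regional_sensitivities,
)

table, tensor, truth = make_synthetic_trilinear(seed=0)
config = HCConfig(n_clusters=3, a_max=8, seed=0)
inverse = fit_hcplsr_inverse(tensor, table, config)
classical = fit_hcplsr_classical(table, tensor, inverse)

print("global sensitivity map (parameters x state variables):")
print(npls_sensitivity(classical.global_model,
                       table.param_names, tensor.var_names).to_frame().round(2))

for mat in regional_sensitivities(classical):
    strongest = np.unravel_index(np.abs(mat.values).argmax(), mat.values.shape)
    print(f"{mat.source}: strongest effect {mat.param_names[strongest[0]]} -> "
          f"{mat.var_names[strongest[1]]} ({mat.values[strongest]:+.2f})")

# follow-up for one output: second-order polynomial 2-way analysis with
# nonlinear terms deflated against the first-order block in regional models
result = poly_hcplsr_2way(table, tensor.values[:, 0, :], clusters=inverse.fcm,
                          config=HCConfig(a_max=6, seed=0))
top = result.coefficients.abs().mean(axis=1).nlargest(4)
print("\npolynomial terms with largest mean |coefficient| for variable V1:")
print(top.round(3).to_string())
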