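"""Population-level molar patterns and spatial-lag regression.

Generates 56 populations with spatially autocorrelated molar sizes,
censuses their size patterns, and fits the M3 allometry with the
spatial simultaneous autoregressive lag model.
"""

import numpy as np

import molaric as m

cfg = m.SyntheticConfig(seed=11, n_groups=56, sar_rho=0.6)
triples, coords, truth = m.gen_population_dataset(cfg)

print("pattern census over 56 populations:")
print(m.pattern_census(triples).to_string(index=False))

weights = m.inverse_distance_weights(coords)
x = np.log(triples["row"].to_numpy())
y = np.log(triples["a3"].to_numpy())
sar = m.lag_sar_fit(x, y, weights)
ols = m.ols_fit(x, y)
print(
    f"\nM3 allometry: OLS slope {ols.slope:.3f}, "
    f"lagSAR slope {sar.slope:.3f} (rho = {sar.rho:.3f}, true rho = {truth['rho']})"
)

fit = m.fit_ic_line(triples, method="lagSAR", weights=weights)
print(
    f"cascade fit (lagSAR): slope {fit.result.slope:.2f} "
    f"({fit.result.ci95_slope[0]:.2f}/{fit.result.ci95_slope[1]:.2f}), "
    f"intercept {fit.result.intercept:.2f}; "
    f"consistent with slope 2: {fit.slope_consistent}"
)
print(
    "The census shows the configured majority of decreasing (M1>M2>M3) rows;\n"
    "rho > 0 means nearby populations are more similar than distant ones."
)
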