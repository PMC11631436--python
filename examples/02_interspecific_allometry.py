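"""Interspecific allometry with phylogenetic regression.

Simulates log molar sizes evolving by Brownian motion on a 21-taxon
tree with known per-tooth scaling exponents, then recovers them with
OLS and PGLS and measures the phylogenetic signal of row size.
"""

import numpy as np

import molaric as m

cfg = m.SyntheticConfig(seed=42, n_taxa=21, true_slopes=(0.82, 1.01, 1.16))
data, tree, truth = m.gen_bm_dataset(cfg)
cov = m.bm_covariance(tree, list(data.index))

print("tooth  truth   OLS slope (95% CI)        PGLS slope (95% CI)   class")
for i, tooth in enumerate(("M1", "M2", "M3"), start=1):
    x = data["log_row"].to_numpy()
    y = data[f"log_a{i}"].to_numpy()
    ols = m.ols_fit(x, y)
    pgls = m.pgls_fit(x, y, cov)
    cls = m.classify_allometry(pgls.ci95_slope)
    print(
        f"{tooth}    {truth['true_slopes'][i-1]:.2f}   "
        f"{ols.slope:.3f} ({ols.ci95_slope[0]:.3f}/{ols.ci95_slope[1]:.3f})   "
        f"{pgls.slope:.3f} ({pgls.ci95_slope[0]:.3f}/{pgls.ci95_slope[1]:.3f})   {cls}"
    )

trait = data["log_row"]
k, p = m.phylosignal_test(tree, trait, n_perm=999, seed=7)
print(f"\nBlomberg's K of log row size: {k:.3f} (permutation p = {p:.3f})")
print(
    "Slopes below/above 1 mean the tooth shrinks/grows relative to the row;\n"
    "K near 1 matches the Brownian-motion expectation on this tree."
)
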