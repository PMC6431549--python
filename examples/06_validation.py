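"""Map validation: Kappa and the fuzzy similarity curve.

Simulates half a synthetic history forward and scores the simulated map
against the held-out true map, at cell level (kappa) and with growing fuzzy
windows.
"""

import numpy as np

from lulcsim import (
    SyntheticConfig,
    TransitionMatrix,
    annualize,
    crosstab,
    estimate_matrix,
    fuzzy_similarity,
    gen_drivers,
    gen_landscape,
    kappa,
    run_simulation,
    similarity_curve,
    simulate_history,
)

cfg = SyntheticConfig(shape=(100, 100), seed=23)
land = gen_landscape(cfg)
drivers = gen_drivers(cfg, land)
P = np.eye(5)
P[0, 1], P[0, 3], P[1, 3] = 0.03, 0.004, 0.006
P[np.arange(5), np.arange(5)] = 1 - (P.sum(1) - 1)
true = TransitionMatrix(P, 1.0, [1, 2, 3, 4, 5])
series = simulate_history(land, true, [], drivers, 8, seed=23)

est = estimate_matrix(crosstab(series[0], series[4]), 4)
annual = annualize(est, enforce_stochastic=True)
sim = run_simulation(series[4], annual, 4, seed=23).final

kr = kappa(series[-1], sim)
print(f"kappa vs held-out map: {kr.kappa:.3f} "
      f"(p_o={kr.p_observed:.3f}, p_e={kr.p_expected:.3f})")
fr = fuzzy_similarity(series[-1], sim, max_window=7)
print("\nfuzzy similarity curve (full-width distance convention):")
print(similarity_curve(fr).round(4).to_string(index=False))
print("\nSimilarity rises with window size: residual disagreement is mostly"
      "\nsmall spatial displacement of correctly sized change, which fuzzy"
      "\ncomparison forgives and cell-by-cell kappa does not.")
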