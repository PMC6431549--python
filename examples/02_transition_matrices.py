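"""Markov transition matrices: annualization, restriction, projection.

Loads the published 1990-2017 transition matrix, takes its yearly root,
restricts it to the deforestation-model whitelist and projects class shares
to 2050.
"""

import numpy as np

from lulcsim import annualize, project_shares, restrict
from lulcsim.datasets import CLASS_LABELS, WHITELIST, area_table, transition_matrix

m = transition_matrix(1990, 2017)
annual = annualize(m)
print(f"27-year matrix annualized; retained negative rate mass: "
      f"{annual.cleanup_magnitude:.2e} (quasi-stochastic exact root)")
err = np.abs(np.linalg.matrix_power(annual.P, 27) - m.P).max()
print(f"round-trip |A^27 - P| max error: {err:.2e}")

restricted = restrict(annual, WHITELIST)
print("\nAnnual rates restricted to the whitelisted transitions "
      "(PF->SF, PF->AWV, PF->HS, SF->AWV):")
print(restricted.to_frame(CLASS_LABELS).round(5).to_string())

at = area_table()
order = restricted.class_order
shares_2017 = np.array([at.share_pct(CLASS_LABELS[c], 2017) / 100 for c in order])
proj = project_shares(restricted, shares_2017, 33)
print("\nMarkov-projected 2050 shares (%):")
for c, s in zip(order, proj):
    print(f"  {CLASS_LABELS[c]}: {100 * s:.2f}")
print("\nUnder continued 1990-2017 dynamics the PF share keeps falling; the"
      "\nCA only decides where on the map that aggregate demand lands.")
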