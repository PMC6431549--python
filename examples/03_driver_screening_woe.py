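"""Driver screening with Cramér's V and Weights-of-Evidence calibration.

Generates a synthetic landscape with drivers, plants an elevation effect on
the PF->SF transition, then screens correlated drivers and recovers the
planted weights.
"""

import numpy as np

from lulcsim import (
    PlantedEffect,
    SyntheticConfig,
    TransitionMatrix,
    compute_woe,
    gen_drivers,
    gen_landscape,
    screen_drivers,
    simulate_history,
)

cfg = SyntheticConfig(shape=(150, 150), seed=8)
land = gen_landscape(cfg)
drivers = gen_drivers(cfg, land)

P = np.eye(5)
P[0, 1] = 0.03
P[0, 0] = 0.97
true = TransitionMatrix(P, 1.0, [1, 2, 3, 4, 5])
beta, w_hi = 0.5, float(np.log(2.0 - np.exp(0.5)))
effects = [
    PlantedEffect((1, 2), "elevation", 0.0, 0.5, beta),
    PlantedEffect((1, 2), "elevation", 0.5, 1.0, w_hi),
]
series = simulate_history(land, true, effects, drivers, 10, seed=8)
eligible = series[0].values == 1
change = eligible & (series[-1].values == 2)

kept, report = screen_drivers(list(drivers.values()), change)
print(f"retained drivers after V>0.5 screening: {[d.name for d in kept]}")
if not report.empty:
    print(report.to_string(index=False))
    print("elevation/slope/TPI derive from one terrain, so the weaker "
          "correlates get dropped")

edges = np.quantile(drivers["elevation"].values[eligible], [0, 0.5, 1.0])
wt = compute_woe(change, eligible, drivers["elevation"], bins=edges, transition=(1, 2))
print(f"\nplanted W+ = ({beta:+.3f}, {w_hi:+.3f}); "
      f"recovered W+ = ({wt.w_plus[0]:+.3f}, {wt.w_plus[1]:+.3f})")
print("positive W+ below the median elevation: degradation is attracted to"
      "\nlow ground, exactly as planted in the generator.")
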