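"""Stochastic cellular-automata allocation of Markov change demand.

Each simulated year, the annual transition matrix fixes *how much* of every
transition must happen (``demand``); the CA decides *where*.  Demand is split
between two allocation functions in the Dinamica tradition:

* ``expander`` grows existing patches of the destination class: only
  from-class cells 8-adjacent to the destination class are eligible, sampled
  without replacement with probability proportional to the transition
  probability map, the frontier being recomputed as patches grow.
* ``patcher`` nucleates new patches: seeds are drawn among from-class cells
  proportionally to the probability map and grown to a lognormally
  distributed target size, growth preferring high-probability neighbors and
  becoming more compact as the ``isometry`` factor increases.

Expander demand that cannot be met (no frontier) cascades to the patcher in
the same year; remaining unmet demand carries over to the next year through
the largest-remainder demand accumulator, so multi-year totals stay unbiased
even for rates well below one cell per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .raster import CategoricalLandscape
from .transition import TransitionMatrix, TransitionWhitelist
from .woe import DriverRaster, WoETable, probability_map

__all__ = [
    "PatchParams",
    "SimulationState",
    "SimulationResult",
    "DemandAccumulator",
    "demand",
    "expander",
    "patcher",
    "update_dynamic_drivers",
    "run_simulation",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class PatchParams:
    """Patch-geometry parameters of one transition's allocation.

    ``mean_patch_size_ha``/``patch_size_variance_ha2`` parameterize the
    lognormal new-patch size; ``isometry`` ≥ 1 biases growth toward cells
    touching more patch cells (compactness); ``expander_fraction`` is the
    share of yearly demand routed to patch expansion rather than nucleation.
    """

    mean_patch_size_ha: float = 0.5
    patch_size_variance_ha2: float = 0.0
    isometry: float = 1.5
    expander_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.mean_patch_size_ha > 0:
            raise ValueError("mean_patch_size_ha must be positive")
        if not 0.0 <= self.expander_fraction <= 1.0:
            raise ValueError("expander_fraction must be in [0, 1]")
        if self.isometry < 1.0:
            raise ValueError("isometry must be >= 1")


@dataclass
class SimulationState:
    """Mutable simulation state threaded through the CA."""

    landscape: CategoricalLandscape
    step_index: int = 0
    drivers: dict[str, DriverRaster] = field(default_factory=dict)
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    ledger: list[dict] = field(default_factory=list)

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ledger, columns=["year", "from", "to", "cells", "ha"])


class DemandAccumulator:
    """Largest-remainder rounding of per-year change demand.

    Fractional demand is carried between years so that, e.g., a rate of 1.55
    cells/year alternates integer demands of 1 and 2 and sums to the exact
    expectation ±1 over any horizon.
    """

    def __init__(self, transitions) -> None:
        self.carry = {t: 0.0 for t in transitions}

    def compute(self, m: TransitionMatrix, class_counts: dict[int, int]) -> dict[tuple, int]:
        out = {}
        budget = {c: class_counts.get(c, 0) for c in m.class_order}
        for (i, j) in self.carry:
            rate = max(float(m.P[m.index_of(i), m.index_of(j)]), 0.0)
            x = class_counts.get(i, 0) * rate + self.carry[(i, j)]
            d = int(np.floor(x + 0.5))
            d = max(0, min(d, budget[i]))
            budget[i] -= d
            self.carry[(i, j)] = x - d
            out[(i, j)] = d
        return out


def demand(
    m: TransitionMatrix,
    landscape: CategoricalLandscape,
    whitelist: TransitionWhitelist | None = None,
    accumulator: DemandAccumulator | None = None,
) -> dict[tuple, int]:
    """Cells to change per transition this year: ``round(count(i)·P[i,j])``.

    With an accumulator, rounding residuals carry between calls.
    """
    transitions = _active_transitions(m, whitelist)
    acc = accumulator if accumulator is not None else DemandAccumulator(transitions)
    return acc.compute(m, landscape.class_counts())


def _active_transitions(m: TransitionMatrix, whitelist: TransitionWhitelist | None) -> list[tuple]:
    pairs = []
    for a, i in ((c, m.index_of(c)) for c in m.class_order):
        for b, j in ((c, m.index_of(c)) for c in m.class_order):
            if i == j:
                continue
            if whitelist is not None and (a, b) not in whitelist:
                continue
            if m.P[i, j] > 0:
                pairs.append((a, b))
    return pairs


def _neighbors_flat(idx: int, shape: tuple[int, int]) -> list[int]:
    nrows, ncols = shape
    r, c = divmod(idx, ncols)
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols:
                out.append(rr * ncols + cc)
    return out


def expander(
    state: SimulationState,
    transition: tuple[int, int],
    quantity: int,
    prob_map: np.ndarray,
    params: PatchParams,
    rng: np.random.Generator,
) -> int:
    """Grow existing destination-class patches; returns the unmet quantity."""
    if quantity <= 0:
        return 0
    i, j = transition
    land = state.landscape
    changed = 0
    while changed < quantity:
        from_mask = land.class_mask(i)
        to_mask = land.class_mask(j)
        if not to_mask.any():
            break
        frontier = from_mask & ndimage.binary_dilation(to_mask, structure=_EIGHT)
        cand = np.flatnonzero(frontier & (prob_map > 0))
        if cand.size == 0:
            break
        w = prob_map.flat[cand]
        k = min(quantity - changed, cand.size)
        sel = rng.choice(cand, size=k, replace=False, p=w / w.sum())
        land.values.flat[sel] = j
        changed += k
    if changed:
        state.ledger.append(
            {"year": state.step_index, "from": i, "to": j,
             "cells": changed, "ha": changed * land.cell_area_ha}
        )
    return quantity - changed


def _lognormal_size(mean_cells: float, var_cells: float, rng: np.random.Generator) -> int:
    if var_cells <= 0:
        return max(1, int(round(mean_cells)))
    sigma2 = np.log1p(var_cells / mean_cells**2)
    mu = np.log(mean_cells) - sigma2 / 2.0
    return max(1, int(round(rng.lognormal(mu, np.sqrt(sigma2)))))


def patcher(
    state: SimulationState,
    transition: tuple[int, int],
    quantity: int,
    prob_map: np.ndarray,
    params: PatchParams,
    rng: np.random.Generator,
) -> int:
    """Nucleate and grow new destination-class patches; returns unmet quantity."""
    import warnings

    if quantity <= 0:
        return 0
    i, j = transition
    land = state.landscape
    shape = land.shape
    cell_ha = land.cell_area_ha
    mean_cells = max(params.mean_patch_size_ha / cell_ha, 1.0)
    var_cells = params.patch_size_variance_ha2 / cell_ha**2
    values = land.values
    changed = 0
    while changed < quantity:
        from_flat = np.flatnonzero(land.class_mask(i) & (prob_map > 0))
        if from_flat.size == 0:
            if changed == 0:
                warnings.warn(
                    f"patcher: no positive-probability cells for {i}->{j}; demand unmet",
                    stacklevel=2,
                )
            break
        w = prob_map.flat[from_flat]
        seed = int(rng.choice(from_flat, p=w / w.sum()))
        target = min(_lognormal_size(mean_cells, var_cells, rng), quantity - changed)
        patch = {seed}
        # candidate from-class neighbors, scored by probability and adjacency
        adjacency: dict[int, int] = {}
        for nb in _neighbors_flat(seed, shape):
            if values.flat[nb] == i and not land.nodata_mask.flat[nb]:
                adjacency[nb] = 1
        while len(patch) < target and adjacency:
            cells = np.fromiter(adjacency.keys(), dtype=np.int64)
            scores = (prob_map.flat[cells] + 1e-12) * params.isometry ** (
                np.fromiter(adjacency.values(), dtype=float) - 1.0
            )
            pick = int(rng.choice(cells, p=scores / scores.sum()))
            patch.add(pick)
            del adjacency[pick]
            for nb in _neighbors_flat(pick, shape):
                if nb in patch:
                    continue
                if values.flat[nb] == i and not land.nodata_mask.flat[nb]:
                    adjacency[nb] = adjacency.get(nb, 0) + 1
        idx = np.fromiter(patch, dtype=np.int64)
        values.flat[idx] = j
        changed += len(patch)
    if changed:
        state.ledger.append(
            {"year": state.step_index, "from": i, "to": j,
             "cells": changed, "ha": changed * cell_ha}
        )
    return quantity - changed


def update_dynamic_drivers(state: SimulationState, rules: dict | None = None) -> None:
    """Recompute dynamic driver rasters from the current landscape.

    The supported rule is ``("distance_to_class", code)``: the exact Euclidean
    distance (in meters) to the nearest cell of the class, ``+inf`` when the
    class is absent.  ``rules`` overrides per-driver ``update_rule``.
    """
    land = state.landscape
    for name, drv in state.drivers.items():
        if not drv.dynamic:
            continue
        rule = (rules or {}).get(name, drv.update_rule)
        if rule is None:
            raise ConfigurationError(f"dynamic driver {name!r} has no update rule")
        kind, code = rule
        if kind != "distance_to_class":
            raise ConfigurationError(f"unknown update rule {kind!r} for driver {name!r}")
        if int(code) not in land.class_labels:
            raise ConfigurationError(f"driver {name!r} references unknown class {code}")
        mask = land.class_mask(int(code))
        if not mask.any():
            drv.values = np.full(land.shape, np.inf)
        else:
            drv.values = ndimage.distance_transform_edt(~mask) * land.cell_size


@dataclass
class SimulationResult:
    """Final state plus per-year snapshots and the realized-change ledger."""

    state: SimulationState
    snapshots: list[CategoricalLandscape]
    ledger: pd.DataFrame
    unmet: dict[tuple, float]

    @property
    def final(self) -> CategoricalLandscape:
        return self.state.landscape


def run_simulation(
    initial: CategoricalLandscape,
    annual_matrix: TransitionMatrix,
    n_years: int,
    seed: int,
    whitelist: TransitionWhitelist | None = None,
    woe_tables: dict[tuple, list[WoETable]] | None = None,
    drivers: dict[str, DriverRaster] | None = None,
    patch_params: dict[tuple, PatchParams] | PatchParams | None = None,
    keep_snapshots: bool = False,
) -> SimulationResult:
    """Run the yearly demand → expander → patcher → driver-update loop.

    Without WoE tables, allocation is spatially uniform over the from-class.
    The same seed yields bitwise-identical output.  The ledger records the
    realized cells per transition per year; leftover demand carries forward.
    """
    if annual_matrix.period_years != 1:
        raise ValueError("run_simulation needs an annual (period 1) matrix")
    rng = np.random.default_rng(seed)
    state = SimulationState(initial.copy(), 0, dict(drivers or {}), rng)
    transitions = _active_transitions(annual_matrix, whitelist)
    acc = DemandAccumulator(transitions)
    default_params = patch_params if isinstance(patch_params, PatchParams) else PatchParams()
    snapshots = [state.landscape.copy()] if keep_snapshots else []
    update_dynamic_drivers(state)
    for year in range(1, n_years + 1):
        state.step_index = year
        demands = acc.compute(annual_matrix, state.landscape.class_counts())
        for t in transitions:
            q = demands.get(t, 0)
            if q == 0:
                continue
            params = (
                patch_params.get(t, default_params)
                if isinstance(patch_params, dict)
                else default_params
            )
            i, j = t
            eligible = state.landscape.class_mask(i)
            if woe_tables and t in woe_tables:
                rate = float(annual_matrix.P[annual_matrix.index_of(i), annual_matrix.index_of(j)])
                prior = min(max(rate, 1e-6), 1 - 1e-6)
                prob = probability_map(woe_tables[t], state.drivers, prior, eligible)
            else:
                prob = eligible.astype(float)
            q_exp = int(round(params.expander_fraction * q))
            unmet_e = expander(state, t, q_exp, prob, params, rng)
            unmet_p = patcher(state, t, q - q_exp + unmet_e, prob, params, rng)
            if unmet_p:
                acc.carry[t] += unmet_p
        update_dynamic_drivers(state)
        if keep_snapshots:
            snapshots.append(state.landscape.copy())
    return SimulationResult(state, snapshots, state.ledger_frame(), dict(acc.carry))
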