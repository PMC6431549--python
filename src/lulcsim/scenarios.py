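"""Scenario construction and projection.

A scenario perturbs the calibrated annual dynamics multiplicatively:
off-diagonal transition rates are scaled per transition, patch parameters
(mean patch size, expander share) are scaled per transition, and selected
classes can be frozen to pure persistence.  The three conventional scenarios
are *stationary* (multipliers 1: history continues unchanged), *optimistic*
(multipliers < 1: conversion pressure reduced) and *pessimistic*
(multipliers > 1: pressure amplified).  The magnitude of "reduced" and
"amplified" is a modeling choice and must be stated with every report; the
package suggests 0.5 and 1.5 as defaults but never applies them silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ca import PatchParams, run_simulation
from .errors import ScenarioInfeasibleError
from .raster import AreaTable, CategoricalLandscape, area_table
from .transition import TransitionMatrix, TransitionWhitelist

__all__ = [
    "ScenarioSpec",
    "apply_scenario",
    "project_scenario",
    "scenario_report",
    "share_change_to_hectares",
]

SUGGESTED_MULTIPLIERS = {"stationary": 1.0, "optimistic": 0.5, "pessimistic": 1.5}


@dataclass
class ScenarioSpec:
    """Multiplicative perturbation of rates and patch dynamics.

    ``rate_multipliers`` maps (from, to) → factor on the annual off-diagonal
    rate (missing pairs default to 1); ``patch_multipliers`` maps
    (from, to) → (mean_patch_size factor, expander_fraction factor);
    ``frozen_classes`` are held to persistence (identity row, and incoming
    mass returned to the senders' diagonals).
    """

    name: str = "custom"
    rate_multipliers: dict[tuple, float] = field(default_factory=dict)
    patch_multipliers: dict[tuple, tuple[float, float]] = field(default_factory=dict)
    frozen_classes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")

    @classmethod
    def uniform(
        cls, name: str, factor: float, transitions, frozen_classes=()
    ) -> "ScenarioSpec":
        """One factor applied to every listed transition's rate and patch size."""
        return cls(
            name=name,
            rate_multipliers={tuple(t): factor for t in transitions},
            patch_multipliers={tuple(t): (factor, 1.0) for t in transitions},
            frozen_classes=set(frozen_classes),
        )

    def scaled_patch_params(self, base: PatchParams, transition) -> PatchParams:
        fs, fe = self.patch_multipliers.get(tuple(transition), (1.0, 1.0))
        return PatchParams(
            mean_patch_size_ha=base.mean_patch_size_ha * fs,
            patch_size_variance_ha2=base.patch_size_variance_ha2 * fs**2,
            isometry=base.isometry,
            expander_fraction=min(base.expander_fraction * fe, 1.0),
        )


def apply_scenario(m: TransitionMatrix, spec: ScenarioSpec) -> TransitionMatrix:
    """Scale off-diagonal rates and refit the diagonal as the remainder.

    Raises :class:`ScenarioInfeasibleError` if a row's scaled off-diagonal
    mass reaches 1 (a negative persistence probability has no meaning).
    """
    P = np.clip(m.P.copy(), 0.0, None)
    order = m.class_order
    k = len(order)
    for i, a in enumerate(order):
        if a in spec.frozen_classes:
            P[i, :] = 0.0
            P[i, i] = 1.0
            continue
        off = 0.0
        for j, b in enumerate(order):
            if i == j:
                continue
            if b in spec.frozen_classes:
                P[i, j] = 0.0
            else:
                P[i, j] *= spec.rate_multipliers.get((a, b), 1.0)
            off += P[i, j]
        if off >= 1.0:
            raise ScenarioInfeasibleError(
                f"scenario {spec.name!r}: off-diagonal mass {off:.4f} >= 1 in row {a}"
            )
        P[i, i] = 1.0 - off
    return TransitionMatrix(P, m.period_years, list(order))


def project_scenario(
    initial: CategoricalLandscape,
    base_annual: TransitionMatrix,
    spec: ScenarioSpec,
    seed: int,
    start_year: int = 2017,
    target_year: int = 2050,
    whitelist: TransitionWhitelist | None = None,
    woe_tables=None,
    drivers=None,
    patch_params: PatchParams | None = None,
):
    """Simulate ``start_year → target_year`` under a perturbed matrix.

    Returns ``(final landscape, AreaTable over both epochs, SimulationResult)``.
    """
    if target_year <= start_year:
        raise ValueError("target_year must be after start_year")
    matrix = apply_scenario(base_annual, spec)
    base_pp = patch_params or PatchParams()
    per_transition = {
        t: spec.scaled_patch_params(base_pp, t)
        for t in spec.rate_multipliers
    }
    result = run_simulation(
        initial,
        matrix,
        n_years=target_year - start_year,
        seed=seed,
        whitelist=whitelist,
        woe_tables=woe_tables,
        drivers=drivers,
        patch_params=per_transition if per_transition else base_pp,
    )
    at = area_table([initial, result.final], [start_year, target_year])
    return result.final, at, result


def share_change_to_hectares(share_a_pct: float, share_b_pct: float, total_area_ha: float) -> float:
    """Hectare change implied by a percentage-share change on a fixed footprint."""
    return (share_b_pct - share_a_pct) / 100.0 * total_area_ha


def scenario_report(
    at_start: AreaTable,
    scenario_tables: dict[str, AreaTable],
    start_epoch,
    end_epoch,
) -> pd.DataFrame:
    """Signed hectare change per class per scenario from share differences.

    ``change_ha = (share_end − share_start)/100 × total footprint``, the
    footprint being the start epoch's total area.
    """
    total = at_start.total_area_ha(start_epoch)
    labels = list(dict.fromkeys(at_start.table["class_label"]))
    rows = []
    for name, at_end in scenario_tables.items():
        for lab in labels:
            rows.append(
                {
                    "scenario": name,
                    "class_label": lab,
                    "change_ha": share_change_to_hectares(
                        at_start.share_pct(lab, start_epoch),
                        at_end.share_pct(lab, end_epoch),
                        total,
                    ),
                }
            )
    return pd.DataFrame(rows)
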