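"""Driver screening (Cramér's V) and Weights-of-Evidence calibration.

Weights of Evidence (WoE) is a Bayesian log-odds method: for a given
transition (e.g. primary forest → cleared land), each driver variable is
discretized into value ranges and every range ``r`` receives a weight

    W⁺(r) = ln[ P(r | change) / P(r | no change) ]

computed over the cells *eligible* for the transition (the from-class at the
start of the period).  Positive W⁺ marks ranges attracting the transition,
negative W⁺ ranges repelling it.  Under conditional independence of the
drivers given the transition, per-cell posterior odds are the prior odds
times ``exp(Σ W⁺)`` over drivers, which yields the transition probability map
the cellular automata allocate change on.

Because WoE assumes driver independence, correlated drivers are screened out
first with Cramér's V: pairs with V above 0.5 are considered associated and
the member with the weaker association to the transition is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import EstimationError

__all__ = [
    "DriverRaster",
    "ContingencyTable",
    "WoETable",
    "bin_edges",
    "cramers_v",
    "screen_drivers",
    "compute_woe",
    "probability_map",
]

DEFAULT_N_BINS = 20


@dataclass
class DriverRaster:
    """Continuous or ordinal explanatory raster.

    ``kind`` is one of ``density`` (features per km²), ``proximity``
    (distance in m) or ``topographic``; ``dynamic`` drivers are recomputed
    every simulation year from an ``update_rule`` such as
    ``("distance_to_class", 4)``.
    """

    values: np.ndarray
    name: str
    kind: str = "proximity"
    dynamic: bool = False
    update_rule: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("density", "proximity", "topographic"):
            raise ValueError(f"unknown driver kind {self.kind!r}")
        if self.dynamic and self.update_rule is None:
            raise ValueError(f"dynamic driver {self.name!r} must declare an update_rule")


@dataclass
class ContingencyTable:
    """Counts plus the χ² machinery feeding Cramér's V."""

    counts: np.ndarray
    chi2: float = field(init=False)
    total: float = field(init=False)
    M: int = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("contingency counts must be non-negative")
        row_ok = counts.sum(axis=1) > 0
        col_ok = counts.sum(axis=0) > 0
        if not row_ok.all() or not col_ok.all():
            warnings.warn("dropping zero-marginal rows/columns before chi-square", stacklevel=2)
            counts = counts[row_ok][:, col_ok]
        if counts.size == 0 or counts.sum() == 0:
            raise ValueError("contingency table is empty")
        self.counts = counts
        self.total = float(counts.sum())
        n, m = counts.shape
        self.M = max(min(n - 1, m - 1), 1)
        if n < 2 or m < 2:
            self.chi2 = 0.0
        else:
            self.chi2 = float(chi2_contingency(counts, correction=False)[0])

    @classmethod
    def from_arrays(cls, x, y) -> "ContingencyTable":
        """Cross-tabulate two discrete arrays of equal length."""
        x = np.asarray(x).ravel()
        y = np.asarray(y).ravel()
        xu, xi = np.unique(x, return_inverse=True)
        yu, yi = np.unique(y, return_inverse=True)
        counts = np.zeros((len(xu), len(yu)))
        np.add.at(counts, (xi, yi), 1)
        return cls(counts)


def cramers_v(ct: ContingencyTable) -> float:
    """Cramér's V = sqrt(χ² / (Γ·M)) in [0, 1].

    Γ is the grand total and M = min(rows−1, cols−1).  No continuity
    correction is applied.  V < 0.5 is conventionally read as independence
    between drivers; V > 0.5 as association warranting removal of one.
    """
    if ct.total <= 0:
        raise ValueError("empty contingency table")
    v = float(np.sqrt(ct.chi2 / (ct.total * ct.M)))
    return min(v, 1.0)


def bin_edges(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-width bin edges over the observed (finite) value range."""
    finite = values[np.isfinite(values)]
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(values, edges[1:-1], right=False)
    return np.clip(idx, 0, len(edges) - 2)


def screen_drivers(
    drivers: list[DriverRaster],
    change_mask: np.ndarray,
    valid_mask: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
    threshold: float = 0.5,
) -> tuple[list[DriverRaster], pd.DataFrame]:
    """Drop the weaker member of every driver pair associated above threshold.

    Drivers are discretized into equal-width bins and cross-tabulated
    pairwise; for each pair with V strictly above ``threshold`` (a tie at the
    threshold is retained), the member with the lower V against the
    change/no-change indicator is dropped.  Returns the retained drivers and
    a report of dropped pairs.
    """
    if len(drivers) < 2:
        raise ValueError("screening needs at least two drivers")
    valid = np.ones(drivers[0].values.shape, bool) if valid_mask is None else valid_mask
    binned = {d.name: _digitize(d.values[valid], bin_edges(d.values[valid], n_bins)) for d in drivers}
    target = np.asarray(change_mask, bool)[valid].astype(int)

    def v_between(a, b) -> float:
        return cramers_v(ContingencyTable.from_arrays(a, b))

    strength = {d.name: v_between(binned[d.name], target) for d in drivers}
    retained = list(drivers)
    dropped_rows = []
    while True:
        worst = None
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                v = v_between(binned[retained[i].name], binned[retained[j].name])
                if v > threshold and (worst is None or v > worst[0]):
                    worst = (v, i, j)
        if worst is None:
            break
        v, i, j = worst
        di, dj = retained[i], retained[j]
        # drop the one with weaker association to the transition
        loser = dj if strength[di.name] >= strength[dj.name] else di
        keeper = di if loser is dj else dj
        dropped_rows.append(
            {"dropped": loser.name, "kept": keeper.name, "pair_v": v,
             "dropped_target_v": strength[loser.name], "kept_target_v": strength[keeper.name]}
        )
        retained = [d for d in retained if d is not loser]
    report = pd.DataFrame(dropped_rows, columns=["dropped", "kept", "pair_v", "dropped_target_v", "kept_target_v"])
    return retained, report


@dataclass
class WoETable:
    """Per-bin W⁺ weights of one driver for one transition."""

    transition: tuple[int, int]
    driver_name: str
    edges: np.ndarray
    w_plus: np.ndarray
    n_change: np.ndarray
    n_nochange: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.w_plus = np.asarray(self.w_plus, dtype=float)
        if len(self.w_plus) != len(self.edges) - 1:
            raise ValueError("need one weight per bin")
        if not np.isfinite(self.w_plus).all():
            raise ValueError("weights must be finite after smoothing")

    def weight_at(self, values: np.ndarray) -> np.ndarray:
        """W⁺ looked up per cell (values outside the range clip to end bins)."""
        return self.w_plus[_digitize(values, self.edges)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transition": [f"{self.transition[0]}->{self.transition[1]}"] * len(self.w_plus),
                "driver": self.driver_name,
                "bin_lo": self.edges[:-1],
                "bin_hi": self.edges[1:],
                "n_change": self.n_change,
                "n_nochange": self.n_nochange,
                "w_plus": self.w_plus,
            }
        )


def compute_woe(
    change_mask: np.ndarray,
    eligible_mask: np.ndarray,
    driver: DriverRaster,
    bins: int | np.ndarray = DEFAULT_N_BINS,
    transition: tuple[int, int] = (0, 0),
) -> WoETable:
    """Weights of Evidence of one driver for one transition.

    ``change_mask`` flags the eligible cells that underwent the transition;
    weights are W⁺(r) = ln[(n(r∧D)/n(D)) / (n(r∧¬D)/n(¬D))].  When a bin's
    2×2 table contains a zero count, 0.5 is added to all four of its counts
    (additive smoothing), keeping weights finite on sparse transitions.
    """
    change_mask = np.asarray(change_mask, bool)
    eligible_mask = np.asarray(eligible_mask, bool)
    if not eligible_mask.any():
        raise EstimationError("empty eligible mask")
    if (change_mask & ~eligible_mask).any():
        raise ValueError("change_mask must be a subset of eligible_mask")
    d_vals = driver.values[eligible_mask]
    d_chg = change_mask[eligible_mask]
    n_d = int(d_chg.sum())
    n_nd = int((~d_chg).sum())
    if n_d == 0 or n_nd == 0:
        raise EstimationError("need at least one changed and one unchanged eligible cell")
    edges = bins if isinstance(bins, np.ndarray) else bin_edges(d_vals, int(bins))
    idx = _digitize(d_vals, edges)
    nbins = len(edges) - 1
    a = np.bincount(idx[d_chg], minlength=nbins).astype(float)      # r ∧ D
    c = np.bincount(idx[~d_chg], minlength=nbins).astype(float)     # r ∧ ¬D
    b = n_d - a                                                     # ¬r ∧ D
    dd = n_nd - c                                                   # ¬r ∧ ¬D
    w = np.empty(nbins)
    for r in range(nbins):
        ar, br, cr, dr = a[r], b[r], c[r], dd[r]
        if min(ar, br, cr, dr) == 0:
            ar, br, cr, dr = ar + 0.5, br + 0.5, cr + 0.5, dr + 0.5
        w[r] = np.log((ar / (ar + br)) / (cr / (cr + dr)))
    return WoETable(transition, driver.name, edges, w, a.astype(int), c.astype(int))


def probability_map(
    tables: list[WoETable],
    drivers: dict[str, DriverRaster],
    prior: float,
    eligible_mask: np.ndarray,
) -> np.ndarray:
    """Per-cell transition probability from prior odds and summed weights.

    ``odds = prior/(1−prior) · exp(Σ W⁺)``; ``P = odds/(1+odds)``.  Cells
    outside the from-class (``eligible_mask``) get probability 0.  All tables
    must describe the same transition.
    """
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    transitions = {t.transition for t in tables}
    if len(transitions) > 1:
        raise ValueError(f"tables mix transitions {transitions}")
    shape = np.asarray(eligible_mask).shape
    logodds = np.full(shape, np.log(prior / (1 - prior)))
    for t in tables:
        if t.driver_name not in drivers:
            raise ValueError(f"driver {t.driver_name!r} missing")
        logodds += t.weight_at(drivers[t.driver_name].values)
    odds = np.exp(logodds)
    p = odds / (1 + odds)
    p[~np.asarray(eligible_mask, bool)] = 0.0
    return p
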