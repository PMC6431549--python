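"""Synthetic landscapes, drivers and transition histories with known truth.

No land-cover maps are distributed with the package, so every stage is
exercised on generated data whose parameters are known exactly:

* :func:`gen_landscape` — spatially autocorrelated categorical maps built by
  thresholding Gaussian-smoothed noise at share-matching quantiles, emulating
  the patchy geometry of classified Landsat scenes.
* :func:`gen_drivers` — the three driver families used in deforestation
  modeling: kernel-density surfaces (features per km²), proximity surfaces
  (exact Euclidean distance to seeded point/line features) and topographic
  surfaces (fractal elevation with derived slope in degrees and topographic
  position index).
* :func:`simulate_history` — a yearly landscape series whose aggregate
  dynamics follow a known annual Markov matrix and whose spatial allocation
  follows planted Weights-of-Evidence effects, so estimation code can be
  checked for parameter recovery.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .raster import CategoricalLandscape
from .transition import TransitionMatrix
from .woe import DriverRaster

__all__ = [
    "DriverSpec",
    "PlantedEffect",
    "SyntheticConfig",
    "DEFAULT_CLASS_LABELS",
    "gen_landscape",
    "gen_drivers",
    "simulate_history",
]

DEFAULT_CLASS_LABELS = {1: "PF", 2: "SF", 3: "HS", 4: "AWV", 5: "WB"}


@dataclass
class DriverSpec:
    """Recipe for one synthetic driver raster.

    ``family`` is ``density``, ``proximity`` or ``topographic``; ``params``
    hold family-specific knobs (n_features, kernel sigma, octaves, ...).
    """

    name: str
    family: str
    params: dict = field(default_factory=dict)
    dynamic: bool = False
    update_rule: tuple | None = None


@dataclass
class PlantedEffect:
    """A known WoE effect: log-odds ``weight`` where the driver value falls
    in the quantile band [q_lo, q_hi) of its distribution over eligible cells."""

    transition: tuple[int, int]
    driver: str
    q_lo: float
    q_hi: float
    weight: float


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic study.

    Defaults mirror a Landsat-like setting: 200×200 cells of 30 m, five
    classes dominated by primary/secondary forest, and patch sizes controlled
    by a 5-cell autocorrelation length.
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    class_shares: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.40, 3: 0.005, 4: 0.04, 5: 0.005}
    )
    class_labels: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_LABELS))
    autocorr_length: float = 5.0
    driver_specs: list[DriverSpec] = field(default_factory=list)
    true_annual_matrix: TransitionMatrix | None = None
    true_effects: list[PlantedEffect] = field(default_factory=list)
    n_years: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class shares sum to {total}, not 1")
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")


def gen_landscape(cfg: SyntheticConfig) -> CategoricalLandscape:
    """Autocorrelated categorical landscape with share-matching quantiles.

    Gaussian-filtered white noise is thresholded at the cumulative-share
    quantiles of its empirical distribution, so realized shares match the
    request up to in-cell ties; ``autocorr_length`` (cells) sets the Gaussian
    sigma and hence typical patch size.  ``autocorr_length 0`` gives spatially
    independent cells.
    """
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal(cfg.shape)
    if cfg.autocorr_length > 0:
        noise = ndimage.gaussian_filter(noise, cfg.autocorr_length)
    codes = list(cfg.class_shares)
    shares = np.array([cfg.class_shares[c] for c in codes])
    cuts = np.quantile(noise, np.cumsum(shares)[:-1])
    values = np.full(cfg.shape, codes[-1], dtype=np.int32)
    bins = np.digitize(noise, cuts)
    for k, code in enumerate(codes):
        values[bins == k] = code
    return CategoricalLandscape(values, None, cfg.cell_size, dict(cfg.class_labels))


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------


def _seed_features(shape, n: int, rng, as_lines: bool) -> np.ndarray:
    """Boolean raster of n random points, or n rasterized random segments."""
    mask = np.zeros(shape, dtype=bool)
    nrows, ncols = shape
    if not as_lines:
        r = rng.integers(0, nrows, n)
        c = rng.integers(0, ncols, n)
        mask[r, c] = True
        return mask
    for _ in range(n):
        r0, c0 = rng.integers(0, nrows), rng.integers(0, ncols)
        r1, c1 = rng.integers(0, nrows), rng.integers(0, ncols)
        length = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
        rr = np.linspace(r0, r1, length).round().astype(int)
        cc = np.linspace(c0, c1, length).round().astype(int)
        mask[rr, cc] = True
    return mask


def _fractal_elevation(shape, rng, octaves: int = 4, base_sigma: float = 32.0) -> np.ndarray:
    elev = np.zeros(shape)
    sigma, amp = base_sigma, 1.0
    for _ in range(octaves):
        elev += amp * ndimage.gaussian_filter(rng.standard_normal(shape), max(sigma, 0.5))
        sigma /= 2.0
        amp /= 2.0
    elev -= elev.min()
    span = elev.max() or 1.0
    return 1000.0 + 1500.0 * elev / span  # plausible sierra elevations, meters


def slope_degrees(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Slope from central differences, in degrees."""
    dzdy, dzdx = np.gradient(elevation, cell_size)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def topographic_position_index(elevation: np.ndarray, radius: int = 5) -> np.ndarray:
    """Elevation minus the neighborhood mean within a square window."""
    size = 2 * radius + 1
    return elevation - ndimage.uniform_filter(elevation, size=size, mode="nearest")


def gen_drivers(
    cfg: SyntheticConfig, landscape: CategoricalLandscape
) -> dict[str, DriverRaster]:
    """Generate the configured driver rasters (or a standard default set).

    Defaults: a road-proximity surface (line features), a settlement-density
    surface (points, kernel-smoothed to features/km²), and elevation with
    derived slope and TPI.  Class-anchored dynamic drivers (e.g. distance to
    cleared areas) are computed from the landscape.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    specs = cfg.driver_specs or [
        DriverSpec("dist_roads", "proximity", {"n_features": 4, "lines": True}),
        DriverSpec("dens_settlements", "density", {"n_features": 25, "sigma": 8.0}),
        DriverSpec("elevation", "topographic", {"derive": "elevation"}),
        DriverSpec("slope", "topographic", {"derive": "slope"}),
        DriverSpec("tpi", "topographic", {"derive": "tpi", "radius": 5}),
    ]
    out: dict[str, DriverRaster] = {}
    elevation = None
    for spec in specs:
        p = spec.params
        if spec.family == "proximity":
            if spec.update_rule and spec.update_rule[0] == "distance_to_class":
                mask = landscape.class_mask(int(spec.update_rule[1]))
            else:
                mask = _seed_features(cfg.shape, p.get("n_features", 5), rng, p.get("lines", False))
            vals = (
                ndimage.distance_transform_edt(~mask) * cfg.cell_size
                if mask.any()
                else np.full(cfg.shape, np.inf)
            )
        elif spec.family == "density":
            pts = _seed_features(cfg.shape, p.get("n_features", 20), rng, False)
            sigma = p.get("sigma", 8.0)
            smoothed = ndimage.gaussian_filter(pts.astype(float), sigma)
            cell_km2 = (cfg.cell_size / 1000.0) ** 2
            vals = smoothed / cell_km2
        elif spec.family == "topographic":
            if elevation is None:
                elevation = _fractal_elevation(cfg.shape, rng, p.get("octaves", 4))
            derive = p.get("derive", "elevation")
            if derive == "elevation":
                vals = elevation.copy()
            elif derive == "slope":
                vals = slope_degrees(elevation, cfg.cell_size)
            elif derive == "tpi":
                vals = topographic_position_index(elevation, p.get("radius", 5))
            else:
                raise ConfigurationError(f"unknown topographic derivative {derive!r}")
        else:
            raise ConfigurationError(f"unknown driver family {spec.family!r}")
        out[spec.name] = DriverRaster(vals, spec.name, spec.family if spec.family != "topographic" else "topographic", spec.dynamic, spec.update_rule)
    return out


# ---------------------------------------------------------------------------
# Known-parameter transition history
# ---------------------------------------------------------------------------


def _effect_multiplier(
    effects: list[PlantedEffect],
    transition: tuple[int, int],
    drivers: dict[str, DriverRaster],
    eligible: np.ndarray,
) -> np.ndarray:
    """Per-eligible-cell odds multiplier exp(Σ planted weights)."""
    logw = np.zeros(int(eligible.sum()))
    for eff in effects:
        if tuple(eff.transition) != tuple(transition):
            continue
        vals = drivers[eff.driver].values[eligible]
        lo = np.quantile(vals, eff.q_lo)
        hi = np.quantile(vals, eff.q_hi)
        inside = (vals >= lo) & (vals < hi) if eff.q_hi < 1 else (vals >= lo)
        logw[inside] += eff.weight
    return np.exp(logw)


def simulate_history(
    initial: CategoricalLandscape,
    true_matrix: TransitionMatrix,
    effects: list[PlantedEffect],
    drivers: dict[str, DriverRaster],
    n_years: int,
    seed: int,
) -> list[CategoricalLandscape]:
    """Yearly series following a known matrix and planted WoE effects.

    Each year, each cell of class ``i`` moves to class ``j`` with probability
    ``P[i,j] · m_c / mean(m)`` where ``m_c`` is the cell's planted odds
    multiplier; the empirical renormalization by ``mean(m)`` keeps the
    aggregate expected demand equal to the Markov matrix regardless of the
    planted spatial structure.  Returns ``n_years + 1`` landscapes including
    the initial one.
    """
    if true_matrix.period_years != 1:
        raise ValueError("simulate_history needs an annual matrix")
    rng = np.random.default_rng(seed)
    series = [initial.copy()]
    current = initial.copy()
    order = true_matrix.class_order
    for _ in range(n_years):
        new_values = current.values.copy()
        for i_code in order:
            i = true_matrix.index_of(i_code)
            eligible = current.class_mask(i_code)
            n_el = int(eligible.sum())
            if n_el == 0:
                continue
            probs = np.zeros((n_el, len(order)))
            for j, j_code in enumerate(order):
                if j_code == i_code:
                    continue
                rate = max(float(true_matrix.P[i, j]), 0.0)
                if rate == 0.0:
                    continue
                mult = _effect_multiplier(effects, (i_code, j_code), drivers, eligible)
                probs[:, j] = rate * mult / mult.mean()
            total = probs.sum(axis=1)
            over = total > 1.0
            if over.any():  # extreme planted odds; cap the move probability
                probs[over] /= total[over, None]
            stay = 1.0 - probs.sum(axis=1)
            full = np.column_stack([probs, stay])
            u = rng.random(n_el)
            choice = (u[:, None] >= np.cumsum(full, axis=1)).sum(axis=1)
            dest = np.where(
                choice >= len(order),
                i_code,
                np.array(order, dtype=int)[np.minimum(choice, len(order) - 1)],
            )
            new_values[eligible] = dest
        current = CategoricalLandscape(
            new_values, current.nodata_mask.copy(), current.cell_size, dict(current.class_labels)
        )
        series.append(current)
    return series
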