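"""Config-driven orchestration of the full change-analysis study.

The three commands mirror the study workflow: change accounting between
classified epochs, scenario simulation to a target year, and validation of a
simulated map against a reference.  Every command is re-runnable — the same
config and seed produce byte-identical CSV outputs — and writes a manifest
recording the seed, parameters, config hash and package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ca import PatchParams
from .errors import ComparabilityError, ConfigurationError
from .raster import (
    AreaTable,
    CategoricalLandscape,
    change_type_map,
    net_change,
    read_landscape,
    write_landscape,
)
from .scenarios import ScenarioSpec, project_scenario, scenario_report
from .transition import (
    TransitionWhitelist,
    annualize,
    estimate_matrix,
    restrict,
    write_matrix_csv,
)
from .raster import crosstab
from .validation import fuzzy_similarity, kappa, similarity_curve

__all__ = ["RunConfig", "cmd_change_analysis", "cmd_simulate", "cmd_validate"]


@dataclass
class RunConfig:
    """Study configuration: input epochs, whitelist, scenarios, seed."""

    map_paths: list[str] = field(default_factory=list)
    epochs: list[int] = field(default_factory=list)
    driver_paths: dict[str, str] = field(default_factory=dict)
    whitelist: list[tuple[int, int]] = field(default_factory=list)
    n_bins: int = 20
    scenarios: dict[str, dict] = field(default_factory=dict)
    target_year: int = 2050
    out_dir: str = "out"
    seed: int = 0
    cell_size: float | None = None
    class_labels: dict[int, str] = field(default_factory=dict)
    patch: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.epochs and list(self.epochs) != sorted(set(self.epochs)):
            raise ConfigurationError("epochs must be strictly increasing")
        if len(self.map_paths) != len(self.epochs):
            raise ConfigurationError("map_paths and epochs differ in length")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["whitelist"] = [tuple(p) for p in raw.get("whitelist", [])]
        raw["class_labels"] = {int(k): v for k, v in raw.get("class_labels", {}).items()}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def load_maps(self) -> list[CategoricalLandscape]:
        maps = [
            read_landscape(p, cell_size=self.cell_size, class_labels=self.class_labels or None)
            for p in self.map_paths
        ]
        for prev, cur, pa, pb in zip(maps, maps[1:], self.map_paths, self.map_paths[1:]):
            if not prev.comparable(cur):
                raise ComparabilityError(f"rasters misaligned: {pa} vs {pb}")
        return maps

    def patch_params(self) -> PatchParams:
        return PatchParams(**self.patch) if self.patch else PatchParams()


def _write_manifest(out: Path, config: RunConfig, extra: dict | None = None) -> None:
    manifest = {
        "package": "lulcsim",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    manifest.update(extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def cmd_change_analysis(config: RunConfig) -> AreaTable:
    """Area/share accounting, net change and change-type maps for all epochs."""
    if len(config.epochs) < 2:
        raise ConfigurationError("change analysis needs at least two epochs")
    maps = config.load_maps()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    at = AreaTable.from_landscapes(maps, config.epochs)
    at.to_csv(out / "area_table.csv")
    rows = []
    for (ea, ma), (eb, mb) in zip(
        zip(config.epochs, maps), zip(config.epochs[1:], maps[1:])
    ):
        nc = net_change(at, ea, eb)
        for lab, ha in nc.items():
            rows.append({"class_label": lab, "period": f"{ea}-{eb}", "change_ha": ha})
        cmap, totals = change_type_map(ma, mb)
        write_landscape(cmap, out / f"change_types_{ea}_{eb}.asc")
        totals.rename_axis("category").to_frame("area_ha").to_csv(
            out / f"change_type_totals_{ea}_{eb}.csv"
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "net_change.csv", index=False)
    _write_manifest(out, config, {"command": "change", "epochs": config.epochs})
    return at


def cmd_simulate(config: RunConfig, scenario: str) -> dict:
    """Calibrate on the historical period, then project one scenario.

    The matrix is estimated from the first and last epoch maps, annualized,
    and restricted to the configured whitelist; the scenario's multipliers
    perturb it before the CA run to the target year.
    """
    maps = config.load_maps()
    if len(maps) < 2:
        raise ConfigurationError("simulation needs a two-epoch history")
    spec_raw = config.scenarios.get(scenario)
    if spec_raw is None:
        raise ConfigurationError(f"scenario {scenario!r} not in config")
    first, last = maps[0], maps[-1]
    period = config.epochs[-1] - config.epochs[0]
    wl = TransitionWhitelist(set(config.whitelist)) if config.whitelist else None
    m = estimate_matrix(crosstab(first, last), period)
    annual = annualize(m)
    if wl is not None:
        annual = restrict(annual, wl)
    factor = float(spec_raw.get("factor", 1.0))
    transitions = config.whitelist or [
        (a, b) for a in m.class_order for b in m.class_order if a != b
    ]
    spec = ScenarioSpec.uniform(
        scenario, factor, transitions,
        frozen_classes=set(spec_raw.get("frozen_classes", [])),
    )
    out = Path(config.out_dir) / scenario
    out.mkdir(parents=True, exist_ok=True)
    final, at, result = project_scenario(
        last,
        annual,
        spec,
        seed=config.seed,
        start_year=config.epochs[-1],
        target_year=config.target_year,
        whitelist=wl,
        patch_params=config.patch_params(),
    )
    write_matrix_csv(annual, out / "annual_matrix.csv", last.class_labels)
    at.to_csv(out / "area_table.csv")
    report = scenario_report(at, {scenario: at}, config.epochs[-1], config.target_year)
    report.to_csv(out / "change_report.csv", index=False)
    result.ledger.to_csv(out / "ledger.csv", index=False)
    write_landscape(final, out / f"landscape_{config.target_year}.asc")
    _write_manifest(
        out,
        config,
        {
            "command": "simulate",
            "scenario": scenario,
            "rate_multiplier": factor,
            "frozen_classes": sorted(spec.frozen_classes),
            "patch_params": config.patch_params().__dict__,
        },
    )
    return {"final": final, "area_table": at, "report": report, "result": result}


def cmd_validate(config: RunConfig, observed_path, simulated_path, max_window: int = 7):
    """Kappa plus the fuzzy-similarity curve between two maps."""
    obs = read_landscape(observed_path, cell_size=config.cell_size,
                         class_labels=config.class_labels or None)
    sim = read_landscape(simulated_path, cell_size=config.cell_size,
                         class_labels=config.class_labels or None)
    kr = kappa(obs, sim)
    fr = fuzzy_similarity(obs, sim, max_window=max_window)
    curve = similarity_curve(fr)
    curve["kappa"] = kr.kappa
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve.to_csv(out / "validation.csv", index=False)
    _write_manifest(out, config, {"command": "validate", "max_window": max_window})
    return kr, fr
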