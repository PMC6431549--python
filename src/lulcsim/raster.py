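"""Categorical raster data model, I/O and change accounting.

The unit of analysis is a :class:`CategoricalLandscape`: an integer-coded
land-use/land-cover (LULC) map on a regular square grid with an explicit
nodata mask.  All maps taking part in a change analysis must be *comparable*
(same shape, cell size and nodata footprint); the package performs no
reprojection or resampling — inputs are assumed co-registered, as is standard
for single-footprint Landsat time series.

Areas are reported in hectares: ``cells × cell_size² / 10 000``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ComparabilityError, RasterFormatError

__all__ = [
    "CategoricalLandscape",
    "TransitionCounts",
    "AreaTable",
    "read_landscape",
    "write_landscape",
    "crosstab",
    "area_table",
    "net_change",
    "annualized_rate",
    "change_type_map",
    "DEFAULT_CHANGE_RULES",
]

M2_PER_HA = 10_000.0


@dataclass
class CategoricalLandscape:
    """Integer-coded LULC raster with a nodata mask.

    Parameters
    ----------
    values
        2-D integer array of class codes (row-major, 0-based indexing).
    nodata_mask
        Boolean array, ``True`` where the cell carries no data.
    cell_size
        Cell edge length in meters (square cells); Landsat default 30 m.
    class_labels
        Mapping from class code to short label, e.g. ``{1: "PF", 2: "SF"}``.
    """

    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    cell_size: float = 30.0
    class_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("landscape values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise RasterFormatError(
                f"class codes must be integers, got dtype {self.values.dtype}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata mask shape differs from values shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not self.class_labels:
            codes = np.unique(self.values[~self.nodata_mask])
            self.class_labels = {int(c): str(int(c)) for c in codes}
        else:
            present = set(np.unique(self.values[~self.nodata_mask]).tolist())
            unknown = present - set(self.class_labels)
            if unknown:
                raise ValueError(f"codes {sorted(unknown)} missing from class_labels")

    # -- basic geometry ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / M2_PER_HA

    def comparable(self, other: "CategoricalLandscape") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and bool(np.array_equal(self.nodata_mask, other.nodata_mask))
        )

    # -- class accounting --------------------------------------------------
    def class_counts(self) -> dict[int, int]:
        """Valid-cell count per class code (codes absent from the map → 0)."""
        valid = self.values[~self.nodata_mask]
        out = {code: 0 for code in self.class_labels}
        codes, counts = np.unique(valid, return_counts=True)
        for c, n in zip(codes.tolist(), counts.tolist()):
            out[int(c)] = int(n)
        return out

    def class_shares(self) -> dict[int, float]:
        """Fraction of valid cells per class code."""
        n = self.n_valid
        return {c: (k / n if n else 0.0) for c, k in self.class_counts().items()}

    def class_mask(self, code: int) -> np.ndarray:
        return (self.values == code) & ~self.nodata_mask

    def copy(self) -> "CategoricalLandscape":
        return CategoricalLandscape(
            self.values.copy(),
            self.nodata_mask.copy(),
            self.cell_size,
            dict(self.class_labels),
        )

    def label(self, code: int) -> str:
        return self.class_labels.get(int(code), str(int(code)))


@dataclass
class TransitionCounts:
    """Cross-tabulation of two comparable maps.

    ``counts[i, j]`` is the number of cells with ``class_order[i]`` in the
    earlier map and ``class_order[j]`` in the later one; masked cells in
    either map are excluded.
    """

    counts: np.ndarray
    class_order: list[int]
    n_valid: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("transition counts must be non-negative")
        if int(self.counts.sum()) != self.n_valid:
            raise ValueError("counts do not sum to n_valid")

    def to_frame(self, labels: dict[int, str] | None = None) -> pd.DataFrame:
        names = [labels.get(c, str(c)) if labels else str(c) for c in self.class_order]
        return pd.DataFrame(self.counts, index=names, columns=names)


def crosstab(a: CategoricalLandscape, b: CategoricalLandscape) -> TransitionCounts:
    """Cell-by-cell cross-tabulation of two comparable landscapes."""
    if not a.comparable(b):
        raise ComparabilityError(
            f"maps are not comparable: shape {a.shape} vs {b.shape}, "
            f"cell_size {a.cell_size} vs {b.cell_size}, or differing masks"
        )
    valid = ~(a.nodata_mask | b.nodata_mask)
    order = sorted(set(a.class_labels) | set(b.class_labels))
    index = {c: i for i, c in enumerate(order)}
    k = len(order)
    av = np.vectorize(index.get, otypes=[np.int64])(a.values[valid]) if valid.any() else np.empty(0, np.int64)
    bv = np.vectorize(index.get, otypes=[np.int64])(b.values[valid]) if valid.any() else np.empty(0, np.int64)
    flat = np.bincount(av * k + bv, minlength=k * k)
    counts = flat.reshape(k, k)
    return TransitionCounts(counts, order, int(valid.sum()))


# ---------------------------------------------------------------------------
# Area accounting
# ---------------------------------------------------------------------------


@dataclass
class AreaTable:
    """Tidy per-class, per-epoch area accounting.

    ``table`` has columns ``class_code, class_label, epoch, area_ha,
    share_pct``; shares within an epoch sum to 100.
    """

    table: pd.DataFrame

    REQUIRED = ("class_code", "class_label", "epoch", "area_ha", "share_pct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"AreaTable missing columns {missing}")
        for epoch, grp in self.table.groupby("epoch"):
            s = grp["share_pct"].sum()
            if abs(s - 100.0) > 0.01 and grp["area_ha"].sum() > 0:
                raise ValueError(f"shares for epoch {epoch!r} sum to {s}, not 100")

    @classmethod
    def from_landscapes(
        cls, maps: list[CategoricalLandscape], epochs: list
    ) -> "AreaTable":
        if not maps:
            raise ValueError("need at least one landscape")
        if len(maps) != len(epochs):
            raise ValueError("maps and epoch labels differ in length")
        first = maps[0]
        for m in maps[1:]:
            if not first.comparable(m):
                raise ComparabilityError("landscapes in an area table must be comparable")
        rows = []
        for m, epoch in zip(maps, epochs):
            counts = m.class_counts()
            total = sum(counts.values())
            for code in sorted(counts):
                n = counts[code]
                rows.append(
                    {
                        "class_code": code,
                        "class_label": m.label(code),
                        "epoch": epoch,
                        "area_ha": n * m.cell_area_ha,
                        "share_pct": (100.0 * n / total) if total else 0.0,
                    }
                )
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_areas(
        cls, areas_ha: dict, class_labels: dict[int, str] | None = None
    ) -> "AreaTable":
        """Build from published per-epoch hectare totals.

        ``areas_ha`` maps epoch → {class label (or code): hectares}.  Shares
        are recomputed from the hectare column, which is how percentage
        columns in published LULC accounting tables are derived.
        """
        label_to_code = {v: k for k, v in (class_labels or {}).items()}
        rows = []
        for epoch, perclass in areas_ha.items():
            total = float(sum(perclass.values()))
            for key, ha in perclass.items():
                code = label_to_code.get(key, key if isinstance(key, int) else -1)
                rows.append(
                    {
                        "class_code": code,
                        "class_label": str(key),
                        "epoch": epoch,
                        "area_ha": float(ha),
                        "share_pct": 100.0 * float(ha) / total if total else 0.0,
                    }
                )
        return cls(pd.DataFrame(rows))

    # -- lookups -----------------------------------------------------------
    def epochs(self) -> list:
        return list(dict.fromkeys(self.table["epoch"]))

    def _sel(self, epoch) -> pd.DataFrame:
        sub = self.table[self.table["epoch"] == epoch]
        if sub.empty:
            raise ValueError(f"unknown epoch {epoch!r}")
        return sub

    def area_ha(self, class_label: str, epoch) -> float:
        sub = self._sel(epoch)
        row = sub[sub["class_label"] == class_label]
        if row.empty:
            return 0.0
        return float(row["area_ha"].iloc[0])

    def share_pct(self, class_label: str, epoch) -> float:
        sub = self._sel(epoch)
        row = sub[sub["class_label"] == class_label]
        if row.empty:
            return 0.0
        return float(row["share_pct"].iloc[0])

    def total_area_ha(self, epoch) -> float:
        return float(self._sel(epoch)["area_ha"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, columns=["class_label", "epoch", "area_ha", "share_pct"])


def area_table(maps: list[CategoricalLandscape], epochs: list) -> AreaTable:
    """Hectares and percentage shares per class per epoch."""
    return AreaTable.from_landscapes(maps, epochs)


def net_change(at: AreaTable, epoch_a, epoch_b) -> pd.Series:
    """Signed hectare difference ``area(epoch_b) − area(epoch_a)`` per class.

    Over all classes the differences sum to ~0 on a closed (fixed-footprint)
    landscape.
    """
    a = at._sel(epoch_a).set_index("class_label")["area_ha"]
    b = at._sel(epoch_b).set_index("class_label")["area_ha"]
    return (b.reindex(a.index.union(b.index), fill_value=0.0)
            - a.reindex(a.index.union(b.index), fill_value=0.0))


def annualized_rate(at: AreaTable, class_label: str, epoch_a, epoch_b, years: float) -> float:
    """Annualized percent rate of change ``((A2/A1)^(1/Δt) − 1)·100``.

    A convenience helper; published LULC tables often carry rate columns with
    unstated formulas, so any comparison against such columns is the user's
    responsibility.
    """
    a1 = at.area_ha(class_label, epoch_a)
    a2 = at.area_ha(class_label, epoch_b)
    if a1 <= 0:
        return float("nan")
    return ((a2 / a1) ** (1.0 / years) - 1.0) * 100.0


# ---------------------------------------------------------------------------
# Change typing (deforestation / degradation / recovery)
# ---------------------------------------------------------------------------

CHANGE_CATEGORIES = {0: "Stable", 1: "Deforestation", 2: "Degradation", 3: "Recovery", 4: "Other"}

# Default from→to category rules for the 5-class forest legend:
# primary forest to cleared/built land is deforestation, canopy thinning to
# secondary forest is degradation, and the reverse succession is recovery.
DEFAULT_CHANGE_RULES = {
    ("PF", "AWV"): "Deforestation",
    ("PF", "HS"): "Deforestation",
    ("PF", "SF"): "Degradation",
    ("SF", "PF"): "Recovery",
}


def change_type_map(
    a: CategoricalLandscape,
    b: CategoricalLandscape,
    rules: dict[tuple[str, str], str] | None = None,
) -> tuple[CategoricalLandscape, pd.Series]:
    """Categorize each cell's transition and total hectares per category.

    Unlisted from→to pairs fall to ``Other``; unchanged cells are ``Stable``.
    Returns the category map plus a hectare total per category.
    """
    if not a.comparable(b):
        raise ComparabilityError("change_type_map requires comparable maps")
    rules = DEFAULT_CHANGE_RULES if rules is None else rules
    cat_code = {v: k for k, v in CHANGE_CATEGORIES.items()}
    out = np.zeros(a.shape, dtype=np.int32)
    valid = ~(a.nodata_mask | b.nodata_mask)
    changed = valid & (a.values != b.values)
    out[changed] = cat_code["Other"]
    for (lab_from, lab_to), category in rules.items():
        code_from = next((c for c, l in a.class_labels.items() if l == lab_from), None)
        code_to = next((c for c, l in b.class_labels.items() if l == lab_to), None)
        if code_from is None or code_to is None:
            continue
        sel = changed & (a.values == code_from) & (b.values == code_to)
        out[sel] = cat_code[category]
    landscape = CategoricalLandscape(
        out, ~valid, a.cell_size, dict(CHANGE_CATEGORIES)
    )
    counts = landscape.class_counts()
    totals = pd.Series(
        {CHANGE_CATEGORIES[c]: n * a.cell_area_ha for c, n in counts.items()}
    )
    return landscape, totals


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid and single-band GeoTIFF
# ---------------------------------------------------------------------------

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922
_GDAL_NODATA = 42113


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt", ".grd"):
        return "ascii_grid"
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    raise RasterFormatError(f"cannot infer raster format from {path.name!r}")


def read_landscape(
    path,
    format: str | None = None,
    cell_size: float | None = None,
    class_labels: dict[int, str] | None = None,
) -> CategoricalLandscape:
    """Read a single-band integer raster as a :class:`CategoricalLandscape`.

    ``format`` is ``"ascii_grid"`` or ``"geotiff"`` (inferred from the file
    suffix when omitted).  Class codes are preserved bit-exactly; a non-integer
    band raises :class:`RasterFormatError`.  A GeoTIFF without georeferencing
    tags is read with a warning and the default 30 m cell size.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        values, mask, cs = _read_ascii_grid(path)
    elif fmt == "geotiff":
        values, mask, cs = _read_geotiff(path)
    else:
        raise RasterFormatError(f"unknown raster format {fmt!r}")
    if cell_size is not None:
        cs = cell_size
    return CategoricalLandscape(values, mask, cs, class_labels or {})


def write_landscape(landscape: CategoricalLandscape, path, format: str | None = None) -> None:
    """Write a landscape as an ESRI ASCII grid or single-band GeoTIFF."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        _write_ascii_grid(landscape, path)
    elif fmt == "geotiff":
        _write_geotiff(landscape, path)
    else:
        raise RasterFormatError(f"unknown raster format {fmt!r}")


_ASCII_NODATA = -9999


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, np.ndarray, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
            "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise RasterFormatError(f"{path.name}: missing ncols/nrows header")
    tokens = "\n".join(lines[i:]).split()
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if len(tokens) != nrows * ncols:
        raise RasterFormatError(
            f"{path.name}: expected {nrows * ncols} cells, found {len(tokens)}"
        )
    try:
        values = np.array(tokens).astype(np.int64)
    except ValueError as exc:
        raise RasterFormatError(f"{path.name}: non-integer class codes") from exc
    values = values.reshape(nrows, ncols)
    nodata = int(header.get("nodata_value", _ASCII_NODATA))
    mask = values == nodata
    cs = float(header.get("cellsize", 30.0))
    return values.astype(np.int32), mask, cs


def _write_ascii_grid(landscape: CategoricalLandscape, path: Path) -> None:
    nrows, ncols = landscape.shape
    vals = landscape.values.copy()
    vals[landscape.nodata_mask] = _ASCII_NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {landscape.cell_size:g}\n")
        fh.write(f"NODATA_value {_ASCII_NODATA}\n")
        for row in vals:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def _read_geotiff(path: Path) -> tuple[np.ndarray, np.ndarray, float]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise RasterFormatError(f"{path.name}: expected a single-band raster")
        if not np.issubdtype(values.dtype, np.integer):
            raise RasterFormatError(
                f"{path.name}: non-integer band ({values.dtype}); class rasters must be integer"
            )
        cs = 30.0
        tag = page.tags.get(_GEOTIFF_PIXELSCALE)
        if tag is not None:
            cs = float(tag.value[0])
        else:
            warnings.warn(
                f"{path.name}: no georeference (pixel scale) tag; assuming 30 m cells",
                stacklevel=3,
            )
        nodata_tag = page.tags.get(_GDAL_NODATA)
        if nodata_tag is not None:
            nodata = int(float(str(nodata_tag.value)))
            mask = values == nodata
        else:
            mask = np.zeros(values.shape, dtype=bool)
    return values.astype(np.int32), mask, cs


def _write_geotiff(landscape: CategoricalLandscape, path: Path) -> None:
    import tifffile

    vals = landscape.values.astype(np.int32).copy()
    vals[landscape.nodata_mask] = _ASCII_NODATA
    cs = float(landscape.cell_size)
    extratags = [
        (_GEOTIFF_PIXELSCALE, "d", 3, (cs, cs, 0.0)),
        (_GEOTIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
        (_GDAL_NODATA, "s", 0, str(_ASCII_NODATA)),
    ]
    tifffile.imwrite(str(path), vals, extratags=extratags)
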