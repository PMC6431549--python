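"""Published worked-example inputs: Sierra Tarahumara forest footprint.

Land-use/land-cover accounting for a ~497,000-ha temperate-forest region in
western Chihuahua, Mexico (Landsat epochs 1990, 2005, 2017; five classes:
primary forest PF, secondary forest SF, human settlements HS, areas without
vegetation AWV, water bodies WB).  These constants serve as inputs to the
package's accounting and matrix machinery in examples and tests; the original
classified rasters are not distributed, so anything spatial is exercised on
synthetic landscapes instead.
"""

from __future__ import annotations

from .raster import AreaTable
from .transition import TransitionMatrix, TransitionWhitelist

__all__ = [
    "CLASS_LABELS",
    "MATRIX_ORDER",
    "AREAS_HA",
    "SCENARIO_SHARES_PCT",
    "WHITELIST",
    "area_table",
    "transition_matrix",
]

CLASS_LABELS = {1: "PF", 2: "SF", 3: "HS", 4: "AWV", 5: "WB"}
_CODE = {v: k for k, v in CLASS_LABELS.items()}

#: Occupied area per class (hectares) per epoch.
AREAS_HA = {
    1990: {"AWV": 20444.18, "SF": 199121.38, "HS": 154.60, "WB": 26.9712, "PF": 277380.46},
    2005: {"AWV": 23828.59, "SF": 223948.16, "HS": 272.35, "WB": 103.76, "PF": 248973.97},
    2017: {"AWV": 24101.92, "SF": 286922.04, "HS": 521.65, "WB": 153.91, "PF": 185427.79},
}

#: Row/column order of the published transition matrices.
MATRIX_ORDER = ["AWV", "SF", "HS", "WB", "PF"]

# 4-decimal published transition probabilities; rows in MATRIX_ORDER.
_MATRICES = {
    (1990, 2005): [
        [0.9000, 0.0250, 0.0250, 0.0250, 0.0250],
        [0.0222, 0.7516, 0.0008, 0.0005, 0.2248],
        [0.0452, 0.0645, 0.8806, 0.0000, 0.0097],
        [0.0000, 0.1254, 0.0000, 0.8553, 0.0193],
        [0.0020, 0.2865, 0.0000, 0.0000, 0.7115],
    ],
    (2005, 2017): [
        [0.6250, 0.3504, 0.0108, 0.0029, 0.0109],
        [0.0557, 0.8116, 0.0004, 0.0000, 0.1323],
        [0.0557, 0.2479, 0.6959, 0.0000, 0.0004],
        [0.0095, 0.1684, 0.0000, 0.8030, 0.0191],
        [0.0056, 0.3798, 0.0003, 0.0000, 0.6144],
    ],
    (1990, 2017): [
        [0.6615, 0.3124, 0.0120, 0.0035, 0.0106],
        [0.0654, 0.7945, 0.0012, 0.0006, 0.1384],
        [0.0651, 0.0774, 0.8575, 0.0000, 0.0000],
        [0.0000, 0.1868, 0.0000, 0.7957, 0.0175],
        [0.0071, 0.4419, 0.0002, 0.0000, 0.5508],
    ],
}

#: Percentage shares in 2017 and the 2050 projections (stationary,
#: optimistic, pessimistic scenarios).
SCENARIO_SHARES_PCT = {
    2017: {"AWV": 4.848, "SF": 57.716, "HS": 0.105, "WB": 0.031, "PF": 37.300},
    "stationary": {"AWV": 5.275, "SF": 73.721, "HS": 0.105, "WB": 0.031, "PF": 20.868},
    "optimistic": {"AWV": 5.017, "SF": 61.863, "HS": 0.105, "WB": 0.031, "PF": 32.983},
    "pessimistic": {"AWV": 7.695, "SF": 83.628, "HS": 0.105, "WB": 0.031, "PF": 8.541},
}

#: Transitions of interest in the deforestation model.
WHITELIST = TransitionWhitelist(
    {
        (_CODE["PF"], _CODE["SF"]),
        (_CODE["PF"], _CODE["AWV"]),
        (_CODE["PF"], _CODE["HS"]),
        (_CODE["SF"], _CODE["AWV"]),
    }
)


def area_table() -> AreaTable:
    """The three-epoch accounting table built from the published areas."""
    return AreaTable.from_areas(AREAS_HA, CLASS_LABELS)


def transition_matrix(start: int, end: int) -> TransitionMatrix:
    """Published period transition matrix (rows normalized within 5e-4)."""
    try:
        rows = _MATRICES[(start, end)]
    except KeyError:
        raise KeyError(f"no published matrix for {start}-{end}") from None
    order = [_CODE[l] for l in MATRIX_ORDER]
    return TransitionMatrix.from_rows(rows, float(end - start), order)
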