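"""Grid model, raster I/O and the change-accounting arithmetic."""

import numpy as np
import pandas as pd
import pytest

from lulcsim import (
    AreaTable,
    CategoricalLandscape,
    annualized_rate,
    area_table,
    change_type_map,
    crosstab,
    net_change,
    read_landscape,
    write_landscape,
)
from lulcsim.errors import ComparabilityError, RasterFormatError

from conftest import make_landscape, random_landscape


class TestLandscape:
    def test_unknown_codes_rejected(self):
        with pytest.raises(ValueError, match="missing from class_labels"):
            CategoricalLandscape(np.array([[1, 7]]), None, 30.0, {1: "PF"})

    def test_masked_codes_need_no_label(self):
        mask = np.array([[False, True]])
        land = CategoricalLandscape(np.array([[1, 7]]), mask, 30.0, {1: "PF"})
        assert land.n_valid == 1

    def test_float_values_rejected(self):
        with pytest.raises(RasterFormatError):
            CategoricalLandscape(np.array([[1.0, 2.0]]))

    def test_comparability(self):
        a = make_landscape([[1, 2], [2, 1]])
        assert a.comparable(make_landscape([[2, 2], [1, 1]]))
        assert not a.comparable(make_landscape([[1, 2, 1]]))
        assert not a.comparable(make_landscape([[1, 2], [2, 1]], cell_size=10.0))


class TestAsciiGrid:
    def test_nodata_parse(self, tmp_path):
        p = tmp_path / "grid.asc"
        p.write_text(
            "ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\ncellsize 30\n"
            "NODATA_value -9999\n1 1 2\n2 -9999 2\n1 1 1\n"
        )
        land = read_landscape(p)
        assert land.n_valid == 8
        assert land.cell_size == 30.0
        assert land.values[0, 2] == 2

    def test_round_trip_identity(self, tmp_path):
        mask = np.zeros((4, 5), bool)
        mask[1, 3] = True
        land = make_landscape(np.arange(20).reshape(4, 5) % 3 + 1, mask=mask)
        write_landscape(land, tmp_path / "x.asc")
        back = read_landscape(tmp_path / "x.asc")
        assert np.array_equal(back.values[~mask], land.values[~mask])
        assert np.array_equal(back.nodata_mask, land.nodata_mask)

    def test_float_codes_error(self, tmp_path):
        p = tmp_path / "f.asc"
        p.write_text("ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 30\n1.0 2\n")
        with pytest.raises(RasterFormatError, match="non-integer"):
            read_landscape(p)


class TestGeoTiff:
    def test_round_trip(self, tmp_path):
        mask = np.zeros((6, 7), bool)
        mask[0, 0] = True
        land = make_landscape(np.ones((6, 7), int) * 2, cell_size=15.0, mask=mask)
        write_landscape(land, tmp_path / "x.tif")
        back = read_landscape(tmp_path / "x.tif")
        assert back.cell_size == 15.0
        assert np.array_equal(back.values[~mask], land.values[~mask])
        assert np.array_equal(back.nodata_mask, mask)

    def test_missing_georeference_warns(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "plain.tif", np.ones((3, 3), np.int32))
        with pytest.warns(UserWarning, match="georeference"):
            land = read_landscape(tmp_path / "plain.tif")
        assert land.cell_size == 30.0

    def test_float_band_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "f.tif", np.ones((3, 3), np.float32))
        with pytest.raises(RasterFormatError, match="non-integer band"):
            read_landscape(tmp_path / "f.tif")


class TestCrosstab:
    def test_identity_map_diagonal(self):
        a = make_landscape([[1, 2], [2, 1]])
        tc = crosstab(a, a)
        off = tc.counts - np.diag(np.diag(tc.counts))
        assert off.sum() == 0

    def test_enumerated_counts(self):
        a = make_landscape([[1, 1], [2, 2]])
        b = make_landscape([[1, 2], [2, 2]])
        tc = crosstab(a, b)
        i = {c: k for k, c in enumerate(tc.class_order)}
        assert tc.counts[i[1], i[1]] == 1
        assert tc.counts[i[1], i[2]] == 1
        assert tc.counts[i[2], i[2]] == 2
        assert tc.n_valid == 4

    def test_mask_union_excludes(self):
        a = make_landscape([[1, 1], [2, 2]])
        mask = np.array([[False, True], [False, False]])
        b = CategoricalLandscape(np.array([[1, 2], [2, 2]], np.int32), mask)
        a2 = CategoricalLandscape(a.values, mask, 30.0, a.class_labels)
        tc = crosstab(a2, b)
        assert tc.n_valid == 3

    def test_shape_mismatch_raises(self):
        with pytest.raises(ComparabilityError):
            crosstab(make_landscape([[1]]), make_landscape([[1, 2]]))

    def test_marginals_match_class_counts(self, rng):
        for _ in range(5):
            a = random_landscape(rng)
            b = random_landscape(rng)
            tc = crosstab(a, b)
            for k, code in enumerate(tc.class_order):
                assert tc.counts[k, :].sum() == a.class_counts()[code]
                assert tc.counts[:, k].sum() == b.class_counts()[code]


class TestAreaTable:
    def test_hectares_from_cells(self):
        land = make_landscape(np.ones((10, 10), int), cell_size=30.0)
        at = area_table([land], ["t0"])
        assert at.area_ha("1", "t0") == pytest.approx(9.00)

    def test_absent_class_zero(self, forest_labels):
        land = make_landscape(np.ones((5, 5), int), labels=forest_labels)
        at = area_table([land], [2017])
        assert at.area_ha("SF", 2017) == 0.0
        assert at.share_pct("SF", 2017) == 0.0

    def test_shares_sum_100(self, rng):
        for _ in range(5):
            land = random_landscape(rng, codes=(1, 2, 3, 4))
            at = area_table([land], [0])
            assert at.table["share_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_map_list_rejected(self):
        with pytest.raises(ValueError):
            area_table([], [])

    def test_published_area_shares(self):
        from lulcsim.datasets import area_table as published

        at = published()
        assert at.share_pct("PF", 1990) == pytest.approx(55.80, abs=0.005)
        assert at.share_pct("PF", 2017) == pytest.approx(37.30, abs=0.005)


class TestNetChange:
    def test_identical_epochs_zero(self):
        land = make_landscape([[1, 2], [2, 1]])
        at = area_table([land, land], ["a", "b"])
        assert (net_change(at, "a", "b") == 0).all()

    def test_published_differences(self):
        from lulcsim.datasets import area_table as published

        nc = net_change(published(), 1990, 2017)
        assert nc["SF"] == pytest.approx(87800.66, abs=1e-9)
        assert nc["AWV"] == pytest.approx(3657.74, abs=1e-9)

    def test_changes_sum_zero_on_fixed_footprint(self, rng):
        a = random_landscape(rng, codes=(1, 2, 3))
        b = random_landscape(rng, codes=(1, 2, 3))
        at = area_table([a, b], [0, 1])
        assert net_change(at, 0, 1).sum() == pytest.approx(0.0, abs=1e-9)

    def test_unknown_epoch_raises(self):
        land = make_landscape([[1]])
        at = area_table([land], [0])
        with pytest.raises(ValueError, match="unknown epoch"):
            net_change(at, 0, 99)


class TestChangeTypeMap:
    def test_no_change_all_stable(self, forest_labels):
        land = make_landscape([[1, 2], [4, 3]], labels=forest_labels)
        cmap, totals = change_type_map(land, land)
        assert set(np.unique(cmap.values)) == {0}
        assert totals.get("Deforestation", 0.0) == 0.0

    def test_single_degradation_cell(self, forest_labels):
        a = make_landscape([[1, 1]], labels=forest_labels)
        b = make_landscape([[1, 2]], labels=forest_labels)
        _, totals = change_type_map(a, b)
        assert totals["Degradation"] == pytest.approx(0.09)

    def test_enumerated_categories(self, forest_labels):
        a = make_landscape([[1, 2], [1, 2]], labels=forest_labels)
        b = make_landscape([[4, 1], [1, 2]], labels=forest_labels)
        cmap, totals = change_type_map(a, b)
        counts = cmap.class_counts()
        assert counts[1] == 1  # PF->AWV deforestation
        assert counts[3] == 1  # SF->PF recovery
        assert counts[0] == 2

    def test_unlisted_pair_is_other(self, forest_labels):
        a = make_landscape([[3]], labels=forest_labels)
        b = make_landscape([[4]], labels=forest_labels)
        cmap, _ = change_type_map(a, b)
        assert cmap.values[0, 0] == 4


def test_annualized_rate_closed_form():
    at = AreaTable(
        pd.DataFrame(
            {
                "class_code": [1, 1],
                "class_label": ["PF", "PF"],
                "epoch": [2000, 2010],
                "area_ha": [100.0, 50.0],
                "share_pct": [100.0, 100.0],
            }
        )
    )
    r = annualized_rate(at, "PF", 2000, 2010, 10)
    assert r == pytest.approx(((0.5) ** 0.1 - 1) * 100)
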