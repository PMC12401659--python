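"""Hexagonal grid geometry, assignment and occurrence filters."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from xericfish.hexgrid import (HexGrid, assign_hex, bin_all, count_digits,
                               filter_freshwater, filter_precision,
                               filter_xeric, hex_area, hex_centroid)


class TestGeometry:
    def test_area_at_nominal_11km_radius(self):
        assert round(hex_area(11.0)) == 314

    def test_unit_radius_closed_form(self):
        assert hex_area(1.0) == pytest.approx(3 * math.sqrt(3) / 2)

    def test_doubling_radius_quadruples_area(self):
        assert hex_area(2.0) == pytest.approx(4 * hex_area(1.0))

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            hex_area(0.0)


class TestAssignment:
    def test_centroid_maps_to_own_cell(self):
        grid = HexGrid()
        for q, r in [(0, 0), (3, -2), (-5, 7), (10, 10)]:
            lon, lat = hex_centroid(q, r, grid)
            assert assign_hex(lat, lon, grid) == (q, r)

    def test_matches_nearest_centroid_brute_force(self, rng):
        grid = HexGrid()
        lat = rng.uniform(-5, 5, 1000)
        lon = rng.uniform(-5, 5, 1000)
        q, r = assign_hex(lat, lon, grid)
        # brute force: search a generous neighborhood of candidate cells
        for k in range(1000):
            best = None
            for dq in range(-2, 3):
                for dr in range(-2, 3):
                    cq, cr = q[k] + dq, r[k] + dr
                    clon, clat = hex_centroid(cq, cr, grid)
                    d = (lon[k] - clon) ** 2 + (lat[k] - clat) ** 2
                    if best is None or d < best[0] - 1e-15:
                        best = (d, cq, cr)
            assert (best[1], best[2]) == (q[k], r[k])

    def test_shared_vertex_breaks_to_smallest_qr(self):
        grid = HexGrid()
        # vertex shared by cells (0,0), (1,0) and (0,1): top-right vertex of
        # cell (0,0) at angle 30 degrees
        R = grid.circumradius
        vx = R * math.sqrt(3) / 2
        vy = R / 2
        assert assign_hex(vy, vx, grid) == (0, 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_hex(91.0, 0.0)


class TestPrecisionFilter:
    def test_digit_counting(self):
        assert count_digits("46.1") == 3
        assert count_digits("-99.4") == 3
        assert count_digits("−99.432") == 5  # unicode minus
        assert count_digits("046.10") == 5   # leading zeros count
        assert count_digits("abc") == -1

    def test_rules(self, occurrence_frame):
        kept, dropped = filter_precision(occurrence_frame)
        kept_species = set(kept["species"])
        # three-digit latitude kept
        assert "Xerichthys sp001" in kept_species
        # two-digit latitude, three-digit longitude dropped
        assert "Xerichthys sp002" not in kept_species
        # two-digit latitude rescued by a five-digit longitude
        assert "Xerichthys sp003" in kept_species
        # ... but not by a six-digit longitude
        assert "Xerichthys sp004" not in kept_species
        reasons = dict(zip(dropped["species"], dropped["drop_reason"]))
        assert reasons["Xerichthys sp006"] == "unparseable_coordinate"
        assert reasons["Xerichthys sp002"] == "low_precision"

    def test_partition(self, occurrence_frame):
        kept, dropped = filter_precision(occurrence_frame)
        assert len(kept) + len(dropped) == len(occurrence_frame)


def _ray_cast(poly_xy, x, y):
    """Independent even-odd ray casting (boundary not guaranteed)."""
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


class TestPolygonFilter:
    square = Polygon([(0, 0), (2, 0), (2, 2), (0, 2)])

    def _frame(self, pts):
        return pd.DataFrame(pts, columns=["lat", "lon"])

    def test_centroid_kept_outside_dropped(self):
        df = self._frame([(1.0, 1.0), (5.0, 5.0)])
        kept, dropped = filter_xeric(df, self.square)
        assert len(kept) == 1 and kept.iloc[0]["lat"] == 1.0
        assert dropped.iloc[0]["drop_reason"] == "outside_habitat"

    def test_boundary_counts_as_inside(self):
        kept, _ = filter_xeric(self._frame([(0.0, 1.0)]), self.square)
        assert len(kept) == 1

    def test_matches_ray_casting_on_nonconvex_polygon(self, rng):
        xy = [(0, 0), (4, 0), (4, 3), (2, 1.2), (0, 3)]  # concave chevron
        poly = Polygon(xy)
        x = rng.uniform(-0.5, 4.5, 500)
        y = rng.uniform(-0.5, 3.5, 500)
        df = pd.DataFrame({"lat": y, "lon": x})
        kept, _ = filter_xeric(df, poly)
        expected = {i for i in range(500) if _ray_cast(xy, x[i], y[i])}
        assert set(kept.index) == expected


class TestFreshwaterFilter:
    traits = pd.DataFrame({
        "species": [f"s{i}" for i in range(1, 7)],
        "freshwater": [True, True, True, False, False, False],
    })

    def _site(self, species, lat=1.0):
        return pd.DataFrame({"species": species,
                             "lat": lat, "lon": 2.0})

    @pytest.mark.parametrize("species, kept_site", [
        (["s1", "s2", "s3", "s4"], True),    # 3 of 4 freshwater
        (["s4", "s5", "s6", "s1"], False),   # 1 of 4 freshwater
        (["s1", "s2", "s4", "s5"], True),    # exactly 2 of 4 ("at least 50%")
    ])
    def test_majority_rule_by_species(self, species, kept_site):
        df = self._site(species)
        kept, dropped = filter_freshwater(df, self.traits)
        assert (len(kept) > 0) == kept_site

    def test_exactly_half_keeps_site_and_strips_marine(self):
        kept, _ = filter_freshwater(self._site(["s1", "s2", "s4", "s5"]),
                                    self.traits)
        assert set(kept["species"]) == {"s1", "s2"}

    def test_marine_records_removed_in_kept_sites(self):
        kept, dropped = filter_freshwater(
            self._site(["s1", "s2", "s3", "s4"]), self.traits)
        assert "s4" not in set(kept["species"])
        assert "marine_or_brackish_taxon" in set(dropped["drop_reason"])

    def test_missing_species_dropped_with_warning(self):
        df = self._site(["s1", "s2", "unknown sp"])
        with pytest.warns(UserWarning, match="missing"):
            kept, dropped = filter_freshwater(df, self.traits)
        assert "species_not_in_traits" in set(dropped["drop_reason"])
        assert len(kept) + len(dropped) == len(df)


class TestBinAll:
    def _records(self, n, lat0=0.0, lon0=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "species": "s1",
            "lat": lat0 + rng.uniform(-0.01, 0.01, n),
            "lon": lon0 + rng.uniform(-0.01, 0.01, n),
        })

    def test_richness_only_cell_has_empty_gauge_list(self):
        rec = self._records(5)
        gauges = pd.DataFrame(columns=["gauge", "lat", "lon"])
        clim = pd.DataFrame(columns=["point", "lat", "lon"])
        _, _, _, manifest = bin_all(rec, gauges, clim)
        assert manifest["n_gauges"].iloc[0] == 0
        assert manifest["n_records"].iloc[0] == 5

    def test_twenty_gauges_in_one_cell(self):
        rec = self._records(3)
        gauges = pd.DataFrame({"gauge": [f"g{i}" for i in range(20)],
                               "lat": 0.0, "lon": 0.0})
        clim = pd.DataFrame(columns=["point", "lat", "lon"])
        _, _, _, manifest = bin_all(rec, gauges, clim)
        assert manifest.set_index("hexid")["n_gauges"].max() == 20

    def test_disjoint_extents_share_no_cells(self):
        rec = self._records(5, lat0=0.0)
        gauges = pd.DataFrame({"gauge": ["g"], "lat": [40.0], "lon": [40.0]})
        clim = pd.DataFrame(columns=["point", "lat", "lon"])
        rec_b, gau_b, _, _ = bin_all(rec, gauges, clim)
        assert not set(rec_b["hexid"]) & set(gau_b["hexid"])


def test_precision_and_polygon_filters_commute(occurrence_frame):
    poly = Polygon([(-120, 0), (120, 0), (120, 60), (-120, 60)])
    k1, _ = filter_precision(occurrence_frame)
    k1, _ = filter_xeric(k1, poly)
    k2, _ = filter_xeric(occurrence_frame, poly)
    k2, _ = filter_precision(k2)
    assert sorted(k1["species"]) == sorted(k2["species"])
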