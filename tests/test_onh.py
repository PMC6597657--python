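"""Optic-nerve-head morphometry: unit conversion, reference planes, the
nine parameters, symmetry/invariance properties, and area oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from octmorph.onh import (OnhMeasureConfig, measure_onh, reference_planes,
                          um_to_deg)
from octmorph.scan import BoundarySet, ScanMeta, flip_nasal_side, mirror_boundaries
from octmorph.synth import generate_onh_bscan

from conftest import AX_PX, DEG_PX, random_onh_geometry


@pytest.mark.parametrize("x_um, expected", [
    (292.0, 1.0),            # the model-eye small-angle calibration
    (0.0, 0.0),
    (1634.0, 5.596),         # the glaucoma-group mean disc diameter in um
])
def test_um_to_deg(x_um, expected, onh_meta):
    assert um_to_deg(x_um, onh_meta) == pytest.approx(expected, abs=2e-3)


def _flat_boundary_set(bm_nasal=900.0, bm_temporal=900.0, n=200):
    x = (np.arange(n) + 0.5) * 20.0
    bm = np.linspace(bm_nasal, bm_temporal, n)
    opening = (x > 1500) & (x < 2500)
    bm_curve = np.where(opening, np.nan, bm)
    ilm = bm - 300.0
    return BoundarySet(x, {"ILM": ilm, "BM": bm_curve},
                       disc_edge_nasal_um=1500.0, disc_edge_temporal_um=2500.0)


class TestReferencePlanes:
    def test_horizontal_bm(self):
        b = _flat_boundary_set()
        (m, c), (mo, co) = reference_planes(b, offset_um=150.0)
        assert m == pytest.approx(0.0, abs=1e-9)
        assert c == pytest.approx(900.0, abs=0.5)
        assert co == pytest.approx(750.0, abs=0.5)

    def test_tilted_bm_offsets_linearly(self):
        b = _flat_boundary_set(bm_nasal=800.0, bm_temporal=1000.0)
        (_, _), (mo, co) = reference_planes(b, offset_um=150.0)
        z_at = lambda x: mo * x + co
        assert z_at(1500.0) == pytest.approx(
            np.interp(1500.0, b.x_um, np.linspace(800, 1000, 200)) - 150, abs=1.0)

    def test_zero_offset_planes_coincide(self):
        b = _flat_boundary_set()
        disc, offset = reference_planes(b, offset_um=0.0)
        assert disc == offset

    def test_missing_edge_errors(self):
        b = _flat_boundary_set()
        b.disc_edge_nasal_um = None
        with pytest.raises(ValueError, match="disc edges"):
            reference_planes(b)


class TestMeasureOnh:
    def test_recovers_group_mean_geometry(self, pcg_geometry, onh_meta, no_noise):
        _, truth = generate_onh_bscan(pcg_geometry, onh_meta, no_noise)
        p = measure_onh(truth, onh_meta)
        assert p.disc_diameter_deg == pytest.approx(5.596, abs=DEG_PX)
        assert p.cup_diameter_deg == pytest.approx(3.782, abs=DEG_PX)
        assert p.cup_disc_ratio == pytest.approx(3.782 / 5.596, abs=0.013)
        assert p.cup_depth_um == pytest.approx(781.8, abs=AX_PX)
        assert p.rim_width_deg == pytest.approx(5.596 - 3.782, abs=2 * DEG_PX)
        assert p.rnfl_nasal_um == pytest.approx(51.1, abs=AX_PX)
        assert p.rnfl_temporal_um == pytest.approx(59.6, abs=AX_PX)
        assert not p.no_cup

    def test_no_cup_degenerate(self, onh_meta):
        b = _flat_boundary_set()  # ILM everywhere anterior to the offset plane
        p = measure_onh(b, onh_meta)
        assert p.no_cup
        assert p.cup_diameter_deg == 0 and p.cup_depth_um == 0
        assert p.cup_disc_ratio == 0 and p.cup_area_degum == 0
        assert p.rim_width_deg == pytest.approx(p.disc_diameter_deg)

    def test_axial_translation_invariance(self, pcg_geometry, onh_meta, no_noise):
        _, truth = generate_onh_bscan(pcg_geometry, onh_meta, no_noise)
        shifted = BoundarySet(truth.x_um,
                              {k: v + 137.0 for k, v in truth.curves.items()},
                              truth.disc_edge_nasal_um, truth.disc_edge_temporal_um)
        a = measure_onh(truth, onh_meta).to_dict()
        b = measure_onh(shifted, onh_meta).to_dict()
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k

    def test_lateral_mirror_swaps_nasal_temporal(self, onh_meta, no_noise):
        rng = np.random.default_rng(0)
        geom = random_onh_geometry(rng)
        _, truth = generate_onh_bscan(geom, onh_meta, no_noise)
        a = measure_onh(truth, onh_meta).to_dict()
        b = measure_onh(mirror_boundaries(truth), flip_nasal_side(onh_meta)).to_dict()
        assert a["rnfl_nasal_um"] == pytest.approx(b["rnfl_nasal_um"], abs=1e-6)
        assert a["rnfl_temporal_um"] == pytest.approx(b["rnfl_temporal_um"], abs=1e-6)
        for k in ("disc_diameter_deg", "cup_diameter_deg", "cup_depth_um",
                  "cup_area_degum", "rim_width_deg", "rim_area_degum"):
            assert a[k] == pytest.approx(b[k], rel=1e-6), k

    def test_deeper_cup_increases_depth_and_area(self, onh_meta, no_noise):
        from dataclasses import replace
        rng = np.random.default_rng(1)
        geom = random_onh_geometry(rng)
        depths, areas = [], []
        for extra in (0.0, 150.0, 300.0):
            g = replace(geom, cup_depth_um=geom.cup_depth_um + extra)
            _, truth = generate_onh_bscan(g, onh_meta, no_noise)
            p = measure_onh(truth, onh_meta)
            depths.append(p.cup_depth_um)
            areas.append(p.cup_area_degum)
        assert depths[0] < depths[1] < depths[2]
        assert areas[0] <= areas[1] <= areas[2]

    @given(seed=st.integers(0, 10_000))
    def test_cdr_bounded(self, onh_meta, no_noise, seed):
        rng = np.random.default_rng(seed)
        _, truth = generate_onh_bscan(random_onh_geometry(rng), onh_meta, no_noise)
        p = measure_onh(truth, onh_meta)
        assert 0.0 <= p.cup_disc_ratio <= 1.0

    def test_rnfl_from_margin_alternative(self, pcg_geometry, onh_meta, no_noise):
        _, truth = generate_onh_bscan(pcg_geometry, onh_meta, no_noise,
                                      field_beyond_disc_deg=10.0)
        cfg = OnhMeasureConfig(rnfl_from="margin")
        p = measure_onh(truth, onh_meta, cfg)
        # flat nerve-fibre band: same thickness at either sampling rule
        assert p.rnfl_nasal_um == pytest.approx(51.1, abs=AX_PX)


def pixel_count_area(x_um, upper, lower, upd, cell_deg=0.005, cell_um=1.0):
    """Brute-force area oracle: rasterise the strip between two curves on a
    fine grid and count the cells whose centre lies inside."""
    fine_x = np.arange(x_um[0], x_um[-1], cell_deg * upd)
    up = np.interp(fine_x, x_um, upper)
    low = np.interp(fine_x, x_um, lower)
    count = 0
    for u, l in zip(up, low):
        if l > u:
            ks = np.arange(np.floor(u / cell_um), np.ceil(l / cell_um) + 1)
            centres = (ks + 0.5) * cell_um
            count += int(np.sum((centres > u) & (centres < l)))
    return count * cell_deg * cell_um


class TestAreaOracles:
    @pytest.mark.parametrize("seed", range(8))
    def test_cup_and_rim_area_match_pixel_count(self, seed, onh_meta, no_noise):
        rng = np.random.default_rng(seed)
        geom = random_onh_geometry(rng)
        _, truth = generate_onh_bscan(geom, onh_meta, no_noise)
        p = measure_onh(truth, onh_meta)
        (m, _), (mo, co) = reference_planes(truth)
        plane = mo * truth.x_um + co
        ilm = truth["ILM"]
        upd = onh_meta.um_per_degree
        lo, hi = sorted((truth.disc_edge_nasal_um, truth.disc_edge_temporal_um))
        inside = (truth.x_um > lo) & (truth.x_um < hi)
        x, pl, il = truth.x_um[inside], plane[inside], ilm[inside]
        # cup: region below the offset plane and above the ILM;
        # rim: region above the plane and below the ILM (both between edges)
        cup_oracle = pixel_count_area(x, pl, np.maximum(il, pl), upd)
        rim_oracle = pixel_count_area(x, np.minimum(il, pl), pl, upd)
        if p.cup_area_degum > 50:
            assert p.cup_area_degum == pytest.approx(cup_oracle, rel=0.01)
        if p.rim_area_degum > 50:
            assert p.rim_area_degum == pytest.approx(rim_oracle, rel=0.01)
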