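"""Boundary detection: noise-free exactness, noisy accuracy, degradation."""

import numpy as np
import pytest

from octmorph.scan import BScan, ScanMeta
from octmorph.segment import (detect_bm_and_disc, detect_ilm, elm_detectability,
                              segment_fovea_layers, segment_onh)
from octmorph.synth import (FoveaGeometry, NoiseModel, generate_fovea_bscan,
                            generate_onh_bscan)

from conftest import AX_PX, LAT_PX

FOVEA_CURVES = ["ILM", "RNFL_post", "GCLIPL_post", "INL_post", "OPL_post",
                "ONLIS_post", "OSRPE_post"]


class TestIlm:
    def test_noise_free_recovery(self, pcg_geometry, onh_meta, no_noise):
        scan, truth = generate_onh_bscan(pcg_geometry, onh_meta, no_noise)
        ilm = detect_ilm(scan)
        err = np.abs(ilm - truth["ILM"]) / AX_PX
        assert np.nanmax(err) < 1.0

    def test_blank_image_all_missing(self, onh_meta):
        scan = BScan(np.zeros((80, 80)), onh_meta)
        ilm = detect_ilm(scan)
        assert np.sum(~np.isfinite(ilm)) == scan.n_cols

    def test_noisy_mean_error_below_two_pixels(self, pcg_geometry, onh_meta):
        errs = []
        for seed in range(15):
            scan, truth = generate_onh_bscan(pcg_geometry, onh_meta,
                                             NoiseModel(seed=seed))
            errs.append(np.nanmean(np.abs(detect_ilm(scan) - truth["ILM"])) / AX_PX)
        assert np.mean(errs) < 2.0


class TestDiscEdges:
    def test_noise_free_separation_within_one_pixel(self, pcg_geometry,
                                                    onh_meta, no_noise):
        scan, truth = generate_onh_bscan(pcg_geometry, onh_meta, no_noise)
        _, en, et = detect_bm_and_disc(scan)
        sep_true = abs(truth.disc_edge_temporal_um - truth.disc_edge_nasal_um)
        assert abs(abs(et - en) - sep_true) < LAT_PX

    def test_fovea_scan_rejected(self, control_fovea_geometry, fovea_meta,
                                 no_noise):
        scan, _ = generate_fovea_bscan(control_fovea_geometry, fovea_meta,
                                       no_noise)
        with pytest.raises(ValueError, match="disc edges not found"):
            detect_bm_and_disc(scan)

    def test_noisy_edge_localisation(self, pcg_geometry, onh_meta):
        errs = []
        for seed in range(15):
            scan, truth = generate_onh_bscan(pcg_geometry, onh_meta,
                                             NoiseModel(seed=seed))
            _, en, et = detect_bm_and_disc(scan)
            errs += [abs(en - truth.disc_edge_nasal_um) / LAT_PX,
                     abs(et - truth.disc_edge_temporal_um) / LAT_PX]
        assert np.median(errs) <= 1.0


class TestFoveaLayers:
    def test_noise_free_exact(self, control_fovea_geometry, fovea_meta, no_noise):
        scan, truth = generate_fovea_bscan(control_fovea_geometry, fovea_meta,
                                           no_noise)
        b = segment_fovea_layers(scan)
        for name in FOVEA_CURVES:
            err = np.abs(b[name] - truth[name]) / AX_PX
            assert np.nanmax(err) < 1.0, name

    def test_constructed_inl_thickness_recovered(self, fovea_meta, no_noise):
        layers = dict(FoveaGeometry().layer_thicknesses_um)
        layers["INL"] = (40.0, 40.0, 40.0, 40.0)
        geom = FoveaGeometry(layer_thicknesses_um=layers, pit_depth_um=125.0)
        scan, _ = generate_fovea_bscan(geom, fovea_meta, no_noise)
        b = segment_fovea_layers(scan)
        inl = b["INL_post"] - b["GCLIPL_post"]
        assert np.nanmedian(inl) == pytest.approx(40.0, abs=AX_PX)

    def test_ordering_invariant(self, control_fovea_geometry, fovea_meta):
        scan, _ = generate_fovea_bscan(control_fovea_geometry, fovea_meta,
                                       NoiseModel(seed=5))
        b = segment_fovea_layers(scan)
        b.check_ordering(atol_um=AX_PX)

    def test_noisy_mean_boundary_error(self, control_fovea_geometry, fovea_meta):
        errs = {name: [] for name in FOVEA_CURVES}
        for seed in range(15):
            scan, truth = generate_fovea_bscan(control_fovea_geometry,
                                               fovea_meta, NoiseModel(seed=seed))
            b = segment_fovea_layers(scan)
            for name in FOVEA_CURVES:
                errs[name].append(np.nanmean(np.abs(b[name] - truth[name])) / AX_PX)
        for name, vals in errs.items():
            assert np.mean(vals) < 2.0, name

    def test_error_grows_with_speckle(self, control_fovea_geometry, fovea_meta):
        """Graceful degradation: boundary error is non-decreasing in the
        speckle level (averaged over seeds)."""
        means = []
        for speckle in (0.15, 0.45, 0.9):
            errs = []
            for seed in range(8):
                noise = NoiseModel(speckle_scale=speckle, seed=seed)
                scan, truth = generate_fovea_bscan(control_fovea_geometry,
                                                   fovea_meta, noise)
                b = segment_fovea_layers(scan)
                errs.append(np.nanmean([
                    np.nanmean(np.abs(b[n] - truth[n])) for n in FOVEA_CURVES]))
            means.append(np.mean(errs))
        assert means[0] <= means[1] <= means[2]


class TestElm:
    def test_noise_free_present_and_absent(self, fovea_meta, no_noise):
        for present in (True, False):
            scan, _ = generate_fovea_bscan(FoveaGeometry(elm_present=present),
                                           fovea_meta, no_noise)
            res = elm_detectability(scan, segment_fovea_layers(scan))
            assert res.detected is present
            assert not res.indeterminate

    def test_separation_under_noise(self, fovea_meta):
        """Scores separate presence from absence across seeded noisy scans
        (area under the ROC curve above 0.95)."""
        scores, labels = [], []
        for seed in range(20):
            for present in (True, False):
                scan, _ = generate_fovea_bscan(
                    FoveaGeometry(elm_present=present), fovea_meta,
                    NoiseModel(seed=seed + (0 if present else 500)))
                scores.append(elm_detectability(scan,
                                                segment_fovea_layers(scan)).score)
                labels.append(present)
        scores, labels = np.array(scores), np.array(labels)
        pos, neg = scores[labels], scores[~labels]
        auc = np.mean([p > n for p in pos for n in neg])
        assert auc > 0.95

    def test_thin_slab_flagged_indeterminate(self, fovea_meta, no_noise):
        layers = dict(FoveaGeometry().layer_thicknesses_um)
        layers["ONLIS"] = (8.0, 8.0, 8.0, 8.0)
        geom = FoveaGeometry(layer_thicknesses_um=layers, pit_depth_um=120.0,
                             elm_present=False)
        scan, truth = generate_fovea_bscan(geom, fovea_meta, no_noise)
        res = elm_detectability(scan, truth)
        assert res.indeterminate


class TestSegmentOnh:
    def test_rnfl_posterior_outside_disc_only(self, pcg_geometry, onh_meta,
                                              no_noise):
        scan, truth = generate_onh_bscan(pcg_geometry, onh_meta, no_noise)
        b = segment_onh(scan)
        lo, hi = sorted((b.disc_edge_nasal_um, b.disc_edge_temporal_um))
        inside = (b.x_um > lo + LAT_PX) & (b.x_um < hi - LAT_PX)
        assert not np.isfinite(b["RNFL_post"][inside]).any()
        outside = np.isfinite(truth["RNFL_post"]) & np.isfinite(b["RNFL_post"])
        err = np.abs(b["RNFL_post"][outside] - truth["RNFL_post"][outside])
        assert np.nanmean(err) / AX_PX < 1.0
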