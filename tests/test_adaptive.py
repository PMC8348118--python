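"""Haar patterns, coefficient store, wavelet prediction, and ABS-WP."""

import math

import numpy as np
import pytest
import pywt

from mtcs import (SamplingSchedule, TrackLayout, abswp_multitrack,
                  cube_to_matrix)
from mtcs.adaptive import build_subqueues, form_compound_patterns, predict_details
from mtcs.datacube import Scene
from mtcs.haar import (MEASURED, PENDING, ZEROED, CoefficientStore,
                       WaveletIndex, approx_indices, detail_indices,
                       haar_pattern, supporting_track)


def _true_coeffs(img, J):
    """pywt oracle: dict {(orient, level): 2D array} + approx at level J."""
    coeffs = pywt.wavedec2(img, "haar", mode="periodization", level=J)
    out = {("a", J): coeffs[0]}
    for k, (cH, cV, cD) in enumerate(coeffs[1:]):
        j = J - k
        out[("h", j)], out[("v", j)], out[("d", j)] = cH, cV, cD
    return out


class TestHaarPattern:
    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_inner_products_match_pywt(self, rng, level):
        # <pattern, image> must equal the DWT coefficient — pywt is the oracle
        img = rng.normal(size=(16, 16))
        truth = _true_coeffs(img, level)
        for idx in approx_indices(16, 16, level) + detail_indices(16, 16, level):
            key = (idx.orientation, idx.level)
            if key not in truth:
                continue
            p = haar_pattern(idx, 16, 16)
            assert np.vdot(p, img) == pytest.approx(
                truth[key][idx.row, idx.col], abs=1e-10)

    def test_orthonormality(self):
        idxs = approx_indices(8, 8, 2) + detail_indices(8, 8, 2) \
            + detail_indices(8, 8, 1)
        pats = [haar_pattern(i, 8, 8).ravel() for i in idxs]
        G = np.array(pats) @ np.array(pats).T
        np.testing.assert_allclose(G, np.eye(len(idxs)), atol=1e-12)

    def test_entry_values(self):
        p = haar_pattern(WaveletIndex(2, "h", 0, 0), 8, 8)
        assert set(np.unique(p)) == {-0.25, 0.0, 0.25}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haar_pattern(WaveletIndex(2, "a", 2, 0), 8, 8)

    def test_non_dyadic_dims_rejected(self):
        with pytest.raises(ValueError):
            haar_pattern(WaveletIndex(2, "a", 0, 0), 6, 8)


class TestSupportingTrack:
    def test_contained_support(self):
        layout = TrackLayout(16, 16, 2)  # track width 8
        assert supporting_track(WaveletIndex(3, "a", 0, 0), layout) == 0
        assert supporting_track(WaveletIndex(3, "a", 0, 1), layout) == 1

    def test_straddling_support_rejected(self):
        layout = TrackLayout(16, 16, 4)  # track width 4
        with pytest.raises(ValueError, match="straddles"):
            supporting_track(WaveletIndex(3, "a", 0, 0), layout)


class TestCoefficientStore:
    def test_status_lifecycle_and_counts(self):
        store = CoefficientStore(8, 8, 2, J=2)
        idx = WaveletIndex(2, "h", 1, 1)
        assert store.status_of(idx) == PENDING
        store.set_measured(idx, np.array([1.0, 2.0]))
        assert store.status_of(idx) == MEASURED
        store.set_zeroed(WaveletIndex(1, "d", 0, 0))
        c = store.counts()
        assert c["measured"] == 1 and c["zeroed"] == 1
        assert c["measured"] + c["zeroed"] + c["pending"] == 64

    def test_reconstruct_requires_no_pending(self):
        store = CoefficientStore(4, 4, 1, J=1)
        with pytest.raises(ValueError, match="pending"):
            store.reconstruct()

    def test_roundtrip_through_pywt_layout(self, rng):
        img = rng.normal(size=(16, 16))
        store = CoefficientStore(16, 16, 1, J=3)
        truth = _true_coeffs(img, 3)
        for idx in approx_indices(16, 16, 3):
            store.set_measured(idx, truth[("a", 3)][idx.row, idx.col, None])
        for j in (3, 2, 1):
            for idx in detail_indices(16, 16, j):
                store.set_measured(
                    idx, truth[(idx.orientation, j)][idx.row, idx.col, None])
        np.testing.assert_allclose(store.reconstruct()[:, :, 0], img,
                                   atol=1e-12)

    def test_approx_image_at_top_level_is_ca(self, rng):
        store = CoefficientStore(8, 8, 1, J=2)
        vals = rng.normal(size=(2, 2))
        for idx in approx_indices(8, 8, 2):
            store.set_measured(idx, vals[idx.row, idx.col, None])
        np.testing.assert_array_equal(store.approx_image(2, 0), vals)


class TestPrediction:
    def test_requires_coarser_levels_complete(self):
        store = CoefficientStore(8, 8, 1, J=2)
        with pytest.raises(ValueError):
            predict_details(store, 1)

    @pytest.mark.parametrize("j", [4, 3, 2, 1])
    def test_top_k_covers_true_support_on_edge_scene(self, edge_image, j):
        # threshold frozen from an oracle run on this fixture: the top-k
        # predicted magnitudes covered the true nonzero support exactly
        J = 4
        truth = _true_coeffs(edge_image, J)
        store = CoefficientStore(64, 64, 1, J=J)
        for idx in approx_indices(64, 64, J):
            store.set_measured(idx, truth[("a", J)][idx.row, idx.col, None])
        for jj in range(J, j, -1):
            for idx in detail_indices(64, 64, jj):
                store.set_measured(
                    idx, truth[(idx.orientation, jj)][idx.row, idx.col, None])
        pred = predict_details(store, j)
        pv = np.concatenate([pred[o].ravel() for o in ("h", "v", "d")])
        tv = np.concatenate([truth[(o, j)].ravel() for o in ("h", "v", "d")])
        nonzero = np.abs(tv) > 1e-9
        k = int(nonzero.sum())
        assert k > 0
        topk = np.argsort(-np.abs(pv))[:k]
        coverage = nonzero[topk].mean()
        assert coverage >= 0.9


class TestSubQueues:
    def test_matches_brute_force_oracle(self, rng):
        layout = TrackLayout(16, 16, 2)
        j, p = 2, 40.0
        preds = {o: rng.normal(size=(4, 4)) for o in ("h", "v", "d")}
        # percentage_for(j=J) reads percentages[0]
        sq = build_subqueues(preds, SamplingSchedule(J=2, percentages=(p, 0.0)),
                             layout, j)
        for i in range(layout.n_tracks):
            cand = [idx for idx in detail_indices(16, 16, j)
                    if supporting_track(idx, layout) == i]
            cand.sort(key=lambda ix: (-abs(preds[ix.orientation][ix.row, ix.col]),
                                      "hvd".index(ix.orientation), ix.row, ix.col))
            keep = math.ceil(p / 100.0 * len(cand))
            assert sq.queues[i] == cand[:keep]

    def test_single_track_equals_global_top_p(self, rng):
        # nτ = 1 degeneracy: the retained set is the global top-p set
        layout = TrackLayout(16, 16, 1)
        preds = {o: rng.normal(size=(8, 8)) for o in ("h", "v", "d")}
        sq = build_subqueues(preds, SamplingSchedule(J=1, percentages=(25.0,)),
                             layout, 1)
        all_idx = detail_indices(16, 16, 1)
        mags = sorted((abs(preds[ix.orientation][ix.row, ix.col]) for ix in all_idx),
                      reverse=True)
        keep = math.ceil(0.25 * len(all_idx))
        retained_mags = sorted((abs(preds[ix.orientation][ix.row, ix.col])
                                for ix in sq.queues[0]), reverse=True)
        assert len(sq.queues) == 1
        np.testing.assert_allclose(retained_mags, mags[:keep])

    def test_zero_percent_zeroes_everything_in_store(self, rng):
        layout = TrackLayout(8, 8, 2)
        store = CoefficientStore(8, 8, 1, J=1)
        preds = {o: rng.normal(size=(4, 4)) for o in ("h", "v", "d")}
        sq = build_subqueues(preds, SamplingSchedule(J=1, percentages=(0.0,)),
                             layout, 1, store)
        assert sq.max_length == 0
        assert (store.status[("h", 1)] == ZEROED).all()

    def test_tie_break_is_deterministic(self):
        layout = TrackLayout(8, 8, 1)
        preds = {o: np.ones((4, 4)) for o in ("h", "v", "d")}
        sq = build_subqueues(preds, SamplingSchedule(J=1, percentages=(10.0,)),
                            layout, 1)
        # all magnitudes equal: order is orientation h,v,d then raster
        assert sq.queues[0][0] == WaveletIndex(1, "h", 0, 0)
        assert sq.queues[0] == sorted(
            sq.queues[0], key=lambda ix: ("hvd".index(ix.orientation),
                                          ix.row, ix.col))


class TestCompoundPatterns:
    def test_exhausted_queue_idles_on_offset(self, rng):
        from mtcs.adaptive import SubQueues
        layout = TrackLayout(8, 8, 2)
        q0 = [WaveletIndex(1, "h", 0, 0), WaveletIndex(1, "v", 1, 1)]
        q1 = [WaveletIndex(1, "h", 0, 2)]
        pats = form_compound_patterns(SubQueues(scale=1, queues=[q0, q1]), layout)
        assert len(pats) == 2
        _, active = pats[1]
        assert active == [q0[1], None]
        cp, _ = pats[1]
        assert cp.subpatterns[1].is_offset


class TestSchedule:
    def test_percentage_indexing(self):
        s = SamplingSchedule(J=3, percentages=(80.0, 50.0, 10.0))
        assert s.percentage_for(3) == 80.0
        assert s.percentage_for(1) == 10.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            SamplingSchedule(J=2, percentages=(50.0,))

    def test_support_must_fit_track(self):
        s = SamplingSchedule(J=3, percentages=(100.0,) * 3)
        with pytest.raises(ValueError):
            s.validate_for(TrackLayout(16, 16, 4))  # track width 4 < 8


class TestAbswp:
    def test_full_percentages_noiseless_is_exact(self, blob_scene):
        layout = TrackLayout(32, 32, 2)
        schedule = SamplingSchedule(J=2, percentages=(100.0, 100.0))
        res = abswp_multitrack(cube_to_matrix(blob_scene), layout, schedule)
        rel = (np.linalg.norm(res.scene.values - blob_scene.values)
               / np.linalg.norm(blob_scene.values))
        assert rel < 1e-8
        assert res.sampling_ratio == 1.0

    def test_shot_accounting_small_case(self, rng):
        # 16×16, nτ=2, J=2, all p=100:
        # 1 offset + 16/2 approx + 48/2 coarse details + 192/2 fine details
        scene = Scene(values=rng.random((16, 16, 2)))
        layout = TrackLayout(16, 16, 2)
        res = abswp_multitrack(cube_to_matrix(scene), layout,
                               SamplingSchedule(J=2, percentages=(100.0, 100.0)))
        assert res.n_shots == 1 + 8 + 24 + 96
        assert not res.shot_log["is_offset"].iloc[1:].any()

    def test_measured_coefficients_match_pywt(self, rng):
        img = rng.random((16, 16)) + 0.1
        scene = Scene(values=img[:, :, None])
        layout = TrackLayout(16, 16, 2)
        res = abswp_multitrack(cube_to_matrix(scene), layout,
                               SamplingSchedule(J=2, percentages=(100.0, 100.0)))
        truth = _true_coeffs(img, 2)
        for key, arr in truth.items():
            np.testing.assert_allclose(res.store.values[key][0], arr, atol=1e-9)

    def test_multitrack_equals_single_track(self, blob_scene):
        # track parallelism changes shot packing, not the measured values
        m = cube_to_matrix(blob_scene)
        schedule = SamplingSchedule(J=2, percentages=(100.0, 50.0))
        r1 = abswp_multitrack(m, TrackLayout(32, 32, 1), schedule)
        r2 = abswp_multitrack(m, TrackLayout(32, 32, 2), schedule)
        np.testing.assert_allclose(r1.scene.values, r2.scene.values, atol=1e-9)
        assert r2.n_shots < r1.n_shots

    def test_error_monotone_in_retention(self, mosaic_scene):
        # with the coarse scale fixed, finer-scale retained sets are nested
        # across p, so the noiseless error cannot increase with p (up to
        # float roundoff in the transforms)
        m = cube_to_matrix(mosaic_scene)
        layout = TrackLayout(32, 32, 2)
        errs = []
        for p in (10.0, 50.0, 100.0):
            res = abswp_multitrack(m, layout,
                                   SamplingSchedule(J=2, percentages=(100.0, p)))
            errs.append(np.linalg.norm(res.scene.values - mosaic_scene.values))
        slack = 1e-12 * np.linalg.norm(mosaic_scene.values)
        assert errs[0] >= errs[1] - slack >= errs[2] - 2 * slack
        assert errs[0] > errs[2]  # retention genuinely matters on this scene

    def test_sampling_ratio_decreases_with_percentages(self, blob_scene):
        m = cube_to_matrix(blob_scene)
        layout = TrackLayout(32, 32, 2)
        lo = abswp_multitrack(m, layout,
                              SamplingSchedule(J=2, percentages=(50.0, 10.0)))
        hi = abswp_multitrack(m, layout,
                              SamplingSchedule(J=2, percentages=(100.0, 100.0)))
        assert lo.sampling_ratio < hi.sampling_ratio
        assert lo.n_shots < hi.n_shots
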