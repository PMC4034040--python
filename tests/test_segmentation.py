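"""AAHC microstate segmentation, model-order selection, smoothing, GEV."""

import numpy as np
import pytest

import erptopo as et
from erptopo.segmentation import (
    aahc,
    cross_validation,
    gev,
    krzanowski_lai,
    select_q,
    smooth_labels,
)
from erptopo.topography import ZeroFieldError


def planted_maps(templates, labels, gains):
    return templates[labels] * np.asarray(gains)[:, None]


class TestAahc:
    def test_noiseless_recovery_exact(self, templates4, rng):
        labels = np.repeat(np.arange(4), 50)
        maps = planted_maps(templates4, labels, rng.uniform(0.5, 3.0, 200))
        h = aahc(maps, 1, 6)
        lv = h.levels[4]
        # labels recover the blocks up to permutation, GEV = 1
        assert lv.gev_total == pytest.approx(1.0, abs=1e-9)
        assert len(set(zip(labels.tolist(), lv.labels.tolist()))) == 4
        assert h.levels[3].gev_total < 1.0 - 1e-6

    def test_templates_unit_gfp(self, templates4, rng):
        maps = planted_maps(templates4, rng.integers(0, 4, 100),
                            rng.uniform(0.5, 2, 100)) + 0.1 * rng.normal(size=(100, 16))
        h = aahc(maps, 2, 6)
        for q, lv in h.levels.items():
            gfps = np.sqrt(np.mean(lv.templates**2, axis=1))
            np.testing.assert_allclose(gfps, 1.0, atol=1e-9)
            assert np.abs(lv.templates.mean(axis=1)).max() < 1e-9

    def test_gev_nondecreasing_in_q(self, templates4, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            maps = planted_maps(templates4, r.integers(0, 4, 150),
                                r.uniform(0.5, 2, 150)) + 0.3 * r.normal(size=(150, 16))
            h = aahc(maps, 1, 10)
            assert np.all(np.diff(h.curve("gev_total")) >= -1e-9)

    def test_rejects_flat_maps_and_bad_range(self, templates4):
        maps = np.vstack([templates4[0], np.zeros(16)])
        with pytest.raises(ZeroFieldError):
            aahc(maps, 1, 2)
        with pytest.raises(ValueError):
            aahc(templates4, q_min=10, q_max=12)  # fewer maps than q_min


class TestCrossValidation:
    def test_zero_residual_for_perfect_fit(self, templates4, rng):
        labels = rng.integers(0, 4, 80)
        maps = planted_maps(templates4, labels, rng.uniform(0.5, 2, 80))
        assert cross_validation(labels, templates4, maps, 16) == pytest.approx(0.0, abs=1e-12)

    def test_penalty_increases_with_q(self):
        # same residual, more clusters → larger CV
        N = 20
        sigma2 = 1.7

        def cv_formula(q):
            return sigma2 * ((N - 1) / (N - 1 - q)) ** 2

        assert cv_formula(3) < cv_formula(5) < cv_formula(8)

    def test_matches_direct_formula_oracle(self, rng):
        N, T, q = 8, 12, 3
        maps = rng.normal(size=(T, N))
        maps -= maps.mean(axis=1, keepdims=True)
        tmpl = rng.normal(size=(q, N))
        tmpl -= tmpl.mean(axis=1, keepdims=True)
        labels = rng.integers(0, q, T)
        that = tmpl / np.linalg.norm(tmpl, axis=1, keepdims=True)
        sigma2 = sum(
            maps[t] @ maps[t] - (that[labels[t]] @ maps[t]) ** 2 for t in range(T)
        ) / (T * (N - 1))
        expected = sigma2 * ((N - 1) / (N - 1 - q)) ** 2
        assert cross_validation(labels, tmpl, maps, N) == pytest.approx(expected)

    def test_undefined_for_q_near_n(self, rng):
        maps = rng.normal(size=(10, 5))
        tmpl = rng.normal(size=(4, 5))
        assert np.isnan(cross_validation(np.zeros(10, int), tmpl, maps, 5))


class TestKrzanowskiLai:
    def test_flat_dispersion_gives_zero(self):
        qs = np.arange(1, 8)
        kl = krzanowski_lai(qs, np.full(7, 3.0), 16)
        assert np.all(kl[np.isfinite(kl)] == 0.0)

    def test_elbow_detected(self):
        qs = np.arange(1, 9)
        # sharp elbow at q*=4: steep decrease then flat
        W = np.array([100.0, 60.0, 30.0, 5.0, 4.5, 4.2, 4.0, 3.9])
        kl = krzanowski_lai(qs, W, 16)
        assert qs[np.nanargmax(kl)] == 4

    def test_hand_computed_sequence(self):
        qs = np.arange(1, 6)
        W = np.array([10.0, 6.0, 3.0, 2.5, 2.2])
        N = 10
        kl = krzanowski_lai(qs, W, N)

        def diff(q):
            return (q - 1) ** (2 / N) * W[q - 2] - q ** (2 / N) * W[q - 1]

        for i, q in enumerate([2, 3, 4]):
            d, d1 = diff(q), diff(q + 1)
            expected = abs(d) / abs(d1) if (d > 0 and d1 < d) else 0.0
            assert kl[i + 1] == pytest.approx(expected)
        assert np.isnan(kl[0]) and np.isnan(kl[-1])


class TestSelectQ:
    def test_agreement(self):
        qs = np.arange(1, 8)
        cv = np.array([9, 7, 5, 2, 4, 6, 8.0])
        kl = np.array([np.nan, 0.5, 1.0, 9.0, 1.0, 0.2, np.nan])
        assert select_q(qs, cv, kl) == 4

    def test_flat_cv_kl_wins(self):
        qs = np.arange(1, 6)
        cv = np.ones(5)
        kl = np.array([np.nan, 0.1, 3.0, 0.1, np.nan])
        assert select_q(qs, cv, kl) == 3

    def test_no_admissible_peak_errors(self):
        qs = np.arange(1, 5)
        with pytest.raises(ValueError, match="manually"):
            select_q(qs, np.ones(4), np.zeros(4))


class TestSmoothing:
    def test_fixed_point_unchanged(self, templates4, rng):
        labels = np.repeat([0, 1, 2], 30)
        maps = planted_maps(templates4, labels, np.ones(90))
        out = smooth_labels(labels, maps, templates4, 20.0, 512.0)
        np.testing.assert_array_equal(out, labels)

    def test_island_absorbed(self, templates4):
        labels = np.array([0] * 40 + [1] * 5 + [0] * 40)  # 5 samples ≈ 9.8 ms
        maps = planted_maps(templates4, np.zeros(85, int), np.ones(85))
        out = smooth_labels(labels, maps, templates4, 20.0, 512.0)
        np.testing.assert_array_equal(out, 0)

    def test_no_segment_below_criterion(self, templates4):
        min_samples = int(np.ceil(20.0 * 512.0 / 1000.0))
        for seed in range(20):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 4, 120)
            maps = planted_maps(templates4, labels, np.ones(120)) \
                + 0.2 * r.normal(size=(120, 16))
            out = smooth_labels(labels, maps, templates4, 20.0, 512.0)
            runs = np.split(np.arange(120), np.flatnonzero(np.diff(out) != 0) + 1)
            if len(runs) > 1:
                assert min(len(rn) for rn in runs) >= min_samples

    def test_respects_condition_boundaries(self, templates4):
        # a short run at a block start must not merge across the boundary
        labels = np.array([0] * 30 + [1] * 4 + [1] * 4 + [2] * 30)
        maps = planted_maps(templates4, labels, np.ones(68))
        out = smooth_labels(labels, maps, templates4, 20.0, 512.0,
                            boundaries=[0, 34])
        assert set(out[:34]) <= {0, 1} and set(out[34:]) <= {1, 2}
        # and the 8-sample run of 1s, split 4|4 by the boundary, is dissolved
        runs1 = np.flatnonzero(out[:34] == 1)
        assert len(runs1) == 0 or len(runs1) >= 11


class TestGev:
    def test_perfect_and_orthogonal(self, templates4, rng):
        labels = rng.integers(0, 4, 60)
        maps = planted_maps(templates4, labels, rng.uniform(0.5, 3, 60))
        total, per = gev(maps, templates4, labels)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert per.sum() == pytest.approx(total)
        # orthogonal mislabeling: templates are mutually orthogonal by construction
        total0, _ = gev(maps, templates4, (labels + 1) % 4)
        assert total0 == pytest.approx(0.0, abs=1e-9)

    def test_small_instance_formula_oracle(self, rng):
        maps = rng.normal(size=(5, 8))
        tmpl = rng.normal(size=(2, 8))
        labels = np.array([0, 1, 0, 1, 1])
        total, per = gev(maps, tmpl, labels)
        X = maps - maps.mean(axis=1, keepdims=True)
        Th = tmpl - tmpl.mean(axis=1, keepdims=True)
        g = np.sqrt((X**2).mean(axis=1))
        num = 0.0
        for t in range(5):
            r = np.corrcoef(X[t], Th[labels[t]])[0, 1]
            num += (g[t] * r) ** 2
        assert total == pytest.approx(num / np.sum(g**2))

    def test_label_permutation_invariance(self, templates4, rng):
        labels = rng.integers(0, 4, 50)
        maps = planted_maps(templates4, labels, np.ones(50)) + \
            0.1 * rng.normal(size=(50, 16))
        perm = np.array([2, 0, 3, 1])
        total1, per1 = gev(maps, templates4, labels)
        total2, per2 = gev(maps, templates4[np.argsort(perm)], perm[labels])
        assert total1 == pytest.approx(total2)
        np.testing.assert_allclose(np.sort(per1), np.sort(per2), atol=1e-12)


class TestSegmentPipeline:
    def test_shared_templates_and_boundaries(self, small_study, small_averages):
        stim_by, resp_by = small_averages
        grp = et.combine_group(stim_by, resp_by, small_study.rt_table, level="group")
        res = et.segment({c: grp[c].epoch for c in grp}, q_min=1, q_max=12)
        assert res.conditions == ("A", "B")
        lens = [grp[c].epoch.n_samples for c in res.conditions]
        assert len(res.labels) == sum(lens)
        assert len(res.labels_for("A")) == lens[0]
        assert 0 < res.gev_total <= 1
        assert res.gev_per_template.sum() == pytest.approx(res.gev_total)
        # every retained within-condition segment respects the 20 ms criterion
        min_samples = int(np.ceil(20.0 * res.fs / 1000.0))
        for _, _, dur in res.segment_durations_ms():
            assert dur >= min_samples * 1000.0 / res.fs - 1e-9

    def test_serial_shift_signature(self, small_study, small_averages):
        """The lengthened map delays the next map's onset in condition B but
        preserves that next map's own duration (the design's key signature)."""
        stim_by, resp_by = small_averages
        grp = et.combine_group(stim_by, resp_by, small_study.rt_table, level="group")
        res = et.segment({c: grp[c].epoch for c in grp}, q_min=1, q_max=12,
                         q=small_study.design.n_templates)
        # match segmentation templates to planted ones by correlation
        fidx = 5  # the map following the lengthened one
        matched = {}
        for k, tt in enumerate(small_study.templates):
            corrs = [abs(et.spatial_correlation(tt, t)) for t in res.templates]
            matched[k] = int(np.argmax(corrs))
        if matched[fidx] == matched[4]:
            pytest.skip("segmentation merged the two planted maps at this size")
        dt = 1000.0 / res.fs
        onset, dur = {}, {}
        for cond in res.conditions:
            lab = res.labels_for(cond)
            pts = np.flatnonzero(lab == matched[fidx])
            assert pts.size > 0
            onset[cond] = pts[0] * dt
            dur[cond] = pts.size * dt
        assert onset["B"] > onset["A"] + 15.0
        assert abs(dur["B"] - dur["A"]) < 30.0
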