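"""Template back-fitting, duration/GEV metrics and Wilcoxon comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

import erptopo as et
from erptopo.backfit import map_metrics, wilcoxon_signed_rank


def epoch_from_labels(templates, labels, fs=500.0, gain=2.0):
    data = (templates[np.asarray(labels)] * gain).T
    return et.ErpEpoch(data=data, fs=fs, alignment="combined")


class TestFitTemplates:
    def test_pure_template_stream(self, templates4):
        ep = epoch_from_labels(templates4, [2] * 50)
        labels, _ = et.fit_templates(ep, templates4)
        np.testing.assert_array_equal(labels, 2)

    def test_planted_boundary(self, templates4, rng):
        truth = np.array([0] * 60 + [3] * 60)
        data = (templates4[truth] * 2.0 + 0.05 * rng.normal(size=(120, 16))).T
        ep = et.ErpEpoch(data=data, fs=500.0, alignment="combined")
        labels, _ = et.fit_templates(ep, templates4)
        flips = np.flatnonzero(np.diff(labels) != 0)
        assert len(flips) == 1 and abs(flips[0] - 59) <= 1

    def test_tie_goes_to_lowest_index(self):
        # exactly equidistant map between two orthogonal templates
        t0 = np.array([1.0, -1.0, 0.0, 0.0])
        t1 = np.array([0.0, 0.0, 1.0, -1.0])
        mid = t0 + t1
        ep = et.ErpEpoch(data=np.tile(mid, (5, 1)).T, fs=500.0, alignment="combined")
        labels, _ = et.fit_templates(ep, np.vstack([t0, t1]))
        np.testing.assert_array_equal(labels, 0)

    def test_window_and_candidates(self, templates4):
        ep = epoch_from_labels(templates4, [0] * 100 + [1] * 100, fs=500.0)
        labels, sl = et.fit_templates(ep, templates4, window_ms=(200.0, 400.0),
                                      candidates=[1, 2])
        assert sl == slice(100, 200)
        np.testing.assert_array_equal(labels, 1)

    def test_flat_points_unlabeled(self, templates4):
        data = np.tile(templates4[0], (40, 1))
        data[10:15] = 0.0
        ep = et.ErpEpoch(data=data.T, fs=500.0, alignment="combined")
        labels, _ = et.fit_templates(ep, templates4)
        assert np.all(labels[10:15] == -1)
        assert np.all(labels[:10] == 0) and np.all(labels[15:] == 0)


class TestMapMetrics:
    def test_duration_arithmetic(self, templates4):
        ep = epoch_from_labels(templates4, [1] * 100, fs=500.0)
        labels, sl = et.fit_templates(ep, templates4)
        m = map_metrics(labels, ep, templates4, sl)
        assert m.loc[m.template == 1, "duration_ms"].item() == pytest.approx(200.0)
        assert m.loc[m.template == 0, "duration_ms"].item() == 0.0
        assert m.loc[m.template == 0, "gev"].item() == 0.0

    def test_run_length_encoding_oracle(self, templates4, rng):
        truth = rng.integers(0, 4, 200)
        ep = epoch_from_labels(templates4, truth, fs=512.0)
        labels, sl = et.fit_templates(ep, templates4)
        m = map_metrics(labels, ep, templates4, sl)
        for k in range(4):
            expected = np.sum(truth == k) * 1000.0 / 512.0
            assert m.loc[m.template == k, "duration_ms"].item() == pytest.approx(expected)

    def test_duration_conservation_and_gev_partition(self, templates4, rng):
        truth = rng.integers(0, 4, 150)
        data = (templates4[truth] * 2 + 0.3 * rng.normal(size=(150, 16))).T
        ep = et.ErpEpoch(data=data, fs=512.0, alignment="combined")
        labels, sl = et.fit_templates(ep, templates4)
        m = map_metrics(labels, ep, templates4, sl)
        assert m["duration_ms"].sum() == pytest.approx(ep.duration_ms, abs=1000.0 / 512.0)
        total, _ = et.gev(data.T, templates4, labels)
        assert m["gev"].sum() == pytest.approx(total, abs=1e-9)


def exact_signed_rank_oracle(d):
    """Two-sided exact p from full enumeration of sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.asarray(ws, dtype=float)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestWilcoxon:
    def test_identical_conditions(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank(np.ones(8), np.ones(8))
        assert res["p"] == 1.0

    def test_all_positive_n8_exact(self, rng):
        d = rng.uniform(0.5, 2.0, 8)
        res = wilcoxon_signed_rank(d)
        assert res["p"] == pytest.approx(exact_signed_rank_oracle(d))
        assert res["p"] == pytest.approx(2 / 256)
        assert res["z"] > 0

    @pytest.mark.parametrize("n", range(5, 11))
    def test_matches_enumeration_for_small_n(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, n)
            res = wilcoxon_signed_rank(d)
            assert res["p"] == pytest.approx(exact_signed_rank_oracle(d), abs=1e-12)

    def test_normal_approximation_large_n(self, rng):
        d = rng.normal(0.4, 1.0, 40)
        res = wilcoxon_signed_rank(d)
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(d, alternative="two-sided", method="approx",
                             correction=True)
        assert res["p"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_size_and_power_simulation(self):
        rej_null = rej_eff = 0
        n_sims = 60
        for s in range(n_sims):
            r = np.random.default_rng(s)
            rej_null += wilcoxon_signed_rank(r.normal(0, 10, 18))["p"] < 0.05
            rej_eff += wilcoxon_signed_rank(r.normal(30, 10, 18))["p"] < 0.05
        assert rej_null / n_sims < 0.15  # near-nominal size
        assert rej_eff / n_sims > 0.9    # clear power for a +30 effect


class TestCompareConditions:
    def _metrics(self, rng, effect=0.0):
        rows = []
        for s in range(10):
            base = rng.uniform(80, 120)
            for cond, shift in (("A", 0.0), ("B", effect)):
                rows.append({"subject_id": f"S{s:02d}", "condition": cond,
                             "template": 0,
                             "duration_ms": base + shift + rng.normal(0, 3),
                             "gev": 0.5})
        return pd.DataFrame(rows)

    def test_identical_conditions_p1(self, rng):
        m = self._metrics(rng)
        m["duration_ms"] = 100.0
        with pytest.warns(UserWarning):
            out = et.compare_conditions(m, "duration_ms")
        assert out["p"].item() == 1.0

    def test_planted_effect_detected(self, rng):
        out = et.compare_conditions(self._metrics(rng, effect=30.0), "duration_ms")
        assert out["p"].item() < 0.05
        assert out["z"].item() < 0  # A < B

    def test_needs_five_subjects(self, rng):
        m = self._metrics(rng)
        m = m[m.subject_id.isin([f"S{s:02d}" for s in range(4)])]
        with pytest.raises(ValueError, match=">= 5"):
            et.compare_conditions(m, "duration_ms")
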