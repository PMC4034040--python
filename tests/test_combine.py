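"""Combination of stimulus- and response-aligned epochs by production latency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import erptopo as et
from erptopo.combine import CombineError

SPEC = et.CombineSpec(stim_len_ms=500, resp_len_ms=500, resp_offset_ms=100)


class TestCombinedWindow:
    def test_worked_example_850ms(self):
        w = et.combined_window(850, SPEC)
        assert w.removed_ms == 250.0
        assert (w.resp_keep_start_ms, w.resp_keep_end_ms) == (-350.0, -100.0)

    def test_no_overlap_boundary_1100ms(self):
        w = et.combined_window(1100, SPEC)
        assert w.removed_ms == 0.0
        assert (w.resp_keep_start_ms, w.resp_keep_end_ms) == (-600.0, -100.0)

    def test_fast_trial_fully_removed(self):
        # rt - off <= stim length: the whole response epoch overlaps
        w = et.combined_window(600, SPEC)
        assert w.removed_ms == 500.0
        assert w.resp_keep_start_ms == w.resp_keep_end_ms == -100.0

    def test_rt_inside_offset_rejected(self):
        with pytest.raises(CombineError):
            et.combined_window(80, SPEC)

    @settings(derandomize=True)
    @given(rt=st.floats(150, 2000))
    def test_removed_matches_clamp_oracle_and_monotone(self, rt):
        w = et.combined_window(rt, SPEC)
        assert w.removed_ms == pytest.approx(min(max(500 - (rt - 600), 0), 500))
        w2 = et.combined_window(rt + 10, SPEC)
        assert w2.removed_ms <= w.removed_ms + 1e-9


def _trial(seed=0, **design_kw):
    kw = dict(n_electrodes=16, noise_rms_uv=0.5)
    kw.update(design_kw)
    design = et.SimulationDesign(**kw)
    rng = np.random.default_rng(seed)
    montage = et.make_montage(design.n_electrodes, seed)
    templates = et.make_templates(design.n_templates, montage, rng)
    return design, et.simulate_trial(design, templates, rng=rng, montage=montage)


class TestCombineEpochs:
    def test_continuity_oracle(self):
        """Epochs cut from one continuous trial recombine exactly."""
        _, sim = _trial(seed=5)
        c = et.combine_epochs(sim.stim, sim.resp, sim.rt_ms)
        n_pre = -sim.t0_smp
        truth = sim.continuous[:, n_pre:n_pre + c.epoch.n_samples]
        assert np.abs(c.epoch.data - truth).max() == 0.0
        assert c.epoch.alignment == "combined"

    def test_850_example_geometry(self):
        fs = 512.0
        rng = np.random.default_rng(0)
        stim = et.ErpEpoch(rng.normal(size=(8, 256)), fs, "stimulus")
        resp = et.ErpEpoch(rng.normal(size=(8, 256)), fs, "response", t0_ms=-600.0)
        c = et.combine_epochs(stim, resp, 850.0, SPEC)
        assert c.epoch.n_samples == round(750 * fs / 1000)
        assert c.removed_ms == pytest.approx(250.0)
        # first 500 ms is the stimulus epoch bit-for-bit
        np.testing.assert_array_equal(c.epoch.data[:, :256], stim.data)

    def test_degenerate_splice_stim_only(self):
        rng = np.random.default_rng(1)
        stim = et.ErpEpoch(rng.normal(size=(8, 256)), 512.0, "stimulus")
        resp = et.ErpEpoch(rng.normal(size=(8, 256)), 512.0, "response", t0_ms=-600.0)
        c = et.combine_epochs(stim, resp, 600.0, SPEC)  # rt == S + off
        assert c.stim_only
        np.testing.assert_array_equal(c.epoch.data, stim.data[:, :c.epoch.n_samples])

    def test_gap_requires_opt_in(self):
        rng = np.random.default_rng(2)
        stim = et.ErpEpoch(rng.normal(size=(8, 256)), 512.0, "stimulus")
        resp = et.ErpEpoch(rng.normal(size=(8, 256)), 512.0, "response", t0_ms=-600.0)
        with pytest.raises(CombineError, match="gap"):
            et.combine_epochs(stim, resp, 1300.0, SPEC)
        c = et.combine_epochs(stim, resp, 1300.0, SPEC, allow_gap=True)
        assert c.gap_mask is not None and c.gap_mask.any()
        assert np.isnan(c.epoch.data[:, c.gap_mask]).all()
        assert not np.isnan(c.epoch.data[:, ~c.gap_mask]).any()

    def test_fs_mismatch_and_bad_rt(self):
        rng = np.random.default_rng(3)
        stim = et.ErpEpoch(rng.normal(size=(8, 256)), 512.0, "stimulus")
        resp = et.ErpEpoch(rng.normal(size=(8, 250)), 500.0, "response", t0_ms=-600.0)
        with pytest.raises(CombineError, match="mismatch"):
            et.combine_epochs(stim, resp, 850.0)
        resp = et.ErpEpoch(rng.normal(size=(8, 256)), 512.0, "response", t0_ms=-600.0)
        with pytest.raises(CombineError):
            et.combine_epochs(stim, resp, 50.0)

    @settings(derandomize=True, max_examples=30)
    @given(rt=st.floats(620, 1090))
    def test_sample_count_contract(self, rt):
        rng = np.random.default_rng(4)
        stim = et.ErpEpoch(rng.normal(size=(4, 256)), 512.0, "stimulus")
        resp = et.ErpEpoch(rng.normal(size=(4, 256)), 512.0, "response", t0_ms=-600.0)
        c = et.combine_epochs(stim, resp, rt, SPEC)
        expected = round((rt - 100) * 512 / 1000)
        assert abs(c.epoch.n_samples - expected) <= 1


class TestCombineGroup:
    def test_single_subject_group_equals_subject(self, small_study, small_averages):
        stim_by, resp_by = small_averages
        one_stim = {k: v for k, v in stim_by.items() if k[0] == "S01"}
        one_resp = {k: v for k, v in resp_by.items() if k[0] == "S01"}
        rts = small_study.rt_table[small_study.rt_table.subject_id == "S01"]
        subj = et.combine_group(one_stim, one_resp, rts, level="subject")
        grp = et.combine_group(one_stim, one_resp, rts, level="group")
        for cond in grp:
            np.testing.assert_allclose(
                grp[cond].epoch.data, subj[("S01", cond)].epoch.data
            )

    def test_group_uses_mean_rt(self, rng):
        fs = 512.0
        stim_by, resp_by = {}, {}
        for sid in ("S01", "S02"):
            stim_by[(sid, "A")] = et.ErpEpoch(
                rng.normal(size=(8, 256)), fs, "stimulus", subject_id=sid, condition="A")
            resp_by[(sid, "A")] = et.ErpEpoch(
                rng.normal(size=(8, 256)), fs, "response", t0_ms=-600.0,
                subject_id=sid, condition="A")
        import pandas as pd
        rts = pd.DataFrame({"subject_id": ["S01", "S02"], "condition": ["A", "A"],
                            "trial": [0, 0], "rt_ms": [700.0, 900.0]})
        grp = et.combine_group(stim_by, resp_by, rts, SPEC, level="group")
        # mean RT 800 ms → combined covers 700 ms (within 1-sample quantization)
        assert abs(grp["A"].epoch.n_samples - round((800 - 100) * fs / 1000)) <= 1

    def test_per_subject_lengths_match_rts(self, small_study, small_averages):
        stim_by, resp_by = small_averages
        subj = et.combine_group(stim_by, resp_by, small_study.rt_table, level="subject")
        mean_rt = small_study.rt_table.groupby(["subject_id", "condition"])["rt_ms"].mean()
        off = small_study.design.resp_offset_ms
        fs = small_study.design.fs
        for k, c in subj.items():
            expected = round((mean_rt.loc[k] - off) * fs / 1000)
            assert abs(c.epoch.n_samples - expected) <= 1

    def test_missing_rt_lists_offenders(self, small_study, small_averages):
        stim_by, resp_by = small_averages
        rts = small_study.rt_table[small_study.rt_table.subject_id != "S03"]
        with pytest.raises(CombineError, match="S03"):
            et.combine_group(stim_by, resp_by, rts, level="subject")
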