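"""TMRM trace generation, parameter extraction, profiles and clustering."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mitomorph.simulate import (
    TracePreset,
    generate_condition_traces,
    generate_tmrm_traces,
    make_trace_preset,
)
from mitomorph.tmrm import (
    Trace,
    cluster_conditions,
    condition_profiles,
    extract_params_table,
    extract_trace_params,
    stdev_trace,
)


def _noiseless(name):
    p = make_trace_preset(name)
    return dataclasses.replace(p, noise_sd=0.0, flicker_rate_hz=0.0, t_half_jitter_s=0.0)


class TestStdevTrace:
    def test_uniform_frames_give_zero(self):
        frames = np.full((25, 20, 20), 7.0)
        mask = np.ones((20, 20), dtype=bool)
        tr = stdev_trace(frames, mask)
        assert np.allclose(tr.values, 0.0)

    def test_half_half_closed_form(self):
        """100 px, half at 10 and half at 30 -> population StDev 10."""
        frame = np.concatenate([np.full(50, 10.0), np.full(50, 30.0)]).reshape(10, 10)
        frames = np.tile(frame, (20, 1, 1))
        tr = stdev_trace(frames, np.ones((10, 10), dtype=bool))
        assert np.allclose(tr.values, 10.0)

    def test_redistribution_decreases_stdev(self):
        punctate = np.zeros((10, 10))
        punctate[0, 0] = 100.0
        uniform = np.full((10, 10), 1.0)  # same total intensity
        frames = np.stack([punctate] * 20 + [uniform] * 20)
        tr = stdev_trace(frames, np.ones((10, 10), dtype=bool))
        assert tr.values[0] > tr.values[-1]

    def test_empty_mask_and_short_stack_rejected(self):
        with pytest.raises(ValueError):
            stdev_trace(np.ones((25, 5, 5)), np.zeros((5, 5), dtype=bool))
        with pytest.raises(ValueError):
            stdev_trace(np.ones((10, 5, 5)), np.ones((5, 5), dtype=bool))


class TestExtraction:
    def test_constant_trace_censored(self):
        t = np.arange(301.0)
        p = extract_trace_params(Trace(0, t, np.full(301, 40.0)))
        assert (p.MAX, p.MIN, p.Y_spread) == (40.0, 40.0, 0.0)
        assert p.censored

    def test_step_trace(self):
        t = np.arange(301.0)
        v = np.where(t < 100, 40.0, 10.0)
        p = extract_trace_params(Trace(0, t, v))
        assert p.MAX == 40.0 and p.MIN == 10.0 and p.Y_spread == 30.0
        assert abs(p.t_half_decay - 100.0) <= 1.0

    def test_exponential_halflife_closed_form(self):
        tau = 80.0
        t = np.arange(301.0)
        v = 40.0 * np.exp(-t / tau)
        p = extract_trace_params(Trace(0, t, v))
        # median of first 10 points lowers MAX slightly below 40; allow 1 s on
        # top of the analytic tau*ln2
        assert abs(p.t_half_decay - tau * np.log(2)) <= 6.0

    def test_y_spread_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = np.clip(rng.normal(20, 5, 301), 0, None)
            p = extract_trace_params(Trace(0, np.arange(301.0), v))
            assert p.Y_spread == p.MAX - p.MIN

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            extract_trace_params(Trace(0, np.arange(10.0), np.ones(10)))

    def test_flicker_dips_do_not_trigger_crossing(self):
        """A transient dip below threshold shorter than the persistence
        window is ignored."""
        t = np.arange(301.0)
        v = np.full(301, 40.0)
        v[100:103] = 15.0  # 3-sample flicker below MAX/2
        p = extract_trace_params(Trace(0, t, v))
        assert p.censored


class TestGenerator:
    def test_trace_shape_and_reproducibility(self):
        df = generate_tmrm_traces("FM", 3, seed=9)
        assert df.groupby("cell_id").size().eq(301).all()
        assert df.equals(generate_tmrm_traces("FM", 3, seed=9))

    def test_noiseless_crossing_matches_planted_time(self):
        p = _noiseless("FM")
        df = generate_tmrm_traces(p, 1, seed=0)
        r = extract_params_table(df).iloc[0]
        assert abs(r.t_half_decay - 232.0) <= 1.0

    def test_inconsistent_preset_rejected(self):
        with pytest.raises(ValueError, match="never cross"):
            TracePreset("bad", max_level=10.0, min_level=6.0, t_half_s=100.0)

    def test_ba_preset_fully_censored(self):
        params = extract_params_table(generate_tmrm_traces("BA", 50, seed=2))
        assert params.censored.all()

    def test_csa_delays_collapse_relative_to_bss(self):
        bss = extract_params_table(generate_tmrm_traces("BSS", 50, seed=3))
        csa = extract_params_table(generate_tmrm_traces("CsA", 50, seed=4))
        assert csa.t_half_decay.mean() > bss.t_half_decay.mean()

    def test_fm_parameter_recovery(self):
        """Mean extracted t1/2 within 5 s of the planted 232 s; MAX within
        1 a.u. of the plateau."""
        params = extract_params_table(generate_tmrm_traces("FM", 100, seed=1))
        assert abs(params.t_half_decay.mean() - 232.0) <= 5.0
        assert abs(params.MAX.mean() - 40.0) <= 1.0


class TestProfilesAndClustering:
    def test_single_trace_profile_equals_trace(self):
        df = generate_tmrm_traces("BSS", 1, seed=5)
        df["condition"] = "BSS"
        prof = condition_profiles(df)
        assert np.allclose(prof.loc["BSS"].to_numpy(), df.sort_values("t")["value"].to_numpy())

    def test_identical_profiles_merge_at_height_zero(self):
        t = np.arange(301.0)
        prof = pd.DataFrame([np.sin(t / 50), np.sin(t / 50)], index=["a", "b"])
        out = cluster_conditions(prof)
        assert out["linkage"][0, 2] == 0.0

    def test_distances_match_brute_force(self):
        rng = np.random.default_rng(6)
        prof = pd.DataFrame(rng.normal(size=(4, 301)), index=list("abcd"))
        from scipy.spatial.distance import pdist

        Z = cluster_conditions(prof)["linkage"]
        # first merge joins the closest pair at their Euclidean distance
        d = pdist(prof.to_numpy())
        assert Z[0, 2] == pytest.approx(d.min())

    def test_three_condition_groups_recovered(self):
        tr = generate_condition_traces(
            10,
            seed=5,
            conditions=["FM", "BSS", "ceramide", "TNFa", "TRAIL", "camptothecin",
                        "oligomycin", "CCCP", "thapsigargin"],
        )
        out = cluster_conditions(condition_profiles(tr))
        groups = out["cut"](3)
        assert groups["FM"] == groups["BSS"] == groups["ceramide"]
        assert groups["TNFa"] == groups["TRAIL"] == groups["camptothecin"] == groups["oligomycin"]
        assert groups["CCCP"] == groups["thapsigargin"]
        assert len({groups["FM"], groups["TNFa"], groups["CCCP"]}) == 3

    def test_fm_profile_monotone_after_smoothing(self):
        df = generate_tmrm_traces("FM", 30, seed=7)
        df["condition"] = "FM"
        prof = condition_profiles(df).loc["FM"].to_numpy()
        smoothed = np.convolve(prof, np.ones(10) / 10, mode="valid")
        assert (np.diff(smoothed) <= 0.15).all()  # non-increasing up to noise
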