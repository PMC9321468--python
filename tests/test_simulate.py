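"""Generator tests: determinism, ledger structure, calibration, artifacts,
behavioural regimes."""
import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from vpckit import (SIM_BANDS, SimulationConfig, inject_dbs_artifact,
                    simulate_behavior, simulate_ledger, simulate_lfp,
                    simulate_session, state_sequence_from_events)
from vpckit.config import STATE_CODES
from vpckit.simulate import _pulse_train

from conftest import small_config


def _welch_band_power(x, fs, band):
    f, p = sps.welch(x, fs=fs, nperseg=int(10 * fs))
    m = (f >= band[0]) & (f < band[1])
    return float(p[m].sum() * (f[1] - f[0]))


class TestDeterminismAndDegenerates:
    def test_same_seed_bit_identical(self):
        a = simulate_session(small_config(seed=7))
        b = simulate_session(small_config(seed=7))
        assert a[0].signals.tobytes() == b[0].signals.tobytes()
        assert a[0].eeg.tobytes() == b[0].eeg.tobytes()
        assert np.array_equal(a[1].eye_r, b[1].eye_r)
        pd.testing.assert_frame_equal(a[2].blocks, b[2].blocks)
        pd.testing.assert_frame_equal(a[2].events, b[2].events)

    def test_zero_probability_means_no_events(self):
        cfg = small_config(vpc_prob_by_condition={c: 0.0 for c in
                                                  ("NS", "10Hz", "50Hz", "200Hz")},
                           str_prob=0.0)
        _, _, ledger, truth = simulate_session(cfg)
        assert len(truth.true_events) == 0
        assert np.all(truth.state_sequence == STATE_CODES["wake"])

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(vpc_prob_by_condition={"NS": 1.2, "10Hz": 0.2,
                                                    "50Hz": 0.2, "200Hz": 0.2})
        with pytest.raises(ValueError):
            small_config(vpc_prob_by_condition={"NS": 0.95, "10Hz": 0.2,
                                                "50Hz": 0.2, "200Hz": 0.2},
                         kindling_slope=0.2)


class TestLedger:
    def test_events_lie_inside_their_block_with_consistent_stim_flag(self):
        cfg = small_config(seed=2, n_blocks_rest=6, n_blocks_fix=0)
        ledger = simulate_ledger(cfg)
        for _, ev in ledger.events.iterrows():
            blk = ledger.blocks[ledger.blocks.block_id == ev.block_id].iloc[0]
            assert blk.t_start <= ev.event_onset < ev.event_offset <= blk.t_end
            stims = ledger.stim_epochs(ev.block_id)
            inside = bool(((stims.stim_start <= ev.event_onset)
                           & (ev.event_onset < stims.stim_end)).any()) \
                if len(stims) else False
            if ev.event_type == "VPC":
                assert bool(ev.in_stim) == inside

    def test_stim_epochs_only_in_stim_blocks(self):
        ledger = simulate_ledger(small_config(seed=3))
        ns_blocks = set(ledger.blocks[ledger.blocks.condition == "NS"].block_id)
        assert not set(ledger.stims.block_id) & ns_blocks

    def test_kindling_raises_event_rate(self):
        base = dict(n_blocks_rest=0, n_blocks_fix=0, block_duration=420.0,
                    vpc_prob_by_condition={c: 0.1 for c in
                                           ("NS", "10Hz", "50Hz", "200Hz")},
                    str_prob=0.0)
        sched = [("Stim", 300)]
        lo = simulate_ledger(SimulationConfig(**base, kindling_slope=0.0, seed=4),
                             series_schedule=sched)
        hi = simulate_ledger(SimulationConfig(**base, kindling_slope=0.5, seed=4),
                             series_schedule=sched)
        assert hi.event_rate("VPC") > lo.event_rate("VPC")


@pytest.fixture(scope="module")
def two_state_bipolar():
    cfg = small_config(seed=9, n_blocks_rest=1, n_blocks_fix=0,
                       block_duration=120.0)
    out = {}
    for state in ("wake", "vpc"):
        states = np.full(120_000, STATE_CODES[state], np.uint8)
        rec = simulate_lfp(states, cfg)
        # adjacent-contact difference on the first probe
        out[state] = (rec.signals[0].astype(float) - rec.signals[1].astype(float),
                      rec.signals[4].astype(float) - rec.signals[5].astype(float),
                      cfg)
    return out


class TestLfpCalibration:
    def test_band_power_within_20_percent(self, two_state_bipolar):
        for state, (s1, _, cfg) in two_state_bipolar.items():
            for band, target in cfg.state_spectra[state].items():
                measured = _welch_band_power(s1, 1000.0, SIM_BANDS[band])
                assert abs(measured - target) <= 0.2 * target, (state, band)

    def test_cross_area_coherence_within_tolerance(self, two_state_bipolar):
        from vpckit import pooled_coherence
        for state, (s1, s2, cfg) in two_state_bipolar.items():
            f, coh = pooled_coherence(s1, s2, 1000.0)
            for band, target in cfg.state_coupling[state].items():
                lo, hi = SIM_BANDS[band]
                m = (f >= lo) & (f < hi)
                assert abs(float(coh[m].mean()) - target) <= 0.1, (state, band)

    def test_vpc_theta_coherence_exceeds_wake(self, two_state_bipolar):
        from vpckit import pooled_coherence
        vals = {}
        for state, (s1, s2, _) in two_state_bipolar.items():
            f, coh = pooled_coherence(s1, s2, 1000.0)
            m = (f >= 4) & (f < 8)
            vals[state] = float(coh[m].mean())
        assert vals["vpc"] > vals["wake"]

    def test_unreachable_coherence_target_rejected(self):
        cfg = small_config()
        coupling = {s: dict(b) for s, b in cfg.state_coupling.items()}
        coupling["wake"]["delta"] = 0.99
        bad = small_config(state_coupling=coupling)
        states = np.full(2000, STATE_CODES["wake"], np.uint8)
        with pytest.raises(ValueError, match="unreachable"):
            simulate_lfp(states, bad)


class TestArtifacts:
    def test_pulse_count_matches_rate(self):
        train = _pulse_train([(0.0, 60.0)], 10.0, 1.0, 61_000, 1000.0, 61.0)
        assert int(np.sum(train < 0)) == 600

    def test_zero_amplitude_is_identity(self, small_session):
        rec = small_session[0]
        out = inject_dbs_artifact(rec, [(10.0, 20.0)], 50.0, 0.0)
        assert np.array_equal(out.signals, rec.signals)

    def test_psd_line_at_stim_frequency(self):
        cfg = small_config(seed=1, n_blocks_rest=1, n_blocks_fix=0,
                           block_duration=120.0)
        states = np.full(120_000, STATE_CODES["wake"], np.uint8)
        rec = simulate_lfp(states, cfg)
        out = inject_dbs_artifact(rec, [(10.0, 70.0)], 200.0, 20.0)
        seg = out.signals[0, 10_000:70_000].astype(float)
        f, p = sps.welch(seg, fs=1000.0, nperseg=4096)
        at = p[np.argmin(np.abs(f - 200.0))]
        neighbors = p[(np.abs(f - 200.0) > 10) & (np.abs(f - 200.0) < 40)].mean()
        assert at > 10 * neighbors

    def test_overlapping_epochs_rejected(self, small_session):
        with pytest.raises(ValueError, match="overlap"):
            inject_dbs_artifact(small_session[0], [(0.0, 60.0), (30.0, 90.0)],
                                10.0, 1.0)


class TestBehavior:
    def test_wake_has_no_long_stable_gaze(self):
        from vpckit.detect import gaze_stability
        cfg = small_config(seed=5)
        states = np.full(300_000, STATE_CODES["wake"], np.uint8)
        beh = simulate_behavior(states, cfg)
        _, segs = gaze_stability(beh.eye_r, beh.eye_theta, 1000.0)
        assert not any(t1 - t0 > 4.2 for t0, t1 in segs)

    def test_event_freezes_gaze_and_quiets_face(self):
        cfg = small_config(seed=6)
        states = np.full(120_000, STATE_CODES["wake"], np.uint8)
        states[40_000:57_000] = STATE_CODES["vpc"]   # 17 s event
        events = pd.DataFrame([{"block_id": 0, "event_type": "VPC",
                                "event_onset": 40.0, "event_offset": 57.0,
                                "in_stim": False}])
        assert np.array_equal(
            state_sequence_from_events(events, 120_000, 1000.0), states)
        beh = simulate_behavior(states, cfg)
        x = beh.eye_r * np.cos(beh.eye_theta)
        y = beh.eye_r * np.sin(beh.eye_theta)
        # net gaze displacement across the event ~ drift rate * duration
        disp = np.hypot(x[56_500] - x[40_500], y[56_500] - y[40_500])
        assert disp < 5.0
        mouth = np.abs(np.gradient(beh.mouth_lum))
        f0, f1 = int(40 * 30), int(57 * 30)
        wake_mask = np.ones(len(mouth), bool)
        wake_mask[f0:f1] = False
        assert np.median(mouth[f0:f1]) < np.median(mouth[wake_mask])

    def test_zero_length_session(self):
        beh = simulate_behavior(np.zeros(0, np.uint8), small_config())
        assert len(beh.eye_r) == 0 and len(beh.mouth_lum) == 0


class TestSessionAssembly:
    def test_state_sequence_matches_true_events(self, small_session):
        _, _, _, truth = small_session
        fs = 1000.0
        for _, ev in truth.true_events.iterrows():
            code = STATE_CODES["vpc" if ev.event_type == "VPC" else "str"]
            i0 = int(ev.event_onset * fs) + 1
            i1 = int(ev.event_offset * fs) - 1
            assert np.all(truth.state_sequence[i0:i1] == code)

    def test_vpc_spike_rate_scaled_down(self, small_session):
        rec, _, _, truth = small_session
        fs = 1000.0
        vpc = truth.true_events[truth.true_events.event_type == "VPC"]
        wake_dur = np.sum(truth.state_sequence == STATE_CODES["wake"]) / fs
        vpc_dur = np.sum(truth.state_sequence == STATE_CODES["vpc"]) / fs
        n_wake = n_vpc = 0
        for u in rec.spikes:
            t = u["times"]
            codes = truth.state_sequence[np.minimum((t * fs).astype(int),
                                                    len(truth.state_sequence) - 1)]
            n_wake += np.sum(codes == STATE_CODES["wake"])
            n_vpc += np.sum(codes == STATE_CODES["vpc"])
        assert vpc_dur > 10
        assert (n_vpc / vpc_dur) < 0.8 * (n_wake / wake_dur)
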