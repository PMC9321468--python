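"""Synthetic session generator.

Produces complete sessions (multichannel LFP + EEG, eye and face traces,
stimulation/event ledger, ground truth) with the statistical structure the
downstream analyses assume:

* per-block behavioural-arrest events ("VPC") drawn with condition-dependent
  probabilities plus a kindling term in local stimulation predominance, and
  condition-independent control stares ("STR");
* LFPs built from state-gated narrowband stochastic oscillators shared across
  areas (which makes band power and cross-area coherence analytically
  controllable) on top of independent 1/f backgrounds and a common reference;
* a neural regime that switches to elevated 1-15 Hz power and elevated
  low-frequency coherence three seconds before behavioural event onset;
* wake behaviour as saccadic scanning with blinks and face movement, versus
  frozen gaze with slow drift and a quiet face during events.

Calibration targets are expressed at the level of *bipolar-derived* signals,
since every analysis consumes bipolar LFPs.  Source loadings alternate with
contact depth (``1 +- loading_contrast``) so that adjacent-contact differences
retain the oscillatory content while a common reference cancels exactly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import CONDITIONS, SIM_BANDS, STATE_CODES, STIM_FREQ, SimulationConfig
from .session import BehavioralSuite, EventLedger, GroundTruth, SessionRecording

# ---------------------------------------------------------------------------
# Filters and analytic band-power bookkeeping

_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def _band_sos(band: tuple[float, float], fs: float):
    return sps.butter(4, band, btype="bandpass", fs=fs, output="sos")


def _band_stats(fs: float) -> dict:
    """Per-band filter and total output variance for unit white input, plus
    the leakage matrix L[m, s]: the fraction of source band s's variance that
    lands inside measured band m (filters are not brick-wall, so neighbouring
    sources leak across band edges; calibration solves the full system)."""
    out: dict = {}
    freqs = np.linspace(0.0, fs / 2.0, 8192)
    names = list(SIM_BANDS)
    powers = {}
    for name, (lo, hi) in SIM_BANDS.items():
        sos = _band_sos((lo, hi), fs)
        _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
        powers[name] = np.abs(h) ** 2
        out[name] = {"sos": sos, "var": float(np.mean(powers[name]))}
    leak = np.empty((len(names), len(names)))
    for mi, m in enumerate(names):
        lo, hi = SIM_BANDS[m]
        in_band = (freqs >= lo) & (freqs < hi)
        for si, s in enumerate(names):
            leak[mi, si] = float(np.sum(powers[s][in_band]) / np.sum(powers[s]))
    out["_leak"] = leak
    out["_names"] = names
    return out


def _pink_band_vars(fs: float, scale: float) -> dict:
    """In-band variance of the 1/f background at a given total std ``scale``."""
    freqs = np.linspace(0.0, fs / 2.0, 8192)
    w = 2.0 * np.pi * freqs / fs
    _, h = sps.freqz(_PINK_B, _PINK_A, worN=w)
    p = np.abs(h) ** 2
    total = np.sum(p)
    out = {}
    for name, (lo, hi) in SIM_BANDS.items():
        in_band = (freqs >= lo) & (freqs < hi)
        out[name] = scale**2 * float(np.sum(p[in_band]) / total)
    return out


def _unit_band_noise(sos, var: float, n: int, rng) -> np.ndarray:
    return sps.sosfilt(sos, rng.standard_normal(n)) / np.sqrt(var)


def _pink_total_var() -> float:
    # total variance of the pink filter output for unit white input
    _, h = sps.freqz(_PINK_B, _PINK_A, worN=4096)
    return float(np.mean(np.abs(h) ** 2))


_PINK_VAR = _pink_total_var()


def _pink_noise(n: int, scale: float, rng, dtype=np.float64) -> np.ndarray:
    w = rng.standard_normal(n, dtype=np.float32) if dtype == np.float32 \
        else rng.standard_normal(n)
    x = sps.lfilter(_PINK_B.astype(dtype), _PINK_A.astype(dtype), w.astype(dtype))
    return (dtype(scale / np.sqrt(_PINK_VAR))) * x


def _movavg(x: np.ndarray, size: int) -> np.ndarray:
    """Edge-padded moving average (cumsum implementation, O(n))."""
    if size <= 1:
        return np.asarray(x, dtype=float)
    half = size // 2
    xp = np.concatenate([np.full(half, x[0]), x, np.full(size - half - 1, x[-1])])
    c = np.concatenate([[0.0], np.cumsum(xp)])
    return (c[size:] - c[:-size]) / size


# ---------------------------------------------------------------------------
# Gain calibration

def _solve_source_powers(leak: np.ndarray, targets: np.ndarray,
                         tol: np.ndarray, label: str) -> np.ndarray:
    from scipy.optimize import nnls
    powers, _ = nnls(leak, np.maximum(targets, 0.0))
    resid = leak @ powers - targets
    if np.any(np.abs(resid) > tol):
        raise ValueError(f"{label}: targets unreachable (best achievable misses "
                         f"by {np.abs(resid).max():.3f}); adjust spectra, "
                         "coupling or noise settings")
    return powers


def _state_gains(config: SimulationConfig, band_stats: dict, pink_in: dict) -> dict:
    """Monopolar source gains per (state, band) hitting the bipolar targets.

    With depth-alternating loadings ``1 +- g`` the bipolar transfer of any
    area-level source is ``2 g``; a bipolar channel also carries the 1/f
    background of its two contacts.  Per state the in-band power budget

        L @ p_total + 2 pink_in = P_target        (band power)
        L @ p_shared             = C_target * P_target   (coherent part)

    is solved through the leakage matrix L, giving shared/independent source
    powers; negative solutions mean the targets are unreachable above the
    noise floor and raise.
    """
    leak = band_stats["_leak"]
    names = band_stats["_names"]
    twog = 2.0 * config.loading_contrast
    gains: dict = {}
    for state, spectra in config.state_spectra.items():
        coupling = config.state_coupling[state]
        p_target = np.array([spectra[b] for b in names])
        pink_vec = np.array([2.0 * pink_in[b] for b in names])
        c_target = np.array([coupling[b] for b in names])
        p_total = _solve_source_powers(leak, p_target - pink_vec,
                                       0.10 * p_target, f"band power {state}")
        p_shared = _solve_source_powers(leak, c_target * p_target,
                                        0.08 * p_target, f"coherence {state}")
        p_indep = p_total - p_shared
        if np.any(p_indep < -1e-9):
            raise ValueError(f"coherence target in state {state} unreachable "
                             "above the 1/f noise floor")
        p_indep = np.maximum(p_indep, 0.0)
        gains[state] = {b: (np.sqrt(p_shared[i]) / twog, np.sqrt(p_indep[i]) / twog)
                        for i, b in enumerate(names)}
    return gains


def _eeg_gains(config: SimulationConfig, band_stats: dict, pink_in: dict) -> dict:
    leak = band_stats["_leak"]
    names = band_stats["_names"]
    gains: dict = {}
    for state, spectra in config.eeg_spectra.items():
        p_target = np.array([spectra[b] for b in names])
        pink_vec = np.array([pink_in[b] for b in names])
        p = _solve_source_powers(leak, p_target - pink_vec, 0.10 * p_target,
                                 f"EEG {state}")
        gains[state] = {b: np.sqrt(p[i]) for i, b in enumerate(names)}
    return gains


def expected_coherence(config: SimulationConfig, state: str, band: str) -> float:
    """Calibrated cross-area magnitude-coherence target."""
    return float(config.state_coupling[state][band])


def expected_band_power(config: SimulationConfig, state: str, band: str) -> float:
    """Calibrated in-band power of a bipolar-derived LFP (a.u.)."""
    return float(config.state_spectra[state][band])


# ---------------------------------------------------------------------------
# Ledger simulation

def _truncnorm(mean: float, sd: float, lo: float, rng) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= lo:
            return float(x)
    return lo


def simulate_ledger(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    series_schedule: list[tuple[str, int]] | None = None,
    transition_blocks: int = 32,
) -> EventLedger:
    """Draw the block structure and behavioural events of one session.

    ``series_schedule`` optionally overrides the single-series default with a
    list of ``(series_type, n_blocks)`` segments, e.g. alternating Stim and
    No-Stim series across many days; the first ``transition_blocks`` blocks of
    each segment are labelled "transition", the rest "established".

    Events are Bernoulli draws per block with probability
    ``p(condition) [* fix scale in FX blocks] + kindling_slope * LSP`` where
    LSP is the fraction of stimulation blocks in the trailing kindling window.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    conds = list(config.conditions)

    rows = []
    if series_schedule is None:
        # Interleave RW and FX blocks; pseudorandom condition order per run.
        n_pairs = max(config.n_blocks_rest, config.n_blocks_fix)
        order: list[str] = []
        while len(order) < n_pairs:
            order.extend(rng.permutation(conds))
        n_rw = n_fx = 0
        for cond in order:
            if n_rw >= config.n_blocks_rest and n_fx >= config.n_blocks_fix:
                break
            c = cond if config.series == "Stim" else "NS"
            if n_rw < config.n_blocks_rest:
                rows.append({"task": "RW", "condition": c, "series": config.series,
                             "series_phase": config.series_phase})
                n_rw += 1
            if n_fx < config.n_blocks_fix:
                rows.append({"task": "FX", "condition": c, "series": config.series,
                             "series_phase": config.series_phase})
                n_fx += 1
    else:
        for series, n_blocks in series_schedule:
            order = []
            while len(order) < n_blocks:
                order.extend(rng.permutation(conds))
            for i in range(n_blocks):
                c = order[i] if series == "Stim" else "NS"
                phase = "transition" if i < transition_blocks else "established"
                rows.append({"task": "RW", "condition": c, "series": series,
                             "series_phase": phase})

    blocks = pd.DataFrame(rows)
    blocks["block_id"] = np.arange(len(blocks))
    blocks["t_start"] = blocks.block_id * config.block_duration
    blocks["t_end"] = blocks.t_start + config.block_duration
    blocks = blocks[["block_id", "task", "condition", "series", "series_phase",
                     "t_start", "t_end"]]

    stim_rows = []
    for _, blk in blocks.iterrows():
        if blk.condition == "NS":
            continue
        for onset in list(config.stim_onsets)[: config.stim_epochs_per_block]:
            stim_rows.append({"block_id": blk.block_id, "condition": blk.condition,
                              "stim_start": blk.t_start + onset,
                              "stim_end": blk.t_start + onset + config.stim_duration})
    stims = pd.DataFrame(stim_rows, columns=["block_id", "condition", "stim_start", "stim_end"])

    # Event draws with kindling on local stimulation predominance.
    is_stim_block = (blocks.condition != "NS").to_numpy()
    event_rows = []
    for i, blk in blocks.iterrows():
        lo = max(0, i - config.kindling_window + 1)
        lsp = float(np.mean(is_stim_block[lo: i + 1]))
        scale = config.fix_event_scale if blk.task == "FX" else 1.0
        p_vpc = config.vpc_prob_by_condition[blk.condition] * scale \
            + config.kindling_slope * lsp * scale
        if not 0.0 <= p_vpc <= 1.0:
            raise ValueError(f"event probability {p_vpc:.3f} outside [0, 1] after kindling")
        intervals: list[tuple[float, float]] = []

        def _place(duration: float, in_stim: bool) -> tuple[float, float] | None:
            margin_lo = blk.t_start + 35.0
            margin_hi = blk.t_end - duration - 5.0
            if margin_hi <= margin_lo:
                return None
            block_stims = stims[stims.block_id == blk.block_id] if not stims.empty else stims
            for _ in range(50):
                if in_stim and len(block_stims):
                    s = block_stims.iloc[rng.integers(len(block_stims))]
                    onset = rng.uniform(max(s.stim_start, margin_lo),
                                        min(s.stim_end, margin_hi))
                else:
                    onset = rng.uniform(margin_lo, margin_hi)
                    if len(block_stims) and bool(
                            ((block_stims.stim_start <= onset)
                             & (onset < block_stims.stim_end)).any()):
                        continue   # keep the inside/outside intent exact
                offset = onset + duration
                if all(offset + 2.0 < a or b + 2.0 < onset for a, b in intervals):
                    return onset, offset
            return None

        n_ev = 0
        if rng.random() < p_vpc and n_ev < config.max_events_per_block:
            dur = _truncnorm(*config.vpc_duration[:2], config.vpc_duration[2], rng)
            in_stim = bool(is_stim_block[i]) and rng.random() < config.p_event_in_stim
            placed = _place(dur, in_stim)
            if placed:
                event_rows.append({"block_id": blk.block_id, "event_type": "VPC",
                                   "event_onset": placed[0], "event_offset": placed[1],
                                   "in_stim": in_stim})
                intervals.append(placed)
                n_ev += 1
        if rng.random() < config.str_prob * scale:
            dur = _truncnorm(*config.str_duration[:2], config.str_duration[2], rng)
            placed = _place(dur, False)
            if placed:
                event_rows.append({"block_id": blk.block_id, "event_type": "STR",
                                   "event_onset": placed[0], "event_offset": placed[1],
                                   "in_stim": False})

    events = pd.DataFrame(event_rows,
                          columns=["block_id", "event_type", "event_onset",
                                   "event_offset", "in_stim"])
    return EventLedger(blocks=blocks, stims=stims, events=events)


def state_sequence_from_events(events: pd.DataFrame, n_samples: int, fs: float,
                               lead: float = 0.0) -> np.ndarray:
    """Per-sample state codes; ``lead`` starts states early (neural regime)."""
    seq = np.full(n_samples, STATE_CODES["wake"], dtype=np.uint8)
    if events is None or len(events) == 0:
        return seq
    for _, ev in events.iterrows():
        code = STATE_CODES["vpc"] if ev.event_type == "VPC" else STATE_CODES["str"]
        i0 = max(0, int((ev.event_onset - lead) * fs))
        i1 = min(n_samples, int(ev.event_offset * fs))
        seq[i0:i1] = code
    return seq


# ---------------------------------------------------------------------------
# LFP / EEG simulation

def _channel_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for probe_idx, (area, layer, n) in enumerate(config.areas):
        probe = f"{area}_{layer}" if layer != "none" else area
        for c in range(n):
            rows.append({"probe": probe, "area": area, "layer": layer, "contact": c})
    return pd.DataFrame(rows)


def _state_weights(state_sequence: np.ndarray, smooth: int) -> dict:
    """Smoothed one-hot weight per state code present (0.5 s ramps between
    regimes); a lone state maps to the scalar 1.0."""
    present = np.unique(state_sequence)
    if len(present) == 1:
        return {int(present[0]): 1.0}
    return {int(code): _movavg((state_sequence == code).astype(float), smooth)
            for code in present}


def simulate_lfp(
    state_sequence: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SessionRecording:
    """Synthesize multichannel LFP + EEG following a per-sample state path.

    Each area receives a globally shared narrowband source (setting cross-area
    coherence) and an area-private source per band, both gated by state; every
    contact adds an independent 1/f background and a common reference term.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    fs = config.sample_rate
    n = len(state_sequence)
    bands = _band_stats(fs)
    pink_in = _pink_band_vars(fs, config.pink_scale)
    gains = _state_gains(config, bands, pink_in)
    eeg_gains = _eeg_gains(config, bands, _pink_band_vars(fs, config.pink_scale))
    smooth = max(1, int(0.5 * fs))
    code_to_name = {v: k for k, v in STATE_CODES.items()}
    for code in np.unique(state_sequence):
        if code_to_name.get(int(code)) not in config.state_spectra:
            raise ValueError(f"state code {code} lacks a spectral definition")
    weights = _state_weights(state_sequence, smooth)

    meta = _channel_table(config)
    areas = list(dict.fromkeys(meta.area))
    n_ch = len(meta)

    shared = {b: _unit_band_noise(bands[b]["sos"], bands[b]["var"], n, rng)
              for b in SIM_BANDS}

    # Area-level oscillatory mixtures (identical for contacts of one area):
    # one fixed per-state mixture per area, cross-faded by the state weights.
    area_mix = {}
    for a in areas:
        src = {b: _unit_band_noise(bands[b]["sos"], bands[b]["var"], n, rng)
               for b in SIM_BANDS}
        acc = np.zeros(n)
        for code, w in weights.items():
            g = gains[code_to_name[code]]
            base = np.zeros(n)
            for b in SIM_BANDS:
                base += g[b][0] * shared[b] + g[b][1] * src[b]
            acc += w * base
        area_mix[a] = acc

    ref = _pink_noise(n, config.ref_scale, rng, dtype=np.float32)
    # precompute the two loading variants per area in float32
    base32 = {}
    for a in areas:
        for parity in (1.0, -1.0):
            loading = 1.0 + config.loading_contrast * parity
            base32[(a, parity)] = (loading * area_mix[a]).astype(np.float32) + ref
    signals = np.empty((n_ch, n), dtype=np.float32)
    for i, row in meta.iterrows():
        parity = (-1.0) ** row.contact
        signals[i] = base32[(row.area, parity)]
        signals[i] += _pink_noise(n, config.pink_scale, rng, dtype=np.float32)

    eeg = np.zeros(n)
    eeg_src = {b: _unit_band_noise(bands[b]["sos"], bands[b]["var"], n, rng)
               for b in SIM_BANDS}
    for code, w in weights.items():
        g = eeg_gains[code_to_name[code]]
        base = np.zeros(n)
        for b in SIM_BANDS:
            base += g[b] * eeg_src[b]
        eeg += w * base
    eeg += _pink_noise(n, config.pink_scale, rng)

    return SessionRecording(signals=signals, sample_rate=fs, channel_meta=meta,
                            eeg=eeg.astype(np.float32))


def inject_dbs_artifact(
    rec: SessionRecording,
    epochs: list[tuple[float, float]],
    freq: float,
    amplitude: float,
) -> SessionRecording:
    """Add a biphasic pulse train (400 us pulses, negative phase first) to all
    channels during the given epochs.  Returns a new recording."""
    if freq not in (10.0, 50.0, 200.0, 10, 50, 200):
        raise ValueError("stimulation frequency must be 10, 50 or 200 Hz")
    epochs = sorted(epochs)
    for (a0, a1), (b0, b1) in zip(epochs, epochs[1:]):
        if b0 < a1:
            raise ValueError("overlapping stimulation epochs")
    fs = rec.sample_rate
    n = rec.n_samples
    train = _pulse_train(epochs, freq, amplitude, n, fs, rec.duration)
    signals = rec.signals + train[None, :]
    eeg = rec.eeg + train if rec.eeg is not None else None
    return SessionRecording(signals=signals, sample_rate=fs,
                            channel_meta=rec.channel_meta, eeg=eeg, spikes=rec.spikes)


def pulse_times(start: float, end: float, freq: float) -> np.ndarray:
    """Pulse onset times of a stimulation epoch (one pulse per cycle)."""
    n_pulses = int(round((end - start) * freq))
    return start + np.arange(n_pulses) / freq


def _pulse_train(epochs, freq: float, amplitude: float, n: int, fs: float,
                 duration: float) -> np.ndarray:
    train = np.zeros(n, dtype=np.float32)
    for start, end in epochs:
        if start < 0 or end > duration + 1e-9:
            raise ValueError("stimulation epoch outside session")
        idx = (pulse_times(start, end, freq) * fs).astype(int)
        idx = idx[idx + 1 < n]
        train[idx] -= amplitude       # negative phase first
        train[idx + 1] += amplitude
    return train


# ---------------------------------------------------------------------------
# Behaviour simulation

def simulate_behavior(
    state_sequence: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ledger: EventLedger | None = None,
) -> BehavioralSuite:
    """Eye position (polar, tracker clock) and face luminance (video clock).

    Wake: saccadic scanning (inter-saccade 0.2-1 s), blinks, intermittent
    mouth/nose movement.  Events: frozen gaze with slow drift, open eyes and a
    quiet face; in FX blocks the frozen gaze sits off the fixation target.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    fs = config.sample_rate
    n = len(state_sequence)
    if n == 0:
        return BehavioralSuite(eye_r=np.array([]), eye_theta=np.array([]),
                               eye_lum=np.array([]), mouth_lum=np.array([]),
                               nose_lum=np.array([]), sample_rate=fs,
                               frame_rate=config.frame_rate, fixation_target=(0.0, 0.0))
    wake_code = STATE_CODES["wake"]

    in_fx = np.zeros(n, dtype=bool)
    if ledger is not None:
        for _, blk in ledger.blocks.iterrows():
            if blk.task == "FX":
                in_fx[int(blk.t_start * fs): int(blk.t_end * fs)] = True

    x = np.empty(n)
    y = np.empty(n)
    t = 0
    pos = np.array([5.0, 0.0])
    while t < n:
        state = state_sequence[t]
        if state != wake_code:
            # frozen gaze: drift at a constant slow rate in a random direction
            run_end = t
            while run_end < n and state_sequence[run_end] == state:
                run_end += 1
            if in_fx[t]:
                ang = rng.uniform(0, 2 * np.pi)
                pos = np.array([np.cos(ang), np.sin(ang)]) * rng.uniform(5.0, 9.0)
            direction = rng.uniform(0, 2 * np.pi)
            dt = np.arange(run_end - t) / fs
            x[t:run_end] = pos[0] + config.drift_rate * dt * np.cos(direction)
            y[t:run_end] = pos[1] + config.drift_rate * dt * np.sin(direction)
            pos = np.array([x[run_end - 1], y[run_end - 1]])
            t = run_end
            continue
        # wake fixation segment until next saccade
        if in_fx[t]:
            hold = rng.uniform(0.5, 2.0)
        else:
            lo, hi = config.saccade_interval
            hold = rng.uniform(lo, hi)
            if config.long_stare_rate > 0 and rng.random() < config.long_stare_rate:
                hold = rng.exponential(2.0)
        run_end = min(n, t + max(1, int(hold * fs)))
        # truncate at a state change
        change = np.nonzero(state_sequence[t:run_end] != wake_code)[0]
        if len(change):
            run_end = t + int(change[0])
        x[t:run_end] = pos[0]
        y[t:run_end] = pos[1]
        t = run_end
        if t < n and state_sequence[t] == wake_code:
            if in_fx[t]:
                ang = rng.uniform(0, 2 * np.pi)
                amp = rng.uniform(0.2, config.fixation_window)
                pos = np.array([np.cos(ang), np.sin(ang)]) * amp
            else:
                ang = rng.uniform(0, 2 * np.pi)
                amp = rng.uniform(*config.saccade_amplitude)
                cand = pos + amp * np.array([np.cos(ang), np.sin(ang)])
                if np.hypot(*cand) > 20:
                    cand = -pos
                pos = cand

    x = x + rng.normal(0, config.eye_noise_deg, n)
    y = y + rng.normal(0, config.eye_noise_deg, n)

    # blinks: wake only; tracker noise burst + closed-eye luminance
    n_frames = int(np.ceil(n / fs * config.frame_rate))
    frame_t = np.arange(n_frames) / config.frame_rate
    eye_lum = 20.0 + rng.normal(0, 1.0, n_frames)
    wake_mask = state_sequence == wake_code
    n_blinks = rng.poisson(config.blink_rate * n / fs)
    for _ in range(n_blinks):
        t0 = rng.uniform(0, n / fs)
        i0 = int(t0 * fs)
        if i0 >= n or not wake_mask[i0]:
            continue
        i1 = min(n, i0 + int(0.15 * fs))
        x[i0:i1] += rng.normal(0, 1.0, i1 - i0)
        y[i0:i1] += rng.normal(0, 1.0, i1 - i0)
        f0, f1 = int(t0 * config.frame_rate), int(t0 * config.frame_rate) + max(
            1, int(0.15 * config.frame_rate))
        eye_lum[f0:f1] = 80.0

    # mouth / nose movement: telegraph bursts in wake, near-still in events
    frame_states = state_sequence[np.minimum((frame_t * fs).astype(int), n - 1)]
    frame_wake = frame_states == wake_code

    def _face_trace() -> np.ndarray:
        moving = np.zeros(n_frames, dtype=bool)
        i = 0
        state_on = rng.random() < 0.5
        while i < n_frames:
            dur = max(1, int(rng.exponential(1.0) * config.frame_rate))
            moving[i:i + dur] = state_on
            state_on = not state_on
            i += dur
        step_sd = np.where(frame_wake & moving, 3.0, 0.3)
        steps = rng.normal(0, 1.0, n_frames) * step_sd
        # mean-reverting (AR(1)) walk around the baseline luminance
        return 50.0 + sps.lfilter([1.0], [1.0, -0.95], steps)

    return BehavioralSuite(
        eye_r=np.hypot(x, y), eye_theta=np.arctan2(y, x),
        eye_lum=eye_lum, mouth_lum=_face_trace(), nose_lum=_face_trace(),
        sample_rate=fs, frame_rate=config.frame_rate, fixation_target=(0.0, 0.0),
    )


# ---------------------------------------------------------------------------
# Spikes and full-session assembly

def _simulate_spikes(state_sequence: np.ndarray, config: SimulationConfig,
                     rng: np.random.Generator) -> list:
    fs = config.sample_rate
    duration = len(state_sequence) / fs
    rate_lut = np.ones(max(STATE_CODES.values()) + 1)
    rate_lut[STATE_CODES["vpc"]] = config.vpc_spike_scale
    rate_lut[STATE_CODES["anesthesia"]] = config.vpc_spike_scale
    units = []
    areas = list(dict.fromkeys(a for a, _, _ in config.areas))
    for area in areas:
        for u in range(config.n_units_per_area):
            n_max = rng.poisson(config.spike_rate_hz * duration * 1.1) + 10
            cand = np.sort(rng.uniform(0, duration, n_max))
            mult = rate_lut[state_sequence[np.minimum((cand * fs).astype(int),
                                                      len(state_sequence) - 1)]]
            keep = rng.random(n_max) < (config.spike_rate_hz * duration / n_max) * mult
            units.append({"unit": f"{area}_u{u}", "area": area, "times": cand[keep]})
    return units


def simulate_session(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[SessionRecording, BehavioralSuite, EventLedger, GroundTruth]:
    """Generate one complete synthetic session.

    Deterministic for a given ``config`` (and optional ``seed`` override).
    """
    config = SimulationConfig() if config is None else config
    base_seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(base_seed)
    r_ledger, r_lfp, r_beh, r_spk = [np.random.default_rng(s) for s in root.spawn(4)]

    ledger = simulate_ledger(config, r_ledger)
    n = int(config.n_blocks * config.block_duration * config.sample_rate)
    behav_states = state_sequence_from_events(ledger.events, n, config.sample_rate)
    neural_states = state_sequence_from_events(ledger.events, n, config.sample_rate,
                                               lead=config.neural_lead)

    rec = simulate_lfp(neural_states, config, r_lfp)
    beh = simulate_behavior(behav_states, config, r_beh, ledger)
    rec.spikes = _simulate_spikes(neural_states, config, r_spk)

    if len(ledger.stims):
        # accumulate all condition trains, then add in place (avoids copying
        # the full signal array once per condition)
        train = np.zeros(rec.n_samples, dtype=np.float32)
        for cond, grp in ledger.stims.groupby("condition"):
            epochs = list(zip(grp.stim_start, grp.stim_end))
            train += _pulse_train(epochs, STIM_FREQ[cond], config.dbs_amplitude,
                                  rec.n_samples, rec.sample_rate, rec.duration)
        rec.signals += train[None, :]
        if rec.eeg is not None:
            rec.eeg += train

    truth = GroundTruth(state_sequence=behav_states, state_codes=dict(STATE_CODES),
                        true_events=ledger.events.copy(),
                        latent_coupling={s: dict(b) for s, b in config.state_coupling.items()})
    return rec, beh, ledger, truth


def score_detection(true_events: pd.DataFrame, detected: pd.DataFrame,
                    min_overlap: float = 0.3) -> dict:
    """Sensitivity and false-discovery rate per event type.

    A detected event matches a true event when their intersection-over-union
    exceeds ``min_overlap`` and the types agree.
    """
    out = {}
    for etype in ("VPC", "STR"):
        t = true_events[true_events.event_type == etype] if len(true_events) else true_events
        d = detected[detected.event_type == etype] if len(detected) else detected
        matched_true: set = set()
        n_tp = 0
        for _, de in d.iterrows():
            best, best_iou = None, min_overlap
            for ti, te in t.iterrows():
                if ti in matched_true:
                    continue
                inter = min(de.event_offset, te.event_offset) - max(de.event_onset, te.event_onset)
                union = max(de.event_offset, te.event_offset) - min(de.event_onset, te.event_onset)
                iou = inter / union if union > 0 else 0.0
                if iou > best_iou:
                    best, best_iou = ti, iou
            if best is not None:
                matched_true.add(best)
                n_tp += 1
        sens = n_tp / len(t) if len(t) else float("nan")
        fdr = (len(d) - n_tp) / len(d) if len(d) else 0.0
        out[etype] = {"sensitivity": sens, "fdr": fdr,
                      "n_true": int(len(t)), "n_detected": int(len(d))}
    return out
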