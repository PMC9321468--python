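"""Behavioural-arrest event detection and EEG-based classification.

Candidate events are maximal intervals in which the gaze is stable, the eyes
remain open and the face is still, lasting longer than 4.2 s (the upper 95 %
bound of ordinary fixation durations); during fixation-task blocks the frozen
gaze must additionally sit more than 3 degrees of visual angle off the
fixation target.  A candidate is classified as a perturbed-consciousness
event (VPC) when the EEG shows a significant power increase at any frequency
between 1 and 9 Hz relative to the pre-event period, and as a control stare
(STR) otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from scipy.ndimage import binary_closing, uniform_filter1d

from .preprocess import excise_stim_artifact
from .session import BehavioralSuite, EventLedger, SessionRecording
from .simulate import STIM_FREQ, pulse_times
from .spectral import multitaper_psd
from .stats import holm_bonferroni

MIN_DURATION = 4.2     # s; 95 % bound of ordinary fixation durations
GAZE_TOLERANCE = 3.0   # deg; on-target criterion in the fixation task


@dataclass
class DetectedEvent:
    onset: float
    offset: float
    event_type: str                 # "VPC" | "STR" | "unclassifiable"
    gaze_on_target: bool
    evidence: dict                  # per-criterion booleans / availability

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def gaze_stability(eye_r: np.ndarray, eye_theta: np.ndarray, fs: float,
                   threshold: float | None = None, trim: float = 0.2,
                   smooth: float = 0.02) -> tuple[np.ndarray, list]:
    """Stable-gaze segments from the derivative of the polar eye trace.

    Gaze speed combines the radial derivative and the tangential term
    ``r * d(theta)/dt``; samples where the lightly smoothed speed exceeds the
    threshold (default: 3x the trace median, i.e. saccades) break stability,
    and each saccade-bounded segment is trimmed by ``trim`` seconds at both
    ends.  Returns (per-sample stability mask, list of (t0, t1) segments).
    """
    if len(eye_r) == 0:
        return np.zeros(0, dtype=bool), []
    x = eye_r * np.cos(eye_theta)
    y = eye_r * np.sin(eye_theta)
    vx = np.gradient(x) * fs
    vy = np.gradient(y) * fs
    speed = np.hypot(vx, vy)
    speed = uniform_filter1d(speed, size=max(1, int(smooth * fs)))
    if threshold is None:
        threshold = 3.0 * float(np.median(speed))
    moving = speed >= threshold
    stable = ~moving
    # trim 200 ms after the previous saccade and before the next one
    k = int(trim * fs)
    if k > 0:
        stable = ~(uniform_filter1d((~stable).astype(float), size=2 * k + 1,
                                    mode="nearest") > 0)
    segments = _runs(stable, fs)
    return stable, segments


def _runs(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    idx = np.nonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))[0]
    return [(idx[i] / fs, idx[i + 1] / fs) for i in range(0, len(idx), 2)]


def face_stillness(eye_lum: np.ndarray | None, mouth_lum: np.ndarray | None,
                   nose_lum: np.ndarray | None, frame_rate: float,
                   smooth: float = 0.25) -> dict:
    """Smoothed luminance-derivative movement indices and an eyes-open flag.

    Eyes are open where the eye-window luminance is low.  A missing trace
    marks the corresponding criterion unavailable (None) and detection then
    proceeds on the remaining signals.
    """
    out: dict = {"frame_rate": frame_rate}
    k = max(1, int(smooth * frame_rate))

    def _movement(trace):
        if trace is None or len(trace) == 0:
            return None
        d = np.abs(np.gradient(np.asarray(trace, dtype=float))) * frame_rate
        return uniform_filter1d(d, size=k)

    out["mouth_move"] = _movement(mouth_lum)
    out["nose_move"] = _movement(nose_lum)
    if eye_lum is not None and len(eye_lum):
        lum = np.asarray(eye_lum, dtype=float)
        med = float(np.median(lum))
        spread = float(np.max(lum)) - med
        # closed-eye excursions are large positive deviations; traces without
        # any (never-blinking segments) are treated as all-open
        if spread > 20.0:
            out["eyes_open"] = lum < med + 0.5 * spread
        else:
            out["eyes_open"] = np.ones(len(lum), dtype=bool)
    else:
        out["eyes_open"] = None
    return out


def _to_eye_clock(frame_trace: np.ndarray, n: int, fs: float, frame_rate: float
                  ) -> np.ndarray:
    idx = np.minimum((np.arange(n) / fs * frame_rate).astype(int),
                     len(frame_trace) - 1)
    return frame_trace[idx]


def find_candidates(beh: BehavioralSuite, ledger: EventLedger,
                    threshold: float | None = None,
                    still_factor: float = 0.5,
                    min_duration: float = MIN_DURATION) -> list[DetectedEvent]:
    """Candidate behavioural-arrest intervals from the joint criteria."""
    if not beh.has_eye():
        raise ValueError("candidate search requires eye traces")
    fs = beh.sample_rate
    n = len(beh.eye_r)
    stable, _ = gaze_stability(beh.eye_r, beh.eye_theta, fs, threshold)

    crit = face_stillness(beh.eye_lum, beh.mouth_lum, beh.nose_lum, beh.frame_rate)
    ok = stable.copy()
    evidence_avail = {"eye": True, "eyes_open": crit["eyes_open"] is not None,
                      "face": crit["mouth_move"] is not None or crit["nose_move"] is not None}
    close = np.ones(max(1, int(1.0 * beh.frame_rate)), dtype=bool)
    if crit["eyes_open"] is not None:
        eyes = binary_closing(crit["eyes_open"], structure=close)
        ok &= _to_eye_clock(eyes.astype(float), n, fs, beh.frame_rate) > 0.5
    for key in ("mouth_move", "nose_move"):
        mv = crit[key]
        if mv is not None:
            # face movement is slow and noisy: bridge sub-second flickers;
            # <= keeps an exactly still (zero-derivative) trace all-still
            still = binary_closing(mv <= still_factor * np.median(mv), structure=close)
            ok &= _to_eye_clock(still.astype(float), n, fs, beh.frame_rate) > 0.5

    x = beh.eye_r * np.cos(beh.eye_theta)
    y = beh.eye_r * np.sin(beh.eye_theta)
    events = []
    for t0, t1 in _runs(ok, fs):
        if t1 - t0 <= min_duration:
            continue
        i0, i1 = int(t0 * fs), int(t1 * fs)
        on_target = False
        if beh.fixation_target is not None:
            gx, gy = np.mean(x[i0:i1]), np.mean(y[i0:i1])
            tx, ty = beh.fixation_target
            on_target = np.hypot(gx - tx, gy - ty) <= GAZE_TOLERANCE
        block = ledger.blocks[(ledger.blocks.t_start <= t0) & (t0 < ledger.blocks.t_end)]
        task = block.iloc[0].task if len(block) else "RW"
        if task == "FX" and on_target:
            continue   # goal-directed fixation, not an arrest
        events.append(DetectedEvent(onset=t0, offset=t1, event_type="candidate",
                                    gaze_on_target=on_target,
                                    evidence=dict(evidence_avail)))
    return events


def classify_event(candidate: DetectedEvent, eeg: np.ndarray, fs: float,
                   ledger: EventLedger | None = None, pre: float = 30.0,
                   alpha: float = 0.05, min_epochs: int = 5) -> DetectedEvent:
    """VPC / STR assignment from the 1-9 Hz EEG criterion.

    Log power in each integer frequency bin 1-9 Hz is compared between 1 s
    epochs during the event and up to 30 s of pre-event epochs (one-sided
    t-tests, Holm-corrected across the nine bins); any significant increase
    labels the event VPC.  The comparison is invariant to EEG scalar gain.
    """
    t_pre0 = max(0.0, candidate.onset - pre)
    if ledger is not None:
        blk = ledger.blocks[(ledger.blocks.t_start <= candidate.onset)
                            & (candidate.onset < ledger.blocks.t_end)]
        if len(blk):
            t_pre0 = max(t_pre0, float(blk.iloc[0].t_start))
    eeg = np.asarray(eeg, dtype=float)
    if ledger is not None and len(ledger.stims):
        lo, hi = t_pre0, candidate.offset
        near = ledger.stims[(ledger.stims.stim_end > lo) & (ledger.stims.stim_start < hi)]
        if len(near):
            i0, i1 = int(lo * fs), int(np.ceil(hi * fs))
            seg = eeg[i0:i1].copy()
            for _, s in near.iterrows():
                p = pulse_times(max(s.stim_start, lo), min(s.stim_end, hi),
                                STIM_FREQ[s.condition]) - lo
                seg, _ = excise_stim_artifact(seg, p, STIM_FREQ[s.condition], fs)
            eeg = eeg.copy()
            eeg[i0:i1] = seg

    def _epoch_power(t0: float, t1: float) -> np.ndarray:
        k = int(np.floor(t1 - t0))
        rows = []
        for j in range(k):
            i0 = int((t0 + j) * fs)
            seg = eeg[i0:i0 + int(fs)]
            if len(seg) < fs or seg.std() == 0:
                continue
            freqs, psd = multitaper_psd(seg - seg.mean(), fs)
            mask = (freqs >= 1.0) & (freqs <= 9.0)
            # average PSD into integer-Hz bins 1..9
            bins = np.clip(np.round(freqs[mask]).astype(int), 1, 9)
            rows.append([np.log(psd[mask][bins == b].mean()) for b in range(1, 10)])
        return np.array(rows)

    pre_p = _epoch_power(t_pre0, candidate.onset)
    dur_p = _epoch_power(candidate.onset, candidate.offset)
    if len(pre_p) < min_epochs or len(dur_p) < min_epochs:
        return DetectedEvent(candidate.onset, candidate.offset, "unclassifiable",
                             candidate.gaze_on_target,
                             {**candidate.evidence, "eeg": False})
    pvals = []
    for b in range(9):
        diff = dur_p[:, b].mean() - pre_p[:, b].mean()
        scale = max(np.abs(dur_p[:, b]).max(), np.abs(pre_p[:, b]).max(), 1e-30)
        if abs(diff) <= 1e-9 * scale:
            pvals.append(1.0)          # identical signals up to float rounding
            continue
        t_stat, p = scipy_stats.ttest_ind(dur_p[:, b], pre_p[:, b], equal_var=False)
        if not np.isfinite(t_stat):
            pvals.append(1.0)          # degenerate (zero-variance) bin
        else:
            pvals.append(p / 2 if t_stat > 0 else 1 - p / 2)   # one-sided: increase
    _, reject = holm_bonferroni(np.array(pvals), alpha=alpha)
    etype = "VPC" if np.any(reject) else "STR"
    return DetectedEvent(candidate.onset, candidate.offset, etype,
                         candidate.gaze_on_target,
                         {**candidate.evidence, "eeg": True,
                          "low_freq_increase": bool(np.any(reject))})


def detect_events(rec: SessionRecording, beh: BehavioralSuite,
                  ledger: EventLedger, alpha: float = 0.05) -> pd.DataFrame:
    """Full detection pass: candidates + EEG classification.

    Returns a DataFrame in ledger-event format (block_id, event_type,
    event_onset, event_offset, in_stim).
    """
    cands = find_candidates(beh, ledger)
    rows = []
    for c in cands:
        ev = classify_event(c, rec.eeg, rec.sample_rate, ledger, alpha=alpha)
        if ev.event_type == "unclassifiable":
            continue
        block_id = ledger.block_of(ev.onset)
        in_stim = False
        if len(ledger.stims):
            s = ledger.stims
            in_stim = bool(((s.stim_start <= ev.onset) & (ev.onset < s.stim_end)).any())
        rows.append({"block_id": block_id, "event_type": ev.event_type,
                     "event_onset": ev.onset, "event_offset": ev.offset,
                     "in_stim": in_stim})
    return pd.DataFrame(rows, columns=["block_id", "event_type", "event_onset",
                                       "event_offset", "in_stim"])
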