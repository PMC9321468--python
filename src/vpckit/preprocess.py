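"""LFP preprocessing: filtering, line-noise removal, channel QC, bipolar
derivation, stimulation-artifact excision, epoching, and the
decorrelate/normalize/binarize path applied before entropy and Phi*."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as scipy_stats

from .session import SessionRecording


@dataclass
class EpochSet:
    """Epochs x channels x samples with per-epoch metadata.

    ``effective_lengths`` records the usable seconds per epoch after artifact
    excision (used to normalize rates); ``derivation`` is "monopolar" or
    "bipolar".
    """

    data: np.ndarray
    sample_rate: float
    channel_meta: pd.DataFrame
    meta: pd.DataFrame                       # per-epoch: t_start, tag, ...
    derivation: str = "monopolar"
    effective_lengths: np.ndarray | None = None
    excluded_channels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.effective_lengths is None:
            self.effective_lengths = np.full(self.data.shape[0],
                                             self.data.shape[2] / self.sample_rate)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def filter_lfp(x: np.ndarray, low: float, high: float, fs: float,
               order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward)."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError("high cutoff at or above Nyquist")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def downsample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Anti-aliased decimation to an integer-divisor target rate."""
    q = int(round(fs / target_fs))
    if abs(fs / q - target_fs) > 1e-6:
        raise ValueError("target rate must divide the sampling rate")
    return sps.decimate(x, q, ftype="fir", axis=-1, zero_phase=True)


def _fit_sine(seg: np.ndarray, freq: float, fs: float):
    t = np.arange(len(seg)) / fs
    design = np.column_stack([np.sin(2 * np.pi * freq * t),
                              np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(design, seg - seg.mean(), rcond=None)
    fitted = design @ coef
    return fitted


def remove_line_noise(x: np.ndarray, freq: float, fs: float,
                      window: float = 1.0, alpha: float = 0.05) -> np.ndarray:
    """Regress out significant sinusoids at ``freq`` in non-overlapping windows.

    Per window a sine/cosine pair at the target frequency is fitted by least
    squares and subtracted only when an F-test deems it significant
    (Bonferroni-corrected across windows), so broadband content is preserved.
    """
    if freq >= fs / 2:
        raise ValueError("line frequency at or above Nyquist")
    x = np.asarray(x, dtype=float)
    out = x.copy()
    w = int(window * fs)
    n_win = max(1, len(x) // w)
    thresh = alpha / n_win
    for i in range(n_win):
        seg = x[i * w:(i + 1) * w]
        if len(seg) < 8:
            continue
        fitted = _fit_sine(seg, freq, fs)
        rss1 = float(np.sum((seg - seg.mean() - fitted) ** 2))
        rss0 = float(np.sum((seg - seg.mean()) ** 2))
        if rss1 <= 0:
            out[i * w:(i + 1) * w] = seg - fitted
            continue
        dof = len(seg) - 3
        f_stat = ((rss0 - rss1) / 2.0) / (rss1 / dof)
        p = scipy_stats.f.sf(f_stat, 2, dof)
        if p < thresh:
            out[i * w:(i + 1) * w] = seg - fitted
    return out


def flag_bad_channels(epochs: EpochSet, n_sd: float = 5.0) -> list[int]:
    """Flag channels whose session RMS amplitude sits more than ``n_sd``
    spreads above the other contacts on the same probe.

    The comparison is leave-one-out with a robust location (median) and a
    scale taken as max(1.4826*MAD, SD/2): the MAD keeps a second outlier from
    masking the first, while the SD floor keeps legitimately bimodal
    amplitude profiles (e.g. laminar gain alternation) from degenerating to a
    zero spread.
    """
    rms = np.sqrt(np.mean(epochs.data.astype(float) ** 2, axis=(0, 2)))
    flagged: list[int] = []
    for probe, grp in epochs.channel_meta.groupby("probe"):
        idx = grp.index.to_numpy()
        if len(idx) < 3:
            raise ValueError(f"probe {probe} has fewer than 3 channels")
        probe_flagged = []
        for i in idx:
            others = rms[idx[idx != i]]
            center = np.median(others)
            spread = max(1.4826 * np.median(np.abs(others - center)),
                         0.5 * others.std(ddof=1))
            if rms[i] > center + n_sd * spread:
                probe_flagged.append(int(i))
        if len(probe_flagged) == len(idx):
            raise ValueError(f"all channels on probe {probe} flagged; probe corrupt")
        flagged.extend(probe_flagged)
    return sorted(flagged)


def bipolar_derive(epochs: EpochSet) -> EpochSet:
    """Adjacent-contact differences within each probe.

    Excluded contacts break the chain: no derivation is formed across a gap.
    Probes left with fewer than two usable contacts are dropped with a warning.
    """
    if epochs.derivation != "monopolar":
        raise ValueError("bipolar derivation requires monopolar input")
    excluded = set(epochs.excluded_channels)
    out_rows = []
    out_data = []
    for probe, grp in epochs.channel_meta.groupby("probe", sort=False):
        grp = grp.sort_values("contact")
        usable = [i for i in grp.index if i not in excluded]
        if len(usable) < 2:
            warnings.warn(f"probe {probe}: fewer than 2 usable contacts, dropped")
            continue
        made_any = False
        for i, j in zip(grp.index, grp.index[1:]):
            if i in excluded or j in excluded:
                continue
            out_data.append(epochs.data[:, i, :].astype(float)
                            - epochs.data[:, j, :].astype(float))
            row = epochs.channel_meta.loc[i].to_dict()
            row["contact"] = int(epochs.channel_meta.loc[i, "contact"])
            out_rows.append(row)
            made_any = True
        if not made_any:
            warnings.warn(f"probe {probe}: exclusions left no adjacent pairs")
    if not out_data:
        raise ValueError("no bipolar channels could be derived")
    data = np.stack(out_data, axis=1)
    return EpochSet(data=data, sample_rate=epochs.sample_rate,
                    channel_meta=pd.DataFrame(out_rows).reset_index(drop=True),
                    meta=epochs.meta.copy(), derivation="bipolar",
                    effective_lengths=np.array(epochs.effective_lengths).copy())


def excise_stim_artifact(x: np.ndarray, times: np.ndarray, stim_freq: float,
                         fs: float, window_ms: float = 1.0,
                         remove_sines: bool = True) -> tuple[np.ndarray, float]:
    """Excise ``window_ms`` around each pulse (linear interpolation), then
    remove residual sinusoids at the stimulation frequency.

    Returns the cleaned signal and the effective (non-excised) fraction."""
    half = window_ms / 2000.0
    if len(times) > 1 and np.min(np.diff(np.sort(times))) < window_ms / 1000.0:
        raise ValueError("pulses denser than the excision window")
    out = np.asarray(x, dtype=float).copy()
    n = len(out)
    excised = np.zeros(n, dtype=bool)
    for t in np.sort(times):
        i0 = max(0, int(np.floor((t - half) * fs)))
        i1 = min(n - 1, int(np.ceil((t + half) * fs)))
        if i1 <= i0:
            continue
        lo = max(0, i0 - 1)
        hi = min(n - 1, i1 + 1)
        out[i0:i1 + 1] = np.interp(np.arange(i0, i1 + 1), [lo, hi], [out[lo], out[hi]])
        excised[i0:i1 + 1] = True
    if remove_sines and len(times) and stim_freq < fs / 2:
        out = remove_line_noise(out, stim_freq, fs)
    return out, 1.0 - excised.mean()


def effective_epoch_lengths(pulse_times: np.ndarray, epoch_starts: np.ndarray,
                            epoch_len: float, window_ms: float = 1.0) -> np.ndarray:
    """Usable seconds per epoch after excision (for rate normalization)."""
    out = np.full(len(epoch_starts), epoch_len)
    for k, t0 in enumerate(epoch_starts):
        n_p = np.sum((pulse_times >= t0) & (pulse_times < t0 + epoch_len))
        out[k] = epoch_len - n_p * window_ms / 1000.0
    return out


def epoch_windows(rec: SessionRecording, intervals: list[tuple[float, float, str]],
                  length: float = 1.0, channels: np.ndarray | None = None,
                  use_eeg: bool = False) -> EpochSet:
    """Tile non-overlapping ``length``-second windows over each interval.

    ``intervals`` is a list of (t_start, t_end, tag); windows that would
    extend past the recording are dropped (truncated tiling).
    """
    fs = rec.sample_rate
    n = rec.n_samples
    w = int(length * fs)
    if use_eeg:
        source = rec.eeg[None, :]
        meta_ch = pd.DataFrame([{"probe": "EEG", "area": "EEG", "layer": "none",
                                 "contact": 0}])
    else:
        source = rec.signals if channels is None else rec.signals[channels]
        meta_ch = rec.channel_meta if channels is None \
            else rec.channel_meta.iloc[channels].reset_index(drop=True)
    data, rows = [], []
    for (t0, t1, tag) in intervals:
        t0 = max(0.0, t0)
        t1 = min(n / fs, t1)
        k = int(np.floor((t1 - t0) / length))
        if k <= 0:
            warnings.warn(f"interval ({t0:.1f}, {t1:.1f}) shorter than one window")
            continue
        for j in range(k):
            i0 = int((t0 + j * length) * fs)
            if i0 + w > n:
                break
            data.append(source[:, i0:i0 + w])
            rows.append({"t_start": t0 + j * length, "tag": tag, "index_in_interval": j})
    if not data:
        data = np.empty((0, source.shape[0], w), dtype=source.dtype)
        return EpochSet(data=data, sample_rate=fs, channel_meta=meta_ch,
                        meta=pd.DataFrame(columns=["t_start", "tag", "index_in_interval"]))
    return EpochSet(data=np.stack(data).astype(float), sample_rate=fs,
                    channel_meta=meta_ch,
                    meta=pd.DataFrame(rows))


def event_intervals(event_onset: float, event_offset: float,
                    pre: float = 30.0, post: float = 30.0,
                    bounds: tuple[float, float] | None = None) -> list:
    """Pre / during / post intervals around one event, clipped to bounds."""
    lo = 0.0 if bounds is None else bounds[0]
    hi = np.inf if bounds is None else bounds[1]
    return [
        (max(lo, event_onset - pre), event_onset, "pre"),
        (event_onset, min(hi, event_offset), "during"),
        (event_offset, min(hi, event_offset + post), "post"),
    ]


def prepare_phi_inputs(epochs: EpochSet, binarize: bool = True) -> EpochSet:
    """Decorrelate within area, normalize to the day mean, optionally binarize.

    Per area the channels are linearly decorrelated by whitening (eigenvalue
    symmetric orthogonalization of the across-epoch covariance), each
    component is normalized to its mean absolute level across all epochs, and
    finally each epoch is median-split to {0, 1}.  Constant channels are
    dropped with a warning.  With ``binarize=False`` the continuous
    decorrelated-and-normalized signals are returned instead (the default
    input path for the Gaussian integration measures).
    """
    data = epochs.data.astype(float)
    n_ep, n_ch, n_s = data.shape
    keep = [c for c in range(n_ch) if data[:, c, :].std() > 1e-12]
    if len(keep) < n_ch:
        warnings.warn(f"dropping {n_ch - len(keep)} constant channel(s)")
    data = data[:, keep, :]
    meta_ch = epochs.channel_meta.iloc[keep].reset_index(drop=True)

    out = np.empty_like(data)
    for area, grp in meta_ch.groupby("area", sort=False):
        idx = grp.index.to_numpy()
        flat = data[:, idx, :].transpose(1, 0, 2).reshape(len(idx), -1)
        flat = flat - flat.mean(axis=1, keepdims=True)
        cov = flat @ flat.T / flat.shape[1]
        vals, vecs = np.linalg.eigh(cov)
        vals = np.maximum(vals, 1e-12 * vals.max())
        white = (vecs / np.sqrt(vals)) @ vecs.T      # ZCA whitening
        comp = white @ flat
        scale = np.mean(np.abs(comp), axis=1, keepdims=True)
        comp = comp / np.maximum(scale, 1e-12)
        out[:, idx, :] = comp.reshape(len(idx), n_ep, n_s).transpose(1, 0, 2)

    if binarize:
        med = np.median(out, axis=2, keepdims=True)
        out = (out > med).astype(float)

    return EpochSet(data=out, sample_rate=epochs.sample_rate, channel_meta=meta_ch,
                    meta=epochs.meta.copy(), derivation=epochs.derivation,
                    effective_lengths=np.array(epochs.effective_lengths).copy())
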