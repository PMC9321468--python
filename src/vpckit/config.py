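"""Simulation configuration.

The synthetic-session generator emulates a primate DBS experiment: blocks of
resting wake (RW) and rewarded fixation (FX), each block of ~7 minutes with up
to three 60 s stimulation epochs at 10, 50 or 200 Hz (or a no-stimulation
control), multichannel ~1 kHz LFPs from four brain areas plus a skull-screw
EEG, eye-tracker and face-luminance traces, and rare behavioural-arrest events
whose per-block probability depends on the stimulation condition and on the
recent predominance of stimulation blocks ("kindling").
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

CONDITIONS = ("NS", "10Hz", "50Hz", "200Hz")
STIM_FREQ = {"10Hz": 10.0, "50Hz": 50.0, "200Hz": 200.0}

STATES = ("wake", "vpc", "str", "anesthesia")
STATE_CODES = {name: i for i, name in enumerate(STATES)}

#: Oscillator bands used by the generator (Hz).  These match the decoder's
#: band scheme: delta, theta, alpha, beta, gamma.
SIM_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 90.0),
}


def _default_state_spectra() -> dict:
    # Target in-band power (a.u. variance) of bipolar-derived LFPs per state.
    # The perturbed state elevates 1-15 Hz power and damps gamma; the control
    # stare keeps the wake regime; the anesthesia-like regime is delta heavy.
    wake = {"delta": 1.0, "theta": 1.0, "alpha": 1.5, "beta": 1.0, "gamma": 0.8}
    return {
        "wake": dict(wake),
        "vpc": {"delta": 4.0, "theta": 4.0, "alpha": 4.0, "beta": 1.0, "gamma": 0.4},
        "str": dict(wake),
        "anesthesia": {"delta": 6.0, "theta": 2.5, "alpha": 1.0, "beta": 0.5, "gamma": 0.3},
    }


def _default_state_coupling() -> dict:
    # Target cross-area magnitude coherence per band and state.
    wake = {"delta": 0.05, "theta": 0.10, "alpha": 0.10, "beta": 0.05, "gamma": 0.02}
    return {
        "wake": dict(wake),
        "vpc": {"delta": 0.50, "theta": 0.50, "alpha": 0.40, "beta": 0.05, "gamma": 0.02},
        "str": dict(wake),
        "anesthesia": {"delta": 0.60, "theta": 0.35, "alpha": 0.15, "beta": 0.05, "gamma": 0.02},
    }


def _default_eeg_spectra() -> dict:
    wake = {"delta": 1.0, "theta": 1.0, "alpha": 1.5, "beta": 1.0, "gamma": 0.8}
    return {
        "wake": dict(wake),
        "vpc": {"delta": 5.0, "theta": 5.0, "alpha": 4.0, "beta": 1.0, "gamma": 0.8},
        "str": dict(wake),
        "anesthesia": {"delta": 6.0, "theta": 2.5, "alpha": 1.0, "beta": 0.5, "gamma": 0.3},
    }


def _default_areas() -> tuple:
    # (area, layer, n_contacts) per probe; cortical probes are split into
    # superficial and deep segments, subcortical probes carry no layer label.
    return (
        ("CL", "none", 24),
        ("CN", "none", 16),
        ("FEF", "superficial", 8),
        ("FEF", "deep", 8),
        ("LIP", "superficial", 12),
        ("LIP", "deep", 12),
    )


@dataclass
class SimulationConfig:
    """Parameters of a synthetic recording session.

    Defaults mirror the experimental design being emulated: 420 s blocks with
    three 60 s stimulation epochs starting 60, 180 and 300 s into the block;
    per-condition event probabilities of 12.9 % (no stimulation), 23.9 %
    (10 Hz), 14.8 % (50 Hz) and 30.0 % (200 Hz); and event durations of
    17.64 +- 5.96 s (behavioural-arrest) and 15.31 +- 6.63 s (control stare).
    """

    # Block / paradigm structure
    n_blocks_rest: int = 4
    n_blocks_fix: int = 4
    block_duration: float = 420.0
    stim_epochs_per_block: int = 3
    stim_duration: float = 60.0
    stim_onsets: Sequence[float] = (60.0, 180.0, 300.0)
    conditions: Sequence[str] = CONDITIONS
    series: str = "Stim"               # "Stim" or "No-Stim"
    series_phase: str = "established"  # "transition" or "established"

    # Event model
    vpc_prob_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"NS": 0.129, "10Hz": 0.239, "50Hz": 0.148, "200Hz": 0.300}
    )
    str_prob: float = 0.19
    fix_event_scale: float = 0.15      # event probability multiplier in FX blocks
    kindling_slope: float = 0.10       # dP(event)/d(local stim predominance)
    kindling_window: int = 32          # blocks defining "local"
    p_event_in_stim: float = 0.65      # P(onset inside a stimulation epoch | stim block)
    vpc_duration: tuple[float, float, float] = (17.64, 5.96, 6.0)  # mean, sd, min (s)
    str_duration: tuple[float, float, float] = (15.31, 6.63, 6.0)
    max_events_per_block: int = 1
    neural_lead: float = 3.0           # spectral regime switches this early (s)

    # Recording geometry / rates
    areas: Sequence[tuple[str, str, int]] = field(default_factory=_default_areas)
    sample_rate: float = 1000.0
    frame_rate: float = 30.0

    # Signal model
    state_spectra: Mapping = field(default_factory=_default_state_spectra)
    state_coupling: Mapping = field(default_factory=_default_state_coupling)
    eeg_spectra: Mapping = field(default_factory=_default_eeg_spectra)
    pink_scale: float = 0.35           # std of per-contact 1/f background
    ref_scale: float = 0.5             # std of the common reference (cancels in bipolar)
    loading_contrast: float = 0.5      # depth-alternating source loading (see methods)

    # Behaviour model
    saccade_interval: tuple[float, float] = (0.2, 1.0)   # wake inter-saccade (s)
    saccade_amplitude: tuple[float, float] = (1.5, 12.0)  # degrees
    eye_noise_deg: float = 0.01        # tracker noise std per sample (deg)
    drift_rate: float = 0.1            # frozen-gaze drift (deg/s)
    blink_rate: float = 0.2            # blinks per second, wake only
    fixation_window: float = 1.0       # FX gaze jitter around target (deg)
    long_stare_rate: float = 0.0       # tail probability of natural long fixations

    # Stimulation artifact and spiking
    dbs_amplitude: float = 20.0
    spike_rate_hz: float = 10.0
    vpc_spike_scale: float = 0.5
    n_units_per_area: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        probs = dict(self.vpc_prob_by_condition)
        for cond, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"vpc_prob_by_condition[{cond}]={p} outside [0, 1]")
        if probs and max(probs.values()) + max(self.kindling_slope, 0.0) > 1.0:
            raise ValueError(
                "event probability exceeds 1 after kindling; lower "
                "vpc_prob_by_condition or kindling_slope"
            )
        if not 0.0 <= self.str_prob <= 1.0:
            raise ValueError("str_prob outside [0, 1]")
        onsets = sorted(self.stim_onsets[: self.stim_epochs_per_block])
        for a, b in zip(onsets, onsets[1:]):
            if a + self.stim_duration > b:
                raise ValueError("stimulation epochs overlap")
        if onsets and onsets[-1] + self.stim_duration > self.block_duration:
            raise ValueError("stimulation epoch extends past end of block")
        top = max(hi for (_, hi) in SIM_BANDS.values())
        if self.sample_rate <= 2.0 * top:
            raise ValueError(
                f"sample_rate {self.sample_rate} must exceed twice the highest "
                f"synthesized frequency ({top} Hz)"
            )
        for state_map in (self.state_coupling,):
            for state, bands in state_map.items():
                for band, c in bands.items():
                    if not 0.0 <= c < 1.0:
                        raise ValueError(f"coherence target {state}/{band}={c} outside [0, 1)")
        if self.frame_rate > self.sample_rate:
            raise ValueError("frame_rate must not exceed sample_rate")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def n_blocks(self) -> int:
        return self.n_blocks_rest + self.n_blocks_fix
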