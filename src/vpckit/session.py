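"""In-memory containers for a recording session.

A session couples continuous multichannel signals with per-channel anatomy,
behavioural traces on a shared clock, and an event ledger describing blocks,
stimulation epochs and behavioural events.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BLOCK_COLUMNS = ["block_id", "task", "condition", "series", "series_phase", "t_start", "t_end"]
STIM_COLUMNS = ["block_id", "condition", "stim_start", "stim_end"]
EVENT_COLUMNS = ["block_id", "event_type", "event_onset", "event_offset", "in_stim"]


@dataclass
class SessionRecording:
    """Continuous signals: ``signals`` is channels x samples (float32)."""

    signals: np.ndarray
    sample_rate: float
    channel_meta: pd.DataFrame  # columns: probe, area, layer, contact
    eeg: np.ndarray | None = None
    spikes: list | None = None  # list of dicts: unit, area, times (s)

    def __post_init__(self) -> None:
        if self.signals.ndim != 2:
            raise ValueError("signals must be channels x samples")
        if len(self.channel_meta) != self.signals.shape[0]:
            raise ValueError("channel_meta rows must match channel count")
        for probe, grp in self.channel_meta.groupby("probe"):
            contacts = np.sort(grp["contact"].to_numpy())
            if not np.array_equal(contacts, np.arange(contacts[0], contacts[0] + len(contacts))):
                raise ValueError(f"contact indices on probe {probe} are not contiguous")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class BehavioralSuite:
    """Eye traces on the signal clock; luminance traces on the video clock."""

    eye_r: np.ndarray | None
    eye_theta: np.ndarray | None
    eye_lum: np.ndarray | None
    mouth_lum: np.ndarray | None
    nose_lum: np.ndarray | None
    sample_rate: float = 1000.0
    frame_rate: float = 30.0
    fixation_target: tuple[float, float] | None = None

    def has_eye(self) -> bool:
        return self.eye_r is not None and self.eye_theta is not None

    def has_video(self) -> bool:
        return self.mouth_lum is not None and self.nose_lum is not None


@dataclass
class EventLedger:
    """Blocks, stimulation epochs and events of one or more sessions.

    Times are seconds on the session clock.  ``events`` may mix ground-truth
    and detected events; the ``event_type`` column distinguishes "VPC" from
    "STR" (control stare).
    """

    blocks: pd.DataFrame
    stims: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=STIM_COLUMNS))
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        for col in BLOCK_COLUMNS:
            if col not in self.blocks.columns:
                raise ValueError(f"ledger blocks missing column {col}")

    def block_of(self, t: float) -> int | None:
        hit = self.blocks[(self.blocks.t_start <= t) & (t < self.blocks.t_end)]
        return None if hit.empty else int(hit.iloc[0].block_id)

    def stim_epochs(self, block_id: int) -> pd.DataFrame:
        return self.stims[self.stims.block_id == block_id]

    def events_of_type(self, event_type: str) -> pd.DataFrame:
        if self.events.empty:
            return self.events
        return self.events[self.events.event_type == event_type]

    def event_rate(self, event_type: str = "VPC", task: str | None = None,
                   condition: str | None = None) -> float:
        """Fraction of (selected) blocks containing at least one such event."""
        blocks = self.blocks
        if task is not None:
            blocks = blocks[blocks.task == task]
        if condition is not None:
            blocks = blocks[blocks.condition == condition]
        if blocks.empty:
            return float("nan")
        ev = self.events_of_type(event_type)
        hit = blocks.block_id.isin(ev.block_id.unique() if not ev.empty else [])
        return float(hit.mean())

    def to_flat(self) -> pd.DataFrame:
        """Denormalized single-table view (one row per stim epoch / event)."""
        rows = []
        for _, blk in self.blocks.iterrows():
            stims = self.stim_epochs(blk.block_id)
            evs = self.events[self.events.block_id == blk.block_id] if not self.events.empty \
                else pd.DataFrame(columns=EVENT_COLUMNS)
            base = {c: blk[c] for c in BLOCK_COLUMNS}
            if stims.empty and evs.empty:
                rows.append(base)
                continue
            for _, s in stims.iterrows():
                rows.append({**base, "stim_start": s.stim_start, "stim_end": s.stim_end})
            for _, e in evs.iterrows():
                rows.append({**base, "event_type": e.event_type,
                             "event_onset": e.event_onset, "event_offset": e.event_offset})
        return pd.DataFrame(rows)

    @classmethod
    def from_flat(cls, flat: pd.DataFrame) -> "EventLedger":
        need = set(BLOCK_COLUMNS)
        missing = need - set(flat.columns)
        if missing:
            raise ValueError(f"flat ledger missing columns {sorted(missing)}")
        for i, row in flat.iterrows():
            if pd.isna(row["block_id"]) or pd.isna(row["t_start"]):
                raise ValueError(f"malformed ledger row {i}")
        blocks = flat[BLOCK_COLUMNS].drop_duplicates("block_id").reset_index(drop=True)
        stims = pd.DataFrame(columns=STIM_COLUMNS)
        events = pd.DataFrame(columns=EVENT_COLUMNS)
        if "stim_start" in flat.columns:
            s = flat.dropna(subset=["stim_start"])
            if not s.empty:
                stims = s[["block_id", "condition", "stim_start", "stim_end"]].reset_index(drop=True)
        if "event_onset" in flat.columns:
            e = flat.dropna(subset=["event_onset"])
            if not e.empty:
                events = e[["block_id", "event_type", "event_onset", "event_offset"]].copy()
                events["in_stim"] = np.nan
                events = events.reset_index(drop=True)
        return cls(blocks=blocks, stims=stims, events=events)


@dataclass
class GroundTruth:
    """Generator-side truth used for parameter-recovery tests."""

    state_sequence: np.ndarray            # per-sample state codes
    state_codes: dict
    true_events: pd.DataFrame             # event_type, onset, offset, block_id
    latent_coupling: dict                 # state -> band -> coherence target

    def state_labels(self) -> np.ndarray:
        inv = {v: k for k, v in self.state_codes.items()}
        return np.array([inv[c] for c in self.state_sequence])
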