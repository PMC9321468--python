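"""Session container I/O.

A session directory holds ``signals.h5`` (float32 signal arrays + eye trace),
``behavior.csv`` (video-frame luminance table), ``ledger.csv`` (denormalized
block/stimulation/event table), ``meta.json`` and ``config.yaml``.  Arrays
round-trip losslessly at float32; the eye trace lives in the HDF5 store
because it runs on the signal clock rather than the video clock.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .session import BehavioralSuite, EventLedger, SessionRecording

SCHEMA_VERSION = 1


def write_session(path, rec: SessionRecording, beh: BehavioralSuite | None,
                  ledger: EventLedger, config: dict | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "signals.h5", "w", track_order=True) as f:
        f.create_dataset("signals", data=rec.signals.astype(np.float32),
                         track_times=False)
        if rec.eeg is not None:
            f.create_dataset("eeg", data=np.asarray(rec.eeg, dtype=np.float32),
                             track_times=False)
        if beh is not None and beh.has_eye():
            f.create_dataset("eye", data=np.stack([beh.eye_r, beh.eye_theta]
                                                  ).astype(np.float32),
                             track_times=False)
        if rec.spikes:
            g = f.create_group("spikes", track_order=True)
            for u in rec.spikes:
                d = g.create_dataset(u["unit"], data=np.asarray(u["times"],
                                                                dtype=np.float64),
                                     track_times=False)
                d.attrs["area"] = u["area"]
    meta = {
        "schema_version": SCHEMA_VERSION,
        "sample_rate": rec.sample_rate,
        "clock_origin": 0.0,
        "frame_rate": beh.frame_rate if beh is not None else None,
        "fixation_target": list(beh.fixation_target)
        if beh is not None and beh.fixation_target is not None else None,
        "channel_meta": rec.channel_meta.to_dict(orient="records"),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if beh is not None and beh.has_video():
        n = len(beh.mouth_lum)
        pd.DataFrame({
            "time": np.arange(n) / beh.frame_rate,
            "eye_lum": np.asarray(beh.eye_lum, dtype=np.float32),
            "mouth_lum": np.asarray(beh.mouth_lum, dtype=np.float32),
            "nose_lum": np.asarray(beh.nose_lum, dtype=np.float32),
        }).to_csv(path / "behavior.csv", index=False, float_format="%.6g")
    ledger.to_flat().to_csv(path / "ledger.csv", index=False, float_format="%.10g")
    if config is not None:
        (path / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))


def read_session(path) -> tuple[SessionRecording, BehavioralSuite, EventLedger]:
    """Load a session container; missing behaviour files leave the respective
    criteria unavailable (None traces)."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {meta.get('schema_version')} "
                         f"(reader supports {SCHEMA_VERSION})")
    with h5py.File(path / "signals.h5", "r") as f:
        signals = f["signals"][()]
        eeg = f["eeg"][()] if "eeg" in f else None
        eye = f["eye"][()] if "eye" in f else None
        spikes = []
        if "spikes" in f:
            for name, d in f["spikes"].items():
                spikes.append({"unit": name, "area": d.attrs["area"],
                               "times": d[()]})
    channel_meta = pd.DataFrame(meta["channel_meta"])[
        ["probe", "area", "layer", "contact"]]
    rec = SessionRecording(signals=signals, sample_rate=meta["sample_rate"],
                           channel_meta=channel_meta, eeg=eeg,
                           spikes=spikes or None)
    eye_lum = mouth = nose = None
    if (path / "behavior.csv").exists():
        b = pd.read_csv(path / "behavior.csv")
        eye_lum = b.eye_lum.to_numpy()
        mouth = b.mouth_lum.to_numpy()
        nose = b.nose_lum.to_numpy()
    beh = BehavioralSuite(
        eye_r=eye[0] if eye is not None else None,
        eye_theta=eye[1] if eye is not None else None,
        eye_lum=eye_lum, mouth_lum=mouth, nose_lum=nose,
        sample_rate=meta["sample_rate"], frame_rate=meta.get("frame_rate") or 30.0,
        fixation_target=tuple(meta["fixation_target"])
        if meta.get("fixation_target") else None,
    )
    ledger = EventLedger.from_flat(pd.read_csv(path / "ledger.csv"))
    return rec, beh, ledger
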