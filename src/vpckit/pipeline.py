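"""End-to-end orchestration: simulate -> detect -> preprocess -> spectral ->
phi -> decode -> stats, with per-stage seeds, content-hashed artifacts and a
JSON report.  This is a library-level driver; see the ``examples/`` scripts
for narrative single-capability walkthroughs."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, detect, integration, preprocess, spectral, stats
from .config import SimulationConfig
from .session_io import write_session
from .simulate import score_detection, simulate_session

STAGES = ("simulate", "detect", "preprocess", "spectral", "phi", "decode", "stats")
_REQUIRES = {
    "detect": ("simulate",),
    "preprocess": ("simulate", "detect"),
    "spectral": ("preprocess",),
    "phi": ("preprocess",),
    "decode": ("preprocess", "detect"),
    "stats": ("detect",),
}

#: Reduced geometry / boosted event rates for quick demonstration runs.
DEMO_OVERRIDES = {
    "n_blocks_rest": 2,
    "n_blocks_fix": 2,
    "areas": (("CN", "none", 6), ("FEF", "superficial", 4), ("FEF", "deep", 4),
              ("LIP", "superficial", 4), ("LIP", "deep", 4)),
    "vpc_prob_by_condition": {"NS": 0.5, "10Hz": 0.6, "50Hz": 0.5, "200Hz": 0.7},
    "str_prob": 0.5,
    "kindling_slope": 0.0,
}

PART_OF = {("CN", "none"): "CN", ("CL", "none"): "CL",
           ("FEF", "superficial"): "F_s", ("FEF", "deep"): "F_d",
           ("FEF", "middle"): "F_m",
           ("LIP", "superficial"): "L_s", ("LIP", "deep"): "L_d",
           ("LIP", "middle"): "L_m"}


def part_labels(channel_meta: pd.DataFrame) -> pd.Series:
    return channel_meta.apply(lambda r: PART_OF.get((r.area, r.layer), r.area), axis=1)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "pipeline_out"
    n_sessions: int = 2
    sim_overrides: dict = field(default_factory=lambda: dict(DEMO_OVERRIDES))
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    tau_ms: int = 15
    nboot: int = 2000
    sliding_window: int = 4

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, False)
        for s, on in self.stages.items():
            if on:
                for req in _REQUIRES.get(s, ()):
                    if not self.stages.get(req, False):
                        raise ValueError(f"stage '{s}' requires stage '{req}'")


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, STAGES.index(stage)])


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _event_epochs(rec, ledger, events: pd.DataFrame, excluded: list,
                  max_pre: float = 30.0):
    """Bipolar, filtered epochs for pre/during/post of each event."""
    out = []
    for _, ev in events.iterrows():
        blk = ledger.blocks[ledger.blocks.block_id == ev.block_id]
        bounds = (float(blk.iloc[0].t_start), float(blk.iloc[0].t_end)) if len(blk) else None
        ivals = preprocess.event_intervals(ev.event_onset, ev.event_offset,
                                           pre=max_pre, bounds=bounds)
        eset = preprocess.epoch_windows(rec, ivals)
        if eset.n_epochs == 0:
            continue
        eset.excluded_channels = excluded
        eset.data = preprocess.filter_lfp(eset.data, 1.0, 250.0, rec.sample_rate) \
            if rec.sample_rate > 500 else eset.data
        bip = preprocess.bipolar_derive(eset)
        out.append((ev, bip))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the report dictionary.

    Artifacts are written under ``config.outdir`` with content hashes; the
    run is deterministic for a fixed config + seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    artifacts: dict = {}

    # --- simulate ------------------------------------------------------
    sessions = []
    if config.stages["simulate"]:
        seeds = _stage_seed(config.seed, "simulate").generate_state(config.n_sessions)
        for i in range(config.n_sessions):
            sim = SimulationConfig(**{**config.sim_overrides,
                                      "seed": int(seeds[i] % 2**31)})
            rec, beh, ledger, truth = simulate_session(sim)
            sdir = outdir / f"session_{i}"
            write_session(sdir, rec, beh, ledger, config=sim.to_dict())
            sessions.append({"rec": rec, "beh": beh, "ledger": ledger,
                             "truth": truth, "dir": sdir})
            artifacts[f"session_{i}/ledger.csv"] = _hash_file(sdir / "ledger.csv")
        report["stages"]["simulate"] = {
            "n_sessions": len(sessions),
            "n_blocks": int(sum(len(s["ledger"].blocks) for s in sessions)),
            "n_true_events": int(sum(len(s["truth"].true_events) for s in sessions)),
        }

    # --- detect --------------------------------------------------------
    detected_all = []
    if config.stages["detect"]:
        scores = []
        for s in sessions:
            det = detect.detect_events(s["rec"], s["beh"], s["ledger"])
            s["detected"] = det
            detected_all.append(det)
            scores.append(score_detection(s["truth"].true_events, det))
        det_df = pd.concat(detected_all, ignore_index=True) if detected_all \
            else pd.DataFrame()
        det_path = outdir / "detected_events.csv"
        det_df.to_csv(det_path, index=False, float_format="%.6g")
        artifacts["detected_events.csv"] = _hash_file(det_path)
        report["stages"]["detect"] = {
            "n_detected": int(len(det_df)),
            "per_session_scores": scores,
        }

    # --- preprocess ----------------------------------------------------
    if config.stages["preprocess"]:
        n_epochs = 0
        for s in sessions:
            rec, ledger = s["rec"], s["ledger"]
            qc = preprocess.epoch_windows(rec, [(0.0, min(30.0, rec.duration), "qc")])
            excluded = preprocess.flag_bad_channels(qc)
            s["excluded"] = excluded
            s["event_epochs"] = _event_epochs(rec, ledger, s["detected"], excluded)
            n_epochs += sum(e.n_epochs for _, e in s["event_epochs"])
        report["stages"]["preprocess"] = {
            "n_event_epoch_sets": int(sum(len(s["event_epochs"]) for s in sessions)),
            "n_epochs": int(n_epochs),
            "excluded_channels": [s["excluded"] for s in sessions],
        }

    # --- spectral ------------------------------------------------------
    if config.stages["spectral"]:
        rows = []
        for s in sessions:
            for ev, eset in s["event_epochs"]:
                for tag in ("pre", "during"):
                    sel = eset.meta.tag == tag
                    if not sel.any():
                        continue
                    data = eset.data[sel.to_numpy()]
                    freqs, psd = spectral.multitaper_psd(data, eset.sample_rate)
                    gram = spectral.SpectralGram(values=psd.mean(axis=(0, 1))[None, :],
                                                 times=np.array([0.0]), freqs=freqs)
                    banded = spectral.band_average(gram, spectral.DECODER_BANDS)
                    for b, v in zip(banded.freqs, banded.values[0]):
                        rows.append({"event_type": ev.event_type, "tag": tag,
                                     "band": b, "power": float(v)})
        spec_df = pd.DataFrame(rows)
        spec_path = outdir / "band_power.csv"
        spec_df.to_csv(spec_path, index=False, float_format="%.6g")
        artifacts["band_power.csv"] = _hash_file(spec_path)
        summary = {}
        if not spec_df.empty:
            piv = spec_df.groupby(["event_type", "tag", "band"]).power.mean()
            summary = {"mean_band_power": {"|".join(k): float(v)
                                           for k, v in piv.items()}}
        report["stages"]["spectral"] = {"n_rows": int(len(spec_df)), **summary}

    # --- phi -----------------------------------------------------------
    if config.stages["phi"]:
        phi_rows = []
        for s in sessions:
            for ev, eset in s["event_epochs"]:
                labels = part_labels(eset.channel_meta)
                parts = {p: np.nonzero((labels == p).to_numpy())[0].tolist()
                         for p in labels.unique()}
                if len(parts) < 2:
                    continue
                for tag in ("pre", "during"):
                    sel = (eset.meta.tag == tag).to_numpy()
                    if sel.sum() < 3:
                        continue
                    covs = [integration.lagged_covariances(d, config.tau_ms)
                            for d in eset.data[sel]]
                    cov_t = np.mean([c[0] for c in covs], axis=0)
                    cov_x = np.mean([c[1] for c in covs], axis=0)
                    cov_l = np.mean([c[2] for c in covs], axis=0)
                    res = integration.find_mip(cov_t, cov_x, cov_l, parts)
                    phi_rows.append({"event_type": ev.event_type, "tag": tag,
                                     "H": res.entropy, "I": res.mutual_info,
                                     "phi_star": res.phi_star,
                                     "mip": "/".join(",".join(side) for side in res.mip)})
        phi_df = pd.DataFrame(phi_rows)
        phi_path = outdir / "phi_star.csv"
        phi_df.to_csv(phi_path, index=False, float_format="%.6g")
        artifacts["phi_star.csv"] = _hash_file(phi_path)
        section = {"n_rows": int(len(phi_df))}
        if not phi_df.empty:
            section["mean_phi_star"] = {
                f"{k[0]}|{k[1]}": float(v) for k, v in
                phi_df.groupby(["event_type", "tag"]).phi_star.mean().items()}
        report["stages"]["phi"] = section

    # --- decode --------------------------------------------------------
    if config.stages["decode"]:
        rng = np.random.default_rng(_stage_seed(config.seed, "decode"))
        X_rows, y_rows = [], []
        for s in sessions:
            for ev, eset in s["event_epochs"]:
                if ev.event_type not in ("VPC", "STR"):
                    continue
                labels = part_labels(eset.channel_meta).to_numpy()
                sel = (eset.meta.tag == "during").to_numpy()
                for d in eset.data[sel]:
                    freqs, psd = spectral.multitaper_psd(d, eset.sample_rate)
                    feats = []
                    for part in sorted(set(labels)):
                        gram = spectral.SpectralGram(
                            values=psd[labels == part].mean(axis=0)[None, :],
                            times=np.array([0.0]), freqs=freqs)
                        feats.extend(spectral.band_average(
                            gram, spectral.DECODER_BANDS).values[0])
                    X_rows.append(feats)
                    y_rows.append(ev.event_type)
        section: dict = {"n_samples": len(X_rows)}
        y = np.array(y_rows)
        if len(X_rows) and min((y == "VPC").sum(), (y == "STR").sum()) >= 10:
            cv = decoding.cross_validate(np.log(np.array(X_rows)), y, rng=rng)
            section.update({"accuracy": cv.accuracy, "se": cv.se,
                            "status": "ok", "note": "pooled during-event epochs"})
        else:
            section.update({"status": "insufficient events for decoding"})
        report["stages"]["decode"] = section

    # --- stats ---------------------------------------------------------
    if config.stages["stats"]:
        rng_seed = int(_stage_seed(config.seed, "stats").generate_state(1)[0] % 2**31)
        blocks = pd.concat([s["ledger"].blocks.assign(session=i)
                            for i, s in enumerate(sessions)], ignore_index=True)
        det = pd.concat([s["detected"].assign(session=i)
                         for i, s in enumerate(sessions)], ignore_index=True)
        section = {}
        rates = {}
        for cond in sorted(blocks.condition.unique()):
            sub = blocks[(blocks.condition == cond) & (blocks.task == "RW")]
            hit = 0
            for i, s in enumerate(sessions):
                ids = sub[sub.session == i].block_id
                dts = det[(det.session == i) & (det.event_type == "VPC")]
                hit += dts.block_id.isin(ids).sum()
            rates[cond] = {"n_blocks": int(len(sub)), "n_events": int(hit),
                           "probability": float(hit / len(sub)) if len(sub) else np.nan}
        section["vpc_probability_by_condition"] = rates
        pop = {c: v["n_blocks"] for c, v in rates.items() if v["n_blocks"] > 0}
        obs = {c: v["n_events"] for c, v in rates.items() if v["n_blocks"] > 0}
        if sum(obs.values()) > 0:
            null = stats.simulated_null_test(pop, obs, nboot=config.nboot,
                                             rng=rng_seed)
            section["null_test"] = {c: {"z": r.z, "p": r.p, "p_corrected": r.p_corrected}
                                    for c, r in null.items()}
        stim_conds = [c for c in rates if c != "NS"]
        if "NS" in rates and stim_conds and rates["NS"]["n_blocks"] > 0:
            p_ns = rates["NS"]["probability"]
            n_stim = sum(rates[c]["n_events"] for c in stim_conds)
            d_stim = sum(rates[c]["n_blocks"] for c in stim_conds)
            if d_stim and p_ns < 1:
                section["causal_power_stim_vs_ns"] = float(
                    stats.causal_power((n_stim / d_stim, p_ns)))
        try:
            merged = type(sessions[0]["ledger"])(
                blocks=blocks.drop(columns="session").reset_index(drop=True),
                events=det.rename(columns={}).drop(columns="session"))
            sl = stats.sliding_probability(merged, window=config.sliding_window)
            r, p = stats.lep_lsp_correlation(sl)
            section["lep_lsp_correlation"] = {"r": r, "p": p,
                                              "window": config.sliding_window}
        except ValueError as e:
            section["lep_lsp_correlation"] = {"status": str(e)}
        stats_path = outdir / "stats.json"
        _write_json(stats_path, section)
        artifacts["stats.json"] = _hash_file(stats_path)
        report["stages"]["stats"] = section

    report["artifacts"] = artifacts
    _write_json(outdir / "report.json", report)
    return report
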