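"""Generate one synthetic recording session and inspect its ledger.

A session mimics a primate DBS experiment: alternating resting-wake (RW) and
fixation-task (FX) blocks of 420 s, each stimulation block carrying three
60 s thalamic DBS epochs at 10, 50 or 200 Hz, with rare behavioural-arrest
(VPC) events and control stares (STR) drawn per block.
"""
import numpy as np

from vpckit import SimulationConfig, simulate_session

# reduced geometry keeps this demo quick; defaults mirror the full paradigm
config = SimulationConfig(
    n_blocks_rest=2, n_blocks_fix=2,
    areas=(("CN", "none", 6), ("LIP", "deep", 6)),
    vpc_prob_by_condition={"NS": 0.5, "10Hz": 0.6, "50Hz": 0.5, "200Hz": 0.7},
    str_prob=0.5, kindling_slope=0.0, seed=11,
)
rec, beh, ledger, truth = simulate_session(config)

print(f"signals: {rec.n_channels} channels x {rec.n_samples} samples "
      f"@ {rec.sample_rate:.0f} Hz ({rec.duration:.0f} s)")
print(f"spike units: {len(rec.spikes)}")
print("\nblocks:")
print(ledger.blocks[["block_id", "task", "condition"]].to_string(index=False))
print("\nground-truth events (type, onset, offset in s):")
print(truth.true_events[["event_type", "event_onset", "event_offset",
                         "in_stim"]].round(1).to_string(index=False))
frac_wake = np.mean(truth.state_sequence == truth.state_codes["wake"])
print(f"\n{100 * (1 - frac_wake):.1f}% of samples lie inside an event; "
      "during events the generator elevates 1-15 Hz LFP/EEG power and "
      "low-frequency cross-area coherence (VPC) or keeps the wake regime (STR).")
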