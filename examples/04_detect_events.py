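"""Detect behavioural-arrest events and classify VPC versus control stare.

Candidates are intervals (> 4.2 s) of stable gaze with open eyes and a still
face; a candidate becomes VPC when the EEG shows a significant 1-9 Hz power
increase over the pre-event period, and a control stare (STR) otherwise.
"""
from vpckit import SimulationConfig, detect_events, score_detection, simulate_session

config = SimulationConfig(
    n_blocks_rest=4, n_blocks_fix=2,
    areas=(("CN", "none", 4), ("LIP", "deep", 4)),
    vpc_prob_by_condition={"NS": 0.5, "10Hz": 0.6, "50Hz": 0.5, "200Hz": 0.7},
    str_prob=0.5, kindling_slope=0.0, seed=11,
)
rec, beh, ledger, truth = simulate_session(config)
detected = detect_events(rec, beh, ledger)

print("ground truth:")
print(truth.true_events[["event_type", "event_onset", "event_offset"]]
      .round(1).to_string(index=False))
print("\ndetected:")
print(detected[["event_type", "event_onset", "event_offset", "in_stim"]]
      .round(1).to_string(index=False))

scores = score_detection(truth.true_events, detected)
for etype, s in scores.items():
    print(f"\n{etype}: sensitivity {s['sensitivity']:.2f}, "
          f"false-discovery rate {s['fdr']:.2f} "
          f"({s['n_detected']} detected / {s['n_true']} true)")
print("\nSensitivity is the fraction of true events recovered (matched by "
      "interval overlap and type); FDR the fraction of detections without a "
      "matching true event.")
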