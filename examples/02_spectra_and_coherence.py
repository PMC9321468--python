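"""Multitaper band power and cross-area coherence of simulated LFPs.

Compares the wake and perturbed (VPC-like) regimes: the perturbed state has
elevated 1-15 Hz power and strong low-frequency coherence between areas.
"""
import numpy as np

from vpckit import (SIM_BANDS, SimulationConfig, band_power_in,
                    bipolar_derive, epoch_windows, pooled_coherence,
                    simulate_lfp)
from vpckit.config import STATE_CODES

config = SimulationConfig(
    n_blocks_rest=1, n_blocks_fix=0, block_duration=120.0,
    stim_epochs_per_block=1, stim_onsets=(30.0,),
    areas=(("CN", "none", 4), ("LIP", "deep", 4)), seed=3,
    vpc_prob_by_condition={c: 0.0 for c in ("NS", "10Hz", "50Hz", "200Hz")},
    str_prob=0.0,
)

for state in ("wake", "vpc"):
    states = np.full(120_000, STATE_CODES[state], dtype=np.uint8)
    rec = simulate_lfp(states, config)
    bip = bipolar_derive(epoch_windows(rec, [(0.0, 120.0, "all")]))
    cn = bip.data[:, 0, :].ravel()        # a CN bipolar channel
    lip = bip.data[:, 3, :].ravel()       # a LIP bipolar channel
    f, coh = pooled_coherence(cn, lip, 1000.0)
    print(f"\n{state} regime (120 s, bipolar-derived):")
    for band, (lo, hi) in SIM_BANDS.items():
        p = band_power_in(cn, 1000.0, (lo, hi))
        c = float(coh[(f >= lo) & (f < hi)].mean())
        target_p = config.state_spectra[state][band]
        target_c = config.state_coupling[state][band]
        print(f"  {band:6s} power {p:5.2f} (target {target_p:4.1f})   "
              f"CN-LIP coherence {c:4.2f} (target {target_c:4.2f})")

print("\nPower is the integrated PSD over the band (a.u.); coherence is the "
      "pooled multitaper magnitude coherence in [0, 1]. Measured values land "
      "on the generator's calibration targets.")
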