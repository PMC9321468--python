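# vpckit

Analysis toolkit for studying **DBS-induced perturbations of consciousness**
in cortico-striato-thalamic (CST) recordings. During thalamic deep brain
stimulation, awake primates can lapse into episodes of abnormally long,
vacant staring with low-frequency EEG activity — *vacant perturbed
consciousness* (VPC) — behaviourally similar to absence seizures. `vpckit`
implements the full analysis chain for such experiments, together with a
calibrated synthetic-session generator so every stage is testable without
animal data:

- **Synthetic sessions** (`vpckit.simulate`): block/stimulation ledgers
  (resting-wake and fixation blocks, 60 s DBS epochs at 10/50/200 Hz),
  state-gated multichannel LFP + EEG with analytically controlled band power
  and cross-area coherence, eye/face behaviour, spikes and stimulation
  artifacts, plus ground truth for parameter-recovery tests.
- **Preprocessing** (`vpckit.preprocess`): zero-phase Butterworth filtering,
  line-noise removal, robust channel QC, bipolar derivation, 1 ms artifact
  excision with effective-window bookkeeping, epoching, and the
  decorrelate/normalize/binarize path used before entropy analyses.
- **Spectral estimation** (`vpckit.spectral`): multitaper power and
  coherence (NW = 3, K = 5 Slepian tapers; 1 s windows, 0.1 s stride), with
  magnitude coherence `C(f) = |S12| / sqrt(S11 S22)` and band averaging
  (δ 1–4, θ 4–8, α 8–15, β 15–30, γ 30–90 Hz).
- **Integrated information** (`vpckit.integration`): Gaussian entropy
  `H = ½ log|Σ| + N/2 log 2πe`, lagged mutual information
  `I(X_t; X_{t−τ})` (default τ = 15 ms), mismatched information I* under a
  partitioned decoding model, `Φ* = I − I*`, and exhaustive search for the
  minimum information partition (MIP) minimizing `Φ*_P / N_P` with
  `N_P = (m−1) min_k H(M_k)`.
- **Event detection** (`vpckit.detect`): behavioural-arrest candidates
  (stable gaze > 4.2 s, eyes open, still face, off-target in fixation
  blocks) classified VPC vs control stare (STR) by a Holm-corrected 1–9 Hz
  EEG power increase relative to the pre-event period.
- **Decoding** (`vpckit.decoding`): Gaussian Bayesian classifier with shared
  shrinkage-regularized covariance (posterior `softmax(W_c^T x + w_c0)`,
  `W_c = Σ⁻¹ μ_c`), repeated stratified 60/40 cross-validation, and
  permutation feature importance (mean decrease in accuracy).
- **Statistics** (`vpckit.stats`): simulated-null permutation tests with Z
  and smoothed two-sided p, causal power
  `CP = (P(e⁺|c⁺) − P(e⁺|c⁻)) / (1 − P(e⁺|c⁻))`, sliding 32-block event
  probability vs stimulation predominance ("kindling"), cluster-based
  permutation on time–frequency maps, kernel-smoothed KS comparison of MIP
  distributions, Holm–Bonferroni control, interaction linear models with
  centered dichotomous coding, and normalized spike-rate summaries.
- **Orchestration** (`vpckit.pipeline`): an end-to-end driver
  (simulate → detect → preprocess → spectral → Φ* → decode → stats) with
  per-stage seeds, content-hashed artifacts and a JSON report.

## Worked example

```python
import numpy as np
from vpckit import find_mip, mutual_information

def var1_covariances(A):
    S = np.eye(A.shape[0])
    for _ in range(2000):
        S = A @ S @ A.T + np.eye(A.shape[0])
    return S, A @ S, S       # Sigma_t, Sigma_cross, Sigma_lag

A = np.zeros((4, 4))          # two disconnected 2-channel islands
A[:2, :2] = [[0.5, 0.3], [0.2, 0.4]]
A[2:, 2:] = [[0.6, 0.1], [0.3, 0.5]]
cov_t, cov_cross, cov_lag = var1_covariances(A)
res = find_mip(cov_t, cov_cross, cov_lag,
               {"CN": [0], "F_d": [1], "L_s": [2], "L_d": [3]})
print(mutual_information(cov_t, cov_cross, cov_lag), res.mip, res.phi_star)
```

prints

```
0.8544502173041612 (('CN', 'F_d'), ('L_d', 'L_s')) 0.0
```

— the system carries 0.854 nats of lagged information about its own past,
but the MIP cuts exactly between the two islands and Φ* = 0: nothing is lost
by modelling the halves separately, i.e. the network is not integrated.
Coupling the islands (see `examples/03_phi_star_mip.py`) makes Φ* positive.

The `examples/` directory walks through each capability: session simulation,
spectral calibration, Φ*/MIP, event detection, decoding with MDA, and the
ledger statistics (condition probabilities, causal power, kindling).

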