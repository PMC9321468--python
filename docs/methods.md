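# Methods

This note records the models, estimators and design choices behind `vpckit`,
in the spirit of a methods appendix: what each component assumes, which
parameters matter, and what the synthetic data can and cannot show.

## The experimental design being emulated

Sessions alternate resting-wake (RW) and rewarded-fixation (FX) blocks of
420 s. In a stimulation series, each block is assigned one of four
conditions — no stimulation (NS) or thalamic DBS at 10, 50 or 200 Hz — in
pseudorandom runs of all four; stimulation blocks carry three 60 s DBS
epochs starting 60, 180 and 300 s into the block (400 µs biphasic pulses,
negative phase first). Series of recording days alternate between Stim and
No-Stim; the first blocks after a switch are "transition", the rest
"established". Recordings span four areas — central lateral thalamus (CL),
caudate (CN), frontal eye fields (FEF) and lateral intraparietal area (LIP) —
with cortical probes split into superficial/deep segments, plus a skull EEG,
an eye tracker on the signal clock and face-luminance video at 30 Hz (the
video rate is a declared default; acquisition hardware differs).

## Synthetic sessions

**Event model.** Each block draws at most one VPC event with probability
`p(condition) + kindling_slope × LSP` (scaled by `fix_event_scale` = 0.15 in
FX blocks), where LSP is the fraction of stimulation blocks in the trailing
32-block window. Defaults use the emulated study's per-condition
probabilities (NS 12.9 %, 10 Hz 23.9 %, 50 Hz 14.8 %, 200 Hz 30.0 %) and a
kindling slope of 0.10; configurations whose probability can leave [0, 1]
are rejected. Control stares are drawn independently at 0.19 per block.
Durations are truncated normals — VPC 17.64 ± 5.96 s, STR 15.31 ± 6.63 s,
minimum 6 s so that classification always has ≥ 5 during-event epochs. VPC
onsets fall inside a stimulation epoch with probability 0.65 in stimulation
blocks, and the inside/outside flag is exact by construction.

**LFP/EEG model.** Signals are sums of state-gated narrowband stochastic
oscillators (order-4 Butterworth-filtered white noise per band: δ, θ, α, β,
γ) plus an independent 1/f background per contact and a common reference.
One globally shared source per band sets cross-area coherence; one private
source per area adds within-area structure. Because every analysis consumes
*bipolar-derived* signals, calibration targets (band power in a.u., pairwise
magnitude coherence) are defined at the bipolar level: contact loadings
alternate with depth (1 ± 0.5), so adjacent-contact differences retain
oscillatory content with a fixed transfer of 2×0.5 while the common
reference cancels exactly. Source powers solve a nonnegative least-squares
system through the band leakage matrix (filters are not brick-wall; leakage
into neighbouring bands is accounted for), with residual tolerances of 10 %
of the power target and 0.08 of the coherent-power target; infeasible
targets (e.g. coherence above what the 1/f floor allows) raise. The neural
regime switches to the event state 3 s before behavioural onset, mirroring
the observation that network changes precede the behaviour; STR keeps the
wake spectrum while VPC elevates 1–15 Hz power (×4) and low-frequency
coherence (≈ 0.5), and the EEG gains a strong 1–15 Hz component that the
detector's classification step relies on. Regime transitions are smoothed
with 0.5 s ramps. Calibration holds when measured with adequate spectral
resolution (e.g. Welch with ≥ 10 s segments); single-second multitaper
windows smear ±3 Hz and under-read the narrow δ band by design of the
estimator, not of the generator.

**Behaviour.** Wake gaze is saccadic scanning (inter-saccade 0.2–1 s,
amplitudes 1.5–12°, tracker noise 0.01° per sample) with blinks at 0.2 /s;
FX blocks fixate the central target within 1°. During events the gaze
freezes and drifts at 0.1 °/s — in FX blocks at an off-target position — the
eyes stay open, and mouth/nose luminance switches from bursty movement
(AR(1) steps of 3 a.u.) to near-stillness (0.3 a.u.). By default wake
inter-saccade intervals never exceed 1 s, so long stares arise only from
generated events; a `long_stare_rate` tail is available but off.

**Spikes** are thinned Poisson trains (10 Hz base rate, two units per area)
whose rate halves during VPC and anesthesia-like states.

What the generator does *not* emulate: spike waveforms and sorting, volume
conduction geometry, non-stationary electrode drift, eye-tracker dropouts,
reward licking artifacts in the LFP, and any biophysical mechanism of DBS —
passing recovery tests therefore shows the *analyses* are correct and
calibrated, not that real recordings will behave this way.

## Preprocessing

LFPs are bandpass filtered 1–250 Hz (Butterworth order 6, forward–backward,
hence zero phase), line noise is removed per non-overlapping 1 s window by
least-squares sine/cosine regression at the target frequency, subtracted
only when an F-test is significant at a Bonferroni-corrected threshold
(α = 0.05 / n_windows) so that clean signals pass through bit-identically.
Channel QC flags contacts whose session RMS exceeds the leave-one-out
median + 5 × max(1.4826·MAD, SD/2) of the other same-probe contacts — the
MAD keeps a second outlier from masking the first; the SD floor keeps
legitimately bimodal laminar amplitude profiles from degenerating the
spread. Bipolar derivation differences adjacent contacts within a probe;
excluded contacts break the chain and probes with fewer than two usable
contacts are dropped with a warning. Stimulation artifacts are excised by
linear interpolation over 1 ms around each pulse, followed by sinusoid
removal at the stimulation frequency; the effective (non-excised) fraction
is recorded and used as the rate divisor downstream. Epochs are
non-overlapping 1 s windows; event alignment uses up to 30 s pre/post.

Before the integration measures, each area's channels are linearly
decorrelated by ZCA whitening of the across-epoch covariance (any linear
decorrelation meets the requirement; whitening is symmetric and
deterministic), normalized to their mean absolute level across the day, and
optionally binarized at the per-epoch median. The Gaussian formulas are
coherent on continuous inputs, so the continuous path is the default and
binarization is retained as a switch (`prepare_phi_inputs(binarize=...)`).

## Spectral estimation

Multitaper estimates use 5 Slepian tapers at time–bandwidth 3 on 1 s windows
slid by 0.1 s. Coherence is reported as the *magnitude* of the normalized
cross-spectrum (a squared variant is a flag); per-window K-taper coherence
is biased upward for independent signals (≈ 0.42 at K = 5), which is a
property of the estimator and is exercised in tests. For calibration checks
a pooled estimator averages cross- and auto-spectra over windows first.
Pathway-level coherence averages the per-pair magnitudes over all bipolar
pairs of two regions, so random loading signs cannot cancel.

## Integrated information

States are modelled as multivariate Gaussian; entropy and lagged mutual
information use the closed forms, with covariance and lag-τ cross-covariance
(τ = 15 ms default) estimated by Ledoit–Wolf shrinkage on the joint
`[X_t, X_{t−τ}]` vector so the three blocks are jointly positive definite,
and averaged across all 1 s windows of a recording day before the partition
search. Mismatched information I* is the Gaussian mismatched-decoding
value: the disconnected model regresses each part's present on that part's
own past (block-diagonal regression and conditional covariance), and the
decoding functional is integrated in closed form up to a scalar inverse
temperature β, maximized numerically by bounded scalar optimization
(β ∈ [0, 10], tolerance 1e−10; a fine β-grid oracle in the test suite pins
the optimizer to 1e−4 nats). For the single-part "partition" the model is
exact and I* = I at β = 1; for block-diagonal dynamics Φ* = I − I* = 0.
Only bipartitions are searched (m = 2), so `N_P` reduces to the smaller
side's entropy; parts (areas/layers) are atomic; ties in the normalized
minimum break toward the lexicographically smallest partition. Φ* at the
MIP is reported unnormalized; time courses z-score Φ* per event across
windows before averaging. MIP types are integer-coded by their index in the
lexicographic bipartition list (any fixed bijection works; this one is
reproducible), and distributions over types are compared by KS tests on
Gaussian-KDE-smoothed mass functions (Silverman bandwidth), falling back to
empirical CDFs below 5 samples.

## Event detection

Gaze speed combines radial and tangential polar derivatives, lightly
smoothed (20 ms); samples above 3× the trace median (the saccade threshold —
the median tracks the tracker-noise floor) break stability and segments are
trimmed 200 ms at both ends. Face criteria are smoothed (250 ms) absolute
luminance derivatives, thresholded at half the trace median with sub-second
gaps closed (face signals live on the slow 30 Hz video clock); eyes-open
uses the large positive excursions of the eye-window luminance. A candidate
needs all available criteria simultaneously for > 4.2 s — the upper 95 %
bound of ordinary fixation durations — and, in FX blocks, a gaze more than
3° off target. Missing behavioural traces mark their criterion unavailable
and detection proceeds on the rest. Classification compares log power per
integer EEG frequency bin 1–9 Hz between during-event and pre-event 1 s
epochs with one-sided Welch t-tests, Holm-corrected across the nine bins
(α = 0.05): any significant increase ⇒ VPC, else STR. Welch tests were
chosen over paired tests because pre/during epoch counts differ per event,
so a pairing is undefined; the comparison is invariant to EEG gain. Events
overlapping stimulation epochs are artifact-excised before spectral
comparison. Events with fewer than five usable pre or during epochs are
unclassifiable and dropped from the ledger.

## Decoding

The Bayesian classifier models both classes as Gaussians with the
*unweighted mean* of the two class covariances, shrunk toward a scaled
identity with intensity selected from {0, 0.01, 0.1, 0.3, 0.5, 0.9} by
inner-loop validation accuracy; the uninformative prior contributes no
offset. "10-fold cross validation with 60/40 splits" is internally
inconsistent with standard k-fold, so validation uses 10 repeated stratified
random 60/40 splits (Monte-Carlo CV). MDA permutes one feature's values
across held-out samples (1000 permutations by default) — the standard
operation that severs that feature's relationship with the outcome and the
other features; permuting sample labels instead is available as a mode but
measures a global, feature-unspecific quantity. Feature tables are 5 bands ×
5 areas (CN, F_s, F_d, L_s, L_d; CL is excluded as only intermittently
available) on a −10.5…+4.5 s grid at 0.5 s stride (31 bins).

## Statistics

Simulated-null tests draw n observations from the pooled member population
(without replacement when the population is finite and unrepeatable, e.g.
block-level draws; with replacement otherwise), nboot times, and report per
category the probability (count / N_cat) or proportion (count / n), a Z
score against the null mean/SD, a two-sided p with +1 smoothing in numerator
and denominator, and Holm-corrected p across categories. Causal power
follows the probabilistic-contrast form and is monotone increasing in
P(e⁺|c⁺) and decreasing in P(e⁺|c⁻). Sliding ledger statistics use
32-block windows stepped by one block, both series normalized to their
maxima; note that adjacent windows share 31 blocks, so naive correlation
dof are optimistic — recovery tests use the number of non-overlapping
windows as effective n under the null. Cluster-based permutation thresholds
pointwise two-sample t-maps at the two-sided α = 0.05 critical value, sums
contiguous supra-threshold tiles per sign, and compares observed masses to
the permutation maximum-mass distribution. Interaction models are plain OLS
on centered dichotomous (±0.5) codings with product interaction columns and
animal as a fixed covariate — matching the printed model formulas rather
than a mixed-effects variant; rank deficiency raises. Spike rates divide
counts by effective epoch lengths after excision and normalize each unit to
its pre-event mean; per-area one-sample t-tests against 1 are
Holm-corrected.

## Orchestration and reproducibility

`run_pipeline` expands one global seed into per-stage `SeedSequence`s keyed
by stage index, so stages can be rerun independently; artifacts are written
with deterministic formatting and content hashes (HDF5 datasets disable
timestamp tracking), and a rerun with the same config + seed reproduces the
hashes bit for bit. The demo configuration uses two sessions with reduced
probe geometry and boosted event probabilities so that every report section
(including decoding, as pooled during-event epochs) has material to show;
study-scale defaults remain on `SimulationConfig` itself. The session
container stores the eye trace in `signals.h5` (it runs on the signal
clock) and the video-frame luminance table in `behavior.csv`; `ledger.csv`
is a denormalized block/stimulation/event table and round-trips losslessly.

## Problem sizes and known limitations

Recovery suites run on sessions of 8 × 420 s blocks with the full 80-contact
geometry (detection: ten sessions) and on reduced geometries elsewhere;
toy Φ*/MIP systems use 2–4 channels where brute-force enumeration and
β-grid search are exact oracles; the cluster-test error rate uses 100 null
replicates at nboot = 1000 on 15 × 12 grids. Φ* on the generator's VPC
regime *increases* with the coupling the regime adds — the generator
calibrates spectra and coherence, not the integration-collapse phenomenology
of real events, which would require structured cross-area dynamics beyond a
single shared source per band. Gradient-based β optimization is scalar and
bounded; systems near non-stationarity (spectral radius ≥ 0.95) are excluded
from tests because the VAR covariance iteration itself becomes
ill-conditioned there.
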