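# Methods

`axatp` quantifies two simultaneously recorded signals from ex vivo
myelinated nerve (optic nerve) preparations expressing a FRET-based ATP
biosensor: a three-channel fluorescence time series reporting axonal ATP,
and stimulus-evoked compound action potentials (CAPs) reporting
conduction.  Because such preparations ship no public raw data, the
package includes a synthetic-data generator built from a minimal axonal
energy-balance model, so that every analysis stage can be validated by
closed-loop parameter recovery: simulate raw signals with known ground
truth, push them through the full pipeline, and check that the documented
endpoint and onset values come back out.

## Sensor model

The sensor (ATeam1.03-YEMK class; CFP donor, cpVenus/YFP acceptor) binds
ATP with half-saturation K_D = 1.2 mM.  Its intrinsic FRET/CFP ratio is

    R(A) = R_min + (R_max − R_min) · Aⁿ / (K_Dⁿ + Aⁿ)

with Hill coefficient n = 2 by convention: no in-situ values for n,
R_min or R_max exist for myelinated axons, so these are generator
conventions, flagged as such.  R(K_D) = (R_min + R_max)/2 holds exactly
for every n.  R_min and the unit dynamic range are calibrated so that
complete ATP depletion lowers the raw channel-level F/C ratio by ≈35%,
matching the documented depletion experiment.

Channel rendering: FRET efficiency E = R/(1+R); CFP = (1−E)·g_CFP,
FRET = E·g_FRET + bleed-through·CFP, direct-YFP = g_YFP independent of
ATP (the pH/artifact control channel).  With this convention the
noiseless channel ratio FRET/CFP is an affine image of R, and the
two-point normalization below removes gains and bleed-through exactly.
Per-frame Gaussian noise (σ = 0.5% of each channel's baseline) is chosen
so the normalized ATP trace carries ≈2% frame-to-frame noise, comparable
to the visual noise level of published whole-field recordings.  Photon
(Poisson) noise, bleaching and motion are not modelled.

## Axonal energy balance

State variables: A (axonal ATP, mM), G (astroglial glycogen reserve, mM
ATP-equivalents), B (phosphagen-like rapid buffer, mM), D (ion-gradient
debt, mM).  Fluxes (mM ATP/s):

* **Direct glycolysis** J_glyc = V_glc·glc/(glc+K_glc)·pasteur, small at
  rest (~25% of production).  Under respiratory blockade the Pasteur
  factor jumps to `pasteur_boost` and relaxes to `pasteur_floor` with
  τ = 150 s — a transient anaerobic compensation that delays, but cannot
  prevent, ATP failure when mitochondria are blocked.
* **Mitochondrial production** J_mito = (1−azide)·V_mito·min(1, s).  The
  substrate supply s pools glucose-derived monocarboxylates
  (eta_shuttle·glc-fraction), glycogen-derived lactate while bath glucose
  is absent and G > 0 (gly_shuttle·G/(G+K_G)), and exogenous
  lactate/pyruvate (exo_efficiency·S/(S+K_sub)); all three pass the MCT
  factor (reduced by D-lactate or AR-C155858) and an ADP-like demand
  factor 1 + demand_gain·max(0, 1−A/A_base) that ramps supply up under
  load.  A small azide-insensitive glycogen-fed glycolytic term V_gly
  also exists.
* **Rapid buffer** J_buf = k_buf·(B/B_0)·(A_base−A)/A_base with
  dB/dt = −J_buf and slow ATP-consuming refill at rest; it sets the
  half-minute delay between combined blockade and detectable ATP decay.
* **Consumption** C = (c_0 + c_spike·f(t))·A/(A+K_A), with f(t) the
  burst-averaged stimulation rate.  While A sits below `debt_threshold`
  the ion-gradient debt D accrues; during recovery it is repaid at
  min(c_repay·D/(D+K_debt), repay_frac·production) — the Na⁺/K⁺ pumps
  claim most newly made ATP first, so after deep depletion conduction
  (gradients) recovers before the ATP signal does.

Euler integration at dt = 0.1 s (non-stiff by construction; a
step-halving convergence test is part of the suite); A clipped to
[0, A_max].

Deliberate deviations from a "textbook" flux split, each forced by the
documented phenomenology: glycogen feeds the mitochondrial substrate
pool (its support is azide-sensitive — combined blockade + deprivation
collapses ATP in half a minute while deprivation alone is buffered for
13 minutes); demand activation applies to the monocarboxylate supply
(glucose conditions ride out high-frequency load far better than any
fixed-production model allows, while MCT inhibition caps exactly this
reserve); the Pasteur transient separates the azide-alone onset from the
combined one; the debt pool orders CAP-before-ATP recovery.

## CAP waveform and conduction coupling

Each sweep is a stimulus artifact at t = 0 plus three Gaussian peaks
(amplitudes 1.4/1.0/0.35 mV at 0.6/1.15/2.3 ms); only the first two fall
inside the standard analysis window.  Peak amplitudes scale with
ψ_fatigue(f, t)·φ(A):

* ψ relaxes toward 1−β(f) with τ = 40 s during stimulation and recovers
  with τ = 60 s; β is tabulated per burst frequency (calibrated at
  16/50/100 Hz) with a power-law fallback for ramp protocols.
* φ(A) = min(1, A/A_safe)^q with A_safe = 0.3 mM, q = 4: conduction is
  unaffected until ATP nears the safety threshold, then collapses.

Latencies drift by latency_drift·(1−ψ) during fatigue; because the
analysis window is frozen from baseline, drift reduces measured area by
design.  Whether the decline at 10 mM glucose is ATP-limited or pure
fatigue is not decidable from endpoint data; the generator resolves the
split by convention: at 10 mM glucose ATP stays above A_safe, so the CAP
drop there is carried entirely by ψ, and φ only engages under depletion
or inhibitor conditions (the "safety window").

One sweep is recorded per baseline stimulus and one per 100-stimulus
burst (acquired during the 460 ms inter-burst gap), mirroring the
recording structure of the documented protocol.

## Analysis pipeline conventions

* **ATP**: whole-field per-frame channel means (optional mask; per-axon
  ROIs out of scope), ratio F/C, then two-point normalization
  value = (R − R₀)/(R_b − R₀) with R_b the pre-treatment baseline mean
  and R₀ the mean of the last 30 s of the terminal mitochondrial
  blockade + glucose deprivation application (plateau mean; the minimum
  is available as an option).  Values outside [0, 1] are retained.
* **CAP**: integration window frozen from the averaged baseline sweep —
  start at the first sustained rise above the pre-stimulus noise band
  (fallback 0.2 ms), end at the trough after the second peak (≈1.7 ms);
  area = trapezoidal integral of the rectified, baseline-subtracted
  deflection (rectification is a package convention and switchable); the
  pre-stimulus baseline excludes the artifact tail (samples before
  −0.2 ms), which keeps areas sample-rate invariant to <0.5%.  Areas are
  normalized to the initial baseline-period mean.
* **Kinetics**: rates are least-squares slopes ("m coefficients").  Rate
  metrics use centred 5-frame windows; onset detection uses trailing
  (causal) windows so a detected onset never precedes the change.  The
  onset threshold is max(k_sd·SD of baseline slopes, 3.5×10⁻³·value
  range per s) with k_sd = 3 and a two-consecutive-frame persistence
  rule; at default noise the relative floor dominates, making noiseless
  and noisy detection consistent and holding the false-onset rate on
  pure-noise baselines well below 1%.  HFS metrics follow the fixed
  windows: overall amplitude = mean of the last 15 s of stimulation,
  initial decay rate over the first 45 s, recovery rate over the 60 s
  after stimulation end.  The ATP/CAP drop ratio uses remaining
  amplitudes (≈1 when both fall by the same factor); the decrement
  convention is available as an option.
* **Statistics**: Welch's t (Welch–Satterthwaite df), paired t, one-way
  ANOVA with a hand-rolled Newman–Keuls step-down on the studentized
  range (no installed package provides NK); normality assumed, no extra
  multiplicity correction by default.  One simulated nerve = one
  independent replicate.

## Calibration

Free constants (c_spike, B_0, pasteur_boost, G_0, sensor R_min, three
fatigue depths, two exogenous-substrate efficiencies, two MCT inhibition
factors) are fitted by `scripts/calibrate_presets.py` against the
documented endpoint and onset values, using the noiseless generator →
full pipeline loop as the oracle: continuous endpoints by Brent root
finding, frame-quantized onsets by interval search (centre of the
parameter interval that lands the detected onset on the target frame,
given the 10.4 s imaging cadence).  Stages are iterated to a fixed point
because c_spike and B_0 interact through the HFS transient.  The fitted
values ship as the package defaults; treatment and HFS onsets are placed
on the frame grid (312 s) so frame-quantized onset estimates can land on
the documented values.

## Known limitations

* Simulated replicates share one parameter set and differ only in
  measurement noise: between-animal biological variability is absent, so
  significance tests across simulated nerves are far more sensitive than
  their experimental counterparts and passing recovery tests say nothing
  about biological scatter.
* The frequency dependence of the ATP endpoint at 16 and 50 Hz emerges
  from the model rather than being calibrated; it runs a few points high
  (≈96–97% and ≈83–84% of baseline) relative to the documented
  intermediate values while preserving ordering and the near-diagonal
  ATP-vs-CAP relation.
* At 2 mM glucose the model lowers ATP but leaves the CAP fatigue-only,
  whereas real nerves also lose conduction; separating that would need a
  second, slower conduction-ATP coupling out of scope here.
* No spatial structure: no microdomains, diffusion, or per-axon
  heterogeneity; the image mode paints a stripe texture purely to test
  ROI extraction.
* Lactate/pyruvate presets assume the glycogen reserve is exhausted by
  the long glucose-free pre-incubation (G₀ = 0); with glycogen present a
  150 s stimulation could not distinguish substrates.
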