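# Methods

## Model

Five firing-rate units — auditory (A) and visual (V) input units, a
multisensory output unit (M), and two modality-specific inhibitory
interneurons (Ia, Iv) — each governed by

    tau_fast * du/dt = -u + net,    z = z_max / (1 + exp(-s (u - theta)))

integrated with explicit Euler.  Principal units share the activation
center `theta = act_center`; the interneurons use a higher center
`act_center_I`, so they are silent at rest while the principal units
keep a small spontaneous rate.  Both choices matter:

* The principal units' spontaneous rate (~0.03 of maximum) is what lets
  the *cross-modal* weight influence *unisensory* processing: with
  `Wav < 0`, the resting visual activity slightly inhibits the auditory
  unit, so a more inhibitory cross-modal state slows even auditory-only
  responses.  This coupling is the mechanism by which delayed
  cross-modal maturation slows every condition, not only the
  audiovisual ones.
* If the interneurons also had a spontaneous rate, the slow traces
  would exert a *tonic* feedback inhibition that grows as the feedback
  weights are trained, making repeat RTs increase with age — the
  opposite of the empirical age-related speedup.  A higher inhibitory
  threshold removes the tonic term without touching the evoked
  winner-takes-all dynamics.

The slow feedback inhibition is realized as first-order traces `q_a,
q_v` that low-pass filter the interneuron outputs with `tau_slow` and
inhibit the opposite-modality input unit with magnitudes `La, Lv`.  A
60 ms stimulus leaves a trace that is still present 1 s later and has
largely decayed by 3 s, spanning the task's inter-stimulus intervals:
this single mechanism produces the modality switch cost.

### Reaction-time readout

The simulated RT is the time from stimulus onset until `z_M` crosses
10% of the maximum rate, linearly interpolated between integration
samples; crossings later than 1000 ms post-onset are timeouts.  RTs are
in model milliseconds: with a 60 ms pulse and a 15 ms membrane time
constant, threshold crossings happen 15–30 ms after onset, an order of
magnitude faster than empirical button presses.  A single uniform
non-decision offset (default 0) can be added when aligning to empirical
scales; no acceptance property depends on the absolute scale, only on
differences and orderings, which is why the offset is left at zero.

### Parameters

Shipped presets (all efficacies dimensionless, times in ms):

| parameter | td_child | asd_child | adult (trained) | role |
|---|---|---|---|---|
| w_ma, w_mv | 11 | 11 | 14 | feedforward drive; sets overall RT speed |
| w_av, w_va | −24 | −29 | +8 | cross-modal coupling; sign = competition vs facilitation |
| w_Ia, w_Iv | 240 | 240 | 240 | interneuron drive; must be strong enough for the WTA to resolve within the pulse |
| l_av, l_va | 150 | 150 | 150 | interneuron mutual inhibition (WTA) |
| l_a, l_v | 5 | 5 | 32 | feedback inhibition; sets the switch cost |
| tau_fast / tau_slow | 15 / 1800 | | | two-timescale separation |
| act_slope / act_center / act_center_I | 0.35 / 9.5 / 20 | | | logistic activation |
| i0_a, i0_v | 11 | 11 | 11 | stimulus efficacy; mid-sigmoid operating point |

Every value is a calibration of this package (the source experiments
publish their data as figures, and no parameter table was available to
substitute).  The decisive calibration choices:

* **Mid-sigmoid operating point** (`i0` close to `act_center`): input
  units respond at ~0.3–0.5 of maximum, so cross-modal inhibition can
  genuinely null the audiovisual advantage in the child network (the
  young multisensory gain is ~2 ms; pushing `w_av` more negative makes
  it negative) while leaving headroom for the adult facilitation.
  Operating near saturation instead makes multisensory facilitation
  unavoidable at every age.
* **ASD child offset**: `w_av = −29` vs −24 keeps the ASD child's
  audiovisual response measurable (more negative values push the
  suppressed audiovisual drive below the detection threshold — a
  timeout cliff, not a slower RT).
* **Winner-takes-all**: the tie between symmetrically driven
  interneurons is broken by a ≤1e-6 perturbation applied to one
  interneuron at stimulus onset (the perturbed side is drawn from the
  run's RNG; batteries fix it to the auditory side, which the A/V
  mirror symmetry makes inconsequential).  For an infinitesimal seed
  to grow into a decided winner within the 60 ms pulse, the unstable
  mode of the interneuron pair must have a fast growth rate, which
  requires the strong `w_I` drive and `l_av = 150` above.  The winner
  is asserted at the end of the pulse; interneuron activity necessarily
  decays once the stimulus ends.

## Hebbian development

One epoch = one exposure; the session is continuous, so slow traces
carry across exposures exactly as in the task.  After each exposure the
trained synapses update from firing rates averaged over the 150 ms
post-onset window:

    w_ma += gamma_ff * za * zm          (clip [0, 14]);  w_mv symmetric
    w_av += gamma_cm * zv * za          (clip [−40, +8]); w_va symmetric
    l_a  += gamma_fb * zIa * (1 − zv)   (clip [0, 80]);  l_v symmetric

with `gamma_ff = 0.045`, `gamma_cm = 2.9`, `gamma_fb = 0.03` for
typical development (×0.8 under reduced plasticity).  Rationale for the
non-obvious choices:

* **150 ms window.**  The window covers the pulse and the decay of the
  evoked response.  A longer window (e.g. 500 ms) averages in the
  spontaneous rates, and the cross-modal product `zv * za` then picks up
  nearly as much drive from unisensory exposures as from audiovisual
  ones — at which point the AV fraction of experience (the exposure
  hypothesis, and the entire intervention logic) stops mattering.  In
  the short window, a unisensory pulse actively suppresses the other
  modality below its spontaneous rate, so cross-modal LTP is almost
  exclusively audiovisual-driven.
* **Asymmetric cross-modal clip `[−40, +8]`.**  The floor merely has to
  contain the most inhibitory initial condition (LTP never moves the
  weight down); the ceiling is the mature facilitatory efficacy and must
  stay low enough that the excitatory A↔V loop remains stable at rest.
* **Learning-rate calibration.**  `gamma_cm` places the sign flip of the
  cross-modal weights between epochs 1000 and 1500 of typical
  development (checkpoint 1000 still inhibitory, adolescent-to-adult
  transition excitatory), verified by `msinet calibrate`.  `gamma_ff`
  and `gamma_fb` balance so that all six condition RTs fall with age
  while the unisensory switch cost rises — feedforward speedup alone
  leaves the cost flat (the ablation with `gamma_cm = gamma_fb = 0`
  moves it by < 0.1 ms), and feedback growth alone would make switch
  RTs rise with age.
* **Caps** realize the saturation of development: all cohorts converge
  to the same adult configuration, which is what produces the ASD
  "catch-up" at the adult row.

The stimulus mix of an exposure phase is (p_AV, p_A, p_V): typical
(0.30, 0.20, 0.50); reduced exposure starts at (0.20, 0.40, 0.40) and
gains +10 AV points per 500 epochs (literal increments by default, the
remainder split equally; `cap_exposure_at_td` caps the ramp at the
typical 30% instead); interventions use (0.60, 0.10, 0.30) from epoch 0
(early) or 500 (late).

With the 50%-V / 20%-A mix, the visual pathway and the inhibition *onto*
the auditory unit (`l_v`) mature faster than their counterparts, so the
A-side switch cost dominates, and the V-side cost alone is not monotone
late in development.  The modality switch effect is therefore reported
as the pooled unisensory switch cost (mean of the A and V costs), which
is positive and non-decreasing across all four age groups; each side's
cost stays strictly positive throughout.

## Cohorts and comparison

Checkpoints at epochs {0, 500, ..., 3000} map to age groups 6-9, 10-12,
13-17; the adult row averages the batteries at epochs 1500–3000.  At
each checkpoint plasticity is frozen and the six-condition battery runs
(ISI 2000 ms; the multisensory switch RT averages the V→AV and A→AV
variants).  The frozen network is deterministic, so each condition runs
once; the "median RT" column name is kept for schema compatibility with
empirical tables.

Trajectory comparisons report the RMS difference over the 24 cells and
a one-way ANOVA with factor *data source* (two groups of 24, hence
F(1,46)); the F-distribution tail comes from `scipy.stats`, the sums of
squares are computed directly.

## The synthetic reference generator

`make_fixture_reference` emulates the published developmental medians of
a bisensory detection task at empirical scale (~300–470 ms): RTs fall
with age; the unisensory switch cost grows from ~12 to ~30 ms; the
multisensory gain is ~0 in the youngest group and ~30 ms in adults; the
ASD-like table lags the TD-like one by ~35/25 ms at the middle age
groups and converges by adulthood, with ±1.5 ms seeded jitter.  It does
**not** emulate within-subject RT distributions, race-model structure,
individual differences, or absolute-scale agreement with the simulator
(model RTs are an order of magnitude faster); tests that pass against
these fixtures establish that the simulated *orderings and trajectory
shapes* behave correctly, not that the model fits any particular
empirical dataset.

## Numerical choices

* Explicit Euler at dt = 1 ms (fastest time constant 15 ms); halving dt
  moves every battery RT by < 0.5 ms, against a 2 ms acceptance gate.
* RT crossings linearly interpolated between samples (removes dt
  quantization).
* The zero-input rest state is found by 10 s of relaxation (several
  `tau_slow`) and reused across a battery; every trial prepends a
  further 500 ms settling before its first stimulus.
* The integration kernel is a scalar loop JIT-compiled with numba
  (pure-Python fallback with identical arithmetic); updates are written
  symmetrically in A/V so that swapping all A/V parameters and stimuli
  mirrors trajectories bit-exactly.
* All randomness flows from one top-level seed through
  `numpy.random.SeedSequence` spawning (stream, tie-breaks, fixtures).

## Problem sizes

Full study conditions throughout: 3000-exposure training sessions
(~6·10^6 integration steps each), seven cohorts, seven checkpoints ×
seven trial simulations per battery.  A complete seven-cohort
reproduction takes a few seconds of CPU after JIT compilation.

## Known limitations

* Single neural element per region: no spatial receptive fields,
  no multi-unit sensory sheets, no spiking.
* LTP only, plus saturation bounds: no LTD or homeostatic decay, so
  weight trajectories are monotone by construction.
* Congruent audiovisual stimuli only; no incongruent or spatially
  discrepant cues.
* Simulated RTs live on the model's time scale; only RT differences and
  orderings are compared to behavioral findings.
* The adult switch cost saturates at a few model ms; its growth across
  age groups is robust, but its magnitude is not calibrated to any
  empirical value.
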