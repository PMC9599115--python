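# Methods

## Scope and design

`spnplast` is a desk-scale re-creation of a calcium-based synaptic
plasticity study on a striatal spiny projection neuron (SPN): synthetic
in-vivo-like cortical spike trains drive explicit dendritic spines on a
reduced biophysical neuron; a mechanistic calcium model converts the
synaptic and voltage activity of each spine into a calcium concentration
trace; a dual amplitude/duration threshold rule converts the calcium trace
into a synaptic weight trajectory; and a statistics layer relates the
spatiotemporal input pattern to the resulting weight change.

The electrical model is deliberately reduced.  The full study behind this
design used a morphologically complete, 14-conductance SPN model tuned by
evolutionary optimisation; here the dendritic tree is four primary branches
that each split once (soma-to-tip path ~200 µm, SPN-like tapering), the
dendrites are passive, the soma spikes through a minimal two-conductance
mechanism, and one lumped high-voltage-activated (HVA) calcium conductance
stands in for the six VGCC subtypes.  The passive constants are the
optimised SPN values (RM = 6.02 Ωm², CM = 0.011 F/m², RA = 1.3 Ωm,
E_leak = −80 mV).  What the reduction preserves: the proximal/distal
distinction, spine-level electrical and calcium compartmentalisation,
NMDA-dependent cooperativity between neighbouring spines, and somatic
spiking at an in-vivo-like rate (1–15 Hz under the default 200-train
drive).  What it does not: the channel repertoire shaping the AHP and
up-state dynamics, calcium-activated feedback (BK/SK/CaCC, calcium-dependent
VGCC inactivation), and the implicit-spine membrane compensation of the
full reconstruction.

## Synthetic inputs

One behavioural trial is 1 s of activity in `n_trains` excitatory trains
(default 200; the variability experiments use 50 for speed).  Each train is
an inhomogeneous Poisson process with rate
`base_rate × shared_modulation(t) × ramp(t)`:

* `base_rate` — log-normal across trains (median 4 Hz, log-SD 0.8), so a
  minority of trains carries most spikes, matching the heavy-tailed spread
  of per-train counts in cortical recordings;
* `shared_modulation` — a common slow fluctuation (1 + 0.4 sin(2πt/T)),
  which is what gives different trains positive within-trial correlations;
* `ramp` — a raised-cosine rate bump (amplitude ×3 at peak) centred 150 ms
  before trial end, emulating the late ramp of motor preparatory activity;
  configurable off.

Trial-to-trial variability is imposed by re-transforming the *initial*
trial for every repetition (never cumulatively): spike-time jitter drawn by
inverse-CDF from a normal truncated to the trial window (per-train counts
exactly preserved); spike moving, where each spike keeps its time but, with
probability p, is reassigned to a train drawn with probability
proportional to pre-move train counts (so the whole-neuron spike pattern
and the count distribution are both preserved); and ISI shuffling, which
anchors the first spike and permutes the remaining interspike intervals.
Inhibition is homogeneous Poisson for the entire 21 s experiment (1 s
lead-in + 10 × (1 s trial + 1 s intertrial interval)): fast-spiking
interneuron inputs at 12 Hz within 80 µm of the soma, low-threshold-spiking
inputs at 8 Hz beyond, four GABA_A synapses per dendritic compartment.

What the generator does *not* emulate about real recordings: cell-specific
temporal structure beyond one shared latent profile (real ensembles have
multiple latent dimensions), refractoriness and burstiness of single
neurons, and any behavioural trial-selection criterion.  Passing tests
therefore show that the *mechanism* behaves as designed under controlled,
realistic-order statistics — not that the quantitative results match any
particular dataset.

## Electrical model

Units are mV/ms/µS/nF/µm (so µS·mV = nA).  Compartments are the morphology
segments plus an explicit neck and head compartment per mapped spine.  The
cable equation is integrated with a fixed-step implicit update (default
dt = 0.05 ms): all conductances are evaluated at the previous voltage and
enter the matrix diagonal, the tree system is solved exactly by Hines
elimination, so the stiff passive part is unconditionally stable.  Spikes
are detected as upward crossings of −20 mV at the soma.

Synapses are normalised dual-exponentials (peak = gmax × weight).  Defaults,
from the corticostriatal literature and then calibrated as described below:
AMPA 0.3 nS (τ 1.1/5.75 ms), NMDA 0.15 nS (τ 2.2/60 ms) with the standard
single-exponential Mg²⁺ block (1 mM, 1/(1 + [Mg]/3.57 · e^{−0.062V})),
GABA_A 1.2 nS (τ 0.5/7.5 ms, E = −60 mV, shunting relative to rest).  The
NMDA activation variable is capped at its single-event peak (receptor-pool
saturation): without the cap, linear dual-exponential stacking at the
40–60 Hz rates reached during the late ramp produces unbounded conductance
and hence runaway calcium; with it, per-synapse NMDA current saturates at a
physiological level.  The plasticity weight multiplies AMPA and NMDA gmax,
so potentiation feeds back onto the electrical response within an
experiment.  The lumped HVA conductance (0.02 nS per spine head, 0.1
nS/1000 µm² of shaft, half-activation −5 mV, slope 4 mV) contributes
calcium only; its current is excluded from the voltage equation entirely —
the clean reading of "feeds the calcium model" for a current this small.

The minimal soma mechanism (fast inward, instantaneous Boltzmann m∞,
half −25 mV/slope 4, g = 0.6 µS, E = +50 mV; delayed outward first-order
gate, half −25 mV/slope 4, τ = 2 ms, g = 2.0 µS, E = −90 mV) was tuned to
three constraints in order: a stable rest indistinguishable from E_leak
(< 0.1 mV drift), a regenerative threshold near −50 mV, and 1–15 Hz firing
under the default 200-train drive.  It is a spike generator, not a fit to
SPN electrophysiology.

## Calcium model

Per dendritic segment that carries a mapped spine: three concentric shells
(outermost, the "submembrane" shell, 0.1 µm thick).  Per spine: two head
slabs and two neck slabs in series, the lowest neck slab coupled to the
segment's submembrane shell.  Influx (NMDA calcium fraction 5% of NMDA
current, plus the HVA current) enters the outer head slab; the spine
calcium seen by the plasticity rule is the volume-weighted mean of the head
slabs.

Buffers (1:1 mass action; totals, k_on [1/(µM·ms)], k_off [1/ms], D
[µm²/ms]): calbindin 80 µM, 0.028, 0.0196, 0.027; calmodulin N-lobe 15 µM,
0.2, 3.8, 0.066; calmodulin C-lobe 15 µM, 0.05, 0.013, 0.066; immobile
buffer 300 µM, 0.02, 0.3, immobile.  These are standard values from the
calcium-imaging-constrained modelling literature (binding ratio ≈ 20–40 at
rest).  Pumps are Michaelis–Menten surface fluxes — PMCA (Vmax 0.2
µM·µm/ms, Km 0.3 µM) on every membrane element, NCX (0.5, 1.0) on spines
only — with a constant leak equal to the resting pump flux, making the
50 nM baseline an exact fixed point.  Free calcium diffuses at 0.2 µm²/ms;
mobile buffers diffuse in both free and bound form.

Pump capacities, the NMDA calcium fraction and the HVA conductance were
calibrated jointly, once, against two bracketing conditions: a single
synaptic event at rest must produce a spine transient of order 0.1–1 µM
(measured: 0.13 µM peak, decaying within ~100 ms), and the sustained
late-ramp drive must hold the bulk of spines below the LTP threshold while
letting strongly driven, cooperatively depolarised spines cross it
(measured: 95th percentile ≈ 0.5 µM, brief excursions to a few µM).  The
calibration was fixed before the qualitative experiment suites were run.

### Numerics

One calcium step (default 0.025 ms, two per voltage step) is a symmetric
(Strang) composition: half-step sources/sinks (influx, pumps, leak), half-
step buffer reaction, full-step diffusion, half-step reaction, half-step
sources.  The reaction half-step is a linearised backward-Euler (Newton)
update, stable for the stiff binding kinetics; guards prevent any stage
from overdrawing a concentration, and a genuinely negative concentration
aborts the run with the offending step.  The symmetric composition cancels
the leading splitting error: halving dt changes a pulse-response peak by
~0.1% (the explicit first-order composition erred by ~6%).  Conservation is
exact by construction when pumps and influx are off (reaction and diffusion
are antisymmetric in flux), and is verified to 0.01% over 1 s in the tests.

## Plasticity rule

Thresholds T_AD = 0.33 µM and T_AP = 0.53 µM with duration criteria 28 ms
and 3.3 ms; soft bounds w ∈ [0, 2].  Two continuous-excursion timers per
synapse (time above T_AD, time above T_AP) reset whenever calcium falls to
or below the respective threshold; comparisons are strict, and duration
ties at machine precision count as not exceeded (so a square pulse of
exactly the threshold duration produces no change — the property the
threshold-scan estimators rely on).  When calcium exceeds T_AP only the LTP
branch applies; the LTD band is the open interval (T_AD, T_AP).  Gains are
per unit time (γ_P = 0.0044, γ_D = 0.004 µM⁻¹ms⁻¹; caps 0.01 ms⁻¹) and are
multiplied by dt each step, making trajectories step-size invariant on
smooth traces.  The gain magnitudes are free constants of the rule; γ_P is
fixed by the convention that a 100 ms pulse at 1 µM moves w from 1.0 by
≈ +0.1, and γ_D is set at the same order so sustained in-band plateaus
depress on a comparable timescale.  Weights are carried across trials
within an experiment; the same compiled step function serves the offline
trace API and the in-simulation online update, and is verified step-for-
step against an independent plain-Python reference on random traces.

The threshold-scan estimators feed square pulses of increasing amplitude
(at fixed duration) or duration (at fixed amplitude) to the rule and report
the largest scanned value that produces *no* weight change — the estimate
of the strict threshold, which equals the configured threshold exactly
because the update magnitude is proportional to the excess over threshold.

## Analyses

Instantaneous firing rate is a Gaussian kernel estimate (σ = 50 ms,
reflected at the trial edges so the rate integrates to the spike count) on
a 10 ms grid.  The weight-change triggered average partitions synapse-
trials into 7 bins of trial-level Δw — symmetric edges at ±a, ±a/2 and a
dedicated near-zero band ±a/10, with a the 95th percentile of |Δw|, logged
with every result — and averages the per-synapse-trial series within bins.
Neighbour activity merges the spike trains of the 19 nearest mapped spines
by dendritic path distance (ties broken by spine id) before rate
estimation.  Time-sample features are means over 1–5 equal consecutive
intervals of the trial (5 samples = 200 ms bins).  Random-forest regression
of Δw uses 5 × 4 = 20 random 75/25 train/test splits, reporting test-set R²
and normalised feature importances; 500 trees by default (the acceptance
suite uses 100–200 to keep its runtime in minutes — tree count moves the
variance of the scores, not their ordering).  Feature-set comparisons use
one-way ANOVA with pairwise Welch t-tests, uncorrected for multiplicity and
labelled as such.  Spike-pair features around instantaneous weight-change
events take the latest pre- and post-synaptic spikes at or before the event
(Δt = t_post − t_pre, positive when pre precedes post); events lacking the
required spikes are flagged and excluded from the regressions that need
them.

## Experiment defaults and problem sizes

The packaged experiments are sized for a desk: the variability sweep uses
50 trains × 10 trials × three jitter widths (three 21 s simulations, ~30 s
total); the cluster sweep uses 100 trains on a 2 spines/µm subset, five
(spines-per-cluster, cluster-length) configurations × 3–5 mapping seeds,
one trial each.  The full-scale study settings (200 trains, 125 mappings)
are plain config values; nothing in the code depends on the reduced sizes.

## Known limitations

* The reduced electrical model has a much higher input resistance than a
  full reconstruction, so absolute synaptic counts and conductances are not
  transferable; only the relative/qualitative behaviour is meaningful.
* NMDA receptor saturation is a hard cap rather than a kinetic scheme, and
  there is no calcium-dependent channel feedback.
* LTP at desk scale requires the clustered, dense-input configuration;
  sparse 50-train experiments are depression-dominated. This mirrors the
  role of input cooperativity in the underlying science but means the two
  experiment families probe different weight-change regimes.
* The dendritic calcium model exists only on segments carrying mapped
  spines; shaft calcium elsewhere is not simulated (nothing reads it).
* Buffer/pump constants are literature-typical, not fitted; changing them
  re-scales the calcium operating point and the rule gains would need
  re-calibration.
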