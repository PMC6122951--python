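# Methods

This note documents the models and procedures implemented in `photospike`,
the parameters that matter, the design choices made where the underlying
protocol left them open, and what the synthetic-data generator does and
does not emulate.

## Conventions

Time is seconds everywhere internally; file columns carry unit suffixes
(`time_s`, `t_on_s`, `half_ap_width_ms`).  Every interval — light epoch,
sliding window, behavioral phase — is half-open `[on, off)`, so a spike
exactly on a boundary is counted once, in the later interval, and no spike
is ever double-counted.  Darkness is a first-class schedule entry
(wavelength code 0), which lets bistability analyses span unlit periods.

## Putative dopaminergic identification

A unit is accepted as putative dopaminergic (pDA) when it (1) fires
regularly, (2) has a mean rate of 1–10 Hz, and (3) has an action-potential
half-width > 1.1 ms.  "Regular" is not quantified in the standard
electrophysiological criterion, so it is operationalized here as an ISI
coefficient of variation ≤ `regularity_cv_max` (default 1.0, exposed in
the call signature); this is an artifact decision and is recorded as such.

## Burst detection

Bursts follow the two-criterion extracellular rule for dopamine neurons:
a burst opens at the first spike pair with ISI strictly below 80 ms and
extends while ISIs stay at or below 160 ms; the first ISI strictly above
160 ms (or the end of the train) closes it, and scanning resumes after the
closing spike.  Tie handling is strict on both sides: an ISI of exactly
80 ms does not open a burst, an ISI of exactly 160 ms does not close one.
Both spikes of the opening pair belong to the burst.  Only the two ISI
criteria are enforced: the qualitative burst features (declining spike
amplitude, lengthening ISIs) are not testable from sorted spike times.
The detector is verified against an independent brute-force scanner that
tests candidate ranges directly against the burst invariants, on 1,000
randomized trains.

Sliding series use 60 s windows advancing by 15 s (45 s overlap), anchored
at `t_start`; a truncated final window is dropped so every value covers a
full window.  %SWB within a window is computed over the spikes falling in
that window.  Event-aligned histograms use 250 ms bins and pool counts
over events (rate = total count / (n_events × bin width)).  No
post-transition blanking interval is applied by default.

## Photoswitching analysis

Epoch frequencies are pooled — total spikes in all epochs of a wavelength
over their total duration — rather than averaged per epoch, which is more
robust at 1–10 Hz over 5 s flashes; a per-epoch mean variant is available
behind `pooled=False` for sensitivity analysis.  The index
`100·(f₅₂₀ − f₃₉₀)/f₃₉₀` is positive when firing is lower under violet
light (type 1) and negative when higher (type 2).  It is undefined for
`f₃₉₀ = 0`; callers should pool counts over a longer span first.

The responder threshold is either fixed at 15% absolute photoswitching or
derived from a control cohort as the |index| quantile at the exclusion
fraction (default 0.95), using the linearly interpolated order statistic
(`numpy.quantile`, linear method); the quantile convention is recorded in
the `ThresholdSpec` because other conventions exist.  Values exactly at
the threshold count as responders (≥), so the fixed rule yields a
deterministic partition.  Cohort summaries report mean ± SEM of |index|,
responder fractions, and a two-sample Kolmogorov–Smirnov comparison of
the |index| distributions.

## Pharmacology

The photo-inhibition index of an evoked current is `100·(1 − I₃₈₀/I₅₂₅)`,
invariant to rescaling both amplitudes; opposite-sign amplitude pairs are
rejected as artifactual.  Nicotine responses are measured on the 60/15 s
sliding rate series: baseline is the mean of windows ending in the 180 s
before the injection (a sub-span of the ≥ 5 min pre-injection period;
configurable), and the response is the percent variation of the
largest absolute magnitude among windows starting within 200 s after the
injection, sign preserved — nicotine produces both excitations and
inhibitions in this population.  Light-condition labels are metadata on
the injection (the 30 s flash beginning 10 s pre-injection is protocol,
not inferred from the schedule).  Responses under light are normalized as
a percent of the same neuron's dark response.  %SWB responses use the same
extremum contract on the %SWB series and are reported only for neurons
with at least one pre-injection burst; others are flagged non-bursting and
excluded.  Successive injections are analyzed independently; a refractory
check is provided to warn when firing has not returned to within 20% of
baseline.

## Place preference

Occupancy credits each inter-sample interval (nominally 50 ms at 20
frames/s) to the zone of its leading sample; samples outside every zone
go to an "off" bucket with a warning.  The preference score is
test-minus-pretest time on the drug-paired side only; center-compartment
time never enters the score (a paired-minus-unpaired difference variant
would double effect sizes and is intentionally not the default).  Group
balancing minimizes the maximum absolute group-mean pretest bias over
near-equal-size partitions — exhaustively up to 16 animals, and with a
seeded randomized swap descent beyond.

## Statistics

Two-group comparisons pass through a gated tree: Shapiro–Wilk on both
groups (on the differences for paired data) at α = 0.05; if normality
holds, a Levene test (median-centered, α = 0.05) selects the pooled vs
Welch t-test; otherwise Wilcoxon signed-rank (paired) or Mann–Whitney U
(unpaired).  The variance gate and its α are package choices (the
protocol says only "Welch-corrected if needed") and are recorded in every
`TestResult` along with all gate p-values.  Holm–Bonferroni is the
step-down adjustment with running-max monotonicity and a cap at 1,
implemented here and cross-checked against statsmodels in the tests.
Primitive statistics delegate to scipy; the tree, gating and correction
logic are this package's code.  The empirical type-I error of the full
tree is verified to stay near 0.05 under both Gaussian and log-normal
nulls, so the gating does not inflate the test size.

## Synthetic data

The generator's job is to produce inputs whose ground truth is known by
construction, at the protocol's own scale.

**Photoswitch state.**  The cis fraction is piecewise analytic: violet
light sets cis = 1 instantaneously at epoch onset (antagonism appears
within a flash); green light relieves it exponentially with time constant
`relief_s`; darkness relaxes cis → trans with half-life 74 min.  The
relief time constant defaults to 0.15 s so that relief is ~95% complete
within 450 ms, consistent with full current recovery in under 500 ms — a
0.5 s time constant would leave over a third of the antagonism in place at
that point.  With 5 s epochs this leaves a ~3% mean cis carry-over into
each green epoch, which is why the recovered type 1 index sits ~2–3
points below the construction value 100·(1−m)/m.

**Spike trains.**  Tonic firing is a gamma-renewal process (shape 4,
ISI CV = 0.5 — regular, pacemaker-like) generated exactly by time
rescaling through the cumulative intensity on a 5 ms grid.  The
receptor-to-rate coupling is a multiplicative gate: instantaneous rate =
base rate × (1 + (m₃₉₀ − 1)·cis(t)), applied to both the tonic rate and
the burst-entry rate.  This is the minimal generative stand-in — no
conductance-based modelling, no desensitization, no network simulation;
type 2 behavior is phenomenological (m₃₉₀ > 1).  Bursts are entered as an
inhomogeneous Poisson process (default 4 bursts/min), emit 2+ spikes
(geometric tail, mean ≈ 3.2) with intra-burst ISIs uniform in 30–70 ms,
and merge into the tonic train with a 1 ms refractory guard.  An optional
rebound transient after violet→green relief is available and off by
default, since its kinetics are unquantified.  Default class parameters
mirror the measured group means: type 1 base 3.41 Hz with m₃₉₀ =
1.85/3.41, type 2 base 3.48 Hz with m₃₉₀ = 5.25/3.48; the default cohort
is 28 controls plus 93 transduced units (60 non-responders, 24 type 1,
9 type 2).  Per-neuron base rates get lognormal jitter (CV 0.25,
truncated to 1–10 Hz).  All randomness flows from one seed through
counter-based spawned streams, one per neuron, so cohorts are reproducible
and subsets regenerable.

**Nicotine transients.**  A double-exponential multiplicative kernel
(rise 25 s, decay 150 s, 5 s latency; peak ≈ 59 s post-injection, inside
the 200 s horizon) scales the rate by 1 + (g − 1)·h(t).  Under cis
receptors the increment is scaled by the antagonism factor (default 0.4).
Because the 60 s analysis window averages over the transient, the
recovered response for g = 2 is ~95–100% rather than exactly 100%; the
window-extremum selection partially offsets the smoothing.

**CPP trajectories.**  Sessions are 900 s at 20 frames/s in a two-chamber
arena (11 × 25 cm chambers, 11 cm triangular center).  The generator
works in integer frame counts — animals visit zones in alternating bouts
with Dirichlet-split dwell times and uniform within-zone positions — so
measured occupancy equals the constructed occupancy exactly at the frame
period.  Per-animal pretest bias is Gaussian (SD 120 s), conditioned
groups shift their test-phase paired-side time by the conditioning shift
(default 166 s) plus per-animal noise (SD 100 s); null groups shift by 0.
These scales reproduce group SEMs of ~25–40 s at n = 6–8.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: electrode drift and sorting errors, rate
nonstationarity beyond the modelled light and drug effects, correlated
noise across simultaneously recorded units, the qualitative within-burst
amplitude/ISI structure, receptor desensitization, nicotine
pharmacokinetics, and wall-following or thigmotactic structure in open-
field trajectories.  Recovery results on synthetic cohorts demonstrate
the correctness of the analysis code under the stated generative
assumptions, not robustness to those real-world effects.

## Problem sizes and numerical choices

Verification runs use 1,000 randomized trains for the burst oracle sweep,
50-unit cohorts for index recovery, the full 93-unit composition for
classification, 20 seeds per light condition for nicotine recovery,
2,000 replicates per null for the type-I error estimate, and 8 animals
per CPP group.  The spike-rate grid step is 5 ms (well below every ISI
scale of interest); quantile interpolation is linear; burst-range and
threshold ties are resolved as stated above.  Degenerate inputs have
defined behavior throughout: empty trains yield empty burst sets and
zero-valued series, constant samples at the null give p = 1, a zero
390-nm frequency raises rather than returning an infinite index.
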