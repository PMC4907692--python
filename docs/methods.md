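# Methods

## Gating model and simulator

Channel gating is a continuous-time Markov chain over a small labelled
state set. Each state carries a relative conductance fraction in [0, 1]
(0 = closed, 1 = fully open; intermediate values model subconductance
levels). The rate matrix Q (s⁻¹) has nonnegative off-diagonal rates and
zero row sums; validation requires at least one closed state, but a fully
open state is optional so that silent controls (all-closed models) can be
expressed. The two-state constructor `GatingModel.two_state_po(po)` fixes
the closing rate at 100 s⁻¹ (10 ms mean open time, typical of a strongly
agonist-bound channel) and sets the opening rate to `100·po/(1−po)`.

Paths are realized exactly, event by event (exponential dwells, embedded
jump chain). The stationary law solves πQ = 0 with Σπ = 1 via the null
space of Qᵀ; a multi-dimensional null space (reducible chain) is rejected
rather than silently resolved. P₀ is Σπ over conducting states, or the
conductance-weighted sum when the expected normalized current is wanted
instead.

**Sampling onto the acquisition grid.** A dwell briefer than one sample
contributes its time-weighted share of conductance to the sample(s) it
straddles, emulating how analog filtering blurs brief events. Samples
wholly inside one dwell take its value bit-exactly, so noiseless renders
have mathematically clean plateaus.

**Sweep boundary convention.** Each rendered sweep starts from the
stationary distribution of Q (falling back to the model's initial
distribution when no unique stationary law exists). Episodes of a real
recording are slices of one continuously gating channel; starting every
sweep from a closed initial state would superimpose the relaxation
transient (time constant ≈ 1/(α+β)) on every episode and bias low-P₀
estimates.

**Noise and filtering.** Baseline noise is white Gaussian shaped by the
acquisition filter and rescaled so its post-filter SD equals
`baseline_sd` (default 1 pA); optional open-channel excess noise scales
with the conductance fraction. Both the acquisition and offline filters
are zero-phase Gaussian FIRs with the −3 dB point at the stated cutoff
(defaults 5 kHz and 2 kHz at 20 kHz sampling). A Gaussian kernel is
monotone and non-ringing, which makes it a reasonable digital stand-in
for the high-order Bessel response of recording hardware; the offline
filter belongs to the *analysis* (`lowpass_recording`), not the
simulator, mirroring real workflows. After the 2 kHz offline filter the
1 pA baseline SD drops to ≈ 0.6 pA.

**Protocol and recording structure.** The default protocol is 100 ms at
−90 mV, a 500 ms step to +90 mV, 100 ms at −90 mV, repeated every 700 ms,
with unitary amplitudes +9.09 pA and −2.52 pA (chord conductances of
101 pS and 28 pS — the pronounced rectification of the channel studied).
Null sweeps (leak template + noise, flagged) precede the agonist sweeps;
the agonist wash-in delay forces the channels closed for
⌈delay/cycle⌉ sweeps rather than dropping them, so P₀ time courses show
the silent period. All randomness derives from one master seed through
`numpy.random.SeedSequence` spawning (independent per-channel and noise
streams), making recordings byte-reproducible.

## Leak subtraction and segmentation

The leak template is the pointwise mean of all null sweeps (using a
single trace is expressed by flagging only one null). Subtraction removes
the template from every active sweep and drops the nulls; the output
metadata records how many were averaged. Voltage segmentation uses
half-open, 0-based sample slices computed from cumulative segment
durations (gap- and overlap-free under rounding). When a voltage occurs
more than once per sweep, its *analysis* slice is the occurrence
immediately before the most depolarized segment — channel behaviour at
the holding potential is read from the 100 ms before the step, not the
trailing repolarization segment.

## Idealization

The 50% threshold-crossing rule assigns each sample the count of
thresholds its magnitude strictly exceeds; a sample exactly at a
threshold takes the lower level (conservative opening count, covered by a
dedicated test). Level-k thresholds are (k − 1 + f)·|i| with the sign of
the unitary current: f = 0.50 by default, f = 0.45 in subconductance mode
so substate sojourns are counted as openings (for a 10 pA channel this
gives the 4.5 pA threshold). Negative-voltage data are compared on
magnitudes with the sign carried through. Before thresholding,
small-amplitude (inward) slices may be smoothed with an n-pass
(1,4,6,4,1)/16 binomial kernel, reflected at the edges (default 5 passes
at negative voltages, none at positive). No minimum-dwell or hysteresis
filter is applied; single-sample events are retained.

## Open-probability estimation

*Idealized*: P₀ per sweep is the mean idealized level (NP₀ for N-channel
patches). The patch mean excludes the maximal initial run of sweeps with
P₀ below the activity floor (default 0.005 ≈ one single-sample opening
per 500 ms slice), reflecting agonist-bound channels only; interior
silent sweeps still count. All sweeps silent ⇒ the mean is NaN.

*Histogram*: the all-points histogram is compiled over the analysis
slices of the included sweeps, with 0.1 pA bins (≈ 1/10 of the baseline
noise SD) aligned so 0 pA is a bin center, normalized to unit area. A
Gaussian mixture — one closed component with |mean| ≤ one bin, plus
n open components initialized at multiples of the nominal amplitude and
refined by a deterministic local peak search — is fit by bounded least
squares. Two numerical choices matter:

- the model integrates each Gaussian over the bins (CDF differences)
  instead of evaluating the density at bin centers, which keeps the fit
  unbiased when a peak is narrower than a bin (the noiseless limit);
- component SDs are bounded (closed ≤ |i|/4, open ≤ |i|/2, lower bound
  bin/50). Filtered sub-sample transitions leave a low "bridge" of
  density between levels; an unbounded sparse component otherwise
  degenerates into a wide pedestal that soaks up this bridge and corrupts
  A_C (a 0.03 P₀ bias at true P₀ 0.99 in testing).

P₀ = 1 − A_C counts subconductance occupancy as open by construction,
consistent with the threshold choice. The unitary amplitude is the mean
of the largest-area open component; chord conductance is g = 1000·i/V pS
with reversal at 0 mV. The histogram estimator is restricted to
single-channel patches: 1 − A_C is "at least one channel open", which
equals P₀ only for N = 1, so multi-channel pipelines report idealized
NP₀ only. Method agreement (|P₀ideal − P₀hist| ≤ 0.02 across true P₀
from 0.1 to 0.99 at 300 sweeps) is asserted by the acceptance suite.

## Binding analysis

Specific binding is obtained by paired subtraction (mean nonspecific
signal at each concentration) or by fitting ns = slope·L through the
origin of a reference dataset; negative corrected values are retained
since clipping would bias low-signal points. The Hill fit runs on
replicate means, unweighted, with (K_d, nH, Bmax) parametrized on the log
scale — positivity without hard bounds — and a deterministic multi-start:
K_d from half-maximum interpolation, Bmax from the plateau, nH from
{0.5, 1, 2}. Slopes below 1 are allowed. Standard errors come from the
Jacobian at the optimum, mapped back by the delta method; fold changes
are K_d ratios with combined relative errors, and `format_fold` rounds to
one significant figure for reporting. No ligand-depletion correction is
applied.

The generator produces total counts Bmax·Lⁿᴴ/(K_dⁿᴴ+Lⁿᴴ) + ns·L with
multiplicative Gaussian replicate noise (default CV 5%, triplicates) and
paired nonspecific measurements under the same noise law — the design of
a saturation assay read out in triplicate. Default truths span the
experimentally relevant range (K_d 0.19–18 nM, nH 0.6–1.7).

## What the simulations do and do not emulate

The synthetic recordings capture the statistical structure the estimators
rely on: Markov dwell-time statistics, band-limited noise, leak offsets,
null traces, wash-in silence, superposition of independent channels and
subconductance levels. They do **not** model capacitive-transient
kinetics beyond an additive template, voltage- or ligand-dependent rates,
modal gating/bursting beyond what a chosen Q encodes, ADC quantization,
or baseline drift. Passing tests therefore validate the estimators under
idealized stationarity; on real data, drift correction and mode changes
would need separate handling. Likewise the binding generator's
multiplicative noise ignores counting (Poisson) statistics at very low
counts.

## Problem sizes and tolerances

Estimator-equivalence and oracle checks use 300 sweeps per P₀ grid point
(≈ 4.2 M samples each) with agreement asserted at ±0.02; zero-noise
idealization exactness uses 50 sweeps with at most one mismatched sample
per true transition; Hill recovery uses 8 log-spaced concentrations
(noiseless: 10⁻⁶ relative; 200 Monte-Carlo triplicate datasets at 5% CV:
median |K_d error| < 10%). Determinism tests compare reports byte for
byte. The full suite runs in well under a minute on one CPU.
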