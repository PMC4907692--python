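# patchbind

Analysis tools for single-channel patch-clamp electrophysiology and
saturation radioligand binding, built around the experiment design used to
characterize vanilloid-sensitive TRP channels: episodic voltage-step
recordings of one or two channels per patch, and ³H-ligand binding curves
with nonspecific correction.

The package provides the complete quantitative chain for both assays:

**Single-channel chain** — a continuous-time Markov gating simulator with a
per-state rate matrix *Q* (the analytic ground truth: stationary occupancy
from πQ = 0), rendering of realistic sweep recordings (unitary amplitudes
per voltage, band-limited Gaussian noise, leak templates, null traces,
agonist wash-in silent period, multi-channel superposition, subconductance
states); leak subtraction from averaged null traces; zero-phase offline
filtering and 5-pass binomial smoothing; 50%-threshold-crossing
idealization into occupancy levels 0..N (45% thresholds when subconductance
sojourns should count as openings); and two independent open-probability
estimators:

- *idealized*: P₀ per sweep is the mean of the idealized trace, averaged
  over sweeps after the wash-in silent period (NP₀ for N-channel patches);
- *histogram*: the area-normalized all-points amplitude histogram is
  decomposed into Gaussians, the closed component at 0 pA has area A_C, and
  P₀ = 1 − A_C. The open-peak mean gives the unitary current *i* and the
  chord conductance g = i/V (reversal at 0 mV in symmetrical solutions).

**Binding chain** — total binding B(L) = Bmax·Lⁿᴴ/(K_dⁿᴴ + Lⁿᴴ) + ns·L;
nonspecific correction (paired measurements or a reference line through the
origin); Hill fits in log-parameter space with deterministic multi-start;
and affinity comparisons as K_d ratios with delta-method standard errors
(e.g. the ~3-fold affinity enhancement of a vanilloid by an allosterically
coupled pore toxin, or the ~30-fold affinity difference between two
channel constructs).

## Worked example

```python
import numpy as np
from patchbind import (GatingModel, render_recording, leak_subtract,
                       simulate_binding, correct_nonspecific, fit_hill,
                       fold_change, format_fold, BindingTruth)
from patchbind.config import default_protocol, default_noise
from patchbind.popen import (lowpass_recording, estimate_po_idealized,
                             estimate_po_histogram, chord_conductance)

# simulate a single-channel patch: true P_o 0.9, 100 sweeps of the
# -90/+90/-90 mV step protocol, 5 s agonist wash-in delay
model = GatingModel.two_state_po(0.9)
rec = render_recording(model, default_protocol(n_sweeps=100), default_noise(),
                       n_null_sweeps=5, silent_delay=5.0, seed=42)
filtered = lowpass_recording(leak_subtract(rec), 2000.0)
ideal = estimate_po_idealized(filtered, 9.09, 90.0, subconductance_mode=True)
hist = estimate_po_histogram(filtered, 90.0, 9.09,
                             skip_sweeps=ideal.excluded_prefix_sweeps)
print(ideal.excluded_prefix_sweeps, ideal.mean_po, hist.po_hist)
print(hist.unitary_amplitude, chord_conductance(hist.unitary_amplitude, 90.0))
```

prints (formatted):

```
excluded wash-in sweeps : 8          # ceil(5 s / 0.7 s cycle)
P_o (idealized)         : 0.904      # true value 0.9
P_o (histogram, 1-A_C)  : 0.912
unitary amplitude       : 9.08 pA    # true value 9.09 pA
chord conductance +90 mV: 100.9 pS
```

The two P₀ estimates agree within 0.01 and both sit within Monte-Carlo
error of the simulator's stationary solution. Binding analysis follows the
same pattern:

```python
qm = fit_hill(correct_nonspecific(simulate_binding(
    BindingTruth(Kd=18.0, nH=1.7, Bmax=100.0, ns_slope=0.2, cv=0.05),
    np.geomspace(0.5, 300, 8), seed=1)), label="TRPV2 QM")
v1 = fit_hill(correct_nonspecific(simulate_binding(
    BindingTruth(Kd=0.6, nH=0.8, Bmax=100.0, ns_slope=0.2, cv=0.05),
    np.geomspace(0.02, 10, 8), seed=2)), label="TRPV1")
fc = fold_change(qm, v1)
print(qm.Kd, v1.Kd, fc.ratio, format_fold(fc.ratio))
```

```
TRPV2 QM: Kd = 18.2 nM, nH = 1.76    # truth: 18 nM, 1.7
TRPV1   : Kd = 0.51 nM, nH = 0.84    # truth: 0.6 nM, 0.8
Kd ratio: 35.7 (about 40-fold)       # truth: 30; triplicates at 5% CV
```

A `patchbind` console tool wraps the same stages (`simulate sc`,
`simulate binding`, `leaksub`, `idealize`, `analyze-sc`, `bindfit`,
`run-sc`, `run-binding`) driven by a YAML configuration; see
`patchbind --help`.

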