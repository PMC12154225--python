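# Methods

This note records the models, estimators and numerical choices behind
`pacinia`, what the synthetic generators do and do not emulate, and the
problem sizes used by the validation suite.

## Coordinate and unit conventions

Voxel arrays are `(z, y, x)` with 0-based indices; `z` is the
serial-sectioning axis. Physical voxel pitch is given in nanometres as
`(dx, dy, dz)` and may be strongly anisotropic (a typical high-resolution
block is 7 × 7 × 50 nm). Internally positions are handled in nanometres;
derived lengths and areas are reported in micrometres. Spike times are in
seconds; vibration amplitudes in micrometres, with the decibel convention
`dB = 20·log10(A / 1 µm)` (the 1-µm reference makes the ±4-dB staircase
symmetric in multiplicative steps of 10^(4/20) ≈ 1.585).

## Morphometry

**Surface area.** The lateral surface of a segmented object is estimated
slice-wise as total in-plane perimeter × Δz, summed over slices. Top and
bottom z-faces are deliberately not counted — the estimator is a
lateral-surface convention suited to elongated structures cut transversely,
and keeping it exact to that convention is what makes the analytic ground
truth (2πrL for a cylinder) the right reference.

**Perimeter estimator.** Perimeters are polygon lengths of iso-0.5
marching-squares contours extracted from a lightly Gaussian-smoothed
(σ = 1 px) copy of the binary mask. Raw voxel-edge counting overestimates a
disk's perimeter by up to 4/π; marching squares on a hard binary mask still
overestimates by ~5% (staircase corners are only chamfered). Pre-smoothing
restores the straight-edge limit and brings the digitized-cylinder error to
~0.5% at a 10-nm pitch. The cost is that structures thinner than ~2 px can
fall below the 0.5 iso-level and vanish; phantoms keep all structures ≥ 3 px
thick, and real volumes at 7-nm pitch are far above this.

**Contacts.** Two labels are in contact on a slice wherever their membranes
approach within a gap threshold (default 30 nm, inclusive). Rather than
binarily dilating one label and taking the overlap — whose one- or two-pixel
band the smoothing step could erase — the implementation measures contact
directly on the contours: a contour segment of label *a* counts as contact
where its interpolated distance to *b*'s voxels is within the threshold
(plus half a pixel, compensating the voxel-centre quantization of the
distance field). This is numerically equivalent to the dilate-and-overlap
recipe (the overlap band's perimeter is twice the apposition arc) but
robust at any pitch. Arcs are measured from both labels' contours and
averaged, which makes `contact_map(a, b)` exactly symmetric; the stored
`overlap_perimeter` is the two-sided sum, so
`contact area = overlap perimeter / 2 × Δz` keeps the classical
bookkeeping. Dilation/distance is strictly in-plane (2-D per slice): with
50–200-nm sections, a 30-nm criterion has no meaningful 3-D extent across
the z axis.

"First contact" is the smallest slice index with any contact, reported as
`index × Δz`; ties cannot occur. Protrusion contacts, individually ~0.1 µm
and below the perimeter machinery's scale, are scored as
`Σ contact range × 0.1 µm`; the 0.1-µm factor is a measurement convention,
not an estimate.

**Gap threshold inclusivity.** The 30-nm criterion appears in the
literature both as "≤ 30 nm" and "< 30 nm"; the inclusive form is used (the
distinction is a measure-zero set in continuous geometry and a sub-pixel
one on a grid).

## Stereology

Densities are exact ratios `count / sampled extent`, tagged with the extent
kind (length, area or volume) so that dimensionally inconsistent
extrapolations are rejected. Extrapolation is linear; intermediate
arithmetic is at full precision and only final reported values are rounded,
half away from zero (0.0294/µm³ × 140,900.72 µm³ = 4142.48 → 4142; divided
by 60 cells → 69.04 → 69). The number of lamellar cells defaults to 60 —
the conventional count for one inner core — although nucleus counts in a
full reconstruction can differ (63 in the volume that motivated the
default); both are exposed as parameters. No variance estimates are
attached: the procedure propagates point estimates only.

## Entrainment

For stimulus period `T`, inter-spike intervals of **all** spike pairs
inside the stimulus window are used (k spikes → k(k−1)/2 intervals),
pooled across stimulus repetitions but never across repetition boundaries.
Using all pairs rather than consecutive intervals makes the statistic
insensitive to skipped cycles and to onset jitter between repetitions. Each
ISI is folded to its nearest period multiple, `SISI = T + (ISI − nT)`, with
the deviation constrained to `(−T/2, T/2]`; a tie at exactly half a period
is assigned to the lower multiple. The entrainment probability is the
fraction of deviations within the closed window `[−T/12, +T/12]`: 1 for a
perfectly periodic train, and 1/6 in expectation for phase-random firing
because the window covers one sixth of the period.

Two implementations coexist and are cross-checked in the tests: the direct
pairwise route (chunked, for moderate trains) and an O(k log k) phase-domain
route that counts pairs by circular range search on sorted phases — exact,
and necessary for trains like 10⁴ spikes whose 5 × 10⁷ pairwise intervals
would not fit in memory.

**Bootstrap test.** The entrainment probability is recomputed on `n_boot`
(default 1999) same-size resamples of the ISIs drawn with replacement; the
unit is declared entrained when the 1st percentile of the bootstrap
distribution exceeds 1/6 (one-tailed, P < 0.01). The mirrored reading
(99th percentile below 1/6), which flags sub-chance locking, is available
behind a flag but is not the default, since the scientific question is
excess entrainment. Calibration caveat: on a *single* epoch the pairwise
statistic is a degenerate U-statistic whose distribution is skewed, and the
iid bootstrap then runs slightly hot (~2–2.5% type-I error at nominal 1%).
Averaged over ~10 independent stimulus repetitions — the regime the
procedure is designed for, and the structure the calibration run simulates —
the statistic normalizes and the observed rate returns to ~1–1.5%.

**Closed-form oracle.** Spikes jittered independently with SD σ around
cycle onsets give pairwise deviations distributed as a wrapped normal with
SD σ√2; the expected entrainment probability is the wrapped-normal mass on
`[−T/12, T/12]`, `Σ_k Φ((kT + T/12)/s) − Φ((kT − T/12)/s)` with `s = σ√2`.
It interpolates between 1 (σ = 0) and 1/6 (σ ≫ T) and anchors the
parameter-recovery tests.

## Tuning and thresholds

Single units pass a strict signal-to-noise gate (max |mean waveform| /
noise SD > 5). Responsiveness requires the best stimulus to beat baseline
by more than 5% **of the baseline mean** (the margin's referent is
configurable, since an absolute reading is also defensible), to exceed
baseline + 2 SD, and to do so on ≥ 20% of that stimulus's single trials.

Tuning curves are peak-normalized mean responses fit by a degree-6
least-squares polynomial (fitted in a scaled domain for conditioning, with
coefficients reported in the power basis; at least 8 distinct frequencies
are required for identifiability). Goodness `r` is the Pearson correlation
between fitted and observed responses with its usual t-transform p-value;
the selectivity gate is r > 0.7, P < 0.05 and tuning index > 0.2. The
preferred frequency is the argmax of the fitted curve on a 1-Hz grid within
the sampled range (ties to the lower frequency); the tuning width is the
fitted curve's full width at half maximum divided by two, undefined when
the fitted curve is nowhere positive. The tuning index is
`(µ_pref − µ_ortho)/(µ_pref + µ_ortho)` of the best and worst mean
responses.

Mechanical thresholds come in two definitions: the ramp amplitude at the
first spike of a linearly increasing stimulus (undefined, not an error, for
a silent unit; resolution is one stimulus cycle of the ramp), and the
smallest tested amplitude whose sustained rate (200-ms window starting
50 ms after onset) reaches 20% of the unit's maximum.

## Psychophysics

The staircase starts at the per-frequency maximum amplitude and, after
every block of six vibration trials (~12 trials including catch trials),
attenuates by 4 dB when the block's correct fraction exceeds 70%, amplifies
by 4 dB (capped at the start amplitude) below 60%, and holds in between
(the published rule is silent about the 60–70% band). Catch trials count
toward block fractions. Trial types are pseudo-random with at most three of
a kind in a row. Amplitudes are tracked as integer step counts below the
start amplitude, so repeated visits compare exactly equal.

The session threshold is the lowest visited amplitude whose pooled correct
ratio beats chance (0.5) in a one-sided exact binomial test at P < 0.05.
Only vibration trials enter the test by default: a catch trial carries no
stimulus amplitude, and because correct rejections sit well above chance
even when nothing is detectable, pooling them would let purely guessed
amplitudes drift to significance as trials accumulate. Pooling across the
session (rather than per bout) is the default; both alternatives are
exposed as flags. Session thresholds are averaged per frequency into the
sensitivity curve over the standard set {300, 450, 700, 1000, 1300, 1600,
2000} Hz.

## Synthetic data: what it emulates, and what it does not

**Phantoms** digitize solids of revolution on an anisotropic grid: an axon
cylinder, concentric lamellar shells separated by a nanometre gap and
interrupted over a cleft sector, rod-like protrusions inside the cleft, and
spherical nuclei carved out of shells. All surface areas and apposition
arcs are closed-form, and the rasterization is deterministic. Default
dimensions (1.5-µm axon, three 0.4-µm shells, 20-nm gaps, 60° cleft at
20 × 20 × 100 nm voxels) are deliberately small — real inner cores have
tens of intertwined, *non*-concentric lamellae over hundreds of
micrometres — and are chosen for second-scale construction; no published
geometry fixes them. Passing tests therefore certify the estimators'
accuracy on resolvable smooth geometry, not segmentation quality or the
topological complexity of real lamellae.

**Spike generators** produce one candidate spike per stimulus cycle at a
fixed phase with Gaussian jitter and Bernoulli cycle-skipping, homogeneous
Poisson trains, and ramp-evoked trains that start firing when a linear
amplitude ramp crosses a unit threshold. They emulate phase statistics, not
biophysics: no refractoriness, adaptation, bursting or amplitude-dependent
phase advance.

**Observers** follow a lapse-adjusted cumulative-Gaussian psychometric in
dB, floored at the 0.5 chance level, with fixed catch-trial accuracy and an
`inhibition_factor` that multiplies the linear threshold (a factor of 5 ≈
+14 dB, emulating a strong perceptual elevation). Because chance-level
vibration performance in this form is 0.5, a catch accuracy far above 0.5
would encode a conservative response bias without the matching drop in
vibration hits, and a staircase that counts catch trials would misread it
and sink several steps below threshold; the default catch accuracy of 0.65
keeps the observer close to bias-consistent. The reference observer for
recovery runs sits at −12 dB (0.25 µm) with a 2-dB slope and 2% lapses —
plausible for a trained mouse near its best frequency.

All generators take explicit seeds and never touch global random state;
fixed seeds reproduce outputs bit-for-bit.

## Validation problem sizes

The validation suite (`pacinia.demo`, also run by `scripts/acceptance.py`
and the acceptance tests) uses:

* stereology — the printed densities and the 140,900.72-µm³ inner-core
  volume, exact arithmetic;
* entrainment limits — one noise-free 400-Hz, 1-s train; ten 100-Hz Poisson
  trains of 100 s scored against a 400-Hz stimulus by the phase-domain
  route;
* bootstrap calibration — 500 Poisson datasets, each ten 250-ms repetitions
  at 100 Hz, 499 bootstrap resamples (scaled down from 1999 for runtime;
  the percentile criterion is unchanged);
* morphometry — a 2-µm × 5-µm cylinder at 10-nm in-plane pitch; a one-shell
  phantom whose lamella spans a 90° sector; twenty random two-label
  volumes for the symmetry check;
* parameter recovery — five jitter levels (0.05–0.4 ms), ten 10-s trains
  each, sized so the Monte-Carlo standard error (~0.002) is well below the
  0.01 comparison scale; 100 ramp-evoked units with thresholds in 1–15 µm;
* psychophysics — 100 sessions of 200 trials for threshold recovery and 50
  seed-paired session pairs for the ×5 threshold-elevation check.

The full run completes in under ten seconds on one CPU.

## Known limitations

* The perimeter estimator requires structures ≥ ~2 px thick; ultra-thin
  lamellae at coarse pitch will be under-segmented before they are
  under-measured.
* Contact counting reports per-slice connected runs; it does not merge
  contact components across slices into 3-D patches.
* The bootstrap entrainment test inherits the anti-conservatism of
  bootstrapping correlated pairwise intervals on single epochs (see above);
  interpret single-epoch significance with care.
* The staircase threshold rule applies no multiple-comparison correction
  across amplitudes — faithful to the published procedure, but with a small
  spurious-low-threshold rate that grows with session length.
* Stereological extrapolation assumes spatial homogeneity of junction
  density; no confidence intervals are produced.
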