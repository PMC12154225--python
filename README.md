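# pacinia

Quantitative tools for studying the Pacinian corpuscle (PC) — the layered
mechanoreceptor end-organ tuned to high-frequency (100–2000 Hz) vibration —
and the lamellar Schwann cells (LSCs) that wrap its afferent axon. The
package re-implements, as a tested library, the bespoke computations such a
study needs across three scales:

* **Ultrastructure** (`pacinia.morphometry`, `pacinia.stereology`):
  surface areas and membrane contacts from labeled serial-EM voxel volumes,
  and stereological extrapolation of junction counts to whole-structure
  totals.
* **Afferent physiology** (`pacinia.entrainment`, `pacinia.tuning`):
  phase locking of spike trains to sinusoidal vibration via standardized
  inter-spike intervals (SISIs) with a bootstrap significance test, plus
  tuning-curve fits, tuning index and mechanical-threshold extraction.
* **Behavior** (`pacinia.psychophysics`): the adaptive ±4-dB staircase of a
  two-alternative forced-choice vibration detection task, an exact binomial
  threshold rule, and V-shaped sensitivity curves.

Because EM volumes and recordings of this kind are rarely shareable,
`pacinia.synthetic` generates all three kinds of input with **analytic
ground truth**: voxel phantoms (digitized cylinders and multi-shell
"inner-core" geometries with known surface areas and contact arcs),
phase-locked/Poisson spike trains with controlled jitter, and parametric
psychometric observers. Every estimator in the package is validated against
these closed-form references.

## The statistics at the core

**Surface area.** For anisotropic serial sections (e.g. 7 × 7 × 50 nm
voxels), the lateral surface area of a segmented object is estimated
slice-wise: `A [µm²] = Σ perimeter [µm] × Δz [µm]`. Perimeters come from
sub-voxel iso-contours rather than voxel-edge counting (which overestimates
a disk by up to 4/π).

**Contacts.** Two membranes are in contact wherever they approach within a
gap threshold (30 nm by default, inclusive); the contact area is half the
overlap perimeter times Δz. Tiny protrusion contacts are scored as
`Σ contact range [µm] × 0.1 µm`.

**Stereology.** A density `D = count / sampled extent` extrapolates
linearly: `total = D × whole extent`, `per cell = total / n_cells` (~60
LSCs per inner core), rounded half-away-from-zero only at the end.

**Entrainment.** For stimulus period `T`, every pairwise inter-spike
interval is folded to its nearest multiple of the period,
`SISI = T + (ISI − nT)`; the entrainment probability is the fraction of
deviations inside `[−T/12, +T/12]` — 1 for perfect locking, 1/6 at chance.
Significance: 1999 bootstrap resamples of the ISIs, entrained when the 1st
percentile of the resampled probabilities exceeds 1/6 (one-tailed,
P < 0.01).

**Psychophysics.** Sessions start at the actuator's maximum amplitude and
step −4 dB after every six vibration trials (~12 trials with catch trials)
when the block's correct fraction exceeds 70%, +4 dB below 60%. The
perceptual threshold is the lowest visited amplitude whose vibration-trial
correct ratio beats chance (0.5) in a one-sided exact binomial test at
P < 0.05.

## Worked example

Junction totals of one inner core from measured densities (29.4 gap
junctions and 41.2 desmosomes per 1000 µm³, inner-core volume
140,900.72 µm³, ~60 LSCs):

```python
from pacinia.stereology import ExtentKind, density_estimate, extrapolate_totals

for name, per_1000 in (("gap junctions", 29.4), ("desmosomes", 41.2)):
    d = density_estimate(per_1000, 1000.0, ExtentKind.VOLUME_UM3)
    t = extrapolate_totals(d, 140_900.72, ExtentKind.VOLUME_UM3, n_cells=60)
    print(f"{name}: density {d.density:.4f}/um^3 -> total {t.estimated_total:.1f} "
          f"(~{t.estimated_total_rounded}), ~{t.per_cell_rounded} per LSC")
```

```
gap junctions: density 0.0294/um^3 -> total 4142.5 (~4142), ~69 per LSC
desmosomes: density 0.0412/um^3 -> total 5805.1 (~5805), ~97 per LSC
```

So an inner core hosts roughly 4142 gap junctions and 5805 desmosomes, i.e.
~69 and ~97 per lamellar cell — the numbers behind the picture of LSCs as a
densely, reciprocally coupled network.

Entrainment of a jittered, imperfect (20% skipped cycles) 400-Hz train:

```python
from pacinia.datatypes import VibrationEpoch
from pacinia.entrainment import bootstrap_entrainment_test, pairwise_isis
from pacinia.synthetic import make_phase_locked_spikes

train = make_phase_locked_spikes(400.0, 1.0, jitter_sd_s=1e-4, miss_prob=0.2, seed=1)
epoch = VibrationEpoch(0.0, 1.0, 400.0)
isis = pairwise_isis(train, epoch)
res = bootstrap_entrainment_test(isis, epoch.period_s, n_boot=1999, seed=1)
print(f"{train.n_spikes} spikes, {isis.size} ISIs, "
      f"entrainment probability {res.entrainment_probability:.3f}, "
      f"significant: {res.significant}")
```

```
316 spikes, 49770 ISIs, entrainment probability 0.832, significant: True
```

Despite the misses and 0.1-ms jitter, 83% of interval deviations fall inside
the ±T/12 window (chance would be 17%), and the bootstrap flags the unit as
entrained.

## Command line

A thin CLI wraps the same stages:

```bash
pacinia simulate --out phantom.json --seed 0          # phantom + ground truth
pacinia morpho   --volume phantom.tif --pairs 1-2 --out morpho.json
pacinia stereo   --counts counts.csv --out stereo.json
pacinia entrain  --spikes spikes.csv --epoch epoch.json --out entrain.json
pacinia psycho   --observer observer.json --out psycho.json
pacinia demo     --out demo.json --seed 1             # all validation stages
```

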