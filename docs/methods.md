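# Methods

## Signal model of the simulator

The phantom is a 2-D compartmental brain slice: an elliptical brain with a
cortical gray-matter rim, white-matter interior, two ventricles (CSF), six
small arterial-territory vessels (ACA/MCA/PCA, left/right) and a posterior
superior-sagittal-sinus vessel. Every voxel's instantaneous magnitude during
the acquisition is

    I(x, t) = S0(x) · (1 − β·exp(−r/τ)) · (1 + A(x) · w(u(x, t)))

* `S0` — compartment baseline signal (arbitrary units; white 1.0, gray 1.2,
  CSF 1.5, vessels 1.8).
* `(1 − β·exp(−r/τ))` — transient approach to the bSSFP steady state over
  repetition index `r`. Defaults β = 0.5, τ = 1.0 repetitions, so the
  residual deficit after the 10 discarded repetitions is 2·10⁻⁵ — genuinely
  negligible against the per-phase noise floor. A slower transient (e.g.
  τ = 3, residual 1.8% at repetition 10) is configurable; note that it
  aliases into specific cardiac phases and then dominates the amplitude
  statistics of an otherwise modulation-free phantom, which is exactly why
  the default keeps the post-discard residual below noise: the discard step
  exists to guarantee steady state, and the default honors that premise.
* `A(x)` — cardiac modulation amplitude as a fraction of baseline
  (white 0.004, gray 0.008, CSF 0.012, arteries 0.06, sinus 0.05). These
  put the parenchymal pulsatility (signal contrast) in the observed
  few-tenths-of-a-percent range, with vessels an order of magnitude above.
* `w` — raised-cosine pulse waveform on the unit circle, peak 1, duty cycle
  0.3 of the cardiac cycle. The true tissue FRE waveform shape is unknown;
  any smooth unimodal waveform gives the same phase/delay analysis, and the
  function is configurable.
* `u(x, t) = ((t − T_j − φ(x)) mod RR_j) / RR_j` — cycle fraction relative
  to the compartment's arrival time `φ` (ms after the trigger), with `T_j`
  the start and `RR_j` the length of the cycle containing `t`. Anchoring
  the arrival to each cycle's own trigger keeps the arrival phase stable
  under R-R jitter (trigger times are a jittered random walk, so a global
  time offset would smear the arrival across phases). Default arrivals:
  arteries 200 ms, tissue 300 ms, CSF 350 ms, sinus 550 ms — a 350 ms
  artery→sinus transit, in the middle of the 150–450 ms range typical of
  healthy adults.

k-space is acquired line by line: readout `k` of repetition `r` happens at
`(r·n_pe + k)·TR` and stores row `k` of the centered, unitary 2-D DFT of
`I(·, t)` times the coil sensitivity, plus complex Gaussian noise. Because
`A` and `φ` are piecewise constant per compartment, each line is an exact
linear combination of a handful of precomputed static transforms — fast
without approximating the intra-repetition time dependence (one repetition
lasts 128 × 3.6 = 460.8 ms, half a heart cycle, so lines within one
repetition genuinely see different cardiac states).

Coil sensitivities are Gaussian lobes (plus a positive floor) centered on a
ring around the slice; 4 coils by default — coil count is irrelevant to the
method. Noise convention: `noise_sd` is the per-component k-space noise sd
relative to the mean brain baseline; with unitary DFTs this equals the
relative per-pixel noise of a single-repetition coil image, so
`noise_sd = 0.05` ≙ per-repetition image SNR 20 (default 0.02, SNR 50).

The PMU simulator draws i.i.d. Gaussian-jittered periods (default 1000 ± 50
ms) and samples time-since-trigger on the readout grid. The ASL emulator
produces `control = S0 + noise`, `label = S0 − scale·f(x) + noise` with a
per-compartment perfusion table correlated with the modulation amplitudes;
no kinetic model is simulated.

### What the generator does not emulate

No Bloch simulation (no off-resonance banding, T1/T2, flip-angle effects),
no through-plane flow physics, no respiratory or bulk motion, no arrhythmia,
no ASL kinetics or dispersion, no realistic coil noise correlation.
Consequently, passing tests show the *post-processing chain* is correct and
recovers configured timing/amplitude truth under realistic noise and R-R
jitter — not that the physiological contrast mechanism itself behaves as
modeled.

## Gating

Triggers sit at sawtooth resets: a sample whose value drops below its
predecessor by more than half the running median of the last five cycle
peaks (the predecessor bootstraps the threshold). The trigger time is the
reset sample's time, so detection is quantized to one readout interval
(3.6 ms). A trace starting exactly at a trigger contributes an initial
trigger when its first value is below one sample interval.

Phase binning defaults to per-cycle fractions, `floor(n_phases·value/RR_j)`
clipped to `n_phases − 1`, which populates all 15 bins in every cycle
regardless of R-R variability; fixed-width binning in ms
(`median RR / n_phases`) is available for sensitivity analysis and agrees
exactly when the R-R is constant. Readouts before the first or after the
last detected trigger are dropped, not extrapolated.

## Reconstruction

Lines sharing (phase, encoding row) are complex-averaged; an empty cell
(possible at unlucky R-R/TR resonances) borrows the same row from the
circularly nearest populated phase and is logged, or raises if configured
strict. Per coil, a centered unitary inverse 2-D DFT; coils combined
root-sum-of-squares; the combined magnitude is bicubically interpolated to
256×256. Combining before interpolating is cheaper and differs from the
reverse order only at sub-tolerance levels for smooth coil maps; both the
upsample target and the order are configurable at the call sites.

The guided filter uses the temporal mean across the 15 phase images as its
guide (radius 2 px, `eps = 1e-2 · (guide dynamic range)²`). One common guide
smooths per-phase noise without mixing cardiac information between phases,
preserves anatomy edges, and — because box means are preserved — changes
each phase's spatial mean by well under 0.1%.

## Maps and delays

The phase map is `(argmax_voxel − argmax_brain) mod 15` with ties broken
toward the earliest phase. A series whose brain-mean signal varies by less
than `1e-3` of its level across phases is flagged flat (`is_flat`): with no
detectable modulation the per-voxel argmax is noise and the map should not
be interpreted. A wrap ambiguity is inherent: a voxel peaking one phase
*before* the reference reads as delta 14; delay computations therefore
treat deltas beyond half a cycle as negative ("signed" wrap), with pure
modulo arithmetic available.

The arteriovenous delay of territory T is
`(arrival_SSS − arrival_T) mod 15` phases, times `median RR / 15` ms.
The arrival of a ROI is estimated, by default, as the peak phase of the
ROI-mean signal waveform (`method="roi_curve"`): averaging the waveform over
the ROI before taking the argmax suppresses voxel noise, and the delay is
then literally the phase difference between the two ROI waveform maxima.
The alternative `method="voxel_min"` (wrap-aware minimum per-voxel delta,
i.e. the single earliest voxel) is retained, but it is an order statistic of
the noise: adjacent-phase signal differences near a peak are ~0.5% while
per-voxel noise after averaging ~33 lines is ~0.35%, so single-voxel minima
systematically pull delays early. Delay ROIs should be drawn on clean vessel
cores; the phantom's `roi_set(erode_vessels=1)` mimics this, because rim
voxels are partial-volume mixtures whose peak phase is tissue-contaminated.

Amplitude maps subtract the phase with the lowest brain-mean signal from
every phase; the comparison map against perfusion imaging is the amplitude
at the brain-wide maximum phase (a per-voxel maximum mode exists but
inflates noise). Negative voxel values are kept — clipping would bias the
map mean upward, which matters when testing a modulation-free phantom
against zero. Note one structural property: because the min/max phases are
selected from the same data, the brain-mean of the comparison map is a
range statistic of 15 noisy means, positive even under the null — about
2.5 naive standard errors for pure noise. The signal contrast
(pulsatility index) is `100 · mean(amplitude) / mean(mean-signal)` over a
ROI, with the mean signal from the ungated per-repetition reconstructions.

## Perfusion comparison

Subtraction maps are `mean(control − label)` (positive perfusion); the mean
signal averages control and label together. Percentiles use linear
interpolation between order statistics everywhere (normalization p90 with
clip at 1; binarization at p40 of raw in-mask values per subject, high
fraction ≈ 0.6 by the gray/white volume-fraction argument). Dice is
computed per tissue class; a class empty in both maps yields NaN, reported
as undefined. The Fisher-Z p-value uses the in-mask voxel count minus 3 and
ignores spatial autocorrelation — nominal, as commonly practiced, and a
documented limitation. Rank tests use exact nulls at small n (U test for
combined n ≤ 20 without ties; signed-rank up to 15 nonzero differences) and
tie-corrected normal approximations beyond. The closed-form CBF calibration
implements the consensus single-compartment model
`CBF = 6000·λ·ΔM·exp(PLD/T1b) / (2·α·T1b·M0·(1 − exp(−τ/T1b)))` with
T1b = 1.65 s, α = 0.85, λ = 0.9; it is a deliberate simplification — no
Bayesian spatial regularization, dispersion, or partial-volume correction.

## Cohort simulation

`run_cohort` draws each subject's territory transit times from group
generators (older group medians 169–246 ms, younger 286–419 ms, normal with
sd = IQR/1.35, clipped to [40, 620] ms), maps them to arrival times with a
fixed sinus arrival, runs the full pipeline per subject, and compares the
recovered delays per territory with the Mann-Whitney U test.

## Problem sizes and seeds

Unit and property tests run a 64×64, 2-coil, 200-repetition acquisition
(the method is matrix-size agnostic); the delay-recovery acceptance test
runs the full 128×128 × 500-repetition protocol over 20 seeds with four
territories configured at 134/268/402/536 ms, requiring recovery within one
phase duration in ≥ 95% of measurements. The acceptance script runs one
full-size study per invocation. All randomness flows from explicit seeds;
pipeline runs fan a single root seed out to the acquisition, PMU and ASL
stages, and identical configurations reproduce byte-identical artifacts.

## Known limitations

* Delay resolution is one cardiac phase (~67 ms at 1 beat/s); configured
  delays are recovered to that quantization, not beyond.
* The wrap correction assumes true transit times under half a cardiac
  cycle; longer delays alias.
* Territory ROIs are inputs; nothing segments vascular territories.
* The Dice/Pearson agreement levels of simulated data depend on the
  configured amplitude/perfusion correlation and should not be read as
  predictions for real acquisitions.
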