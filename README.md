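# freewave

Retrospective cardiac gating and pulse-wave mapping for steady-state bSSFP
brain MRI, with quantitative comparison against arterial-spin-labeling (ASL)
perfusion maps.

## The problem

During fast bSSFP imaging the static tissue is driven into a saturated
steady state, while blood flowing into the slice arrives unsaturated and
bright — flow-related enhancement (FRE). Because the inflow pulses with the
heart, the image signal of every voxel carries a small cardiac waveform. If
each k-space readout is tagged with a pulse-oximeter (PMU) timestamp, the
readouts can be re-sorted *after* the scan into cardiac phases, giving a
phase-resolved image series from a single free-running acquisition. From it
one can map, voxel by voxel:

- **pulse-wave phase** — in which of the `n` cardiac phases the voxel peaks,
  relative to the whole-brain peak phase;
- **arteriovenous delay** — the lag between the pulse-wave arrival in an
  arterial territory (ACA/MCA/PCA, left/right) and in the superior sagittal
  sinus, a surrogate pulse-wave transit time sensitive to vascular
  stiffening;
- **pulse-wave amplitude** — the signal difference of each phase against the
  phase with the lowest brain-mean signal; divided by the mean signal this
  is a pulsatility index (in %), and as a map it is weakly
  perfusion-weighted and can be compared against ASL subtraction maps.

This package implements the whole post-processing chain plus a synthetic
phantom/k-space simulator with known ground truth, so every stage is
testable without scanner data.

## The method

1. **Gating.** The PMU channel records time-since-last-trigger, a sawtooth
   over the acquisition clock. Triggers are detected at sawtooth resets
   (drop > 50% of the running median of recent cycle peaks). The first 10
   repetitions (1280 readouts at the reference protocol) are discarded so
   the magnetization is in steady state. Each remaining readout is binned
   into one of 15 phases: `phase = floor(15 · value / RR_cycle)`.
2. **Reconstruction.** All lines with the same phase-encode row and cardiac
   phase are complex-averaged (~33 = 500/15 lines each); each phase is
   reconstructed by centered inverse 2-D DFT per coil, combined
   root-sum-of-squares, bicubically upsampled 128 → 256, and denoised with a
   guided filter whose guide is the temporal mean across phases.
3. **Maps.** Phase maps as `(argmax_voxel − argmax_brain) mod 15`;
   territory delays from the peak phases of ROI-mean waveforms,
   converted to ms via `median RR / 15` (67 ms at 1 beat/s); amplitude maps
   as `phase n − phase with minimum brain-mean signal`.
4. **Comparison.** ASL perfusion-weighted maps as averaged control − label;
   both maps normalized to their 90th percentile, binarized at the 40th
   percentile (gray/white volume fraction), compared with Sørensen-Dice per
   tissue class and voxel-wise Pearson correlation (Fisher-Z test);
   Mann-Whitney U for group delay comparisons, Wilcoxon signed-rank for
   paired contrasts; optional closed-form "white-paper" CBF calibration.

## Worked example

```python
import freewave as fw

# phantom with a known 400 ms MCA -> sinus transit time
truth = fw.make_phantom(fw.PhantomConfig(
    arrival_time_ms={"mca_l": 200.0, "sinus": 600.0}))
acq = fw.AcquisitionConfig(seed=7)            # 128x128, 500 reps, TR 3.6 ms
pmu = fw.simulate_pmu(1000.0, 50.0, acq.total_duration_ms, acq.tr_ms, seed=7)
kspace = fw.simulate_kspace(truth, pmu, acq)

series, trace, counts = fw.discard_steady_state(kspace, pmu, 10)
stats = fw.detect_pmu_peaks(trace)
gated = fw.bin_and_average(series, fw.assign_phases(trace, stats))
phases = fw.guided_filter_series(
    fw.reconstruct_phase_images(gated, cycle_stats=stats))
rep = fw.reconstruct_per_repetition(series)

mask = fw.brain_mask(rep.mean_signal_image)
pmap = fw.phase_map(phases, mask)
rois = truth.roi_set(erode_vessels=1).resize_to(phases.grid)
delays = fw.arteriovenous_delays(pmap, rois, stats, series=phases)
print(counts["discarded_readouts"], round(fw.phase_duration(stats, 15), 1))
print(delays[["territory", "delay_phases", "delay_ms"]].to_string(index=False))
```

prints

```
1280 66.2
territory  delay_phases  delay_ms
    aca_l             6    397.44
    aca_r             6    397.44
    mca_l             6    397.44
    mca_r             6    397.44
    pca_l             6    397.44
    pca_r             6    397.44
```

1280 readouts were discarded before steady state, one cardiac phase lasts
66.2 ms at this recording's median R-R, and the configured 400 ms
MCA-to-sinus delay is recovered as 6 phases = 397 ms (all territories were
configured with the same transit time here). The same chain runs from the
shell:

```bash
freewave run --config run.yaml --out out/ --seed 7
```

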