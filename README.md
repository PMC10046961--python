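# calscreen

Analysis pipeline for plate-reader recordings of synchronized neuronal
Ca²⁺ oscillations, used to screen drugs for neuronal activity and
potential seizure liability.

The package covers five stages:

1. **`calscreen.synthetic`** — simulate 384-well plate recordings
   (Gamma-renewal pulse trains, linear-rise/exponential-decay pulse
   kernels, drift, noise, edge-well instability) with full ground truth,
   so every downstream stage is testable without proprietary raw data.
2. **`calscreen.waveform`** — smooth, differentiate, and threshold the
   derivative to detect bottom/top pulse pairs; estimate background
   fluorescence by bridging pulse spans; compute the five per-well
   parameters (peak number per 10 min, width, amplitude, area under the
   pulse, peak-to-peak time).
3. **`calscreen.stats`** — per-well percent change of peak number
   (post-treatment vs baseline window), two-sided rank-sum tests versus
   same-plate DMSO, and nonparametric (order-statistic) tolerance
   intervals for control groups.
4. **`calscreen.classify`** — drug-level direction calls at the lowest
   significant concentration, fold-over-free-Cmax context, confusion
   matrix versus clinical labels, and sensitivity / specificity / PPV /
   NPV / predictivity.
5. **`calscreen.reference_data`** — the packaged 25-drug reference panel
   (identities, free Cmax, tested concentrations, clinical labels),
   per-drug 2D/3D significance calls, and per-dose percent-change
   summaries, as reviewable TSV fixtures.

## Command line

```sh
calscreen simulate --seed 1 --out-dir out/            # demo plate + ground truth
calscreen features --baseline out/baseline.tsv --post out/post.tsv \
                   --plate-map out/plate_map.tsv --out-dir out/
calscreen stats    --observations out/observations.tsv --out-dir out/
calscreen report   --dose-results out/dose_results.tsv
calscreen replay   --culture 2D --out-dir out/        # packaged-table metrics
```

`replay` skips the waveform stages and scores the packaged per-drug
call table against the clinical labels, reproducing the panel-level
metrics without any raw fluorescence input. Trace files are wide TSV
(`time_s` + one column per well); all outputs are TSV with headers.

## Notes

- Defaults mirror the assay protocol: 2 Hz (2D) / 10 Hz (3D) sampling,
  1200 s windows, α = 0.05, tolerance intervals at 80 % coverage /
  95 % confidence, 144 edge wells excluded from treatment.
- The headline *predictivity* statistic divides (TP + TN) by the number
  of clinically active drugs (22), a reverse-engineered convention that
  reproduces the published 2D and 3D percentages simultaneously; see
  `calscreen.classify.predictivity_metrics`.
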