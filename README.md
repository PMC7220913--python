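# wmcpm

Connectome-based predictive modeling of fluid intelligence from white-matter
BOLD signals, as a tested, reusable pipeline: motion-aware time-series
preprocessing, group mask construction and equal-size parcellation, Fisher-z
connectome construction, cross-validated edge selection and prediction,
permutation inference, and consensus-feature generalization to retest and
external cohorts. A synthetic-data module plants known positive/negative edge
effects so every stage is testable end-to-end without any imaging download.

## Layout

| module | role |
| --- | --- |
| `wmcpm.synth` | synthetic cohorts, retest/external sessions, motion traces, toy volumes |
| `wmcpm.preprocess` | volume discard, FD, 24-parameter nuisance regression, band-pass, scrubbing, QC |
| `wmcpm.maskparc` | probability-map thresholding, group mask, balanced contiguous parcellation, network assignment |
| `wmcpm.connectome` | node time series, Pearson/Fisher-z matrices, canonical edge vectors |
| `wmcpm.cpm` | motion-edge exclusion, p<0.01 edge selection, network strengths, LOOCV / k-fold, consensus features |
| `wmcpm.stats` | permutation test, partial correlation, Steiger's z, explained variance, network edge counts |
| `wmcpm.pipeline` / `wmcpm.cli` | end-to-end orchestration, YAML config, manifests |

Defaults follow the published protocol: discard 7 initial volumes (242 → 235),
FD scrub threshold 0.5 mm with a {−2,−1,0,+1} censoring window, exclusion at
2 mm / 2° / mean FD 0.15 mm / <80% retention, ±2 SD behavioral outliers,
WM probability ≥0.90, group coverage ≥0.80, subcortical removal at 0.25,
band-pass 0.01–0.10 Hz, 128 nodes, selection p < 0.01, 20-fold × 50 repeats,
5000 permutations.

## CLI

```bash
# generate a synthetic study with planted effects
wmcpm synth --n-participants 120 --n-nodes 16 --effect-r 0.4 --seed 1 --out data/

# leave-one-out prediction on the training session
wmcpm cpm loocv --cohort data/time1 --out loocv.json

# consensus-feature model applied to the external cohort
wmcpm cpm external --train data/time1 --test data/external --out external.json

# full internal validation (time1 + retest sessions + k-fold)
wmcpm run-internal --config config.yaml --out runs/demo --seed 1

# statistics helpers
wmcpm stats steiger --r12 0.5 --r13 0.3 --r23 0.2 -n 100
wmcpm stats permutation --cohort data/time1 -B 200 --seed 1
```

`run-internal` / `run-external` read a YAML file mirroring
`wmcpm.config.RunConfig`; every run writes a manifest (config hash, seed,
version) alongside predictions, fold masks, and consensus masks, so results
are reproducible from the manifest alone.

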