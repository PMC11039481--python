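# illusionephys

Stimulus generation and neural/behavioral analysis for experiments in which
an illusory drifting grating is induced by achromatic neon-color-spreading
(NCS) inducers, together with its two control stimuli: a diffusion-blocked
control (DBC) with identical pixel-wise dynamics and a real luminance-defined
grating (LDG) rendered in spatial antiphase to the illusion.

The package covers the full pipeline end to end on synthetic data:

- **`stimgen`** — pixel-exact rendering of the NCS/DBC/LDG stimulus family,
  receptive-field-mapping rectangle sequences, size-tuning patches, and
  pseudo-randomized trial tables.  Rendered frames take only the configured
  black/gray/white levels, the DBC frame-to-frame differences are pixel
  identical to NCS, and the LDG gray bars are 180° out of phase with the NCS
  gray segments by construction.
- **`synthetic`** — a seeded synthetic-session generator (inhomogeneous
  Poisson spiking with von-Mises direction tuning, controllable latencies,
  F1 modulation and response phases; waveforms with a bimodal
  trough-to-peak-latency mixture; laminar LFP with a localized sink;
  rotary-encoder and pupil traces) with the ground truth serialized next to
  the data.
- **`evoked`** — 1 ms PSTHs and the Poisson-baseline deviation detector for
  visually evoked responses and response latencies (three consecutive bins
  at p < 0.01, p < 0.01, p < 0.05), rectangle latencies, and
  equi-responsive-unit selection.
- **`tuning`** — direction/size tuning curves, periodic-spline preferred
  angle, F0/F1 Fourier decomposition, and the scalar indices IGR, IGR_F1,
  CSM, surround modulation, and the NCS delay index.
- **`circstats`** — F1 phase-shift estimation, circular mean with Fisher's
  dispersion-based confidence interval, and the Rayleigh test.
- **`receptive_fields`** — rectangle-response maps, masked rotated 2-D
  Gaussian RF fits, FWHM-ellipse/inducer overlap ratios, RF–inducer
  distances, and retinotopic reversal-point detection.
- **`unitclass`** — trough-to-peak-latency measurement, two-Gaussian
  mixture E/I classification, Butterworth LFP preprocessing, second-spatial-
  derivative CSD, and sink-relative laminar labels.
- **`behavior`** — rotary-encoder disk speed with wrap handling, run/still
  trial classification, pupil-trace normalization and the dilation index.
- **`pipeline`** / **`cli`** — configuration-driven orchestration of
  simulate → analyze → report with tidy CSV/JSON outputs and a markdown +
  figure report.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite: stimulus invariants,
detector calibration against an exact inverse-CDF oracle, parameter recovery
on a 200-unit synthetic cohort (70 trials/condition), oracle-equivalence
checks (Monte-Carlo overlap areas, brute-force spline argmax, mixture
density-intersection root finding, Rayleigh null calibration), and the
optogenetic light-condition scenario.

## CLI

```bash
illusionephys stimgen  --config cfg.json --outdir stimuli     # TIFF stacks + trial table
illusionephys simulate --config cfg.json --outdir bundle      # synthetic recording bundle
illusionephys analyze  --config cfg.json --outdir results     # simulate + analyze, CSV/JSON outputs
illusionephys report   --results results                      # markdown + figures
```

Configs are JSON or YAML; every key has a default (see
`illusionephys.pipeline.default_config`).  Exit codes: 0 ok, 1 input error,
2 internal error.

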