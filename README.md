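# selftouch

An analysis pipeline for force-discrimination studies of **somatosensory
attenuation during reaching to self-touch**, together with a synthetic-study
generator that makes every stage verifiable end to end.

Self-generated touch feels weaker than identical external touch because an
internal forward model predicts, and attenuates, the sensory consequences of
our own movements.  In the paradigm this package analyzes, participants
reach with the right hand toward a force sensor above a finger of the left
hand while brief *test* (2 N) and *comparison* (1–3 N) forces are applied to
that finger; judging "which force felt stronger" across comparison
intensities yields a psychometric function whose **point of subjective
equality (PSE)** measures the perceived test intensity.  Delivering the test
force at different fractions of the movement — and with or without vision of
the hands — maps how attenuation evolves during the reach and how visual
input sharpens the forward model's timing predictions.

## What the package computes

For each participant × session × trial group, responses are fit by maximum
likelihood with the logistic

    p(x) = exp(b0 + b1 x) / (1 + exp(b0 + b1 x)),
    PSE = -b0 / b1,    JND = ln(3) / b1,

gated by McFadden's R² ≥ 0.2.  Upstream of the fits sit the kinematic and
filtering stages: 5-point position smoothing at 240 Hz, movement onset as
the first sample with 3D speed > 5 cm/s sustained 100 ms, offset as the
first target-sensor force sample > 0.2 N, peak velocity within 67% of the
movement, five rejection rules, and rebinning of each trial into
early/mid/late bins — (12.5, 37.5], (37.5, 62.5], (62.5, 87.5]% — from its
realized test-force fraction.  Downstream, baseline-normalized PSEs
(PSE_reaching − PSE_baseline) feed per-participant regressions of ΔPSE on
movement-time fraction, normality-gated paired tests with
Benjamini-Hochberg FDR, Greenhouse-Geisser-corrected repeated-measures
ANOVAs, and (partial) correlations with reach endpoint variability.

The `synthetic_data` side (modules `design`, `observer`, `traces`, `study`,
`population`) simulates the whole experiment: balanced 336-trial schedules,
minimum-jerk reaches with session-dependent endpoint noise, online
test-force scheduling from the last five movement durations, and 2AFC
observers whose PSE drifts linearly with movement-time fraction.

## Worked example

Simulate a small study and fit it, all in memory:

```python
from selftouch.config import PipelineConfig
from selftouch.pipeline import run_pipeline

manifest = run_pipeline(PipelineConfig(n_participants=6, seed=20), "out")
print(manifest.row_counts)
```

```
{'trials': 4032, 'segmentation': 4032, 'kept_trials': 3963,
 'rejected_trials': 69, 'fits': 60, 'participants_excluded': 0}
```

The numbered drivers under `analysis/` run the full 28-participant,
two-session study (per-trial intermediates under `scratch/analysis/`,
summaries under `results/`):

```bash
python analysis/01_simulate_and_segment.py
python analysis/02_filter_trials.py
python analysis/03_fit_psychometrics.py
python analysis/04_temporal_tuning.py
python analysis/05_endpoint_variability.py
```

A run with the default seed prints, among other lines:

```
vision: trial-group ANOVA F(1.45, 31.96) = 8.01, p = 0.0036, partial eta^2 = 0.267
no_vision: trial-group ANOVA F(1.33, 29.37) = 1.68, p = 0.2067, partial eta^2 = 0.071
vision: mean slope -2.690e-03 N/% (paired_t, statistic -3.12, p = 0.0049)
no_vision: mean slope -1.199e-03 N/% (paired_t, statistic -1.28, p = 0.2138)
endpoint variability: vision 0.170 cm, no-vision 0.662 cm
slope ~ variability (no vision, vision partialled out): pearson r = 0.713, p = 0.0002
```

Read: with vision, perceived test intensity drops as the hand approaches
contact (negative slope, significant trial-group effect); without vision the
tuning flattens while overall attenuation persists; endpoint variability is
much larger without vision and, across participants, noisier reaching goes
with flatter temporal tuning — the signature of a forward model starved of
visual input.

There is also a CLI (`selftouch simulate|segment|filter|fit|analyze|report|
run-all`) whose stage subcommands operate on the CSV/JSON artifacts of the
previous stage, so runs can restart from any point.

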