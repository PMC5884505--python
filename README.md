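# ivimkit

Intravoxel incoherent motion (IVIM) model fitting for diffusion-weighted
MRI (DWI), built for test-retest biomarker studies of poorly perfused
tumours such as pancreatic adenocarcinoma. The package provides six voxel-wise
fit algorithms, a synthetic test-retest study generator with known ground
truth, and an evaluation framework that scores each algorithm on parameter
uniqueness, test-retest precision and tumour/normal contrast.

## The model

The IVIM model describes DWI signal decay as a bi-exponential in the
diffusion weighting b (s/mm²):

$$S(b) = S_0\,[\,f\,e^{-b D^*} + (1-f)\,e^{-b D}\,]$$

where *D* is the tissue diffusivity (mm²/s), *D\** the pseudo-diffusion
coefficient of capillary perfusion (mm²/s), and *f* the perfusion fraction.
Fitted signal fractions are converted to blood-volume fractions by undoing
the T1/T2 relaxation weighting of blood versus tissue (see
`docs/methods.md`).

Six fit algorithms share one constraint and result contract:

| name | algorithm |
|---|---|
| `free` | constrained non-linear least squares over (S0, f, D, D\*) |
| `fixed` | least squares with D\* frozen at 70×10⁻³ mm²/s |
| `adaptive` | segmented fit with adaptive high-b threshold selection |
| `mle` | maximum likelihood under Rician magnitude noise |
| `bayes-lin` | per-voxel Bayesian fit, uniform box prior, marginalised noise |
| `bayes-log` | hierarchical Bayesian fit, data-driven Gaussian prior over (logit f, log D, log D\*) |

Evaluation follows quantitative-imaging-biomarker practice: Spearman rank
correlations between fitted parameters (uniqueness), within-subject
coefficient of variation wCV = 100·√(Σ(m₁−m₂)²/2N)/μ across repeated scans
(precision), percentage tumour/normal difference (contrast), with Wilcoxon
signed-rank comparisons against the best algorithm per parameter.

## Worked example

Simulate a 6-patient test-retest study (two sessions, tumour and normal
ROIs, Rician noise at b=0 SNR 20, 5% between-session parameter drift), fit
three algorithms and evaluate:

```python
from ivimkit import PipelineConfig, run_pipeline

config = PipelineConfig.from_dict({
    "phantom": {"n_patients": 6, "n_voxels_tumour": 40, "n_voxels_normal": 24, "seed": 1},
    "algorithms": ["free", "fixed", "bayes-lin"],
})
report = run_pipeline(config, "out/")
print(report.precision_inter.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(report.contrast_table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
```

prints (abridged):

```
algorithm parameter  wcv  best  p_vs_best  n_patients
     free         D 7.01  True        NaN           6
    fixed         D 7.95 False      0.438           6
bayes-lin         D 7.43 False      0.438           6
     free         f 10.5 False      0.688           6
    fixed         f 16.5 False     0.0625           6
bayes-lin         f 7.42  True        NaN           6
     free     Dstar 14.8 False     0.0312           6
bayes-lin     Dstar 3.17  True        NaN           6

algorithm parameter  contrast  best  p_vs_best  n_patients
     free         f      30.4 False      0.156           6
    fixed         f      48.1  True        NaN           6
bayes-lin         f        25 False     0.0312           6
...
```

Reading it: `wcv` is the inter-session within-subject coefficient of
variation in per cent (lower = more repeatable) — here the uniform-prior
Bayesian fit gives the most repeatable perfusion fraction (7.4%) and
pseudo-diffusion (3.2%), while all algorithms determine D with similar,
good precision. `contrast` is the mean percentage tumour/normal difference
(higher = better tumour delineation) — the perfusion fraction carries far
more contrast than D, and the shared-information Bayesian estimate trades
some of that contrast for its precision. `p_vs_best` is the Wilcoxon
signed-rank p-value against the best algorithm of each row group.

The same pipeline is scriptable from the shell:

```sh
ivim simulate -c config.yaml -o data/
ivim fit -c config.yaml -i data/ -o fits/ --algorithms free,fixed,bayes-lin
ivim evaluate -i fits/ -o report/
ivim report -i report/ --plot tradeoff.png
```

`ivim fit` also reads any CSV study with columns
`patient_id/session/acquisition/roi/voxel_id/b_value/signal` (per-direction
rows are averaged), so deposited per-voxel ROI signal tables can be fitted
and evaluated directly.

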