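# fodshift

Cross-age and cross-site domain shift in deep-learning estimation of
white-matter fiber orientation distributions (FODs) from **six diffusion
directions**, studied end to end on synthetic two-site infant dMRI
cohorts.

Dense multi-shell dMRI protocols are impractical for newborns and
babies, so learned estimators reconstruct the FOD — an antipodally
symmetric function on the sphere whose lobes mark fiber bundles — from
as few as six measurements. Such models are vulnerable to domain shift:
a different scanner/protocol, or simply the rapid maturation of infant
white matter, changes the signal distribution between training and test.
This package builds the entire study at desk scale:

- **Synthetic cohorts**: two acquisition sites with different multi-shell
  schemes (b ∈ {0, 400, 1000, 2600} and b ∈ {0, 500, …, 3000} s/mm²),
  1–3 crossing fiber populations per voxel, smooth gain/offset site
  shifts, Rician noise, and an age-dependent white-matter FA trajectory
  `FA(t) = a·arctan(b(t − t0)) + d` (t in postnatal months).
- **Estimator**: selects the six b = 1000 s/mm² directions minimizing
  the condition number of the order-2 SH design, normalizes by the mean
  b = 0 signal, projects to order-2 spherical harmonics, and regresses
  the order-8 FOD coefficients with a compact neural network trained by
  Adam (lr 5·10⁻⁵, weight decay 10⁻³, dropout 0.1, validation-MSE model
  selection); fine-tuning continues at lr 5·10⁻⁶ on 1–10 target
  subjects.
- **Harmonization**: Method of Moments — per-voxel spherical moments
  (mean/variance over the six directions) aligned across sites by
  `f(S) = αS + β` with `α = √(var_ref/var_src)`,
  `β = mean_ref − α·mean_src`.
- **Reference FODs**: single-tissue constrained spherical deconvolution
  with exact non-negativity (active-set least-distance solve), plus the
  split-half gold-standard consistency procedure.
- **Evaluation**: Agreement Rate (% of voxels with the correct peak
  count, per 1/2/3-fiber stratum), Angular Error among optimally matched
  peaks (45° cap), and total apparent-fiber-density error
  (ΔAFD, sphere integral `c₀₀·2√π`).

See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
from fodshift.experiments import ExperimentConfig, run_inter_site

config = ExperimentConfig.site_shift_only(seed=1)   # isolate the scanner shift
report = run_inter_site(config, directions=("a_to_b",))
print(report.to_dataframe()[["arm", "ar_1f", "ae_1f", "afd_error"]])
```

prints the single-fiber agreement rate, angular error and AFD error of
every arm (about ten minutes on one CPU):

```
           arm     ar_1f     ae_1f  afd_error
        self_b 93.797031 16.167887   0.000854
  cross_a_to_b 19.361399 20.612599   0.070338
 mom_a_to_b_n1 90.237950 15.819930   0.000973
  ft_a_to_b_n1 54.830181 19.139734   0.000035
 mom_a_to_b_n2 89.261745 15.755188   0.000959
  ft_a_to_b_n2 87.939801 16.880633   0.000185
 mom_a_to_b_n5 91.295505 15.870997   0.000748
  ft_a_to_b_n5 93.369941 14.749684   0.000065
mom_a_to_b_n10 91.742933 15.892502   0.000719
 ft_a_to_b_n10 92.454749 15.508867   0.000353
 scratch_b_n10 42.342892 25.007612   0.001151
```

Reading it: the model trained on the reference site collapses from 93.8%
to 19.4% single-fiber agreement when tested raw on the shifted site
(`self_b` and `cross_a_to_b` are the upper and lower bounds).
Harmonizing the target signals with moment maps from a single target
subject (`mom_*`) recovers ~95% of that gap; fine-tuning on two or more
target subjects (`ft_*`) recovers ~92–99%, with gains saturating after
two subjects; and a model trained only on the 10 target subjects
(`scratch_b_n10`, 42.3%) stays far below the fine-tuned one (92.5%).
Numbers are from `seed=1` and vary slightly with the seed.

The same library runs the intra-site age-group study
(`run_intra_site`), the gold-standard consistency arm
(`run_gs_consistency`), and the mean-FA-versus-age arctan growth
analysis (`fodshift.dti_masks.fit_arctan_growth`). A thin CLI wraps
these: `fodshift simulate|harmonize|evaluate|gs-consistency|run-experiment`.

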