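# tractatlas

Tractography atlas-based analysis of diffusion-tensor volumes, built to run
entirely on synthetic tensor phantoms: ground-truth deformation simulation,
scalar feature-image registration (FA / hFA / T1), tensor warping with
reorientation, a full tensor-similarity metric suite, deterministic
streamline tractography with arc-length tract parameterization, and
along-tract group statistics (1-D TFCE + permutation family-wise-error
control, ROC/AUC).

## Layout

| module | contents |
|---|---|
| `core_tensor` | tensor volume data model, eigendecomposition, FA, tensor averaging, log-linear tensor fitting |
| `feature_image` | FA, hFA (largest Hessian eigenvalue of FA), and T1 feature images |
| `registration` | affine + B-spline FFD registration, field composition/inversion, groupwise mean deformation |
| `deformation` | sinusoidal ground-truth deformation families, tensor warping with reorientation |
| `similarity` | FA accuracy/precision, OVL, DTED/DVED/AI/COH, corrFA, ROI/histogram summaries, group tests |
| `tractology` | deterministic streamline tracking, ROI-logic bundle selection, arc-length parameterization, native-space sampling |
| `alongtract_stats` | pointwise t-tests, 1-D TFCE, permutation-FWE, tract-averaged tests, ROC/AUC |
| `synthetic_data` | tensor phantom with curved bundles, two-group cohorts with localized FA effects, DWI simulation |
| `pipeline` | end-to-end feature-image benchmark and the full along-tract group analysis |

Conventions: tensors are stored on disk as 4-D NIfTI-1 with 6 components in
lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); deformation fields
are 4-D NIfTI-1 (last axis = 3) holding mm displacements in the pull-back
convention (the value at a target voxel points to its source-space sample
location); streamlines are TCK (TRK readable).

## CLI

All stages are exposed through one entry point:

```sh
tractatlas synth phantom --out phantom/
tractatlas synth cohort --phantom-dir phantom/ --n-per-group 10 --delta 0.1 --seed 1 --out cohort/
tractatlas synth dwi --tensor phantom/tensor.nii.gz --snr 20 --out dwi/
tractatlas feature --kind hFA --tensor phantom/tensor.nii.gz --sigma 2 --out hfa.nii.gz
tractatlas simulate --gt phantom/tensor.nii.gz --n-pairs 10 --seed 1 --out sim/
tractatlas register --moving sub_fa.nii.gz --fixed gt_fa.nii.gz --out warp.nii.gz
tractatlas register --feature FA --subjects cohort/ --out warps/   # groupwise
tractatlas evaluate --gt phantom/tensor.nii.gz --normalized norm/ --atlas atlas.nii.gz --out metrics/
tractatlas track --template template.nii.gz --out whole_brain.tck
tractatlas select --bundle whole_brain.tck --roi AND:wp:waypoint.nii.gz --out bundle.tck
tractatlas parameterize --bundle bundle.tck --k 50 --out curve.csv
tractatlas sample --curve curve.csv --subject s1:warp1.nii.gz:fa1.nii.gz --out samples.csv
tractatlas stats --samples samples.csv --labels labels.csv --n-perm 1000 --seed 1 --out stats/
```

`register` accepts a YAML config (`control_point_spacing`, `levels`,
`iterations`, `bending_weight`) overriding the defaults.

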