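# svfmorph

Longitudinal deformation-based morphometry with stationary velocity fields.

`svfmorph` estimates how a brain (or any 3D structure) deforms over time
from a series of images, expresses every subject's deformation trajectory in
a common anatomical space, and tests where two groups differ. It is aimed at
researchers running longitudinal imaging studies — atrophy in
neurodegeneration being the canonical case — who want the whole chain, from
pairwise registration to corrected group statistics, in one reproducible
package with synthetic ground-truth validation built in.

## The model

Deformations are parameterized by stationary velocity fields (SVFs): a
field `v` encodes the diffeomorphism `φ = exp(v)`, the unit-time flow of
`∂φ/∂s = v(φ)`. The pipeline is:

1. **Registration** — symmetric LCC log-Demons. The SVF `v_ij` aligning two
   time points minimizes a local-correlation similarity evaluated in the
   halfway space (`I_i∘exp(v/2)` vs `I_j∘exp(−v/2)`), weighted voxelwise by
   a confidence mask `ω` built from the two brain masks, alternated with
   Gaussian regularization of the field. `ω` makes the update exactly zero
   outside the brain, so skull remnants and rim artifacts cannot masquerade
   as anatomy.
2. **Trajectory** — all pairwise SVFs of a subject enter the closed-form
   linear-in-time fit through the origin,
   `v̂ = Σ (t_j−t_i) v_ij / Σ (t_j−t_i)²`, so `exp(t·v̂)` models the subject
   after `t` years.
3. **Template** — an unbiased study template by iterative averaging of
   intensities and velocity fields, one resampling per subject and
   iteration.
4. **Transport** — each `v̂` is carried into template space with the pole
   ladder along the subject-to-template SVF, in rungs of at most half a
   voxel, using Lie brackets (`[v,w] = Dv·w − Dw·v`).
5. **Statistics** — voxelwise two-sample t-tests on log-Jacobian maps
   (volume change) and Hotelling's T² on the velocity fields themselves,
   with family-wise error controlled by permutation maxT.

A synthetic-cohort generator with exact ground-truth fields (ventricle
expansion, hippocampal contraction, bias/noise/rim corruption, 2–5 visits
over 0.5–6.9 years) makes every stage testable without any data download.
Details and numerical choices: [docs/methods.md](docs/methods.md).

## Worked example

Register two time points of a phantom that carries a bright rim artifact
outside the brain, with and without the confidence mask, and compare the
spurious volume change in the rim shell:

```python
from svfmorph.validation import mask_robustness_metrics

m = mask_robustness_metrics(n=64, seed=3)
for k, v in m.items():
    print(f"{k:32s} {v:.4f}")
```

```
masked_rim_mean_abs_logjac       0.0040
masked_inmask_rmse_vox           0.0451
unmasked_rim_mean_abs_logjac     0.3339
unmasked_inmask_rmse_vox         1.5245
rim_logjac_ratio_pct             1.1947
```

Read: without the mask, the registration hallucinates |log-Jacobian| ≈ 0.33
of volume change in the artifact shell (≈ 40% apparent expansion) and its
in-mask field is off by 1.5 voxels RMS; with the confidence mask the shell
is quiet (1.2% of the unmasked level) and the true deformation is recovered
to 0.05 voxels. This is the measurable version of the boundary-artifact
problem the masked similarity exists to solve.

The same stages are scriptable from the shell:

```sh
svfmorph simulate --n-per-group 4 --seed 1 --out cohort/
svfmorph register --fixed f.nii.gz --moving m.nii.gz \
    --fixed-mask fm.nii.gz --moving-mask mm.nii.gz --out v.nii.gz
svfmorph trajectory --series series.yaml --out vhat.nii.gz
svfmorph template --images list.txt --out template.nii.gz
svfmorph transport --vhat vhat.nii.gz --w0 w0.nii.gz --out vhatT.nii.gz
svfmorph stats hotelling --inputs manifest.csv --mask mask.nii.gz \
    --perms 5000 --seed 0 --out stats/
svfmorph run --config study.yaml     # the whole pipeline, resumable
```

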