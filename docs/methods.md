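# Methods

This note documents the models, numerical choices and limitations of
`svfmorph`. It is the place to look when a default needs justifying or a
test needs interpreting.

## Deformation model

Deformations are diffeomorphisms parameterized by stationary velocity
fields (SVFs): a field `v` on the image grid encodes the transformation
`phi = exp(v)`, the unit-time flow of `dphi/ds = v(phi(s))`. This gives a
vector-space parameterization of a group of invertible, topology-preserving
maps: `exp(-v)` is the inverse, `exp(t v)` a geodesic-like path in time, and
fields can be averaged, regressed and transported as vectors while the
resulting deformations stay diffeomorphic.

All fields are stored in voxel units on isotropic grids; millimetres appear
only at the NIfTI boundary. Out-of-domain samples evaluate to 0, matching
the modelling assumption that velocities vanish far from the head; the
consequence is that any quantity derived from voxels whose flow leaves the
grid is unreliable, so Jacobian-based error checks exclude a margin of the
maximum displacement and statistics maps should not be read at the grid
boundary.

### Integration

`exponentiate` integrates the flow with forward Euler, with the step count
chosen so no single step exceeds 0.5 voxel, or with scaling-and-squaring
(`v/2^K` then `K` self-compositions). The two schemes agree to discretization
error and serve as mutual cross-checks; both converge to the matrix-
exponential closed form on linear fields (error < 1e-3 voxel at the step
counts used in the validation suite). The log-Jacobian map is the log
determinant of the centered-difference Jacobian of `x + d(x)`; interior
non-positive determinants are reported as non-diffeomorphic (or marked NaN
on request).

### Lie bracket

The bracket convention is `[v, w] = Dv.w - Dw.v` with full 3x3
centered-difference Jacobians (exposed as `BRACKET_CONVENTION`). On linear
fields it reproduces the matrix commutator; transporting a field along a
constant translation `c` with the pole ladder shifts its profile by `-c`
per unit of `c`, which is the oracle that pins the sign.

## Registration

The LCC log-Demons estimates `v` with `moving o exp(v) ~ fixed` by
alternating, over a coarse-to-fine pyramid:

1. both images and both brain masks are resampled into the halfway space
   (`exp(+v/2)` for the moving side, `exp(-v/2)` for the fixed side), which
   keeps the formulation symmetric — swapping the roles of the images
   negates the result to machine precision;
2. the confidence mask `omega` is the average of the two resampled masks,
   clipped to [0, 1];
3. a closed-form update is computed from the gradient of the squared local
   correlation coefficient (LCC), weighted by `omega`:
   `delta_v = -2 Lambda / (|Lambda|^2 + (1/omega) 4 rho^2 sigma_i^2 / sigma_x^2)`,
   zero where `omega = 0` and zero where the local correlation is
   degenerate (windowed energies below guard — constant tiles, empty
   background);
4. the update is clamped (`max_step`, stated in full-resolution voxels),
   optionally fluid-smoothed, composed in the log domain at zeroth
   BCH order (`v <- v + delta_v`), and the result is Gaussian-smoothed
   (`reg_sigma`) — the explicit minimizer of the harmonic regularization
   energy.

### Confidence weighting of the local statistics

The similarity energy weights voxels by `omega`, so structures outside the
brain must not drive the update. Two numerical consequences are enforced
beyond the update formula itself:

* window integrals are confidence-weighted, `G_w(z) = G(omega z)/G(omega)`,
  so out-of-mask intensities do not enter the local statistics of in-mask
  voxels through window overlap (with plain windows the coarsest pyramid
  level's windows span the whole brain, and rim artifacts measurably bias
  in-mask fields);
* each image is continued beyond its own mask with its local in-mask mean
  before resampling and gradient computation. Unlike zero-filling
  (skull-stripping), this creates no artificial boundary gradient; unlike
  using the raw head image, it makes the recovered field provably
  independent of anything outside the masks.

With these choices, adding random intensities strictly outside both masks
changes the recovered in-mask field by ~5e-3 voxel RMS, and a bright rim
artifact outside the mask leaves ~1% of the spurious volume change that an
unmasked registration shows in the rim shell.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `lcc_sigma` | 3.0 grid units | LCC window sigma (reference `-C 3`) |
| `reg_sigma` | 2.0 | field regularization sigma (`-b 2.0`) |
| `fluid_sigma` | 0.15 | update pre-smoothing (`-S 0.15`, interpreted) |
| `max_step` | 3.0 voxels | update clamp (`-u 3.0`, interpreted) |
| `iterations` | 30/20/10 | per level, coarsest first (`-a 30x20x10`) |
| `sigma_i`, `sigma_x` | 1.0, 10.0 | noise / matching-uncertainty weights |
| `lcc_center` | off | classic local-mean-centered LCC variant |

`sigma_x/sigma_i` bounds the size of a single unclamped update
(≈ `sigma_x / 2rho` voxels at full confidence); 10 was chosen on phantom
recovery experiments as the largest stable value — beyond ~12 the iteration
oscillates. The uncentered (product-form) LCC is the default; the centered
variant is available but was not more accurate on bias-field phantoms.
The pyramid is capped so the coarsest level keeps at least 16 voxels per
axis; at the 64-cubed default scale the full 3 levels run.

Registration is deterministic: no randomness anywhere in the estimation.

## Longitudinal trajectory

For a subject observed at times `t_0 < ... < t_{N-1}`, every ordered pair is
registered (`N(N-1)/2` fields `v_ij`) and the annualized trajectory is the
closed-form least-squares fit of a linear-in-time model through the origin:

    v_hat = sum dt_ij v_ij / sum dt_ij^2 .

The pairwise antisymmetry `v_ji = -v_ij` of the symmetric registration is
already consumed by the closed form. Only the linear model is implemented;
with 2-5 time points per subject higher orders are not identifiable in any
useful way. A consequence worth remembering when reading group results: the
variance of `v_hat` scales as `1/sum dt^2`, so subjects with short follow-up
contribute noisy trajectories, and with small cohorts a single 0.5-year
subject visibly inflates group variance. Precision weighting of subjects is
deliberately left out of the fit (it belongs to the group-analysis layer).

## Template

The unbiased template iterates: register every baseline to the current
template; subtract the cohort-mean field from each subject's field in the
log domain (zeroth-order BCH, which is what keeps one resampling per subject
per iteration); resample; average intensities. Stopping: `max_iter`
(default 7) or when the mean squared intensity change falls below 1e-4 of
the intensity range and the RMS change of the mean field below 1e-2 voxel
(the construction has no published thresholds; these are package choices).
The construction is insensitive to the reference image: two templates of the
same phantom cohort started from different references differ by < 0.01% of
the dynamic range. The template brain mask is the voxel-mean of warped
subject masks thresholded at 0.5.

## Parallel transport

The pole ladder transports the subject trajectory SVF along the
subject-to-template field in `n` rungs, `n` chosen so each rung of `w0/n`
stays below 0.5 voxel; each rung applies
`v <- v + [u, v] + [u, [u, v]]/2` with `u = w0/n` held fixed. This is the
second-order expansion of the adjoint action of `exp(u)`.

Direction matters and is easy to get wrong: with `w0` estimated by
registering the subject baseline *to* the template (`A ~ I0 o exp(w0)`), a
structure at template coordinate `x` lies at subject coordinate
`exp(w0)(x)`, and expressing the subject's field in template anatomy is the
adjoint of `exp(-w0)`. `pole_ladder(v, w)` itself is the raw ladder
(transport along `+w`); `transport_cohort` feeds it `-w0` so that cohort
fields land in template space. The flat-space oracle (translation `c`:
raw ladder output is `v(x - c)`; a cohort of shifted subjects averages back
to the template-space truth) pins both conventions and is part of the test
suite.

## Group statistics

Two tests operate on the transported, annualized (`t = 1`) fields over a
binary analysis mask:

* two-sample pooled-variance t on log-Jacobian maps (volumetric change);
* Hotelling's T2 on the 3-vector fields,
  `T2 = (n1 n2/(n1+n2)) d' S^-1 d` with the pooled 3x3 covariance
  (ridge `1e-8 trace/3` only where numerically singular).

Family-wise error is controlled by permutation maxT: group labels are
permuted (distinct relabelings, observed labeling included, exhaustive
enumeration when fewer exist than requested), the maximum |statistic| over
the mask recorded, and the `1-alpha` empirical quantile used as the
threshold. Everything is deterministic given a seed. Defaults: 5000
permutations for T2, 1000 for t. On simulated null cohorts the empirical
FWE at alpha = 0.05 lands within [0.03, 0.07] (200 studies x 200
permutations), and a planted cubic effect is recovered with high Dice.

## Synthetic phantoms

The generator emulates the statistical structure of a longitudinal brain
MRI study, not its appearance: an ellipsoidal "brain" with a smooth random
tissue texture, a dark central "ventricle", two "hippocampus" blobs; a known
annual SVF (radial ventricle expansion with central divergence
`log(1+rate)`, hippocampal contraction at half the rate); per subject 2-5
time points over 0.5-6.9 years of follow-up; per-acquisition smooth
multiplicative bias (amplitude 0.1, scale 12 voxels), additive Gaussian
noise (sd 0.02 on unit-intensity tissue), and a bright patchy rim strictly
outside the brain mask that changes between acquisitions (the boundary
artifact the confidence mask is designed for); a small residual rigid
jitter per subject (0.5 voxel, 0.01 rad). Follow-up images are the baseline
resampled through `exp(t u)`, so registration, trajectory fitting and
transport all have exact ground truth. One seed fans out to per-subject
substreams, so cohorts are bit-reproducible and stable under subsetting.

What the phantoms do *not* model: MR acquisition physics (Rician noise,
partial volume), cortical folding geometry, skull/neck anatomy,
registration-breaking pathology. Passing the validation suite therefore
shows the estimation chain is correct and well-calibrated under its own
assumptions, not that it meets any clinical accuracy bar.

## Validation problem sizes

Single-registration experiments run at the default 64-cubed scale. The
two-group study (10 + 10 subjects, annual ventricle rates 2% vs 0.5%) runs
at 32 cubed; the null-specificity repeats (30 miniature studies with equal
rates, registration in the loop) at 16 cubed with 4 + 4 subjects, since
specificity of the permutation test rests on exchangeability rather than
scale. The FWE calibration uses 200 simulated studies at 32 cubed with 200
permutations each. At these sizes the 2%-vs-0.5% contrast at n = 10 + 10 is
underpowered under the default corruption model (the maximum t falls short
of the maxT threshold): the per-acquisition bias field and the noise
amplification from short-follow-up subjects dominate the between-subject
variance — a useful reminder that this class of analysis needs resolution,
sample size, or precision weighting of unbalanced follow-ups.

## Known limitations

* Gaussian-convolution regularization underestimates field amplitude (the
  classic elastic-like demons bias); recovered fields have slope ~0.8-0.9
  against ground truth at the default scale. Statistics on group contrasts
  are affected equally in both groups.
* Anisotropic voxels are rejected rather than handled.
* No covariate adjustment (age, sex) in the statistics; labels only.
* The linear-in-time trajectory ignores acceleration; with 2-3 time points
  this is the only identifiable choice, but the fitted annual field is an
  average rate, not a local one.
* The unbalanced-precision problem (subjects with very different follow-up
  spans) is surfaced but not corrected.
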