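"""Symmetric LCC log-Demons registration with a confidence-masked similarity.

The registration estimates a stationary velocity field ``v`` such that
``moving o exp(v) ~ fixed``.  It alternates two steps in the log domain:

1. *Similarity*: both images are resampled into the halfway space,
   ``moving o exp(v/2)`` and ``fixed o exp(-v/2)``, and a closed-form update
   ``delta_v`` is computed from the gradient of the squared local correlation
   coefficient (LCC).  The update is weighted by a confidence mask
   ``omega`` built by averaging the two brain masks resampled into the same
   halfway space, so voxels outside the brain (skull, meninges, rim
   artifacts) contribute nothing: where ``omega = 0`` the update is exactly
   zero.
2. *Regularization*: the correspondence field ``v + delta_v`` is smoothed
   with a Gaussian kernel (the closed-form minimizer of the harmonic
   regularization energy).

The scheme runs over a multi-resolution pyramid, coarse to fine.  It is
fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .algebra import exponentiate
from .image import (
    ConfidenceMask,
    ScalarImage,
    Svf,
    build_pyramid,
    gaussian_smooth,
    resample,
    upsample_vector_field,
)

__all__ = [
    "RegistrationParams", "SimilarityMap", "UpdateField", "lcc",
    "build_confidence_mask", "similarity_update", "register",
    "register_symmetric_check",
]

log = logging.getLogger(__name__)

_DENOM_GUARD = 1e-6
_STEP_GUARD = 1e-12


@dataclass
class RegistrationParams:
    """Tunable parameters of the LCC log-Demons.

    Defaults follow the reference configuration for 1 mm brain images:
    a 3-level pyramid with 30/20/10 iterations (coarse to fine), LCC kernel
    sigma 3, regularization sigma 2.0, fluid pre-smoothing 0.15 and a
    3-voxel cap on any single update step.

    Attributes
    ----------
    sigma_i
        Image-noise weight of the similarity term.
    sigma_x
        Matching-uncertainty weight; the ratio ``sigma_x / sigma_i`` bounds
        the magnitude of a single update step (in voxels, at full local
        correlation).
    sigma_T
        Regularization weight of the energy; the explicit Gaussian solver
        exposes its effect through ``reg_sigma`` directly.
    lcc_sigma
        Gaussian kernel sigma (grid units) of the local correlation windows.
    reg_sigma
        Sigma of the regularizing convolution applied to the field.
    fluid_sigma
        Sigma of the fluid-like smoothing of the update before composition.
    max_step
        Clamp on the voxel norm of a single update.
    iterations
        Per-level iteration counts, coarsest first; its length sets the
        pyramid depth.
    lcc_center
        If True, subtract Gaussian local means before forming the LCC
        products (the classic local-correlation variant); the default uses
        raw smoothed products.
    """

    sigma_i: float = 1.0
    sigma_x: float = 10.0
    sigma_T: float = 1.0
    lcc_sigma: float = 3.0
    reg_sigma: float = 2.0
    fluid_sigma: float = 0.15
    max_step: float = 3.0
    iterations: tuple[int, ...] = (30, 20, 10)
    lcc_center: bool = False

    def __post_init__(self) -> None:
        for name in ("sigma_i", "sigma_x", "sigma_T", "lcc_sigma",
                     "reg_sigma", "fluid_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.iterations = tuple(int(i) for i in self.iterations)
        if len(self.iterations) == 0:
            raise ValueError("iterations must be non-empty")

    @property
    def levels(self) -> int:
        return len(self.iterations)


@dataclass
class SimilarityMap:
    """Voxelwise local correlation rho and its domain aggregate."""

    rho: np.ndarray
    aggregate: float


@dataclass
class UpdateField:
    """Closed-form similarity update delta_v and its driving term Lambda."""

    delta_v: Svf
    lambda_term: np.ndarray
    rho: np.ndarray | None = None


def _smooth(x: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(x, sigma, mode="reflect", truncate=3.0)


def lcc(fixed: ScalarImage, moving: ScalarImage, lcc_sigma: float,
        center: bool = False) -> SimilarityMap:
    """Local correlation coefficient map between two images.

    rho(x) = G(I_f I_m) / sqrt(G(I_f^2) G(I_m^2)) with Gaussian windows of
    sigma ``lcc_sigma``; voxels where either windowed energy falls below a
    small guard get rho = 0.  With ``center=True`` the Gaussian local means
    are subtracted first, giving the classic correlation-coefficient form.
    """
    if not fixed.same_grid(moving):
        raise ValueError(f"geometry mismatch: {fixed.shape} vs {moving.shape}")
    if lcc_sigma <= 0:
        raise ValueError("lcc_sigma must be > 0")
    f, m = fixed.data, moving.data
    if center:
        f = f - _smooth(f, lcc_sigma)
        m = m - _smooth(m, lcc_sigma)
    sfm = _smooth(f * m, lcc_sigma)
    sff = _smooth(f * f, lcc_sigma)
    smm = _smooth(m * m, lcc_sigma)
    ok = (sff > _DENOM_GUARD) & (smm > _DENOM_GUARD)
    rho = np.zeros_like(sfm)
    rho[ok] = sfm[ok] / np.sqrt(sff[ok] * smm[ok])
    return SimilarityMap(rho=rho, aggregate=float(rho.mean()))


def build_confidence_mask(M: ConfidenceMask, F: ConfidenceMask, vc: Svf
                          ) -> ConfidenceMask:
    """Symmetric halfway-space confidence mask.

    omega = (M o exp(vc/2) + F o exp(-vc/2)) / 2, linear interpolation,
    clipped to [0, 1].  ``M`` is the moving-image mask, ``F`` the fixed one.
    """
    if not (M.same_grid(F) and M.same_grid(vc)):
        raise ValueError("geometry mismatch between masks and field")
    half = Svf(vc.data / 2.0, spacing=vc.spacing)
    fwd = exponentiate(half)
    bwd = exponentiate(Svf(-half.data, spacing=vc.spacing))
    m_img = ScalarImage(M.values, spacing=M.spacing)
    f_img = ScalarImage(F.values, spacing=F.spacing)
    m_half = resample(m_img, fwd, "linear").data
    f_half = resample(f_img, bwd, "linear").data
    omega = np.clip(0.5 * (m_half + f_half), 0.0, 1.0)
    return ConfidenceMask(omega, spacing=M.spacing)


def _lambda_and_rho(fixed_h: np.ndarray, moving_h: np.ndarray, sigma: float,
                    center: bool, omega: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the LCC gradient vector Lambda and rho in the halfway space.

    Lambda = G(Im grad If)/G(Im If) - G(If grad Im)/G(Im If)
           + G(Im grad Im)/G(Im^2) - G(If grad If)/G(If^2)
    with Im the halfway moving image (the one advanced by +delta_v/2) and If
    the halfway fixed image.  Gradients by centered differences computed
    after resampling.  The smoothed products are shared with the rho map.

    When ``omega`` is given, the window integrals are confidence-weighted,
    G_w(z) = G(omega z) / G(omega): voxels outside the confidence support
    then contribute nothing to the local statistics of in-mask voxels, so
    intensity artifacts outside the brain cannot steer the in-mask update
    through window overlap.  (The weight normalization cancels in every
    ratio of Lambda, so only the numerator/denominator products change.)
    """
    Im, If = moving_h, fixed_h
    if omega is not None:
        omega = omega.astype(Im.dtype, copy=False)
        w_norm = _smooth(omega, sigma)
        w_ok = w_norm > _DENOM_GUARD

        def _wavg(z):
            out = _smooth(omega * z, sigma)
            out[w_ok] /= w_norm[w_ok]
            out[~w_ok] = 0.0
            return out
    else:
        def _wavg(z):
            return _smooth(z, sigma)
    if center:
        Im = Im - _wavg(Im)
        If = If - _wavg(If)
    if omega is not None:
        # Gradients at in-mask voxels must not read raw outside intensities:
        # continue each image beyond the confidence support with its local
        # confidence-weighted mean (a function of in-mask data only).
        s = omega > 0
        Im_g = np.where(s, Im, _wavg(Im))
        If_g = np.where(s, If, _wavg(If))
    else:
        Im_g, If_g = Im, If
    gIm = np.stack(np.gradient(Im_g, axis=(0, 1, 2)), axis=-1)
    gIf = np.stack(np.gradient(If_g, axis=(0, 1, 2)), axis=-1)
    s_mf = _wavg(Im * If)
    s_mm = _wavg(Im * Im)
    s_ff = _wavg(If * If)
    ok_mf = np.abs(s_mf) > _DENOM_GUARD
    ok_mm = s_mm > _DENOM_GUARD
    ok_ff = s_ff > _DENOM_GUARD
    lam = np.zeros(Im.shape + (3,), dtype=Im.dtype)
    for c in range(3):
        t1 = _wavg(Im * gIf[..., c])
        t2 = _wavg(If * gIm[..., c])
        t3 = _wavg(Im * gIm[..., c])
        t4 = _wavg(If * gIf[..., c])
        comp = np.zeros_like(t1)
        comp[ok_mf] += (t1[ok_mf] - t2[ok_mf]) / s_mf[ok_mf]
        comp[ok_mm] += t3[ok_mm] / s_mm[ok_mm]
        comp[ok_ff] -= t4[ok_ff] / s_ff[ok_ff]
        lam[..., c] = comp
    rho = np.zeros_like(s_mf)
    ok = ok_mm & ok_ff
    rho[ok] = s_mf[ok] / np.sqrt(s_mm[ok] * s_ff[ok])
    return lam, rho


def similarity_update(fixed_h: ScalarImage, moving_h: ScalarImage,
                      omega: ConfidenceMask, params: RegistrationParams
                      ) -> UpdateField:
    """Closed-form minimizer of the masked similarity energy.

    Both images must already live in the halfway space.  The update is

        delta_v = -2 Lambda / (|Lambda|^2 + (1/omega) 4 rho^2 sigma_i^2 / sigma_x^2)

    wherever ``omega > 0`` and exactly zero elsewhere.  Voxels with a
    degenerate local correlation (rho = 0 because a windowed energy fell
    below the guard, e.g. constant-intensity tiles) receive a zero update:
    without the rho-dependent penalty the quotient is unbounded there.
    """
    if not (fixed_h.same_grid(moving_h) and fixed_h.same_grid(omega)):
        raise ValueError("geometry mismatch")
    w = omega.values
    lam, rho = _lambda_and_rho(fixed_h.data, moving_h.data, params.lcc_sigma,
                               params.lcc_center,
                               omega=None if np.all(w == 1.0) else w)
    lam2 = (lam ** 2).sum(axis=-1)
    delta = np.zeros_like(lam)
    pos = w > 0
    penalty = np.zeros_like(lam2)
    penalty[pos] = (4.0 * rho[pos] ** 2 * params.sigma_i ** 2
                    / max(params.sigma_x ** 2, _STEP_GUARD)) / w[pos]
    denom = lam2 + penalty
    ok = pos & (denom > _STEP_GUARD) & (rho != 0)
    delta[ok] = -2.0 * lam[ok] / denom[ok][..., None]
    return UpdateField(
        delta_v=Svf(delta, spacing=fixed_h.spacing),
        lambda_term=lam,
        rho=rho,
    )


def _clamp_norm(data: np.ndarray, max_step: float) -> np.ndarray:
    norms = np.sqrt((data ** 2).sum(axis=-1))
    factor = np.ones_like(norms)
    over = norms > max_step
    factor[over] = max_step / norms[over]
    return data * factor[..., None]


def _fill_outside(image: ScalarImage, mask: ConfidenceMask,
                  sigma: float) -> ScalarImage:
    """Continue the image beyond the mask with its local in-mask mean.

    The masked registration energy gives outside voxels zero weight; this
    additionally guarantees that outside intensities (skull, rim artifacts)
    never reach the similarity statistics at all, neither through window
    overlap nor through halfway-space resampling, while avoiding the sharp
    artificial edge that zero-filling (skull-stripping) would create.
    """
    s = (mask.values > 0.5).astype(image.data.dtype)
    num = _smooth(s * image.data, sigma)
    den = _smooth(s, sigma)
    fill = np.zeros_like(num)
    ok = den > _DENOM_GUARD
    fill[ok] = num[ok] / den[ok]
    return image.with_data(np.where(s > 0, image.data, fill))


def _mask_pyramid(mask: ConfidenceMask, levels: int) -> list[ConfidenceMask]:
    imgs = build_pyramid(ScalarImage(mask.values, spacing=mask.spacing), levels)
    return [ConfidenceMask(np.clip(im.data, 0.0, 1.0), spacing=im.spacing)
            for im in imgs]


def register(fixed: ScalarImage, moving: ScalarImage,
             fixed_mask: ConfidenceMask | None = None,
             moving_mask: ConfidenceMask | None = None,
             params: RegistrationParams | None = None,
             init_v: Svf | None = None,
             history: list | None = None) -> Svf:
    """Estimate the SVF ``v`` with ``moving o exp(v) ~ fixed``.

    Runs the alternate similarity/regularization minimization over a
    multi-resolution pyramid.  ``fixed_mask``/``moving_mask`` drive the
    confidence weighting; passing ``None`` for both disables masking
    (omega = 1 everywhere).  ``init_v`` initializes the field at full
    resolution.  ``history``, if given, collects per-iteration records of
    ``(level, iteration, aggregate_lcc)``.
    """
    params = params or RegistrationParams()
    if not fixed.same_grid(moving):
        raise ValueError("fixed and moving images must share one grid")
    if (fixed_mask is None) != (moving_mask is None):
        raise ValueError("provide both masks or neither")
    masked = fixed_mask is not None
    if masked and (fixed_mask.values.max() == 0 or moving_mask.values.max() == 0):
        raise ValueError("mask entirely zero: nothing to drive the similarity")

    # cap the pyramid so the coarsest grid keeps >= 16 voxels per axis:
    # below that the brain fills the whole grid and halfway resampling
    # drags in out-of-domain zeros
    max_levels = max(1, int(np.log2(max(min(fixed.shape) // 16, 1))) + 1)
    levels = min(params.levels, max_levels)
    iterations = params.iterations[params.levels - levels:]
    # single precision inside the iteration loop (the update is a smoothed
    # quotient of order-1 quantities; well within float32 resolution)
    fpyr = [im.with_data(im.data.astype(np.float32))
            for im in build_pyramid(fixed, levels)]
    mpyr = [im.with_data(im.data.astype(np.float32))
            for im in build_pyramid(moving, levels)]
    if masked:
        fm_pyr = _mask_pyramid(fixed_mask, levels)
        mm_pyr = _mask_pyramid(moving_mask, levels)

    v: Svf | None = None
    if init_v is not None:
        from .image import downsample_vector_field
        v = downsample_vector_field(init_v, levels - 1)

    for lvl in range(levels - 1, -1, -1):  # coarse to fine
        f_l, m_l = fpyr[lvl], mpyr[lvl]
        if masked:
            f_l = _fill_outside(f_l, fm_pyr[lvl], params.lcc_sigma)
            m_l = _fill_outside(m_l, mm_pyr[lvl], params.lcc_sigma)
        if v is None:
            v = Svf(np.zeros(f_l.shape + (3,), dtype=np.float32),
                    spacing=f_l.spacing)
        elif v.shape != f_l.shape:
            v = upsample_vector_field(v, f_l.shape, spacing=f_l.spacing)
        if masked:
            mm_img = ScalarImage(mm_pyr[lvl].values.astype(np.float32),
                                 spacing=f_l.spacing)
            fm_img = ScalarImage(fm_pyr[lvl].values.astype(np.float32),
                                 spacing=f_l.spacing)
        n_iter = iterations[levels - 1 - lvl]  # tuple is coarsest-first
        for it in range(n_iter):
            half_f = exponentiate(Svf(v.data / 2.0, spacing=v.spacing))
            half_b = exponentiate(Svf(-v.data / 2.0, spacing=v.spacing))
            moving_h = resample(m_l, half_f, "linear")
            fixed_h = resample(f_l, half_b, "linear")
            if masked:
                m_half = resample(mm_img, half_f, "linear").data
                f_half = resample(fm_img, half_b, "linear").data
                omega = ConfidenceMask(np.clip(0.5 * (m_half + f_half), 0, 1),
                                       spacing=f_l.spacing)
            else:
                omega = ConfidenceMask(np.ones(f_l.shape), spacing=f_l.spacing)
            upd = similarity_update(fixed_h, moving_h, omega, params)
            # max_step is stated in full-resolution voxels
            delta = _clamp_norm(upd.delta_v.data, params.max_step / 2 ** lvl)
            if params.fluid_sigma > 0:
                delta = gaussian_smooth(delta, params.fluid_sigma)
            if not np.all(np.isfinite(delta)):
                raise FloatingPointError(
                    f"non-finite update at level {lvl} iteration {it}")
            vc = (v.data + delta).astype(np.float32)  # zeroth-order BCH
            v = Svf(gaussian_smooth(vc, params.reg_sigma), spacing=f_l.spacing)
            if history is not None:
                # confidence-weighted aggregate of the similarity the
                # update actually optimizes
                wsum = omega.values.sum()
                weighted = (float((upd.rho * omega.values).sum() / wsum)
                            if wsum > 0 else float(upd.rho.mean()))
                history.append((lvl, it, weighted))
    assert v is not None
    return Svf(v.data.astype(np.float64), spacing=v.spacing,
               affine=fixed.affine.copy())


def register_symmetric_check(fixed: ScalarImage, moving: ScalarImage,
                             fixed_mask: ConfidenceMask | None = None,
                             moving_mask: ConfidenceMask | None = None,
                             params: RegistrationParams | None = None) -> dict:
    """Forward/backward inverse-consistency report.

    Registers A to B and B to A and summarizes the interior magnitude of
    ``v_ab + v_ba`` (which vanishes for a perfectly symmetric scheme).
    """
    v_ab = register(fixed, moving, fixed_mask, moving_mask, params)
    v_ba = register(moving, fixed, moving_mask, fixed_mask, params)
    res = v_ab.data + v_ba.data
    norms = np.sqrt((res ** 2).sum(axis=-1))
    core = norms[2:-2, 2:-2, 2:-2]
    return {
        "mean_residual": float(core.mean()),
        "max_residual": float(core.max()),
        "v_ab": v_ab,
        "v_ba": v_ba,
    }
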