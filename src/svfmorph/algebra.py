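"""Lie-algebra numerics on stationary velocity fields.

A stationary velocity field (SVF) ``v`` encodes a diffeomorphism through the
flow of dphi/ds = v(phi), phi(x, 0) = x, evaluated at s = 1:
phi = exp(v).  The group exponential is integrated either by Euler forward
stepping (the default, with the step count chosen so that no single step
moves more than half a voxel) or by scaling and squaring, which serves as an
independent cross-check of the integrator.

The Lie bracket convention used throughout is

    [v, w](x) = Dv(x) w(x) - Dw(x) v(x)

with ``Dv`` the full 3x3 Jacobian of ``v`` by centered differences
(one-sided at the boundary).  Under this sign, transporting a field along a
constant translation c with the pole ladder shifts it by -c per unit step,
i.e. exp(w0) carries the field from subject to template space.
"""

from __future__ import annotations

import numpy as np

from .image import DeformationField, Svf, warp_vector_field

__all__ = [
    "BRACKET_CONVENTION", "exponentiate", "log_jacobian", "lie_bracket",
    "bch_compose", "compose_displacements", "jacobian_matrix",
]

#: Documented sign convention: [v, w] = (Dv) w - (Dw) v.
BRACKET_CONVENTION = "[v,w] = Dv.w - Dw.v"

_MAX_STEP_VOXELS = 0.5


def _auto_steps(max_norm: float) -> int:
    return max(1, int(np.ceil(max_norm / _MAX_STEP_VOXELS)))


def exponentiate(v: Svf, scheme: str = "euler", steps: int | None = None) -> DeformationField:
    """Group exponential phi = exp(v) as a displacement field.

    Parameters
    ----------
    v
        Stationary velocity field in voxel units.
    scheme
        ``"euler"``: forward Euler integration of the stationary flow ODE.
        ``"scaling_squaring"``: halve ``v`` until each step is below half a
        voxel, then square the small deformation by repeated
        self-composition.
    steps
        Euler step count, or number of squarings.  Default: chosen so the
        per-step displacement stays below 0.5 voxel.
    """
    if not np.all(np.isfinite(v.data)):
        raise ValueError("velocity field contains non-finite components")
    if scheme == "euler":
        n = steps if steps is not None else _auto_steps(v.max_norm())
        if n < 1:
            raise ValueError("steps must be >= 1")
        disp = np.zeros_like(v.data)
        h = 1.0 / n
        for _ in range(n):
            disp = disp + h * warp_vector_field(v.data, disp)
        return DeformationField(disp, spacing=v.spacing, affine=v.affine.copy())
    if scheme == "scaling_squaring":
        if steps is not None:
            k = steps
        else:
            m = v.max_norm()
            k = max(0, int(np.ceil(np.log2(max(m, 1e-12) / _MAX_STEP_VOXELS))))
        disp = v.data / (2.0 ** k)
        for _ in range(k):
            disp = compose_displacements(disp, disp)
        return DeformationField(disp, spacing=v.spacing, affine=v.affine.copy())
    raise ValueError(f"unknown integration scheme {scheme!r}")


def compose_displacements(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Displacement of phi1 o phi2 where phi_i(x) = x + d_i(x).

    (phi1 o phi2)(x) = phi2(x) + d1(phi2(x)), so the composed displacement
    is d2(x) + d1(x + d2(x)).
    """
    return d2 + warp_vector_field(d1, d2)


def jacobian_matrix(disp: np.ndarray) -> np.ndarray:
    """(..., 3, 3) spatial Jacobian of phi(x) = x + disp(x), centered differences."""
    J = np.empty(disp.shape[:3] + (3, 3), dtype=np.float64)
    for a in range(3):
        grads = np.gradient(disp[..., a], axis=(0, 1, 2))
        for b in range(3):
            J[..., a, b] = grads[b]
        J[..., a, a] += 1.0
    return J


def _det3(J: np.ndarray) -> np.ndarray:
    return (J[..., 0, 0] * (J[..., 1, 1] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 1])
            - J[..., 0, 1] * (J[..., 1, 0] * J[..., 2, 2] - J[..., 1, 2] * J[..., 2, 0])
            + J[..., 0, 2] * (J[..., 1, 0] * J[..., 2, 1] - J[..., 1, 1] * J[..., 2, 0]))


def log_jacobian(v: Svf, scheme: str = "euler", steps: int | None = None,
                 on_nonpositive: str = "raise") -> np.ndarray:
    """Voxelwise log-determinant of the Jacobian of exp(v).

    Positive values mark local expansion, negative values local contraction;
    a zero field yields an all-zero map.  Non-positive determinants at
    interior voxels indicate a non-diffeomorphic deformation.

    Parameters
    ----------
    on_nonpositive
        ``"raise"`` (default) aborts on interior non-positive determinants;
        ``"nan"`` marks the offending voxels instead.
    """
    disp = exponentiate(v, scheme=scheme, steps=steps).data
    det = _det3(jacobian_matrix(disp))
    # Voxels whose flow may have left the domain (where out-of-domain
    # samples are zero by convention) carry no diffeomorphism information:
    # exclude a margin of the maximum displacement from the check.
    margin = 1 + int(np.ceil(np.sqrt((disp ** 2).sum(axis=-1)).max()))
    margin = min(margin, min(det.shape) // 4)
    interior = np.zeros(det.shape, dtype=bool)
    interior[margin:-margin, margin:-margin, margin:-margin] = True
    bad = (det <= 0) & interior
    if np.any(bad):
        if on_nonpositive == "raise":
            raise ValueError(
                f"non-diffeomorphic deformation: {int(bad.sum())} interior "
                "voxels with non-positive Jacobian determinant")
        det = det.copy()
        det[bad] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log(np.maximum(det, 1e-12))
    out[np.isnan(det)] = np.nan
    return out


def _jacobian_of_field(vdata: np.ndarray) -> np.ndarray:
    """(..., 3, 3) Jacobian Dv of a vector field (no identity added)."""
    J = np.empty(vdata.shape[:3] + (3, 3), dtype=np.float64)
    for a in range(3):
        grads = np.gradient(vdata[..., a], axis=(0, 1, 2))
        for b in range(3):
            J[..., a, b] = grads[b]
    return J


def lie_bracket(v: Svf, w: Svf) -> Svf:
    """Lie bracket [v, w] = Dv.w - Dw.v (see ``BRACKET_CONVENTION``).

    Bilinear and antisymmetric; derivatives by centered differences with
    one-sided stencils at the boundary.
    """
    if not v.same_grid(w):
        raise ValueError(f"geometry mismatch: {v.shape} vs {w.shape}")
    Dv = _jacobian_of_field(v.data)
    Dw = _jacobian_of_field(w.data)
    out = np.einsum("...ab,...b->...a", Dv, w.data)
    out -= np.einsum("...ab,...b->...a", Dw, v.data)
    return Svf(out, spacing=v.spacing, affine=v.affine.copy())


def bch_compose(v: Svf, w: Svf, order: int = 0) -> Svf:
    """Baker-Campbell-Hausdorff approximation of log(exp(v) o exp(w)).

    order 0: v + w; order 1 adds [v, w]/2; order 2 adds
    ([v, [v, w]] + [w, [w, v]])/12.
    """
    if not v.same_grid(w):
        raise ValueError(f"geometry mismatch: {v.shape} vs {w.shape}")
    if order not in (0, 1, 2):
        raise ValueError(f"unsupported BCH order {order}")
    out = v.data + w.data
    if order >= 1:
        vw = lie_bracket(v, w)
        out = out + 0.5 * vw.data
    if order == 2:
        term = lie_bracket(v, vw).data + lie_bracket(w, Svf(-vw.data, spacing=w.spacing)).data
        out = out + term / 12.0
    return Svf(out, spacing=v.spacing, affine=v.affine.copy())
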