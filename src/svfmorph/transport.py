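"""Pole-ladder parallel transport of longitudinal SVFs into template space.

The pole ladder moves a (small) longitudinal velocity field along a (large)
inter-subject deformation in ``n`` rungs.  Each rung applies the
second-order approximation of the adjoint action of ``exp(w0/n)``:

    v  <-  v + [u, v] + [u, [u, v]]/2,      u = w0 / n fixed,

with ``n`` chosen so the per-rung displacement stays below half a voxel.
Under the bracket convention ``[v, w] = Dv.w - Dw.v`` this transports a
field along a constant translation ``c`` to ``v(x - c)``: the transported
field follows the flow of ``w0``.

For a cohort, the anatomically meaningful direction is fixed by how the
inter-subject field is estimated.  With ``w0`` the subject-to-template
field (``A ~ I_0 o exp(w0)``), a structure at template position ``x`` sits
at subject position ``exp(w0)(x)``; expressing the subject's trajectory in
template anatomy therefore requires the ladder along ``-w0``, which
``transport_cohort`` applies.
"""

from __future__ import annotations

import numpy as np

from .algebra import lie_bracket
from .image import ConfidenceMask, ScalarImage, Svf
from .registration import RegistrationParams, register

__all__ = ["ladder_steps", "pole_ladder", "transport_cohort", "mean_trajectory"]


def ladder_steps(w0: Svf, voxel_threshold: float = 0.5) -> int:
    """Number of rungs so each ``w0/n`` step is below ``voxel_threshold`` voxels."""
    if not np.all(np.isfinite(w0.data)):
        raise ValueError("w0 contains non-finite components")
    return max(1, int(np.ceil(w0.max_norm() / voxel_threshold)))


def pole_ladder(v_hat: Svf, w0: Svf, voxel_threshold: float = 0.5) -> Svf:
    """Transport ``v_hat`` along ``w0`` with the pole ladder.

    Applies the second-order ladder rung ``n = ladder_steps(w0)`` times with
    the rung field ``u = w0/n`` held fixed.  ``w0 = 0`` returns ``v_hat``
    unchanged and a zero trajectory stays exactly zero.
    """
    if not v_hat.same_grid(w0):
        raise ValueError(f"geometry mismatch: {v_hat.shape} vs {w0.shape}")
    n = ladder_steps(w0, voxel_threshold)
    if not np.any(w0.data):
        return Svf(v_hat.data.copy(), spacing=v_hat.spacing,
                   affine=v_hat.affine.copy())
    u = Svf(w0.data / n, spacing=w0.spacing)
    v = Svf(v_hat.data.copy(), spacing=v_hat.spacing,
            affine=v_hat.affine.copy())
    for k in range(n):
        b1 = lie_bracket(u, v)
        b2 = lie_bracket(u, b1)
        data = v.data + b1.data + 0.5 * b2.data
        if not np.all(np.isfinite(data)):
            raise FloatingPointError(f"non-finite field at ladder step {k + 1}/{n}")
        v = Svf(data, spacing=v.spacing, affine=v.affine)
    return v


def transport_cohort(trajectories: list[Svf],
                     baselines: list[ScalarImage] | None = None,
                     template: ScalarImage | None = None,
                     masks: list[ConfidenceMask] | None = None,
                     params: RegistrationParams | None = None,
                     template_mask: ConfidenceMask | None = None,
                     w0: list[Svf] | None = None) -> list[Svf]:
    """Transport every subject trajectory into template space.

    The subject-to-template fields ``w0_i`` (``A ~ I_0^i o exp(w0_i)``) are
    either supplied (e.g. from the template construction) or computed here
    by registering each baseline to the template.  Each trajectory is then
    carried by the ladder along ``-w0_i`` so that the transported fields
    live in the template anatomy and can be averaged or tested voxelwise.
    """
    n = len(trajectories)
    if w0 is None:
        if baselines is None or template is None:
            raise ValueError("provide w0 or (baselines, template) to compute it")
        if len(baselines) != n:
            raise ValueError("one baseline per trajectory required")
        w0 = []
        for i in range(n):
            m = masks[i] if masks is not None else None
            w0.append(register(template, baselines[i], template_mask, m, params))
    if len(w0) != n:
        raise ValueError(f"missing inter-subject field: {len(w0)} w0 for {n} "
                         "trajectories")
    out = []
    for v_hat, w in zip(trajectories, w0):
        back = Svf(-w.data, spacing=w.spacing, affine=w.affine.copy())
        out.append(pole_ladder(v_hat, back))
    return out


def mean_trajectory(transported: list[Svf]) -> Svf:
    """Cohort-mean transported SVF; exp of it models the average evolution."""
    if not transported:
        raise ValueError("empty cohort")
    ref = transported[0]
    mean = np.mean([v.data for v in transported], axis=0)
    return Svf(mean, spacing=ref.spacing, affine=ref.affine.copy())
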