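"""Unbiased study-specific template by iterative averaging.

Starting from one (roughly centered) subject image, each iteration registers
every subject to the current template, subtracts the cohort-mean velocity
field from each subject's field (so the template drifts to the Karcher-like
center of the population rather than sticking to the reference anatomy),
resamples every subject exactly once with ``exp(v_i - vbar)``, and averages
intensities.  The log-domain subtraction is the zeroth-order
Baker-Campbell-Hausdorff approximation of composing with the inverse mean
deformation, which avoids a second resampling per subject and iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .algebra import exponentiate
from .image import ConfidenceMask, ScalarImage, Svf, resample
from .registration import RegistrationParams, register

__all__ = ["TemplateState", "build_template"]


@dataclass
class TemplateState:
    """Bookkeeping of the iterative template construction."""

    iteration: int = 0
    history: list[dict] = field(default_factory=list)
    resample_count: int = 0  # subject-image resamplings performed in total


def _field_norm(data: np.ndarray) -> float:
    """RMS voxel-norm of a vector field."""
    return float(np.sqrt((data ** 2).sum(axis=-1).mean()))


def build_template(images: list[ScalarImage], masks: list[ConfidenceMask],
                   reference_index: int = 0,
                   params: RegistrationParams | None = None,
                   max_iter: int = 7,
                   eps: tuple[float, float] = (1e-4, 1e-2),
                   ) -> tuple[ScalarImage, list[Svf], TemplateState]:
    """Build an unbiased template and the subject-to-template fields.

    Parameters
    ----------
    images, masks
        Baseline images of the cohort on a common grid, with brain masks.
    reference_index
        Subject used to initialize the template; the construction is
        insensitive to this choice up to a small residual.
    max_iter
        Iteration cap (default 7).
    eps
        ``(intensity_eps, field_eps)`` stopping thresholds: the mean squared
        intensity change as a fraction of the intensity range, and the RMS
        change of the mean field in voxels.

    Returns
    -------
    (A, w0_list, state)
        The template, one subject-to-template SVF per subject
        (``A ~ I_i o exp(w0_i)``), and the iteration history.
    """
    M = len(images)
    if M < 2:
        raise ValueError("template construction needs at least two images")
    if not 0 <= reference_index < M:
        raise ValueError(f"reference_index {reference_index} out of range")
    if len(masks) != M:
        raise ValueError("one mask per image required")
    shape = images[0].shape
    if any(tuple(im.shape) != shape for im in images):
        raise ValueError("all images must share one grid")
    params = params or RegistrationParams()

    A = images[reference_index].with_data(images[reference_index].data.copy())
    tmpl_mask = ConfidenceMask(masks[reference_index].values.copy(),
                               spacing=A.spacing)
    intensity_range = max(float(np.ptp(np.stack([im.data for im in images]))),
                          1e-12)
    state = TemplateState()
    vbar_prev: np.ndarray | None = None
    rising = 0
    prev_change = np.inf

    for k in range(max_iter):
        fields = [register(A, images[i], tmpl_mask, masks[i], params)
                  for i in range(M)]
        vbar = np.mean([v.data for v in fields], axis=0)
        warped_imgs, warped_masks = [], []
        for i in range(M):
            # one resampling per subject and iteration, exp(v_i - vbar)
            phi = exponentiate(Svf(fields[i].data - vbar, spacing=A.spacing))
            warped_imgs.append(resample(images[i], phi, "linear").data)
            warped_masks.append(resample(
                ScalarImage(masks[i].values, spacing=A.spacing), phi,
                "linear").data)
            state.resample_count += 1
        A_next = np.mean(warped_imgs, axis=0)
        mean_mask = np.mean(warped_masks, axis=0)
        tmpl_mask = ConfidenceMask((mean_mask >= 0.5).astype(np.float64),
                                   spacing=A.spacing)
        intensity_change = float(((A_next - A.data) ** 2).mean()) / intensity_range ** 2
        field_change = (_field_norm(vbar) if vbar_prev is None
                        else _field_norm(vbar - vbar_prev))
        state.history.append({
            "iteration": k,
            "intensity_change": intensity_change,
            "mean_field_norm": _field_norm(vbar),
            "mean_field_change": field_change,
        })
        A = A.with_data(A_next)
        state.iteration = k + 1
        if intensity_change > prev_change:
            rising += 1
            if rising >= 3:
                raise RuntimeError(
                    "template construction diverging: intensity change grew "
                    f"for 3 consecutive iterations; history={state.history}")
        else:
            rising = 0
        prev_change = intensity_change
        vbar_prev = vbar
        if intensity_change < eps[0] and field_change < eps[1]:
            break

    w0 = [register(A, images[i], tmpl_mask, masks[i], params)
          for i in range(M)]
    return A, w0, state
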