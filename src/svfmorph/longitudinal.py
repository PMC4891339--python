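"""Subject-level longitudinal trajectory from pairwise SVFs.

Given a time series of images of one subject, every ordered pair (i, j) with
t_i < t_j is registered to give an SVF v_ij.  The subject's annualized
trajectory field is the least-squares fit of a linear-in-time model through
the origin,

    v_hat = sum_{i<j} (t_j - t_i) v_ij / sum_{i<j} (t_j - t_i)^2,

so that exp(t * v_hat) models the deformation after t years.  The closed
form already consumes the antisymmetry v_ji = -v_ij of the symmetric
registration, so only the upper-triangular pairs are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .algebra import exponentiate
from .image import ConfidenceMask, DeformationField, ScalarImage, Svf
from .registration import RegistrationParams, register

__all__ = [
    "TimeSeries", "PairwiseSvfSet", "compute_pairwise", "fit_trajectory",
    "trajectory_at",
]


@dataclass
class TimeSeries:
    """One subject's ordered image series with acquisition times in years."""

    images: list[ScalarImage]
    masks: list[ConfidenceMask]
    times: list[float]

    def __post_init__(self) -> None:
        n = len(self.images)
        if n < 2:
            raise ValueError("a time series needs at least two time points")
        if len(self.masks) != n or len(self.times) != n:
            raise ValueError("images, masks and times must have equal length")
        t = np.asarray(self.times, dtype=np.float64)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        shape = self.images[0].shape
        for obj in list(self.images) + list(self.masks):
            if tuple(obj.shape) != shape:
                raise ValueError("all images and masks must share one grid")

    @property
    def n_timepoints(self) -> int:
        return len(self.images)


@dataclass
class PairwiseSvfSet:
    """Complete upper-triangular set of pairwise SVFs {(i, j, dt, v_ij)}."""

    entries: list[tuple[int, int, float, Svf]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, j, dt, v in self.entries:
            if not (i < j and dt > 0):
                raise ValueError(f"invalid pair ({i}, {j}) with dt={dt}")
        if self.entries:
            shape = self.entries[0][3].shape
            if any(v.shape != shape for *_, v in self.entries):
                raise ValueError("all pairwise fields must share one grid")


def compute_pairwise(series: TimeSeries,
                     params: RegistrationParams | None = None) -> PairwiseSvfSet:
    """Register every ordered pair i < j of the series.

    Returns N(N-1)/2 fields, each satisfying ``I_i o exp(v_ij) ~ I_j``.
    Registration failures are re-raised with the offending pair attached.
    """
    entries = []
    n = series.n_timepoints
    for i in range(n):
        for j in range(i + 1, n):
            try:
                v = register(series.images[j], series.images[i],
                             series.masks[j], series.masks[i], params)
            except Exception as exc:
                raise RuntimeError(f"registration failed for pair ({i}, {j})"
                                   ) from exc
            dt = float(series.times[j] - series.times[i])
            entries.append((i, j, dt, v))
    return PairwiseSvfSet(entries)


def fit_trajectory(pairs: PairwiseSvfSet) -> Svf:
    """Voxelwise closed-form fit of the annual trajectory field.

    Minimizes sum_{i<j} ||(t_j - t_i) v - v_ij||^2 over v, which gives
    v_hat = sum dt * v_ij / sum dt^2.
    """
    if not pairs.entries:
        raise ValueError("empty pairwise set")
    num = np.zeros_like(pairs.entries[0][3].data)
    den = 0.0
    for _, _, dt, v in pairs.entries:
        num += dt * v.data
        den += dt * dt
    if den == 0:
        raise ValueError("all time intervals are zero")
    ref = pairs.entries[0][3]
    return Svf(num / den, spacing=ref.spacing, affine=ref.affine.copy())


def trajectory_at(v_hat: Svf, t: float) -> DeformationField:
    """Deformation after ``t`` years: exp(t * v_hat); t = 0 is the identity."""
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    return exponentiate(Svf(t * v_hat.data, spacing=v_hat.spacing,
                            affine=v_hat.affine.copy()))
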