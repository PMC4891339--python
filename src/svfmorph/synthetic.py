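"""Longitudinal phantom cohorts with known ground-truth velocity fields.

The phantoms emulate the statistical structure of a longitudinal brain MRI
study: an ellipsoidal "brain" with a dark central "ventricle" and two
lateral "hippocampus" blobs plus a smooth random tissue texture; per
subject, 2-5 time points spread over 0.5-6.9 years of follow-up; a known
annual velocity field (radial ventricle expansion, hippocampal contraction)
applied in the log domain; smooth multiplicative intensity bias, additive
Gaussian noise, and a bright rim artifact just outside the brain mask that
changes between acquisitions (the situation the confidence mask is designed
to neutralize).  Two groups differ only in their annual atrophy/expansion
rates.  Everything is reproducible bit-exactly from a single seed, which
fans out to per-subject substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .algebra import exponentiate
from .image import ConfidenceMask, ScalarImage, Svf, resample
from .longitudinal import TimeSeries

__all__ = ["PhantomSpec", "make_annual_svf", "make_baseline", "make_series",
           "make_cohort"]

_MAX_ANNUAL_DISPLACEMENT = 3.0  # voxels; the registration operating range


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Rates are annual fractional volume changes at the core of the
    corresponding structure (0.02 = 2 % expansion per year); the ventricle
    expands and the hippocampi contract.  ``jitter_sigma`` is the residual
    rigid misalignment (voxels of translation, radians of rotation) left
    after position correction.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    ventricle_rate: float = 0.02
    hippocampus_rate: float = 0.01
    n_timepoints: int = 3
    followup_years: float = 3.0
    noise_sd: float = 0.02
    bias_amplitude: float = 0.1
    rim_amplitude: float = 0.5
    jitter_sigma: float = 0.5
    rotation_sigma: float = 0.01
    group: str = "control"
    seed: int = 0
    times: tuple[float, ...] | None = None

    # anatomy as fractions of the grid size
    brain_axes_frac: tuple[float, float, float] = (0.40, 0.36, 0.38)
    ventricle_radius_frac: float = 0.11
    ventricle_profile_frac: float = 0.09
    hippo_offset_frac: tuple[float, float, float] = (0.18, 0.10, -0.08)
    hippo_radius_frac: float = 0.06
    texture_sigma: float = 2.5
    texture_amplitude: float = 0.15

    translation: np.ndarray = field(default=None)  # type: ignore[assignment]
    rotation: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 2 <= self.n_timepoints <= 5:
            raise ValueError("n_timepoints must be in [2, 5]")
        if self.translation is None:
            self.translation = np.zeros(3)
        if self.rotation is None:
            self.rotation = np.zeros(3)

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=float) - 1) / 2.0

    def timepoints(self) -> np.ndarray:
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
        else:
            t = np.linspace(0.0, self.followup_years, self.n_timepoints)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        return t


def _coords(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    ax, ay, az = angles
    Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    Rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _anatomy_coords(spec: PhantomSpec) -> np.ndarray:
    """Grid coordinates pulled back through the subject's rigid jitter."""
    x = _coords(spec.shape) - spec.center
    R = _rotation_matrix(spec.rotation)
    x = x @ R.T - spec.translation
    return x  # centered anatomical coordinates


def _structures(spec: PhantomSpec):
    n = float(min(spec.shape))
    axes = np.asarray(spec.brain_axes_frac) * n
    vent_r = spec.ventricle_radius_frac * n
    hip_r = spec.hippo_radius_frac * n
    hip_off = np.asarray(spec.hippo_offset_frac) * n
    return axes, vent_r, hip_r, hip_off


def make_baseline(spec: PhantomSpec, rng: np.random.Generator | None = None
                  ) -> tuple[ScalarImage, ConfidenceMask]:
    """Baseline phantom image and its noise-free binary brain mask."""
    rng = rng or np.random.default_rng(spec.seed)
    x = _anatomy_coords(spec)
    axes, vent_r, hip_r, hip_off = _structures(spec)
    r_ell = np.sqrt(((x / axes) ** 2).sum(axis=-1))
    brain = 1.0 / (1.0 + np.exp((r_ell - 1.0) * 12.0))  # soft ellipsoid edge
    r_vent = np.sqrt((x ** 2).sum(axis=-1))
    vent = np.exp(-0.5 * (r_vent / vent_r) ** 4)
    tissue = np.full(spec.shape, 1.0)
    for sgn in (+1, -1):
        c = hip_off * np.array([sgn, 1.0, 1.0])
        r_h = np.sqrt(((x - c) ** 2).sum(axis=-1))
        tissue += 0.25 * np.exp(-0.5 * (r_h / hip_r) ** 2)
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape),
                                      spec.texture_sigma, mode="reflect")
    texture /= max(texture.std(), 1e-12)
    tissue = tissue * (1.0 + spec.texture_amplitude * texture)
    data = brain * (tissue * (1.0 - 0.7 * vent))
    mask = (r_ell < 1.0).astype(np.float64)
    return ScalarImage(data), ConfidenceMask(mask)


def make_annual_svf(spec: PhantomSpec) -> Svf:
    """Ground-truth annual velocity field of one subject.

    Smooth, compactly supported inside the brain: radial expansion around
    the ventricle with central divergence ``log(1 + ventricle_rate)`` and
    radial contraction around each hippocampus blob.  Scales linearly in
    the rates; a zero rate gives a zero field.
    """
    x = _anatomy_coords(spec)
    axes, vent_r, hip_r, hip_off = _structures(spec)
    s_v = spec.ventricle_profile_frac * min(spec.shape)
    a_v = np.log1p(spec.ventricle_rate) / 3.0
    r2 = (x ** 2).sum(axis=-1)
    u = a_v * x * np.exp(-0.5 * r2 / s_v ** 2)[..., None]
    a_h = np.log1p(spec.hippocampus_rate) / 3.0
    s_h = hip_r
    for sgn in (+1, -1):
        c = hip_off * np.array([sgn, 1.0, 1.0])
        d = x - c
        r2h = (d ** 2).sum(axis=-1)
        u -= a_h * d * np.exp(-0.5 * r2h / s_h ** 2)[..., None]
    # taper to zero at the brain boundary
    r_ell = np.sqrt(((x / axes) ** 2).sum(axis=-1))
    window = 1.0 / (1.0 + np.exp((r_ell - 0.9) * 20.0))
    u = u * window[..., None]
    out = Svf(u)
    if out.max_norm() > _MAX_ANNUAL_DISPLACEMENT:
        raise ValueError(
            f"annual displacement {out.max_norm():.2f} voxels exceeds the "
            f"{_MAX_ANNUAL_DISPLACEMENT}-voxel operating range")
    return out


def _rim_artifact(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Bright patchy shell just outside the brain mask, different per call."""
    x = _anatomy_coords(spec)
    axes, *_ = _structures(spec)
    r_ell = np.sqrt(((x / axes) ** 2).sum(axis=-1))
    shell = np.exp(-0.5 * ((r_ell - 1.08) / 0.04) ** 2)
    shell *= r_ell >= 1.0  # strictly outside the brain mask
    pattern = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 3.0,
                                      mode="reflect")
    pattern = np.clip(pattern / max(pattern.std(), 1e-12), 0.0, None)
    return spec.rim_amplitude * shell * pattern


def rim_shell_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean shell covering the rim-artifact band outside the brain."""
    x = _anatomy_coords(spec)
    axes, *_ = _structures(spec)
    r_ell = np.sqrt(((x / axes) ** 2).sum(axis=-1))
    return (r_ell > 1.0) & (r_ell < 1.2)


def ventricle_core_mask(spec: PhantomSpec, frac: float = 1.0) -> np.ndarray:
    """Boolean mask of the ventricle region (ground-truth effect support)."""
    x = _anatomy_coords(spec)
    _, vent_r, *_ = _structures(spec)
    r = np.sqrt((x ** 2).sum(axis=-1))
    return r < frac * vent_r


def make_series(spec: PhantomSpec) -> tuple[TimeSeries, Svf]:
    """One subject's longitudinal series and its ground-truth annual SVF.

    Time point j is the baseline resampled through ``exp(t_j * u)``, then
    corrupted by a per-acquisition multiplicative bias field, additive
    Gaussian noise, and a per-acquisition rim artifact outside the brain.
    Masks are returned noise-free.
    """
    rng = np.random.default_rng(spec.seed)
    baseline, mask = make_baseline(spec, rng)
    u = make_annual_svf(spec)
    times = spec.timepoints()
    images, masks = [], []
    for t in times:
        if t == 0:
            img = baseline.data.copy()
        else:
            phi = exponentiate(Svf(t * u.data))
            img = resample(baseline, phi, "linear").data
        if spec.bias_amplitude > 0:
            bias = ndimage.gaussian_filter(rng.standard_normal(spec.shape),
                                           12.0, mode="reflect")
            bias /= max(np.abs(bias).max(), 1e-12)
            img = img * (1.0 + spec.bias_amplitude * bias)
        if spec.rim_amplitude > 0:
            img = img + _rim_artifact(spec, rng)
        if spec.noise_sd > 0:
            img = img + spec.noise_sd * rng.standard_normal(spec.shape)
        images.append(ScalarImage(img))
        masks.append(ConfidenceMask(mask.values.copy()))
    return TimeSeries(images=images, masks=masks, times=list(times)), u


def make_cohort(n_per_group: int, group_rates: tuple[float, float] = (0.02, 0.005),
                seed: int = 0, base_spec: PhantomSpec | None = None
                ) -> list[tuple[TimeSeries, str, Svf]]:
    """A two-group cohort of longitudinal phantom subjects.

    ``group_rates`` are the annual ventricle volumetric-change rates of the
    "disease" and "control" groups; hippocampal contraction is set to half
    the ventricle rate.  Time-point counts (2-5) and follow-up spans
    (0.5-6.9 years) are sampled per subject, as is a small residual rigid
    jitter.  A single seed fans out to per-subject substreams, so cohorts
    are reproducible under subsetting.
    """
    if n_per_group < 2:
        raise ValueError("need at least two subjects per group")
    base = base_spec or PhantomSpec()
    out = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(2 * n_per_group)
    for idx, child in enumerate(children):
        group = "disease" if idx < n_per_group else "control"
        rate = group_rates[0] if group == "disease" else group_rates[1]
        rng = np.random.default_rng(child)
        n_tp = int(rng.integers(2, 6))
        followup = float(rng.uniform(0.5, 6.9))
        spec = replace(
            base,
            ventricle_rate=rate,
            hippocampus_rate=rate / 2.0,
            n_timepoints=n_tp,
            followup_years=followup,
            times=None,
            group=group,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
            translation=rng.normal(0.0, base.jitter_sigma, size=3),
            rotation=rng.normal(0.0, base.rotation_sigma, size=3),
        )
        series, truth = make_series(spec)
        out.append((series, group, truth))
    return out
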