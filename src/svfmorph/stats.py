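"""Group-wise voxel statistics on transported trajectories.

Two analyses are provided on fields that live on a common template grid:

* a univariate two-sample t-test on log-Jacobian maps of the annualized
  trajectories (volumetric change), and
* a multivariate two-sample Hotelling's T2 test on the 3-vector velocity
  fields themselves (which also sees translations/rotations of structures,
  not only volume change).

Family-wise error over the analysis mask is controlled by the permutation
distribution of the maximum statistic (maxT): group labels are permuted,
the maximum |t| (or T2) over the mask is recorded per relabeling, and the
(1 - alpha) empirical quantile of these maxima is the corrected threshold.
The observed labeling is included in the null sample, and relabelings are
drawn without replacement (exhaustively when fewer than requested exist).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = ["GroupStudy", "StatMap", "two_sample_tmap", "fwe_threshold_maxT",
           "hotelling_t2_map", "ttest_fwe"]

_DET_GUARD = 1e-12


@dataclass
class GroupStudy:
    """Per-subject fields, binary group labels and an analysis mask.

    ``fields`` may be 3D scalar maps (log-Jacobians) or ``(..., 3)`` vector
    fields; all must share the mask's grid.  Exactly two label values are
    required, each with at least two subjects.
    """

    fields: list[np.ndarray]
    labels: list
    mask: np.ndarray
    voxel_volume_mm3: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) > 0.5
        if len(self.fields) != len(self.labels):
            raise ValueError("one label per field required")
        uniq = sorted(set(self.labels))
        if len(uniq) != 2:
            raise ValueError(f"exactly two groups required, got {uniq}")
        counts = [sum(l == u for l in self.labels) for u in uniq]
        if min(counts) < 2:
            raise ValueError("each group needs at least two subjects")
        shape = self.mask.shape
        for f in self.fields:
            if f.shape[:3] != shape:
                raise ValueError("field/mask grid mismatch")
        self._uniq = uniq

    @property
    def group_indicator(self) -> np.ndarray:
        """Boolean array, True for membership in the first (sorted) group."""
        return np.array([l == self._uniq[0] for l in self.labels])

    def data_matrix(self) -> np.ndarray:
        """(n_subjects, n_mask_voxels, n_components) in-mask data."""
        stack = []
        for f in self.fields:
            if f.ndim == 3:
                stack.append(f[self.mask][:, None])
            else:
                stack.append(f[self.mask])
        return np.asarray(stack, dtype=np.float64)


@dataclass
class StatMap:
    """A thresholded voxelwise statistic map."""

    values: np.ndarray
    threshold: float
    significant: np.ndarray
    volume_mm3: float
    alpha: float
    n_perm: int
    null_maxima: np.ndarray


def _t_values(X: np.ndarray, in_g1: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per voxel; zero where variance is zero.

    ``X`` is (n, V, 1); the sign follows group1 mean minus group2 mean.
    """
    x = X[..., 0]
    n1 = int(in_g1.sum())
    n2 = x.shape[0] - n1
    g1, g2 = x[in_g1], x[~in_g1]
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    ss = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
    sp2 = ss / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(m1)
    ok = denom > 0
    t[ok] = (m1 - m2)[ok] / denom[ok]
    return t


def _t2_values(X: np.ndarray, in_g1: np.ndarray) -> np.ndarray:
    """Hotelling's two-sample T2 per voxel for (n, V, C) data.

    Uses the pooled covariance; near-singular covariances receive a ridge of
    ``1e-8 * trace / C`` on the diagonal.
    """
    n, V, C = X.shape
    n1 = int(in_g1.sum())
    n2 = n - n1
    g1, g2 = X[in_g1], X[~in_g1]
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    d = m1 - m2  # (V, C)
    c1 = g1 - m1
    c2 = g2 - m2
    S = (np.einsum("nvc,nvd->vcd", c1, c1)
         + np.einsum("nvc,nvd->vcd", c2, c2)) / (n1 + n2 - 2)
    tr = np.einsum("vcc->v", S) / C
    det = np.linalg.det(S)
    bad = det <= _DET_GUARD * np.maximum(tr, 1e-30) ** C
    if np.any(bad):
        ridge = 1e-8 * np.maximum(tr[bad], 1e-30)
        S = S.copy()
        S[bad] += ridge[:, None, None] * np.eye(C)
    sol = np.linalg.solve(S, d[..., None])[..., 0]
    t2 = (n1 * n2 / (n1 + n2)) * np.einsum("vc,vc->v", d, sol)
    return np.maximum(t2, 0.0)


def _embed(mask: np.ndarray, flat: np.ndarray) -> np.ndarray:
    out = np.zeros(mask.shape, dtype=np.float64)
    out[mask] = flat
    return out


def two_sample_tmap(study: GroupStudy) -> np.ndarray:
    """Voxelwise pooled-variance two-sample t map over the analysis mask.

    The null hypothesis at each voxel is equality of the two group means;
    voxels with zero pooled variance get t = 0, voxels outside the mask 0.
    """
    X = study.data_matrix()
    if X.shape[-1] != 1:
        raise ValueError("t-test expects scalar (log-Jacobian) fields")
    return _embed(study.mask, _t_values(X, study.group_indicator))


def _canonical(pick: tuple[int, ...], n: int, n1: int) -> tuple[int, ...]:
    """Identify a balanced subset with its complement (same unsigned stat)."""
    if 2 * n1 != n:
        return pick
    comp = tuple(i for i in range(n) if i not in set(pick))
    return min(pick, comp)


def _relabelings(n: int, n1: int, n_perm: int, rng: np.random.Generator,
                 observed: tuple[int, ...]) -> list[tuple[int, ...]]:
    """Distinct index subsets defining group 1, observed labeling first.

    Swapping the two groups leaves |t| and T2 unchanged, so for balanced
    designs a subset and its complement are one relabeling; counting both
    would duplicate null values and bias the threshold conservatively.
    """
    balanced = 2 * n1 == n
    total = comb(n, n1) // 2 if balanced else comb(n, n1)
    observed = _canonical(observed, n, n1)
    if total <= n_perm:
        warnings.warn(
            f"only {total} distinct relabelings exist for n={n}, n1={n1}; "
            "enumerating exhaustively", stacklevel=3)
        uniq = {_canonical(c, n, n1) for c in combinations(range(n), n1)}
        uniq.discard(observed)
        return [observed] + sorted(uniq)
    seen = {observed}
    out = [observed]
    while len(out) < n_perm:
        pick = _canonical(tuple(sorted(
            rng.choice(n, size=n1, replace=False).tolist())), n, n1)
        if pick not in seen:
            seen.add(pick)
            out.append(pick)
    return out


def _max_stat_distribution(X: np.ndarray, n1: int, n_perm: int, seed,
                           stat_fn) -> np.ndarray:
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    observed = tuple(range(n1))  # caller pre-sorts group 1 first
    maxima = []
    for subset in _relabelings(n, n1, n_perm, rng, observed):
        in_g1 = np.zeros(n, dtype=bool)
        in_g1[list(subset)] = True
        maxima.append(float(np.abs(stat_fn(X, in_g1)).max()))
    return np.asarray(maxima)


def _sorted_by_group(study: GroupStudy) -> tuple[np.ndarray, int]:
    """Data matrix reordered so group-1 subjects come first."""
    X = study.data_matrix()
    in_g1 = study.group_indicator
    order = np.concatenate([np.flatnonzero(in_g1), np.flatnonzero(~in_g1)])
    return X[order], int(in_g1.sum())


def fwe_threshold_maxT(study: GroupStudy, n_perm: int, alpha: float = 0.05,
                       seed: int | None = 0, statistic: str = "t") -> float:
    """Permutation maxT family-wise-error threshold over the analysis mask.

    Records the maximum |statistic| per relabeling and returns the
    ``1 - alpha`` empirical quantile.  Deterministic for a given seed;
    ``alpha = 1`` returns the smallest recorded maximum.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    X, n1 = _sorted_by_group(study)
    fn = _t_values if statistic == "t" else _t2_values
    maxima = _max_stat_distribution(X, n1, n_perm, seed, fn)
    return _maxT_threshold(maxima, alpha)


def _maxT_threshold(maxima: np.ndarray, alpha: float) -> float:
    """Order-statistic threshold with exact level floor(alpha B)/B.

    With the observed labeling included among the B maxima, declaring
    significance where the statistic strictly exceeds the ceil((1-alpha)B)-th
    smallest maximum rejects a true null with probability floor(alpha B)/B.
    """
    b = len(maxima)
    m = min(max(1, int(np.ceil((1.0 - alpha) * b))), b)
    return float(np.sort(maxima)[m - 1])


def _stat_map(study: GroupStudy, statistic: str, n_perm: int, alpha: float,
              seed) -> StatMap:
    X, n1 = _sorted_by_group(study)
    fn = _t_values if statistic == "t" else _t2_values
    observed = fn(X, np.arange(X.shape[0]) < n1)
    maxima = _max_stat_distribution(X, n1, n_perm, seed, fn)
    thr = _maxT_threshold(maxima, alpha)
    values = _embed(study.mask, observed)
    significant = np.zeros(study.mask.shape, dtype=bool)
    significant[study.mask] = np.abs(observed) > thr
    volume = float(significant.sum()) * study.voxel_volume_mm3
    return StatMap(values=values, threshold=thr, significant=significant,
                   volume_mm3=volume, alpha=alpha, n_perm=len(maxima),
                   null_maxima=maxima)


def ttest_fwe(study: GroupStudy, n_perm: int = 1000, alpha: float = 0.05,
              seed: int | None = 0) -> StatMap:
    """Two-sample t map with permutation maxT FWE thresholding."""
    if study.data_matrix().shape[-1] != 1:
        raise ValueError("t-test expects scalar fields")
    return _stat_map(study, "t", n_perm, alpha, seed)


def hotelling_t2_map(study: GroupStudy, n_perm: int = 5000,
                     alpha: float = 0.05, seed: int | None = 0) -> StatMap:
    """Hotelling's two-sample T2 map on vector fields with maxT correction.

    T2 = (n1 n2 / (n1 + n2)) (m1 - m2)' S_pooled^-1 (m1 - m2) per voxel.
    With one-component inputs this reduces exactly to the squared pooled t.
    """
    if len(study.fields) < 4:
        raise ValueError("need at least four subjects in total")
    return _stat_map(study, "t2", n_perm, alpha, seed)
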