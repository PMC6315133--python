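"""Second-level statistics for relating model fit to brain activity.

Implements the study-level machinery applied after per-subject contrast
volumes and model fits exist: Pearson correlations with Bonferroni
multiplicity control, asymptotic z-tests for comparing correlations
(Meng-Rosenthal-Rubin for correlations sharing a variable, Fisher for
independent groups), voxelwise group maps, conjunction-null testing by the
voxelwise maximum of p-values with Benjamini-Hochberg FDR control, spherical
ROI averaging, and the 2x2 mixed-design ANOVA on model fits.

Conventions: p-volumes are uncorrected per-voxel p values; the conjunction
statistic max(p_1, ..., p_K) tests the conjunction null (not all effects
present), so a small conjunction p supports *all* effects being present.
Zero-variance voxels are flagged and excluded from FDR families rather than
assigned extreme p values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .volumes import StatVolume

__all__ = [
    "CorrelationResult",
    "CorrelationComparison",
    "ConjunctionResult",
    "AnovaResult",
    "SphereSample",
    "pearson_correlation",
    "meng_dependent_z",
    "fisher_independent_z",
    "bh_fdr",
    "conjunction_max_p",
    "conjunction_fdr",
    "voxelwise_two_sample_t",
    "voxelwise_one_sample_t",
    "voxelwise_correlation",
    "sphere_average",
    "mixed_anova_interaction",
    "bonferroni_threshold",
]

Tails = Literal["one", "two"]


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    tails: Tails


@dataclass
class CorrelationComparison:
    r_jk: float
    r_jh: float
    r_kh: float | None
    n: int
    z: float
    p: float
    tails: Tails
    method: Literal["dependent_meng", "independent_fisher"]
    p_one_tailed: float = math.nan
    p_two_tailed: float = math.nan


@dataclass
class ConjunctionResult:
    conjunction: StatVolume
    q: float
    critical_p: float
    mask: np.ndarray
    n_significant: int


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    MSE: float
    p: float
    effect: Literal["within", "between", "interaction"]


@dataclass
class SphereSample:
    value: float
    n_voxels: int

    def __float__(self) -> float:
        return self.value


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], tails: Tails = "two"
) -> CorrelationResult:
    """Product-moment correlation with its t-distributed p value.

    A one-tailed p is reported for the direction of the observed r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("inputs must be equal-length with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    p = res.pvalue if tails == "two" else res.pvalue / 2.0
    return CorrelationResult(r=float(res.statistic), n=len(x), p=float(p), tails=tails)


def _check_psd(r_jk: float, r_jh: float, r_kh: float) -> None:
    R = np.array([[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("inconsistent correlation triple (matrix not positive semidefinite)")


def meng_dependent_z(
    r_jk: float, r_jh: float, r_kh: float, n: int, tails: Tails = "two"
) -> CorrelationComparison:
    """Asymptotic z-test for two correlations sharing one variable.

    Compares r(j,k) with r(j,h) given the correlation r(k,h) between the two
    non-shared variables, following Meng, Rosenthal & Rubin: the difference
    of Fisher-z transforms is scaled by a factor involving r(k,h) and the
    mean squared correlation.  z is antisymmetric in (r_jk, r_jh).
    """
    for r in (r_jk, r_jh, r_kh):
        if abs(r) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    _check_psd(r_jk, r_jh, r_kh)
    z1, z2 = np.arctanh(r_jk), np.arctanh(r_jh)
    rbar2 = (r_jk**2 + r_jh**2) / 2.0
    f = min((1.0 - r_kh) / (2.0 * (1.0 - rbar2)), 1.0)
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r_kh) * h))
    p_one = float(sps.norm.sf(abs(z)))
    p_two = 2.0 * p_one
    return CorrelationComparison(
        r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=n, z=float(z),
        p=p_one if tails == "one" else p_two, tails=tails,
        method="dependent_meng", p_one_tailed=p_one, p_two_tailed=p_two,
    )


def fisher_independent_z(
    r1: float, n1: int, r2: float, n2: int, tails: Tails = "two"
) -> CorrelationComparison:
    """Fisher z-test for correlations from two independent samples."""
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p_one = float(sps.norm.sf(abs(z)))
    p_two = 2.0 * p_one
    return CorrelationComparison(
        r_jk=r1, r_jh=r2, r_kh=None, n=n1 + n2, z=float(z),
        p=p_one if tails == "one" else p_two, tails=tails,
        method="independent_fisher", p_one_tailed=p_one, p_two_tailed=p_two,
    )


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up rejections at level ``q``.

    Returns the boolean rejection mask and the critical p (the largest
    rejected p value; 0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    critical = float(p[reject].max()) if reject.any() else 0.0
    return reject, critical


def _as_p_volume(v) -> StatVolume:
    if isinstance(v, StatVolume):
        return v
    return StatVolume(np.asarray(v, dtype=float), kind="p")


def conjunction_max_p(p_volumes: Sequence[StatVolume]) -> StatVolume:
    """Voxelwise maximum of the input p-volumes (the conjunction-null statistic)."""
    vols = [_as_p_volume(v) for v in p_volumes]
    if len(vols) < 2:
        raise ValueError("conjunction needs at least two p-volumes")
    first = vols[0]
    for v in vols[1:]:
        if not first.same_grid(v):
            raise ValueError("p-volumes are on different grids")
    data = np.maximum.reduce([v.data for v in vols])
    return StatVolume(data, voxel_size=first.voxel_size, origin=first.origin, kind="p")


def conjunction_fdr(p_volumes: Sequence[StatVolume], q: float = 0.05) -> ConjunctionResult:
    """Max-p conjunction followed by voxelwise BH-FDR thresholding.

    The FDR family is all finite voxels of the conjunction volume; NaN
    (e.g., zero-variance) voxels are excluded and never significant.
    """
    conj = conjunction_max_p(p_volumes)
    finite = np.isfinite(conj.data)
    if not finite.any():
        raise ValueError("no finite voxels in the conjunction volume")
    reject_flat, critical = bh_fdr(conj.data[finite], q)
    mask = np.zeros(conj.shape, dtype=bool)
    mask[finite] = reject_flat
    return ConjunctionResult(
        conjunction=conj, q=q, critical_p=critical, mask=mask, n_significant=int(mask.sum())
    )


def _wrap_pair(t, p, template: StatVolume | None, voxel_size, origin):
    if template is not None:
        vs, og = template.voxel_size, template.origin
    else:
        vs, og = voxel_size, origin
    return (
        StatVolume(t, voxel_size=vs, origin=og, kind="t"),
        StatVolume(p, voxel_size=vs, origin=og, kind="p"),
    )


def voxelwise_two_sample_t(
    volumes_a: np.ndarray,
    volumes_b: np.ndarray,
    voxel_size: float = 2.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[StatVolume, StatVolume]:
    """Pooled-variance two-sample t and two-tailed p at every voxel.

    Inputs are (n_subjects, nx, ny, nz) stacks, one per group.  Voxels with
    zero variance in both groups get t = 0, p = 1.
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups are on different grids")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant voxels trigger scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=True)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return _wrap_pair(t, p, None, voxel_size, origin)


def voxelwise_one_sample_t(
    volumes: np.ndarray,
    popmean: float = 0.0,
    voxel_size: float = 2.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[StatVolume, StatVolume]:
    """One-sample t against ``popmean`` at every voxel of a subject stack."""
    a = np.asarray(volumes, dtype=float)
    if a.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_1samp(a, popmean, axis=0)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return _wrap_pair(t, p, None, voxel_size, origin)


def voxelwise_correlation(
    volumes: np.ndarray,
    covariate: Sequence[float],
    voxel_size: float = 2.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[StatVolume, StatVolume]:
    """Per-voxel Pearson correlation of subject values with a covariate."""
    a = np.asarray(volumes, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = a.shape[0]
    if n < 4:
        raise ValueError("need >= 4 subjects")
    if len(c) != n:
        raise ValueError("one covariate value per subject required")
    if c.std() == 0:
        raise ValueError("constant covariate")
    zc = (c - c.mean()) / c.std()
    am = a - a.mean(axis=0)
    sd = a.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        r = np.einsum("i,i...->...", zc, am) / (n * sd)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    degenerate = sd == 0
    r = np.where(degenerate, np.nan, r)
    p = np.where(degenerate, np.nan, p)
    return (
        StatVolume(r, voxel_size=voxel_size, origin=origin, kind="r"),
        StatVolume(p, voxel_size=voxel_size, origin=origin, kind="p"),
    )


def sphere_average(
    volume: StatVolume, center_mm: Sequence[float], radius_mm: float
) -> SphereSample:
    """Mean over voxels whose centers lie within ``radius_mm`` of a point.

    Distances are center-to-center with inclusive boundary, mirroring
    spherical ROI extraction around a peak voxel.
    """
    center = np.asarray(center_mm, dtype=float)
    lo = volume.index_to_mm((0, 0, 0))
    hi = volume.index_to_mm(np.array(volume.shape) - 1)
    if np.any(center < lo - volume.voxel_size / 2) or np.any(center > hi + volume.voxel_size / 2):
        raise ValueError("sphere center lies outside the grid")
    centers = volume.voxel_centers_mm()
    dist = np.linalg.norm(centers - center, axis=-1)
    inside = dist <= radius_mm + 1e-12
    if not inside.any():
        raise ValueError("no voxel centers within the sphere radius")
    return SphereSample(value=float(volume.data[inside].mean()), n_voxels=int(inside.sum()))


def mixed_anova_interaction(
    values: np.ndarray, groups: Sequence, alpha: float = 0.05
) -> AnovaResult:
    """Interaction F of a 2 (within: CAM/EBM fit) x k (between: group) design.

    ``values`` is (n_subjects, 2) with one model-fit column per within level.
    For the two-level within factor this F equals the squared two-sample t on
    within-subject difference scores; a design with zero interaction sum of
    squares reports F = 0, p = 1.
    """
    import pandas as pd

    vals = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if vals.ndim != 2 or vals.shape[1] != 2:
        raise ValueError("values must be (n_subjects, 2): one column per within level")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    if len(groups) != len(vals):
        raise ValueError("one group label per subject required")

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(len(vals)), 2),
            "model": np.tile(["CAM", "EBM"], len(vals)),
            "fit": vals.ravel(),
            "group": np.repeat(groups, 2),
        }
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # pingouin warns on exotic balanced designs
        import pingouin as pg

        table = pg.mixed_anova(
            data=long, dv="fit", within="model", subject="subject", between="group"
        )
    row = table[table["Source"] == "Interaction"].iloc[0]
    F = float(row["F"])
    p = float(row["p_unc"] if "p_unc" in row else row["p-unc"])
    if not np.isfinite(F):  # zero interaction and zero error variance
        F, p = 0.0, 1.0
    # error mean square of the within x subject term, recovered from F = MS/MSE
    mse = float(row["MS"]) / F if F > 0 else 0.0
    return AnovaResult(
        F=F, df=(int(row["DF1"]), int(row["DF2"])), MSE=mse, p=p, effect="interaction"
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for a family of m tests."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m
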