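"""Patch-wise micro-macrostructure coupling and group-level inference.

Within each subject, the coupling between a microstructural vertex metric
(SP or CP tissue fraction) and sulcal depth is the Pearson correlation
over the k-ring neighbourhood ("patch") around every vertex.  Subjects
are grouped into bi-weekly gestational-age bins; at each vertex a
one-sample t-test of the per-subject r values against zero identifies
consistently coupled vertices, with Benjamini-Hochberg FDR control across
all vertices.  The age-mismatched ("back-projection") variant replaces
each subject's own sulcal depth with the group-mean depth of the oldest
bin, probing whether microstructure anticipates *future* folding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fetalfold.metrics import VertexMetric
from fetalfold.surface import PatchSpec


class CouplingError(ValueError):
    pass


@dataclass(frozen=True)
class StatConfig:
    """Group-inference configuration.

    ``q`` is the FDR level (0.05 by default); bins are
    ``bin_width_weeks``-wide half-open intervals centred on odd
    gestational weeks; bins with fewer than ``min_subjects_per_bin``
    subjects are flagged.
    """

    q: float = 0.05
    bin_width_weeks: float = 2.0
    min_subjects_per_bin: int = 2
    bin_centers: tuple[float, ...] = (25.0, 27.0, 29.0, 31.0, 33.0, 35.0)
    fisher_z: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise CouplingError("q must be in (0, 1)")
        if self.bin_width_weeks <= 0:
            raise CouplingError("bin_width_weeks must be > 0")
        if self.min_subjects_per_bin < 2:
            raise CouplingError("min_subjects_per_bin must be >= 2")


@dataclass
class CouplingMap:
    """Per-vertex patch correlation of one subject and one metric.

    ``r`` and ``p`` are NaN wherever the patch was invalid (too few valid
    vertices, or zero variance); ``n`` records the number of valid patch
    vertices used at each centre.
    """

    r: np.ndarray
    p: np.ndarray
    n: np.ndarray
    subject_id: str = ""
    metric_name: str = ""

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.r)


@dataclass
class GroupResult:
    """Vertex-wise one-sample t-test over subject r values within a bin."""

    mean_r: np.ndarray
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray  # FDR-selected vertices
    n: np.ndarray  # subjects contributing a defined r per vertex
    bin_center: float = np.nan
    n_subjects: int = 0
    q: float = 0.05

    def significant_mean_r(self) -> np.ndarray:
        """Mean r only where FDR-selected (display contract); NaN elsewhere."""
        out = np.where(self.mask, self.mean_r, np.nan)
        return out


# -------------------------------------------------------------- patch stats

def patch_coupling(
    metric: VertexMetric,
    depth: VertexMetric,
    patches: list[np.ndarray],
    spec: PatchSpec = PatchSpec(),
    subject_id: str = "",
) -> CouplingMap:
    """Pearson r of metric vs depth over each vertex's patch.

    For every central vertex, the correlation is computed over patch
    members valid in *both* inputs and assigned to the centre.  Patches
    with fewer than ``spec.min_valid_vertices`` valid members, or zero
    variance in either variable, are missing.  Two-sided p-values follow
    the exact t distribution with n - 2 degrees of freedom.
    """
    if len(metric) != len(depth):
        raise CouplingError("metric and depth are on different templates")
    if len(patches) != len(metric):
        raise CouplingError("patch list does not cover the template")
    x = metric.values
    y = depth.values
    ok = metric.mask & depth.mask
    nv = len(x)
    r = np.full(nv, np.nan)
    n_used = np.zeros(nv, dtype=np.int64)
    for c, idx in enumerate(patches):
        sel = idx[ok[idx]]
        m = len(sel)
        if m < spec.min_valid_vertices:
            continue
        xs = x[sel]
        ys = y[sel]
        xc = xs - xs.mean()
        yc = ys - ys.mean()
        sxx = xc @ xc
        syy = yc @ yc
        # zero-variance guard with a relative floor: rounding residue on a
        # constant input must not masquerade as variance
        x_floor = m * (1e-12 * max(1.0, np.abs(xs).max())) ** 2
        y_floor = m * (1e-12 * max(1.0, np.abs(ys).max())) ** 2
        if sxx <= x_floor or syy <= y_floor:
            continue
        r[c] = np.clip((xc @ yc) / np.sqrt(sxx * syy), -1.0, 1.0)
        n_used[c] = m
    p = _pearson_p(r, n_used)
    return CouplingMap(r, p, n_used, subject_id=subject_id,
                       metric_name=metric.name)


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r under the t_(n-2) null."""
    p = np.full_like(r, np.nan)
    ok = np.isfinite(r) & (n > 2)
    rr = r[ok]
    df = n[ok] - 2
    with np.errstate(divide="ignore", over="ignore"):
        t = rr * np.sqrt(df / np.maximum(1.0 - rr**2, np.finfo(float).tiny))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isfinite(r) & (np.abs(r) >= 1.0)] = 0.0
    return np.clip(p, 0.0, 1.0, out=p)


# ------------------------------------------------------------------ binning

def bin_subjects(
    manifest,
    config: StatConfig = StatConfig(),
) -> dict[float, list[str]]:
    """Assign subjects to half-open bi-weekly GA bins [c-1, c+1).

    ``manifest`` is a DataFrame with ``subject_id`` and ``ga_weeks``
    columns.  Each subject falls in exactly one bin; subjects outside all
    configured bins are excluded with a warning.  Bins below
    ``min_subjects_per_bin`` remain in the result but are warned about.
    """
    if manifest["ga_weeks"].isna().any():
        raise CouplingError("gestational age missing for some subjects")
    half = config.bin_width_weeks / 2.0
    bins: dict[float, list[str]] = {c: [] for c in config.bin_centers}
    for sid, ga in zip(manifest["subject_id"], manifest["ga_weeks"]):
        placed = False
        for c in config.bin_centers:
            if c - half <= ga < c + half:
                bins[c].append(str(sid))
                placed = True
                break
        if not placed:
            warnings.warn(
                f"subject {sid} (GA {ga:.2f} w) outside configured bins; excluded",
                stacklevel=2,
            )
    for c, members in bins.items():
        if 0 < len(members) < config.min_subjects_per_bin:
            warnings.warn(
                f"bin {c:g} has only {len(members)} subject(s) "
                f"(minimum {config.min_subjects_per_bin})",
                stacklevel=2,
            )
    return bins


# -------------------------------------------------------------- group tests

def group_test(
    maps: list[CouplingMap],
    config: StatConfig = StatConfig(),
    bin_center: float = np.nan,
) -> GroupResult:
    """Vertex-wise one-sample t-test of subject r values against zero.

    Uses the raw r values (a Fisher-z transform may be enabled via
    ``config.fisher_z``).  Vertices where fewer than
    ``min_subjects_per_bin`` subjects contribute a defined r are missing.
    FDR selection (Benjamini-Hochberg at level ``config.q``) is applied
    across all non-missing vertices.
    """
    if not maps:
        raise CouplingError("empty bin: no coupling maps to test")
    rs = np.vstack([m.r for m in maps])  # (subjects, vertices)
    if config.fisher_z:
        vals = np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12))
    else:
        vals = rs
    n = np.isfinite(vals).sum(axis=0)
    enough = n >= config.min_subjects_per_bin
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(vals), vals, np.nan), axis=0)
        mean_r = np.nanmean(np.where(np.isfinite(rs), rs, np.nan), axis=0)
        sd = np.nanstd(np.where(np.isfinite(vals), vals, np.nan), axis=0, ddof=1)
    t = np.full(vals.shape[1], np.nan)
    p = np.full(vals.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = sd / np.sqrt(n)
        t[enough] = mean[enough] / se[enough]
    # all-equal samples: sd == 0 -> t is +-inf (mean != 0) or 0/0 (mean == 0)
    zero_sd = enough & (sd == 0)
    t[zero_sd & (mean == 0)] = 0.0
    finite = enough & np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), n[finite] - 1)
    p[enough & np.isposinf(np.abs(t))] = 0.0
    mean_r[~enough] = np.nan
    mask = bh_fdr(p, config.q)
    return GroupResult(mean_r, t, p, mask, n, bin_center=bin_center,
                       n_subjects=len(maps), q=config.q)


def bh_fdr(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection over non-missing p-values.

    Returns a boolean mask (False for missing entries).  Selection is the
    classic step-up rule: sort ascending, find the largest i with
    p_(i) <= i q / m, select everything up to it.
    """
    p = np.asarray(p, dtype=np.float64)
    mask = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if not ok.any():
        return mask
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise CouplingError("p-values must be in [0, 1]")
    reject, *_ = multipletests(pv, alpha=q, method="fdr_bh")
    mask[ok] = reject
    return mask


# ------------------------------------------------- age-mismatched machinery

def group_mean_depth(depths: list[VertexMetric]) -> VertexMetric:
    """Vertex-wise mean sulcal depth over a bin's subjects.

    Vertices missing in all subjects stay masked; otherwise the mean is
    over the subjects with a valid value (template correspondence
    assumed).
    """
    if not depths:
        raise CouplingError("empty bin: no depth fields to average")
    arr = np.vstack([d.values for d in depths])
    count = np.isfinite(arr).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
    mean[count == 0] = np.nan
    return VertexMetric(mean, name="mean_sulcal_depth", units="mm")


def age_mismatched_coupling(
    mean_depth_old: VertexMetric,
    metric_young: VertexMetric,
    patches: list[np.ndarray],
    spec: PatchSpec = PatchSpec(),
    subject_id: str = "",
) -> CouplingMap:
    """Coupling of a young subject's microstructure with *future* depth.

    Identical to :func:`patch_coupling` with the subject's own sulcal
    depth replaced by the old-bin group-mean depth, back-projected through
    template vertex correspondence.  Downstream binning, group testing and
    FDR reuse the age-matched machinery unchanged.
    """
    return patch_coupling(metric_young, mean_depth_old, patches, spec,
                          subject_id=subject_id)


__all__ = [
    "CouplingError",
    "StatConfig",
    "CouplingMap",
    "GroupResult",
    "patch_coupling",
    "bin_subjects",
    "group_test",
    "bh_fdr",
    "group_mean_depth",
    "age_mismatched_coupling",
]
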