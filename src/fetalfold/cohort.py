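"""Synthetic fetal cohort generator with known ground truth.

Real in utero MRI is not redistributable, so every downstream stage is
exercised on phantoms that emulate the study conditions: template-topology
surfaces whose fold amplitude grows sigmoidally with gestational age (GA,
24-36 weeks), tissue/fluid-fraction fields in which SP/CP tissue fraction
is linearly coupled (negative slope beta) to *future* sulcal depth plus
Gaussian noise, and a 3-shell DWI forward signal (b = 0/400/1000 s/mm^2,
15/46/80 volumes) from the two-compartment model with Rician noise.

Calibration.  For a planted linear coupling ``metric = base + beta * depth
+ eps`` with ``eps ~ N(0, sigma^2)``, the within-patch population Pearson
correlation is available in closed form,

    rho = beta * sd(depth) / sqrt(beta^2 var(depth) + sigma^2),

where ``sd(depth)`` is the within-patch standard deviation of the depth
field.  :func:`planted_rho` evaluates it, and :func:`matched_noise_sd`
inverts it: choosing ``sigma`` proportional to the local depth spread
plants the *same* population rho in every patch, giving coupling-recovery
tests an exact analytic target.

Observation routes.  Phantoms can expose their microstructure at three
levels of realism: ``"vertex"`` (metrics planted directly on the template,
where the calibration above is exact), ``"volume"`` (fraction fields
painted into a voxel grid and read back through ribbon sampling, which
adds interpolation smoothing), and ``"dwi"`` (a further forward DWI signal
to be decomposed first).

Determinism: all randomness flows from one master seed through
``numpy.random.SeedSequence`` streams keyed by (master_seed, subject
index), so a cohort regenerates bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from fetalfold.decomposition import (
    DEFAULT_SCHEME,
    FractionMaps,
    ResponseFunction,
    ShellScheme,
    default_fluid_response,
    default_tissue_response,
)
from fetalfold.growth import logistic
from fetalfold.metrics import VertexMetric
from fetalfold.surface import Mesh, MeshError, icosphere, sulcal_depth, \
    vertex_normals

GA_MIN, GA_MAX = 24.0, 36.0


@dataclass(frozen=True)
class FoldMode:
    """One developing sulcus: a Gaussian radial indentation.

    ``center`` is a unit direction on the sphere; ``width_rad`` the angular
    standard deviation of the Gaussian bump; ``amplitude_mm`` the asymptotic
    pit displacement; ``onset_ga``/``rate`` parameterise the logistic growth
    of the displacement with GA.
    """

    center: tuple[float, float, float]
    width_rad: float
    amplitude_mm: float
    onset_ga: float
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width_rad <= 0:
            raise ValueError("width must be > 0")

    @property
    def unit_center(self) -> np.ndarray:
        c = np.asarray(self.center, dtype=np.float64)
        return c / np.linalg.norm(c)


@dataclass(frozen=True)
class FoldSpec:
    """Collection of fold modes on a sphere of given radius."""

    modes: tuple[FoldMode, ...]
    radius_mm: float = 30.0


def default_fold_spec() -> FoldSpec:
    """Three primary-sulcus-like folds with staggered sigmoidal onsets."""
    return FoldSpec(
        modes=(
            FoldMode(center=(1.0, 0.3, 0.2), width_rad=0.25,
                     amplitude_mm=8.0, onset_ga=28.0, rate=0.9),
            FoldMode(center=(-0.4, 1.0, -0.3), width_rad=0.22,
                     amplitude_mm=6.5, onset_ga=30.0, rate=1.0),
            FoldMode(center=(0.1, -0.6, -1.0), width_rad=0.28,
                     amplitude_mm=7.0, onset_ga=31.0, rate=0.8),
        ),
        radius_mm=30.0,
    )


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel grid centred on the origin, covering the phantom."""

    voxel_size_mm: float = 1.5
    margin_mm: float = 4.0

    def build(self, radius_mm: float) -> tuple[tuple[int, int, int], np.ndarray]:
        extent = radius_mm + self.margin_mm
        n = int(np.ceil(2 * extent / self.voxel_size_mm))
        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = self.voxel_size_mm
        affine[:3, 3] = -extent + self.voxel_size_mm / 2.0
        return (n, n, n), affine


@dataclass
class SubjectPhantom:
    """One synthetic subject with full ground truth."""

    subject_id: str
    ga: float
    mesh: Mesh
    depth: VertexMetric
    sp_metric: VertexMetric | None = None
    cp_metric: VertexMetric | None = None
    fraction_maps: FractionMaps | None = None
    dwi: np.ndarray | None = None
    truth: dict = field(default_factory=dict)


# --------------------------------------------------------------- geometry

def fold_surface(template: Mesh, spec: FoldSpec, ga: float) -> Mesh:
    """Radially displace a template icosphere into a folded surface.

    The displacement at each vertex is the sum over fold modes of
    ``-A * sigma(ga; onset, rate) * exp(-theta^2 / (2 width^2))`` where
    ``theta`` is the angular distance to the mode centre; vertices move
    along the radial direction only, so template correspondence is
    preserved and the surface stays star-shaped.
    """
    dirs = template.vertices / np.linalg.norm(template.vertices, axis=1,
                                              keepdims=True)
    disp = np.zeros(len(dirs))
    for mode in spec.modes:
        cosang = np.clip(dirs @ mode.unit_center, -1.0, 1.0)
        theta = np.arccos(cosang)
        growth = logistic(ga, 0.0, 1.0, mode.onset_ga, mode.rate)
        disp += mode.amplitude_mm * growth * np.exp(
            -0.5 * (theta / mode.width_rad) ** 2)
    if np.any(disp >= spec.radius_mm):
        raise MeshError("fold displacement exceeds the sphere radius")
    folded = template.with_vertices(dirs * (spec.radius_mm - disp)[:, None])
    folded.metadata["ga"] = float(ga)
    return folded


def future_depth(template: Mesh, spec: FoldSpec,
                 ga_max: float = GA_MAX) -> VertexMetric:
    """Sulcal depth of the fully folded (oldest) surface on the template."""
    return sulcal_depth(fold_surface(template, spec, ga_max))


# ------------------------------------------------------------- calibration

def planted_rho(beta: float, depth_sd: np.ndarray | float,
                noise_sd: np.ndarray | float) -> np.ndarray | float:
    """Population within-patch Pearson correlation of a planted coupling.

    ``rho = beta * sd(depth) / sqrt(beta^2 var(depth) + sigma^2)``; zero
    where both the signal and the noise vanish.
    """
    s = np.asarray(depth_sd, dtype=np.float64)
    sig = np.asarray(noise_sd, dtype=np.float64)
    num = beta * s
    den = np.sqrt((beta * s) ** 2 + sig**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return rho if rho.ndim else float(rho)


def patch_depth_sd(depth: VertexMetric, patches: list[np.ndarray]) -> np.ndarray:
    """Within-patch sample standard deviation of the depth field."""
    d = depth.values
    out = np.zeros(len(patches))
    for c, idx in enumerate(patches):
        vals = d[idx]
        vals = vals[np.isfinite(vals)]
        out[c] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return out


def matched_noise_sd(depth_sd: np.ndarray | float, beta: float,
                     rho: float) -> np.ndarray | float:
    """Noise s.d. that plants population correlation ``rho`` at a given
    within-patch depth spread.

    Inverts the calibration formula: ``sigma = |beta| * sd(depth) *
    sqrt(1/rho^2 - 1)``.  The formula assumes the noise level is
    (locally) constant across the patch, so for spatially varying depth
    spread prefer a single scalar sigma calibrated with
    :func:`calibrate_noise_sd`.
    """
    if not 0.0 < abs(rho) < 1.0:
        raise ValueError("rho must be in (0, 1) in magnitude")
    return np.abs(beta) * np.asarray(depth_sd, dtype=np.float64) * \
        np.sqrt(1.0 / rho**2 - 1.0)


def calibrate_noise_sd(depth: VertexMetric, patches: list[np.ndarray],
                       beta: float, target_mean_rho: float) -> float:
    """Scalar noise s.d. whose patch-mean planted rho equals the target.

    With homoscedastic vertex noise the planted within-patch correlation
    is exactly ``planted_rho(beta, sd_patch, sigma)`` per patch, but
    varies across patches with the local depth spread.  This solves (by
    bisection on the monotone map sigma -> mean rho) for the sigma whose
    *mean* planted rho over all patches with non-degenerate depth equals
    ``target_mean_rho``; coupling-recovery experiments then have an exact
    analytic target for the bin-mean r.
    """
    from scipy.optimize import brentq

    sd = patch_depth_sd(depth, patches)
    sd = sd[sd > 0]
    if len(sd) == 0:
        raise ValueError("depth field has no patches with non-zero variance")
    target = abs(target_mean_rho)
    if not 0.0 < target < 1.0:
        raise ValueError("target_mean_rho must be in (0, 1) in magnitude")

    def mean_rho(sigma: float) -> float:
        return float(np.mean(np.abs(planted_rho(beta, sd, sigma))))

    hi = float(np.abs(beta) * sd.max() * np.sqrt(1.0 / target**2 - 1.0)) * 10
    lo = hi * 1e-12
    if mean_rho(lo) < target:
        raise ValueError("target mean rho unreachable (depth too flat)")
    return float(brentq(lambda s: mean_rho(s) - target, lo, hi, xtol=1e-12,
                        rtol=1e-12))


# -------------------------------------------------------- vertex-level route

def plant_vertex_metrics(
    depth_target: VertexMetric,
    ga: float,
    beta: float,
    noise_sd: np.ndarray | float,
    rng: np.random.Generator,
) -> tuple[VertexMetric, VertexMetric]:
    """Plant SP and CP tissue-fraction metrics directly on the template.

    ``metric_v = base(ga) + beta * depth_target_v + eps_v`` with
    independent Gaussian noise (scalar or per-vertex sigma), clipped to
    [0, 1].  Returns (sp, cp).
    """
    d = depth_target.values
    sigma = np.broadcast_to(np.asarray(noise_sd, dtype=np.float64), d.shape)
    out = []
    for side in ("sp", "cp"):
        eps = rng.standard_normal(d.shape) * sigma
        vals = base_fraction(ga, side) + beta * d + eps
        vals = np.clip(vals, 0.0, 1.0)
        out.append(VertexMetric(vals, depth_target.mask.copy(),
                                name=f"{side}_tissue_fraction"))
    return out[0], out[1]


def base_fraction(ga: float, side: str) -> float:
    """Baseline tissue fraction vs GA.

    CP: linear 0.35 at 24 w to 0.55 at 36 w.  SP: 0.05 below CP until
    30 w, then a steeper (doubled) slope, mirroring the late subplate
    maturation spurt.
    """
    cp_slope = (0.55 - 0.35) / (GA_MAX - GA_MIN)
    cp = 0.35 + cp_slope * (ga - GA_MIN)
    if side == "cp":
        return cp
    sp30 = 0.35 + cp_slope * (30.0 - GA_MIN) - 0.05
    if ga <= 30.0:
        return cp - 0.05
    return sp30 + 2.0 * cp_slope * (ga - 30.0)


# -------------------------------------------------------- volume-level route

def plant_microstructure(
    template: Mesh,
    spec: FoldSpec,
    ga: float,
    beta: float,
    noise_sd: np.ndarray | float,
    grid: GridSpec,
    seed: int | np.random.Generator,
    shell_mm: float = 2.0,
    ga_max: float = GA_MAX,
    depth_future: VertexMetric | None = None,
    mesh: Mesh | None = None,
) -> FractionMaps:
    """Paint coupled tissue/fluid-fraction volumes around the folded surface.

    Voxels within ``shell_mm`` of the subject's surface (along the local
    normal) form the SP (inside) and CP (outside) shells; their tissue
    fraction is ``base(ga) + beta * future_depth(nearest vertex) + eps``
    clipped to [0, 1], where the future depth is the sulcal depth of the
    fully folded (``ga_max``) surface.  ``noise_sd`` may be scalar or
    per-vertex (values are looked up at the nearest vertex, so a
    matched-noise profile carries over to the volume).  Deep interior
    voxels get the SP baseline; exterior voxels beyond the CP shell are
    fluid-dominated.  Fluid = 1 - tissue everywhere.
    """
    rng = np.random.default_rng(seed)
    if mesh is None:
        mesh = fold_surface(template, spec, ga)
    if depth_future is None:
        depth_future = future_depth(template, spec, ga_max)
    shape, affine = grid.build(spec.radius_mm)
    if (np.array(shape) * grid.voxel_size_mm < 2 * (spec.radius_mm + shell_mm)).any():
        raise ValueError("grid too small to cover the mesh plus ribbon")
    ii = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    world = ii @ affine[:3, :3].T + affine[:3, 3]
    tree = cKDTree(mesh.vertices)
    dist, nearest = tree.query(world)
    normals = vertex_normals(mesh)
    signed = np.einsum("ij,ij->i", world - mesh.vertices[nearest],
                       normals[nearest])
    sigma = np.broadcast_to(np.asarray(noise_sd, dtype=np.float64),
                            (template.n_vertices,))
    d_future = depth_future.values[nearest]
    in_shell = np.abs(signed) <= shell_mm
    sp_side = in_shell & (signed < 0)
    cp_side = in_shell & (signed >= 0)
    tissue = np.empty(len(world))
    eps = rng.standard_normal(len(world)) * sigma[nearest]
    tissue[sp_side] = base_fraction(ga, "sp") + beta * d_future[sp_side] \
        + eps[sp_side]
    tissue[cp_side] = base_fraction(ga, "cp") + beta * d_future[cp_side] \
        + eps[cp_side]
    interior = (~in_shell) & (signed < 0)
    exterior = (~in_shell) & (signed >= 0)
    tissue[interior] = base_fraction(ga, "sp")
    tissue[exterior] = 0.05
    tissue = np.clip(tissue, 0.0, 1.0).reshape(shape)
    return FractionMaps(tissue, 1.0 - tissue, affine)


def synth_dwi(
    fractions: FractionMaps,
    tissue_response: ResponseFunction | None = None,
    fluid_response: ResponseFunction | None = None,
    scheme: ShellScheme = DEFAULT_SCHEME,
    snr: float | None = 20.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Forward multi-shell DWI signal from fraction maps.

    Per voxel and volume ``S = w_t R_t(shell) + w_f R_f(shell)`` with the
    tissue/fluid fractions as weights, followed by Rician noise at the
    stated SNR (defined at b = 0, where the noiseless signal is 1).
    ``snr=None`` disables noise.
    """
    if tissue_response is None:
        tissue_response = default_tissue_response(scheme.n_shells)
    if fluid_response is None:
        fluid_response = default_fluid_response(scheme.shells)
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    shells = scheme.shells
    shell_index = np.searchsorted(shells, scheme.bvals)
    rt = tissue_response.amplitudes[shell_index]  # per volume
    rf = fluid_response.amplitudes[shell_index]
    wt = np.nan_to_num(fractions.tissue, nan=0.0)
    wf = np.nan_to_num(fractions.fluid, nan=0.0)
    signal = wt[..., None] * rt + wf[..., None] * rf
    if snr is None:
        return signal
    sigma = 1.0 / snr
    n1 = rng.standard_normal(signal.shape) * sigma
    n2 = rng.standard_normal(signal.shape) * sigma
    return np.sqrt((signal + n1) ** 2 + n2**2)


# ------------------------------------------------------------------ cohort

def _subject_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent per-subject stream keyed on (master seed, index)."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, index)))


def simulate_cohort(
    n_subjects: int,
    ga_range: tuple[float, float] = (GA_MIN, GA_MAX),
    fold_spec: FoldSpec | None = None,
    beta: float = -0.02,
    noise_sd: np.ndarray | float = 0.02,
    master_seed: int = 0,
    template_level: int = 4,
    observation: str = "vertex",
    grid: GridSpec | None = None,
    snr: float | None = 20.0,
    ga_values: np.ndarray | None = None,
    depth_target: str = "own",
) -> list[SubjectPhantom]:
    """Generate an in-memory synthetic cohort.

    GA is sampled uniformly over ``ga_range`` (or taken from
    ``ga_values``).  ``observation`` selects the route: ``"vertex"``
    plants SP/CP metrics directly on the template (exact analytic
    coupling calibration); ``"volume"`` paints fraction volumes;
    ``"dwi"`` additionally simulates the multi-shell signal.
    ``depth_target`` chooses what the metric is coupled to: each
    subject's ``"own"`` measured sulcal depth, or the ``"future"``
    (fully folded, GA 36) depth as in the age-mismatched scenario.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if observation not in ("vertex", "volume", "dwi"):
        raise ValueError(f"unknown observation route {observation!r}")
    if fold_spec is None:
        fold_spec = default_fold_spec()
    if grid is None:
        grid = GridSpec()
    template = icosphere(template_level)
    # GA draws use their own stream so per-subject noise streams are
    # unaffected by cohort size
    ga_rng = np.random.default_rng(
        np.random.SeedSequence((master_seed, 1_000_003)))
    if ga_values is None:
        ga_values = ga_rng.uniform(*ga_range, size=n_subjects)
    else:
        ga_values = np.asarray(ga_values, dtype=np.float64)
        if len(ga_values) != n_subjects:
            raise ValueError("ga_values length must equal n_subjects")
    d_future = future_depth(template, fold_spec)
    subjects = []
    for i in range(n_subjects):
        ga = float(ga_values[i])
        rng = _subject_rng(master_seed, i)
        mesh = fold_surface(template, fold_spec, ga)
        depth = sulcal_depth(mesh)
        target = depth if depth_target == "own" else d_future
        truth = {
            "ga": ga,
            "beta": beta,
            "noise_sd": (noise_sd.tolist() if isinstance(noise_sd, np.ndarray)
                         else noise_sd),
            "master_seed": master_seed,
            "index": i,
            "observation": observation,
            "depth_target": depth_target,
        }
        subject = SubjectPhantom(subject_id=f"sub-{i:03d}", ga=ga, mesh=mesh,
                                 depth=depth, truth=truth)
        if observation == "vertex":
            subject.sp_metric, subject.cp_metric = plant_vertex_metrics(
                target, ga, beta, noise_sd, rng)
        else:
            fm = plant_microstructure(
                template, fold_spec, ga, beta, noise_sd, grid, rng,
                depth_future=target, mesh=mesh)
            subject.fraction_maps = fm
            if observation == "dwi":
                subject.dwi = synth_dwi(fm, snr=snr, seed=rng)
                subject.truth["snr"] = snr
        subjects.append(subject)
    return subjects


def make_cohort(
    out_dir: str | Path,
    n_subjects: int,
    **kwargs,
) -> pd.DataFrame:
    """Generate a cohort and write all artefacts to a run directory.

    Writes ``manifest.csv`` plus, per subject, the folded mesh (PLY), the
    sulcal depth and planted metrics (CSV), fraction/DWI NIfTI volumes
    with a bval sidecar where applicable, and a ``truth.json``.  Returns
    the manifest DataFrame.  The same master seed reproduces the cohort
    bit-identically.
    """
    from fetalfold.io import write_mesh

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = simulate_cohort(n_subjects, **kwargs)
    rows = []
    for s in subjects:
        sdir = out_dir / s.subject_id
        sdir.mkdir(exist_ok=True)
        write_mesh(s.mesh, sdir / "surface.ply")
        s.depth.to_csv(sdir / "sulcal_depth.csv")
        row = {"subject_id": s.subject_id, "ga_weeks": s.ga,
               "surface": str(sdir / "surface.ply"),
               "sulcal_depth": str(sdir / "sulcal_depth.csv")}
        if s.sp_metric is not None:
            s.sp_metric.to_csv(sdir / "sp_tissue_fraction.csv")
            s.cp_metric.to_csv(sdir / "cp_tissue_fraction.csv")
            row["sp_metric"] = str(sdir / "sp_tissue_fraction.csv")
            row["cp_metric"] = str(sdir / "cp_tissue_fraction.csv")
        if s.fraction_maps is not None:
            s.fraction_maps.save(sdir / "tissue_fraction.nii.gz",
                                 sdir / "fluid_fraction.nii.gz")
            row["tissue_fraction"] = str(sdir / "tissue_fraction.nii.gz")
            row["fluid_fraction"] = str(sdir / "fluid_fraction.nii.gz")
        if s.dwi is not None:
            import nibabel as nib

            nib.save(nib.Nifti1Image(s.dwi.astype(np.float32),
                                     s.fraction_maps.affine),
                     str(sdir / "dwi.nii.gz"))
            np.savetxt(sdir / "dwi.bval", DEFAULT_SCHEME.bvals[None, :],
                       fmt="%g")
            row["dwi"] = str(sdir / "dwi.nii.gz")
            row["bval"] = str(sdir / "dwi.bval")
        with open(sdir / "truth.json", "w") as fh:
            json.dump(s.truth, fh, indent=1, sort_keys=True)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


__all__ = [
    "GA_MIN",
    "GA_MAX",
    "FoldMode",
    "FoldSpec",
    "GridSpec",
    "SubjectPhantom",
    "default_fold_spec",
    "fold_surface",
    "future_depth",
    "planted_rho",
    "patch_depth_sd",
    "matched_noise_sd",
    "plant_vertex_metrics",
    "base_fraction",
    "plant_microstructure",
    "synth_dwi",
    "simulate_cohort",
    "make_cohort",
]
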