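"""Two-compartment tissue/fluid decomposition of multi-shell diffusion signal.

The multi-shell DWI signal (b = 0, 400, 1000 s/mm^2 in the reference
acquisition) is reduced to per-shell spherical means and decomposed per
voxel into an anisotropic "tissue-like" and an isotropic "fluid-like"
component by non-negative least squares against two per-shell response
functions.  The non-negative weights, normalised to unit sum, are the
tissue and fluid *fractions* analysed downstream.

This is the l = 0 (spherical-mean) special case of multi-shell
multi-tissue deconvolution: it determines the compartment fractions
without estimating fibre orientations, which are not used in the coupling
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class DecompositionError(ValueError):
    pass


class DegenerateDesignError(DecompositionError):
    """Raised when the two responses are (near-)proportional and the
    per-voxel weights are not identifiable."""


@dataclass(frozen=True)
class ShellScheme:
    """Multi-shell acquisition scheme: per-volume b-values grouped into shells.

    ``shells`` lists the unique b-values (s/mm^2) in increasing order;
    ``counts`` the number of volumes per shell.
    """

    bvals: np.ndarray  # one b-value per volume

    def __post_init__(self) -> None:
        b = np.asarray(self.bvals, dtype=np.float64)
        if b.ndim != 1 or b.size == 0:
            raise DecompositionError("bvals must be a non-empty 1-D sequence")
        if np.any(b < 0):
            raise DecompositionError("b-values must be non-negative")
        object.__setattr__(self, "bvals", b)

    @classmethod
    def from_shells(cls, shells: list[tuple[float, int]]) -> "ShellScheme":
        """Build from (b_value, direction_count) pairs, increasing b."""
        bs = [b for b, _ in shells]
        if sorted(bs) != bs or len(set(bs)) != len(bs):
            raise DecompositionError("shell b-values must be strictly increasing")
        if any(c <= 0 for _, c in shells):
            raise DecompositionError("shell counts must be positive")
        bvals = np.concatenate([np.full(c, b, dtype=np.float64) for b, c in shells])
        return cls(bvals)

    @classmethod
    def from_bval_file(cls, path: str | Path) -> "ShellScheme":
        """FSL-style bval sidecar: whitespace-separated values, one per volume."""
        return cls(np.loadtxt(str(path)).ravel())

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals)

    @property
    def counts(self) -> np.ndarray:
        return np.array([(self.bvals == b).sum() for b in self.shells])

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    def volume_indices(self, b: float) -> np.ndarray:
        return np.nonzero(self.bvals == b)[0]


DEFAULT_SCHEME = ShellScheme.from_shells([(0.0, 15), (400.0, 46), (1000.0, 80)])


@dataclass(frozen=True)
class ResponseFunction:
    """Per-shell mean signal amplitude of one pure compartment.

    Amplitudes are normalised so that the b = 0 entry is 1 (the
    unattenuated signal).
    """

    amplitudes: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=np.float64)
        if np.any(a <= 0):
            raise DecompositionError("response amplitudes must be positive")
        object.__setattr__(self, "amplitudes", a / a[0])


def default_tissue_response(n_shells: int = 3) -> ResponseFunction:
    """Synthetic-mode tissue response: moderately attenuated anisotropic
    tissue, per-shell means (1, 0.80, 0.55)."""
    amps = np.array([1.0, 0.80, 0.55])[:n_shells]
    return ResponseFunction(amps, name="tissue")


def default_fluid_response(shells: np.ndarray | None = None,
                           diffusivity: float = 3.0e-3) -> ResponseFunction:
    """Free-water (CSF-like) response: mono-exponential decay
    exp(-b * D) with D = 3.0e-3 mm^2/s."""
    if shells is None:
        shells = np.array([0.0, 400.0, 1000.0])
    return ResponseFunction(np.exp(-np.asarray(shells) * diffusivity), name="fluid")


@dataclass
class FractionMaps:
    """Co-registered tissue- and fluid-fraction volumes (unit sum per voxel).

    ``mask`` flags voxels where the fit was valid; outside the mask both
    fractions are NaN.
    """

    tissue: np.ndarray
    fluid: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue, dtype=np.float64)
        self.fluid = np.asarray(self.fluid, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.tissue.shape != self.fluid.shape:
            raise DecompositionError("tissue and fluid volumes must share shape")
        if self.affine.shape != (4, 4):
            raise DecompositionError("affine must be 4x4")
        if self.mask is None:
            self.mask = np.isfinite(self.tissue) & np.isfinite(self.fluid)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def save(self, tissue_path: str | Path, fluid_path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.tissue.astype(np.float32), self.affine),
                 str(tissue_path))
        nib.save(nib.Nifti1Image(self.fluid.astype(np.float32), self.affine),
                 str(fluid_path))

    @classmethod
    def load(cls, tissue_path: str | Path, fluid_path: str | Path) -> "FractionMaps":
        import nibabel as nib

        t = nib.load(str(tissue_path))
        f = nib.load(str(fluid_path))
        if not np.allclose(t.affine, f.affine):
            raise DecompositionError("tissue and fluid volumes have different affines")
        return cls(np.asarray(t.dataobj, dtype=np.float64),
                   np.asarray(f.dataobj, dtype=np.float64), t.affine)


# ------------------------------------------------------------------ fitting

def shell_means(dwi: np.ndarray, scheme: ShellScheme) -> np.ndarray:
    """Spherical-mean reduction: per-voxel arithmetic mean over each shell.

    ``dwi`` is (..., n_volumes); returns (..., n_shells) in increasing-b
    order.
    """
    dwi = np.asarray(dwi, dtype=np.float64)
    if dwi.shape[-1] != scheme.n_volumes:
        raise DecompositionError(
            f"volume count {dwi.shape[-1]} does not match scheme "
            f"({scheme.n_volumes})"
        )
    out = np.empty(dwi.shape[:-1] + (scheme.n_shells,))
    for i, b in enumerate(scheme.shells):
        out[..., i] = dwi[..., scheme.volume_indices(b)].mean(axis=-1)
    return out


def estimate_responses(
    means: np.ndarray, tissue_mask: np.ndarray, fluid_mask: np.ndarray
) -> tuple[ResponseFunction, ResponseFunction]:
    """Group response functions from tissue and fluid reference masks.

    Averages the per-shell means over each mask (e.g. mature white matter
    for tissue, ventricles for fluid) and rescales each response so its
    b = 0 amplitude is 1.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    fluid_mask = np.asarray(fluid_mask, dtype=bool)
    if not tissue_mask.any() or not fluid_mask.any():
        raise DecompositionError("response masks must be non-empty")
    if np.any(tissue_mask & fluid_mask):
        raise DecompositionError("tissue and fluid masks must be disjoint")
    t = means[tissue_mask].mean(axis=0)
    f = means[fluid_mask].mean(axis=0)
    return ResponseFunction(t, name="tissue"), ResponseFunction(f, name="fluid")


def fit_fractions(
    means: np.ndarray,
    tissue_response: ResponseFunction,
    fluid_response: ResponseFunction,
    affine: np.ndarray | None = None,
) -> FractionMaps:
    """Per-voxel non-negative two-compartment fit, normalised to unit sum.

    Solves ``min || S - w_t R_t - w_f R_f ||`` with ``w >= 0`` per voxel.
    With two columns the NNLS optimum is either the unconstrained solution
    (when feasible) or the better of the two single-compartment boundary
    solutions, so the fit is computed in closed form, vectorised over
    voxels.  Fractions are ``w / (w_t + w_f)``; all-zero voxels are masked
    invalid.  Negative shell means (possible after noise) are clipped to 0
    before fitting.
    """
    means = np.asarray(means, dtype=np.float64)
    n_shells = means.shape[-1]
    rt = tissue_response.amplitudes
    rf = fluid_response.amplitudes
    if len(rt) != n_shells or len(rf) != n_shells:
        raise DecompositionError("response length does not match shell count")
    if n_shells < 2:
        raise DecompositionError("need at least as many shells as compartments (2)")
    gtt = float(rt @ rt)
    gff = float(rf @ rf)
    gtf = float(rt @ rf)
    det = gtt * gff - gtf**2
    if det <= 1e-12 * gtt * gff:
        raise DegenerateDesignError(
            "tissue and fluid responses are (near-)proportional; "
            "weights are not identifiable"
        )
    s = np.clip(means, 0.0, None)
    flat = s.reshape(-1, n_shells)
    ct = flat @ rt
    cf = flat @ rf
    # unconstrained 2x2 solution
    wt = (gff * ct - gtf * cf) / det
    wf = (gtt * cf - gtf * ct) / det
    infeasible = (wt < 0) | (wf < 0)
    if np.any(infeasible):
        # boundary candidates: one compartment only, clamped at zero
        wt_only = np.clip(ct[infeasible] / gtt, 0.0, None)
        wf_only = np.clip(cf[infeasible] / gff, 0.0, None)
        # residual^2 = |S|^2 - 2 w.c + w G w (|S|^2 common; compare the rest)
        res_t = -2 * wt_only * ct[infeasible] + wt_only**2 * gtt
        res_f = -2 * wf_only * cf[infeasible] + wf_only**2 * gff
        use_t = res_t <= res_f
        wt_b = np.where(use_t, wt_only, 0.0)
        wf_b = np.where(use_t, 0.0, wf_only)
        wt[infeasible] = wt_b
        wf[infeasible] = wf_b
    total = wt + wf
    valid = total > 0
    tissue = np.full(len(flat), np.nan)
    fluid = np.full(len(flat), np.nan)
    tissue[valid] = wt[valid] / total[valid]
    fluid[valid] = wf[valid] / total[valid]
    shape = means.shape[:-1]
    if affine is None:
        affine = np.eye(4)
    return FractionMaps(
        tissue.reshape(shape), fluid.reshape(shape), affine, valid.reshape(shape)
    )


def load_dwi(nifti_path: str | Path, bval_path: str | Path):
    """Load a 4-D DWI NIfTI plus its FSL-style bval sidecar.

    Returns ``(data, affine, scheme)``.
    """
    import nibabel as nib

    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise DecompositionError("DWI volume must be 4-D")
    scheme = ShellScheme.from_bval_file(bval_path)
    if data.shape[-1] != scheme.n_volumes:
        raise DecompositionError("bval count does not match volume count")
    return data, img.affine, scheme


__all__ = [
    "DecompositionError",
    "DegenerateDesignError",
    "ShellScheme",
    "DEFAULT_SCHEME",
    "ResponseFunction",
    "default_tissue_response",
    "default_fluid_response",
    "FractionMaps",
    "shell_means",
    "estimate_responses",
    "fit_fractions",
    "load_dwi",
]
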