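"""Per-vertex scalar fields on the template surface, with missing-data mask.

A :class:`VertexMetric` carries one scalar per template vertex (sulcal
depth, SP/CP tissue fraction, ...) plus a validity mask.  Masked-out
entries are stored as NaN and excluded from all downstream statistics.
I/O: CSV (``vertex_index,value,mask``) and GIFTI functional files (invalid
vertices encoded as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class VertexMetric:
    values: np.ndarray
    mask: np.ndarray | None = None
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).copy()
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
        if self.mask.shape != self.values.shape or self.values.ndim != 1:
            raise ValueError("values and mask must be 1-D arrays of equal length")
        self.mask &= np.isfinite(self.values)
        self.values[~self.mask] = np.nan

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "vertex_index": np.arange(len(self.values)),
                "value": self.values,
                "mask": self.mask.astype(int),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "", units: str = "") -> "VertexMetric":
        df = pd.read_csv(path)
        values = df["value"].to_numpy(dtype=np.float64)
        mask = df["mask"].to_numpy().astype(bool)
        return cls(values, mask, name=name, units=units)

    def to_gifti(self, path: str | Path) -> None:
        import nibabel as nib

        data = self.values.astype(np.float32)
        darr = nib.gifti.GiftiDataArray(
            data, intent="NIFTI_INTENT_NONE", datatype="NIFTI_TYPE_FLOAT32"
        )
        img = nib.gifti.GiftiImage(darrays=[darr])
        img.meta["Name"] = self.name
        img.meta["Units"] = self.units
        nib.save(img, str(path))

    @classmethod
    def from_gifti(cls, path: str | Path) -> "VertexMetric":
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.darrays[0].data, dtype=np.float64)
        meta = dict(img.meta)
        return cls(values, name=meta.get("Name", ""), units=meta.get("Units", ""))


__all__ = ["VertexMetric"]
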