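"""Mesh file I/O: PLY (ASCII / binary little-endian) and GIFTI surfaces.

Vertex coordinates are world mm throughout.  PLY reading/writing is
delegated to :mod:`trimesh` (with ``process=False`` so vertex order, and
hence template correspondence, is preserved); GIFTI goes through
:mod:`nibabel`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from fetalfold.surface import Mesh


def write_mesh(mesh: Mesh, path: str | Path, binary: bool = True) -> None:
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".ply"):
        _write_ply(mesh, path, binary=binary)
    elif suffix.endswith(".gii"):
        _write_gifti(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")


def read_mesh(path: str | Path) -> Mesh:
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".ply"):
        return _read_ply(path)
    if suffix.endswith(".gii"):
        return _read_gifti(path)
    raise ValueError(f"unsupported mesh format: {path.name}")


def _write_ply(mesh: Mesh, path: Path, binary: bool) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    encoding = "binary" if binary else "ascii"
    tm.export(str(path), file_type="ply", encoding=encoding)


def _read_ply(path: Path) -> Mesh:
    import trimesh

    tm = trimesh.load(str(path), file_type="ply", process=False)
    return Mesh(np.asarray(tm.vertices, dtype=np.float64),
                np.asarray(tm.faces, dtype=np.int64))


def _write_gifti(mesh: Mesh, path: Path) -> None:
    import nibabel as nib

    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32),
        intent="NIFTI_INTENT_POINTSET",
        datatype="NIFTI_TYPE_FLOAT32",
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32),
        intent="NIFTI_INTENT_TRIANGLE",
        datatype="NIFTI_TYPE_INT32",
    )
    img = nib.gifti.GiftiImage(darrays=[coords, tris])
    hemi = mesh.metadata.get("hemisphere")
    if hemi:
        img.meta["AnatomicalStructurePrimary"] = hemi
    nib.save(img, str(path))


def _read_gifti(path: Path) -> Mesh:
    import nibabel as nib

    img = nib.load(str(path))
    coords = None
    faces = None
    for da in img.darrays:
        if da.intent == 1008:  # POINTSET
            coords = np.asarray(da.data, dtype=np.float64)
        elif da.intent == 1009:  # TRIANGLE
            faces = np.asarray(da.data, dtype=np.int64)
    if coords is None or faces is None:
        raise ValueError(f"{path} lacks POINTSET/TRIANGLE arrays")
    meta = dict(img.meta)
    md = {}
    if "AnatomicalStructurePrimary" in meta:
        md["hemisphere"] = meta["AnatomicalStructurePrimary"]
    return Mesh(coords, faces, md)


__all__ = ["read_mesh", "write_mesh"]
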