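"""Readers and writers for the pipeline's file formats.

Surfaces and per-vertex data are GIfTI (with a plain-text fallback for
meshes), volumes are uncompressed NIfTI-1, labelings carry a TSV
legend mapping integer codes to area names, and reports are TSV.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import gifti

from .types import AREA_CODES, AreaLabeling, SurfaceMesh, VolumeGrid

__all__ = [
    "save_mesh_gifti",
    "load_mesh_gifti",
    "save_mesh_text",
    "load_mesh_text",
    "save_vertex_arrays",
    "load_vertex_arrays",
    "save_volume",
    "load_volume",
    "save_labeling",
    "load_labeling",
    "write_label_legend",
    "sha256_file",
]


def save_mesh_gifti(mesh: SurfaceMesh, path: str | Path) -> None:
    """Mesh as GIfTI: 3-D pointset, triangles, then the flat pointset (z=0)."""
    img = gifti.GiftiImage()
    img.meta["AnatomicalStructurePrimary"] = (
        "CortexLeft" if mesh.hemisphere == "left" else "CortexRight"
    )
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            mesh.vertex_xyz.astype(np.float32), intent="NIFTI_INTENT_POINTSET",
            datatype="NIFTI_TYPE_FLOAT32",
        )
    )
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE",
            datatype="NIFTI_TYPE_INT32",
        )
    )
    flat3 = np.column_stack([mesh.vertex_flat, np.zeros(mesh.n_vertices)])
    img.add_gifti_data_array(
        gifti.GiftiDataArray(
            flat3.astype(np.float32), intent="NIFTI_INTENT_POINTSET",
            datatype="NIFTI_TYPE_FLOAT32",
        )
    )
    nib.save(img, str(path))


def load_mesh_gifti(path: str | Path) -> SurfaceMesh:
    img = nib.load(str(path))
    from nibabel.nifti1 import intent_codes

    points = [d.data for d in img.darrays if d.intent == intent_codes["pointset"]]
    faces = [d.data for d in img.darrays if d.intent == intent_codes["triangle"]]
    hemi = "left"
    if img.meta.get("AnatomicalStructurePrimary") == "CortexRight":
        hemi = "right"
    return SurfaceMesh(
        vertex_xyz=np.asarray(points[0], dtype=float),
        vertex_flat=np.asarray(points[1], dtype=float)[:, :2],
        faces=np.asarray(faces[0], dtype=int),
        hemisphere=hemi,  # type: ignore[arg-type]
    )


def save_mesh_text(mesh: SurfaceMesh, path: str | Path) -> None:
    """OFF-like plain-text mesh: counts, then x y z fx fy lines, then faces."""
    with open(path, "w") as fh:
        fh.write(f"RETMAP-MESH 1 {mesh.hemisphere}\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces}\n")
        for p, q in zip(mesh.vertex_xyz, mesh.vertex_flat):
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {q[0]:.17g} {q[1]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"{f[0]} {f[1]} {f[2]}\n")


def load_mesh_text(path: str | Path) -> SurfaceMesh:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["RETMAP-MESH", "1"]:
            raise ValueError("not a RETMAP-MESH file")
        hemi = header[2]
        nv, nf = (int(v) for v in fh.readline().split())
        rows = [fh.readline().split() for _ in range(nv)]
        vals = np.asarray(rows, dtype=float)
        faces = np.asarray([fh.readline().split() for _ in range(nf)], dtype=int)
    return SurfaceMesh(
        vertex_xyz=vals[:, :3], vertex_flat=vals[:, 3:5], faces=faces,
        hemisphere=hemi,  # type: ignore[arg-type]
    )


def save_vertex_arrays(arrays: dict[str, np.ndarray], path: str | Path) -> None:
    """Named per-vertex arrays as GIfTI data arrays.

    The GIfTI standard restricts float arrays to float32; small
    integers (labels, flags) survive exactly, and full float64
    precision is available through the NIfTI and text writers.
    """
    img = gifti.GiftiImage()
    for name, arr in arrays.items():
        da = gifti.GiftiDataArray(
            np.asarray(arr, dtype=np.float32),
            intent="NIFTI_INTENT_NONE",
            datatype="NIFTI_TYPE_FLOAT32",
        )
        da.meta["Name"] = name
        img.add_gifti_data_array(da)
    nib.save(img, str(path))


def load_vertex_arrays(path: str | Path) -> dict[str, np.ndarray]:
    img = nib.load(str(path))
    return {d.meta["Name"]: np.asarray(d.data, dtype=float) for d in img.darrays}


def save_volume(grid: VolumeGrid, path: str | Path, dtype=None) -> None:
    data = grid.values
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms((grid.voxel_size_mm,) * 3 + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_volume(path: str | Path, valid_from_nan: bool = True) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    voxel = float(np.abs(affine[0, 0]))
    if valid_from_nan and np.issubdtype(data.dtype, np.floating):
        valid = np.isfinite(data)
        while valid.ndim > 3:
            valid = valid.all(axis=-1)
    else:
        valid = np.ones(data.shape[:3], dtype=bool)
    return VolumeGrid(
        dims=tuple(data.shape[:3]),
        voxel_size_mm=voxel,
        affine=affine,
        values=data,
        valid=valid,
    )


def write_label_legend(path: str | Path) -> None:
    pd.DataFrame(
        sorted(((c, n) for n, c in AREA_CODES.items())), columns=["code", "area"]
    ).to_csv(path, sep="\t", index=False)


def save_labeling(labeling: AreaLabeling, path: str | Path) -> None:
    save_vertex_arrays(
        {
            "labels": labeling.labels.astype(float),
            "sign": labeling.sign.astype(float),
        },
        path,
    )


def load_labeling(path: str | Path, provenance: str = "automatic") -> AreaLabeling:
    arrs = load_vertex_arrays(path)
    return AreaLabeling(
        labels=arrs["labels"].astype(int),
        sign=arrs["sign"].astype(int),
        provenance=provenance,  # type: ignore[arg-type]
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
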