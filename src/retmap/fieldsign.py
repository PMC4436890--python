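"""Visual field sign computation and automatic area delineation.

The Visual Field Ratio (VFR) is the discrete Jacobian of the visual
field representation: per triangle, the signed area of the triangle's
image in the visual field divided by its signed area in the flat
cortical embedding.  Its sign is the visual field sign (mirror vs
non-mirror representation), which flips at every border between
adjacent visual areas.  Delineation proceeds by thresholding SNR and
eccentricity, partitioning the surface into sign-consistent connected
components bounded by the zero-VFR contour, selecting V1 as the
largest component, and labeling the remaining components by adjacency
walks dorsally and ventrally from V1.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .types import (
    AREA_CODES,
    BAND_ORDER,
    AreaLabeling,
    FieldSignMap,
    ParameterError,
    PhaseSNRMap,
    SurfaceMesh,
    VisualFieldMap,
)

__all__ = ["compute_vfr", "label_areas", "perturb_labeling"]

logger = logging.getLogger(__name__)

#: Canonical field signs when V1 is non-mirror (+1): the sign alternates
#: between adjacent bands.
CANONICAL_SIGNS = {"V3d": 1, "V2d": -1, "V1": 1, "V2v": -1, "V3v": 1, "V4": -1}


def compute_vfr(
    mesh: SurfaceMesh, vf: VisualFieldMap, field_space: str = "cartesian"
) -> FieldSignMap:
    """Per-triangle Visual Field Ratio.

    Vertex positions in the visual field are Cartesianized as
    (u, v) = (ecc*cos(theta), ecc*sin(theta)) (``field_space="logpolar"``
    uses (ln ecc, theta) instead); the VFR is the ratio of the signed
    area of the field-space triangle to the signed area of the
    flat-embedding triangle.  Triangles with any invalid vertex, or a
    degenerate flat triangle, are undefined.
    """
    if field_space == "cartesian":
        u = vf.eccentricity * np.cos(vf.polar_angle)
        v = vf.eccentricity * np.sin(vf.polar_angle)
    elif field_space == "logpolar":
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.log(vf.eccentricity)
        v = vf.polar_angle
    else:
        raise ParameterError(f"unknown field_space: {field_space!r}")

    f = mesh.faces
    flat_area = mesh.flat_signed_areas()
    uv = np.column_stack([u, v])[f]  # (m, 3, 2)
    e1 = uv[:, 1] - uv[:, 0]
    e2 = uv[:, 2] - uv[:, 0]
    field_area = 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])

    defined = vf.valid[f].all(axis=1) & (np.abs(flat_area) > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        vfr = np.where(defined, field_area / flat_area, np.nan)
    sign = np.zeros(f.shape[0], dtype=int)
    sign[defined] = np.sign(vfr[defined]).astype(int)
    return FieldSignMap(vfr=vfr, sign=sign, defined=defined)


def _face_adjacency(mesh: SurfaceMesh) -> np.ndarray:
    """Pairs of faces sharing an edge, shape (k, 2)."""
    f = mesh.faces
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    face_ids = np.tile(np.arange(f.shape[0]), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges_s = edges[order]
    faces_s = face_ids[order]
    same = np.all(edges_s[1:] == edges_s[:-1], axis=1)
    return np.column_stack([faces_s[:-1][same], faces_s[1:][same]])


def _smooth_vfr(vfr: np.ndarray, defined: np.ndarray, adj: np.ndarray, n_iter: int) -> np.ndarray:
    """Iterated mean over edge-adjacent triangles (defined ones only)."""
    out = np.where(defined, vfr, 0.0)
    d = defined.astype(float)
    m = vfr.shape[0]
    mat = sparse.csr_matrix(
        (
            np.ones(2 * adj.shape[0] + m),
            (
                np.concatenate([adj[:, 0], adj[:, 1], np.arange(m)]),
                np.concatenate([adj[:, 1], adj[:, 0], np.arange(m)]),
            ),
        ),
        shape=(m, m),
    )
    for _ in range(n_iter):
        num = mat @ (out * d)
        den = mat @ d
        out = np.where(den > 0, num / np.maximum(den, 1), out)
    return np.where(defined, out, np.nan)


def label_areas(
    mesh: SurfaceMesh,
    fsm: FieldSignMap,
    snr_ecc: PhaseSNRMap,
    snr_pol: PhaseSNRMap,
    vf: VisualFieldMap,
    snr_min: float = 3.0,
    ecc_bounds: tuple[float, float] = (0.2, 3.0),
    vfr_tol: float = 0.02,
    vfr_smooth_iters: int = 1,
) -> AreaLabeling:
    """Automatic delineation of V1, V2d/v, V3d/v and V4.

    Steps: (a) vertices are eligible when both smoothed SNR maps exceed
    ``snr_min`` and decoded eccentricity lies inside ``ecc_bounds``
    (the stimulated part of the field); (b) eligible triangles are
    partitioned into maximal edge-connected components of uniform VFR
    sign — triangles whose (neighbor-averaged) |VFR| falls below
    ``vfr_tol`` times the median form the zero-VFR border contour and
    belong to no component; (c) the component with the largest vertex
    count is V1; (d) remaining components are labeled by adjacency
    walks from V1 along the band (y) axis: the first opposite-sign
    component on each side is V2d/V2v, the next V3d/V3v, and the next
    ventral component beyond V3v is V4.  Components not reached within
    three steps stay unlabeled.  An empty eligible set yields an empty
    labeling, not an error.
    """
    n = mesh.n_vertices
    lo, hi = ecc_bounds
    tol = 1e-9 * max(1.0, hi)
    with np.errstate(invalid="ignore"):
        elig_v = (
            snr_ecc.defined
            & snr_pol.defined
            & (snr_ecc.snr > snr_min)
            & (snr_pol.snr > snr_min)
            & vf.valid
            & (vf.eccentricity >= lo - tol)
            & (vf.eccentricity <= hi + tol)
        )
    faces = mesh.faces
    elig_t = fsm.defined & elig_v[faces].all(axis=1)

    empty = AreaLabeling(
        labels=np.zeros(n, dtype=int),
        sign=np.zeros(n, dtype=int),
        provenance="automatic",
    )
    if not elig_t.any():
        return empty

    adj = _face_adjacency(mesh)
    vfr_s = _smooth_vfr(fsm.vfr, fsm.defined, adj, vfr_smooth_iters)
    med = np.median(np.abs(vfr_s[elig_t]))
    border = elig_t & (np.abs(vfr_s) < vfr_tol * med)
    sign_t = np.sign(vfr_s)
    core = elig_t & ~border & (sign_t != 0)
    if not core.any():
        return empty

    # connected components over same-sign edge-adjacent core triangles
    keep = (
        core[adj[:, 0]]
        & core[adj[:, 1]]
        & (sign_t[adj[:, 0]] == sign_t[adj[:, 1]])
    )
    a = adj[keep]
    m = faces.shape[0]
    g = sparse.csr_matrix(
        (np.ones(a.shape[0]), (a[:, 0], a[:, 1])), shape=(m, m)
    )
    n_comp, comp_of = connected_components(g, directed=False)
    comp_of = np.where(core, comp_of, -1)
    comp_ids = np.unique(comp_of[comp_of >= 0])

    comp_vertices = {}
    comp_centroid_y = {}
    comp_sign = {}
    for cid in comp_ids:
        tris = np.flatnonzero(comp_of == cid)
        verts = np.unique(faces[tris])
        comp_vertices[cid] = verts
        comp_centroid_y[cid] = float(mesh.vertex_flat[verts, 1].mean())
        comp_sign[cid] = int(sign_t[tris[0]])

    v1 = max(comp_ids, key=lambda c: (comp_vertices[c].size, -c))
    assignment: dict[int, str] = {v1: "V1"}

    def _walk(side: int, names: list[str]) -> None:
        # side = -1 dorsal (smaller y), +1 ventral (larger y)
        prev = v1
        for name in names:
            ref_y = comp_centroid_y[prev]
            cand = [
                c
                for c in comp_ids
                if c not in assignment
                and comp_sign[c] == -comp_sign[prev]
                and side * (comp_centroid_y[c] - ref_y) > 0
            ]
            if not cand:
                return
            dist = {c: abs(comp_centroid_y[c] - ref_y) for c in cand}
            best = min(cand, key=lambda c: (dist[c], -comp_vertices[c].size, c))
            ties = [c for c in cand if abs(dist[c] - dist[best]) < 1e-9 and c != best]
            if ties:
                logger.info(
                    "adjacency tie while labeling %s: picked larger component", name
                )
            assignment[best] = name
            prev = best

    _walk(-1, ["V2d", "V3d"])
    _walk(+1, ["V2v", "V3v", "V4"])

    # per-vertex labels: majority of incident component triangles,
    # distance ties resolved toward the more ventral (larger-y) component
    labels = np.zeros(n, dtype=int)
    signs = np.zeros(n, dtype=int)
    counts = np.zeros(n, dtype=int)
    ordered = sorted(assignment, key=lambda c: comp_centroid_y[c])
    for cid in ordered:
        name = assignment[cid]
        tris = np.flatnonzero(comp_of == cid)
        vid, cnt = np.unique(faces[tris], return_counts=True)
        better = cnt >= counts[vid]  # later (more ventral) component wins ties
        upd = vid[better]
        counts[upd] = cnt[better]
        labels[upd] = AREA_CODES[name]
        signs[upd] = comp_sign[cid]
    labels[~elig_v] = 0
    signs[~elig_v] = 0
    return AreaLabeling(labels=labels, sign=signs, provenance="automatic")


def perturb_labeling(
    labeling: AreaLabeling,
    mesh: SurfaceMesh,
    boundary_shift_mm: float,
    seed: int = 0,
) -> AreaLabeling:
    """Emulate a second, hand-drawn delineation of the same map.

    Each inter-area border is displaced along the band (y) axis by a
    smooth random offset — a low-order sinusoid mixture in x with RMS
    amplitude ``boundary_shift_mm`` — and labels are reassigned
    accordingly.  The labeled vertex set itself is unchanged (outer
    boundaries stay put).  Deterministic under ``seed``.
    """
    if boundary_shift_mm < 0:
        raise ParameterError("boundary_shift_mm must be non-negative")
    out = labeling.copy()
    out.provenance = "perturbed"
    if boundary_shift_mm == 0:
        return out

    present = [b for b in BAND_ORDER if np.any(labeling.labels == AREA_CODES[b])]
    if len(present) < 2:
        return out
    signs_by_area = {}
    for b in present:
        s = labeling.sign[labeling.labels == AREA_CODES[b]]
        signs_by_area[b] = int(s[0]) if s.size else CANONICAL_SIGNS[b]

    x = mesh.vertex_flat[:, 0]
    y = mesh.vertex_flat[:, 1]
    width = max(x.max() - x.min(), 1e-9)
    rng = np.random.default_rng(seed)

    edges = mesh.edge_list()
    binw = float(
        np.median(
            np.linalg.norm(
                mesh.vertex_flat[edges[:, 0]] - mesh.vertex_flat[edges[:, 1]], axis=1
            )
        )
    )
    col = np.round((x - x.min()) / binw).astype(int)

    labeled = labeling.labels > 0
    band_idx = np.full(mesh.n_vertices, -1)
    for k, b in enumerate(present):
        band_idx[labeling.labels == AREA_CODES[b]] = k

    n_borders = len(present) - 1
    offsets = np.zeros((n_borders, mesh.n_vertices))
    for i in range(n_borders):
        coef = rng.normal(size=3)
        ph = rng.uniform(0, 2 * np.pi, size=3)
        g = np.zeros_like(x)
        for j in range(3):
            g += coef[j] * np.sin(2 * np.pi * (j + 1) * (x - x.min()) / width + ph[j])
        rms = np.sqrt(np.mean(g[labeled] ** 2)) if labeled.any() else 1.0
        offsets[i] = g / max(rms, 1e-12) * boundary_shift_mm

    # base boundary per column: midpoint between the two bands' extents
    global_base = np.zeros(n_borders)
    for i in range(n_borders):
        lo_band = labeled & (band_idx == i)
        hi_band = labeled & (band_idx == i + 1)
        global_base[i] = 0.5 * (y[lo_band].max() + y[hi_band].min())

    new_band = np.full(mesh.n_vertices, -1)
    for c in np.unique(col[labeled]):
        in_col = labeled & (col == c)
        base = global_base.copy()
        for i in range(n_borders):
            lo_band = in_col & (band_idx == i)
            hi_band = in_col & (band_idx == i + 1)
            if lo_band.any() and hi_band.any():
                base[i] = 0.5 * (y[lo_band].max() + y[hi_band].min())
        bounds = base + np.array(
            [offsets[i][in_col].mean() for i in range(n_borders)]
        )
        bounds = np.maximum.accumulate(bounds)  # keep band order
        new_band[in_col] = np.searchsorted(bounds, y[in_col], side="left")

    for k, b in enumerate(present):
        sel = labeled & (new_band == k)
        out.labels[sel] = AREA_CODES[b]
        out.sign[sel] = signs_by_area[b]
    return out
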