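"""Readers and writers for the surface/connectome file formats.

Surfaces are accepted as GIFTI (``.gii``) or FreeSurfer binary geometry;
parcellations as FreeSurfer ``.annot`` or two-column TSV; tractograms as TRK
or TCK (via nibabel) or plain endpoint TSV tables.  Connectivity matrices
use a simple portable container: a ``.npy`` array plus a JSON sidecar that
records the grid checksum and the parameters that produced the matrix, so a
matrix can never be silently combined with the wrong grid.

Vertex indexing is 0-based at every file boundary.  Grid directories store
the two down-sampled hemisphere meshes (GIFTI), the joint mask and the
full-resolution index maps as plain text (one entry per line).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grid import HemispherePairGrid, build_grid
from .mesh import SphereMesh

__all__ = [
    "read_surface", "write_surface_gifti", "read_parcellation",
    "read_matrix", "write_matrix", "read_endpoints_tsv",
    "write_endpoints_tsv", "read_tractogram", "write_grid", "read_grid",
    "read_confounds",
]


# -- surfaces --------------------------------------------------------------

def read_surface(path, hemisphere: str = "left") -> SphereMesh:
    """Load a spherical surface mesh from GIFTI or FreeSurfer geometry.

    Vertices on a sphere of radius r (FreeSurfer registration spheres use
    r = 100) are normalized to the unit sphere with the scale recorded on
    the mesh.  Unknown formats raise with the detected magic bytes.
    """
    import nibabel as nib

    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        verts = tris = None
        for arr in img.darrays:
            code = arr.intent
            if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = np.asarray(arr.data, dtype=float)
            elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                tris = np.asarray(arr.data, dtype=np.int64)
        if verts is None or tris is None:
            raise ValueError(f"{path}: GIFTI file lacks pointset/triangle "
                             "arrays")
        return SphereMesh(vertices=verts, triangles=tris,
                          hemisphere=hemisphere)
    try:
        verts, tris = nib.freesurfer.read_geometry(str(path))
    except Exception:
        with open(path, "rb") as fh:
            magic = fh.read(8)
        raise ValueError(f"{path}: unrecognized surface format "
                         f"(magic bytes {magic!r})") from None
    return SphereMesh(vertices=np.asarray(verts, float),
                      triangles=np.asarray(tris, np.int64),
                      hemisphere=hemisphere)


def write_surface_gifti(mesh: SphereMesh, path):
    import nibabel as nib

    verts = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32),
        intent="NIFTI_INTENT_POINTSET")
    tris = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32),
        intent="NIFTI_INTENT_TRIANGLE")
    nib.save(nib.gifti.GiftiImage(darrays=[verts, tris]), str(path))


# -- grids -----------------------------------------------------------------

def _load_grid_files(d: Path) -> HemispherePairGrid:
    left = read_surface(d / "left.surf.gii", "left")
    right = read_surface(d / "right.surf.gii", "right")
    mask = np.loadtxt(d / "mask.txt", dtype=int).astype(bool)
    lidx = np.loadtxt(d / "left_full_index.txt", dtype=int)
    ridx = np.loadtxt(d / "right_full_index.txt", dtype=int)
    return build_grid(left, right, mask=np.atleast_1d(mask),
                      left_full_index=np.atleast_1d(lidx),
                      right_full_index=np.atleast_1d(ridx))


def write_grid(grid: HemispherePairGrid, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_surface_gifti(grid.left, out / "left.surf.gii")
    write_surface_gifti(grid.right, out / "right.surf.gii")
    np.savetxt(out / "mask.txt", grid.mask.astype(int), fmt="%d")
    np.savetxt(out / "left_full_index.txt", grid.left_full_index, fmt="%d")
    np.savetxt(out / "right_full_index.txt", grid.right_full_index, fmt="%d")
    # GIFTI stores float32 geometry, so the checksum is taken over the
    # canonical re-loaded grid: any consumer of these files agrees on it
    canonical = _load_grid_files(out)
    meta = {"n_left": grid.n_left, "n_right": grid.n_right,
            "n_masked": grid.n_masked, "checksum": canonical.checksum()}
    (out / "grid.json").write_text(json.dumps(meta, indent=2))


def read_grid(grid_dir) -> HemispherePairGrid:
    d = Path(grid_dir)
    grid = _load_grid_files(d)
    meta = json.loads((d / "grid.json").read_text())
    if meta.get("checksum") not in (None, grid.checksum()):
        raise ValueError(f"{d}: grid files do not match recorded checksum")
    return grid


# -- parcellations ---------------------------------------------------------

def read_parcellation(path, grid: HemispherePairGrid):
    """Load ROI labels as a :class:`~sbci.coupling.Parcellation`.

    Supported formats:

    * two-column TSV ``joint_grid_vertex_index<TAB>label`` over all grid
      vertices (masked-out entries are ignored; missing vertices are
      unassigned);
    * FreeSurfer ``.annot`` giving one label per *full-resolution* vertex
      of a single hemisphere — pass a pair ``(lh_annot, rh_annot)`` to
      cover both; labels are carried to grid vertices through the
      full-resolution index maps.
    """
    from .coupling import Parcellation, UNASSIGNED

    labels_joint = np.full(grid.n_total, UNASSIGNED, dtype=np.int64)
    if isinstance(path, (tuple, list)):
        import nibabel as nib

        offset = 0
        for p, idx_map, n in ((path[0], grid.left_full_index, grid.n_left),
                              (path[1], grid.right_full_index,
                               grid.n_right)):
            annot_labels, _, _ = nib.freesurfer.read_annot(str(p))
            if idx_map.max() >= len(annot_labels):
                raise ValueError(
                    f"{p}: annot has {len(annot_labels)} vertices but the "
                    f"grid references index {int(idx_map.max())}")
            lab = annot_labels[idx_map].astype(np.int64)
            # annot convention: -1/0 often mark unknown; keep -1 unassigned
            labels_joint[offset:offset + n] = lab
            offset += n
        # make hemispheres disjoint label spaces
        rh = slice(grid.n_left, grid.n_total)
        valid = labels_joint[rh] != UNASSIGNED
        labels_joint[rh][valid] += labels_joint[:grid.n_left].max() + 1
    else:
        data = np.loadtxt(path, dtype=np.int64, ndmin=2)
        if data.shape[1] != 2:
            raise ValueError(f"{path}: expected two columns (vertex, label)")
        if data[:, 0].max() >= grid.n_total or data[:, 0].min() < 0:
            raise ValueError(
                f"{path}: vertex index out of range for a grid of "
                f"{grid.n_total} vertices")
        labels_joint[data[:, 0]] = data[:, 1]
    return Parcellation(labels=labels_joint[grid.mask], grid=grid)


def write_parcellation_tsv(parc, path):
    grid = parc.grid
    joint = np.flatnonzero(grid.mask)
    rows = np.column_stack([joint, parc.labels])
    np.savetxt(path, rows, fmt="%d", delimiter="\t")


# -- matrices --------------------------------------------------------------

def write_matrix(matrix: np.ndarray, sidecar: dict, path):
    """Write a matrix with its JSON sidecar (``<path>.json``)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(matrix))
    path.with_suffix(".npy.json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path):
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    matrix = np.load(path)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) \
        if sidecar_path.exists() else {}
    return matrix, sidecar


def check_grid_match(sidecar: dict, grid: HemispherePairGrid):
    cs = sidecar.get("grid_checksum")
    if cs is not None and cs != grid.checksum():
        raise ValueError("matrix was computed on a different grid "
                         f"(checksum {cs} != {grid.checksum()})")


# -- endpoints / tractograms ----------------------------------------------

_EP_HEADER = "hemi_a\txa\tya\tza\themi_b\txb\tyb\tzb"


def write_endpoints_tsv(endpoints, path):
    rows = np.column_stack([
        endpoints.hemispheres[:, 0], endpoints.positions[:, 0, :],
        endpoints.hemispheres[:, 1], endpoints.positions[:, 1, :]])
    np.savetxt(path, rows, delimiter="\t", header=_EP_HEADER, comments="",
               fmt=["%d", "%.17g", "%.17g", "%.17g",
                    "%d", "%.17g", "%.17g", "%.17g"])


def read_endpoints_tsv(path):
    from .sc import StreamlineEndpoints

    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if data.shape[1] != 8:
        raise ValueError(f"{path}: expected 8 columns "
                         "(hemi_a, xa, ya, za, hemi_b, xb, yb, zb)")
    pos = np.stack([data[:, 1:4], data[:, 5:8]], axis=1)
    pos /= np.linalg.norm(pos, axis=2, keepdims=True)
    hemi = np.stack([data[:, 0], data[:, 4]], axis=1).astype(np.int8)
    return StreamlineEndpoints(positions=pos, hemispheres=hemi)


def read_tractogram(path):
    """Load TRK/TCK streamlines as a list of (k, 3) point arrays."""
    import nibabel as nib

    tractogram = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tractogram.streamlines]


# -- tables ----------------------------------------------------------------

def read_confounds(path) -> np.ndarray:
    """Confound table: TSV with a header row, one regressor per column."""
    import pandas as pd

    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)
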