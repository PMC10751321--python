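"""Serialization: Gmsh MSH meshes, VTU fields, CSV tables, YAML/JSON configs.

Meshes travel as Gmsh MSH 2.2 ASCII with physical groups encoding the
tissue labels (2D), the lumen and outer contours (1D) and the fixed nodes
(0D), so a written mesh reads back as a fully equivalent
:class:`~athero_ifem.geometry.LabeledMesh`. Field maps are written as VTU
(XML, ASCII appended data) cell arrays for external viewers; tabular data
(frames, strains, curves) as CSV via pandas; material sets and run
configurations as YAML; results and summaries as JSON with provenance
(package version, configuration hash, seeds).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fem import StrainField
from .geometry import LabeledMesh, PlaqueGeometry
from .imaging import FramePair
from .materials import MaterialSet

__all__ = [
    "write_msh", "read_msh", "write_vtu",
    "write_geometry_json", "read_geometry_json",
    "write_materials_yaml", "read_materials_yaml",
    "write_frame_pair", "read_frame_pair",
    "strain_field_frame", "write_strain_csv", "read_strain_csv",
    "write_summary_json", "config_hash",
]


# --------------------------------------------------------------------------
# Gmsh MSH 2.2
# --------------------------------------------------------------------------

def write_msh(path, mesh: LabeledMesh) -> None:
    """Write a labeled mesh as Gmsh MSH 2.2 ASCII."""
    path = Path(path)
    labels_int, names = mesh.element_labels_int()
    phys = [(2, i + 1, n) for i, n in enumerate(names)]
    lumen_tag = len(names) + 1
    outer_tag = len(names) + 2
    fixed_tag = len(names) + 3
    phys += [(1, lumen_tag, "lumen"), (1, outer_tag, "outer"),
             (0, fixed_tag, "fixed")]

    bnd = mesh.boundary_edges()
    lumen_set = {tuple(sorted(e)) for e in mesh.lumen_edges}
    outer_edges = [e for e in bnd if tuple(sorted(e)) not in lumen_set]

    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(phys))]
    lines += [f'{dim} {tag} "{name}"' for dim, tag, name in phys]
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_nodes)]
    lines += [f"{i + 1} {x:.17g} {y:.17g} 0" for i, (x, y) in enumerate(mesh.nodes)]
    lines += ["$EndNodes", "$Elements"]
    n_elem = (mesh.n_elements + len(mesh.lumen_edges) + len(outer_edges)
              + len(mesh.fixed_nodes))
    lines.append(str(n_elem))
    eid = 1
    for n in mesh.fixed_nodes:
        lines.append(f"{eid} 15 2 {fixed_tag} {fixed_tag} {n + 1}")
        eid += 1
    for a, b in mesh.lumen_edges:
        lines.append(f"{eid} 1 2 {lumen_tag} {lumen_tag} {a + 1} {b + 1}")
        eid += 1
    for a, b in outer_edges:
        lines.append(f"{eid} 1 2 {outer_tag} {outer_tag} {a + 1} {b + 1}")
        eid += 1
    for t, li in zip(mesh.triangles, labels_int):
        lines.append(f"{eid} 2 2 {li + 1} {li + 1} "
                     f"{t[0] + 1} {t[1] + 1} {t[2] + 1}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_msh(path) -> LabeledMesh:
    """Read a labeled mesh written by :func:`write_msh`."""
    tokens = Path(path).read_text().splitlines()
    it = iter(tokens)
    phys: dict[tuple[int, int], str] = {}
    nodes = []
    tris, tri_tags = [], []
    lines_1d: list[tuple[int, int, int]] = []
    points_0d: list[tuple[int, int]] = []
    for line in it:
        if line == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                dim, tag, name = next(it).split(maxsplit=2)
                phys[(int(dim), int(tag))] = name.strip('"')
            next(it)  # $End
        elif line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append((float(parts[1]), float(parts[2])))
            next(it)
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = [int(p) for p in next(it).split()]
                etype, ntags = parts[1], parts[2]
                tags = parts[3:3 + ntags]
                conn = parts[3 + ntags:]
                if etype == 2:
                    tris.append([c - 1 for c in conn])
                    tri_tags.append(tags[0])
                elif etype == 1:
                    lines_1d.append((tags[0], conn[0] - 1, conn[1] - 1))
                elif etype == 15:
                    points_0d.append((tags[0], conn[0] - 1))
            next(it)
    labels = np.array([phys[(2, t)] for t in tri_tags], dtype=object)
    lumen_edges = [(a, b) for tag, a, b in lines_1d if phys[(1, tag)] == "lumen"]
    outer_nodes = sorted({n for tag, a, b in lines_1d
                          if phys[(1, tag)] == "outer" for n in (a, b)})
    fixed = [n for _, n in points_0d]
    return LabeledMesh(np.array(nodes), np.array(tris, dtype=np.int64), labels,
                       np.array(lumen_edges, dtype=np.int64),
                       np.array(outer_nodes, dtype=np.int64),
                       np.array(fixed, dtype=np.int64))


# --------------------------------------------------------------------------
# VTU (write-only, ASCII)
# --------------------------------------------------------------------------

def write_vtu(path, mesh: LabeledMesh, cell_data: dict | None = None,
              point_data: dict | None = None,
              coords: np.ndarray | None = None) -> None:
    """Write the mesh (and optional per-cell/per-node arrays) as ASCII VTU."""
    p = mesh.nodes if coords is None else np.asarray(coords, float)
    M, N = mesh.n_elements, mesh.n_nodes

    def data_array(name, arr, n_comp=1):
        arr = np.asarray(arr)
        body = " ".join(f"{v:.9g}" for v in arr.ravel())
        return (f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{n_comp}" format="ascii">{body}'
                f'</DataArray>')

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{N}" NumberOfCells="{M}">',
             "<Points>",
             data_array("Points", np.column_stack([p, np.zeros(N)]), 3),
             "</Points>", "<Cells>",
             '<DataArray type="Int64" Name="connectivity" format="ascii">'
             + " ".join(map(str, mesh.triangles.ravel())) + "</DataArray>",
             '<DataArray type="Int64" Name="offsets" format="ascii">'
             + " ".join(str(3 * (i + 1)) for i in range(M)) + "</DataArray>",
             '<DataArray type="UInt8" Name="types" format="ascii">'
             + " ".join(["5"] * M) + "</DataArray>",
             "</Cells>"]
    if cell_data:
        parts.append("<CellData>")
        for name, arr in cell_data.items():
            parts.append(data_array(name, arr))
        parts.append("</CellData>")
    if point_data:
        parts.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            nc = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(data_array(name, arr, nc))
        parts.append("</PointData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts) + "\n")


# --------------------------------------------------------------------------
# geometry JSON
# --------------------------------------------------------------------------

def write_geometry_json(path, geom: PlaqueGeometry) -> None:
    data = {
        "outer_contour": np.asarray(geom.outer_contour).tolist(),
        "lumen_contour": np.asarray(geom.lumen_contour).tolist(),
        "inclusions": [{"kind": k, "contour": np.asarray(c).tolist()}
                       for k, c in geom.inclusion_contours],
        "units": "mm",
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_geometry_json(path) -> PlaqueGeometry:
    data = json.loads(Path(path).read_text())
    return PlaqueGeometry(
        np.array(data["outer_contour"], dtype=float),
        np.array(data["lumen_contour"], dtype=float),
        tuple((inc["kind"], np.array(inc["contour"], dtype=float))
              for inc in data["inclusions"]),
    )


# --------------------------------------------------------------------------
# material sets
# --------------------------------------------------------------------------

def write_materials_yaml(path, materials: MaterialSet) -> None:
    Path(path).write_text(yaml.safe_dump(materials.to_dict(), sort_keys=True))


def read_materials_yaml(path) -> MaterialSet:
    return MaterialSet.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# frame pairs & strain fields (CSV)
# --------------------------------------------------------------------------

def write_frame_pair(path_csv, pair: FramePair, mesh_path: str | None = None) -> None:
    """Nodal frame data as CSV; the mesh itself travels separately as MSH."""
    df = pd.DataFrame({
        "node": np.arange(pair.mesh.n_nodes),
        "x": pair.coords_lo[:, 0], "y": pair.coords_lo[:, 1],
        "ux": pair.rel_displacements[:, 0],
        "uy": pair.rel_displacements[:, 1],
    })
    with open(path_csv, "w") as fh:
        fh.write(f"# p_lo_mmHg={pair.p_lo} p_hi_mmHg={pair.p_hi}"
                 + (f" mesh={mesh_path}" if mesh_path else "") + "\n")
        df.to_csv(fh, index=False)


def read_frame_pair(path_csv, mesh: LabeledMesh) -> FramePair:
    with open(path_csv) as fh:
        header = fh.readline().strip().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header if "=" in kv)
        df = pd.read_csv(fh)
    return FramePair(mesh=mesh,
                     coords_lo=df[["x", "y"]].to_numpy(),
                     rel_displacements=df[["ux", "uy"]].to_numpy(),
                     p_lo=float(meta["p_lo_mmHg"]), p_hi=float(meta["p_hi_mmHg"]))


_STRAIN_COLS = ("exx", "eyy", "exy", "err", "ett", "ert", "e1", "e2", "evm")


def strain_field_frame(mesh: LabeledMesh, field: StrainField) -> pd.DataFrame:
    c = mesh.centroids()
    data = {"element": np.arange(mesh.n_elements),
            "cx": c[:, 0], "cy": c[:, 1],
            "label": [str(l) for l in mesh.labels]}
    for name in _STRAIN_COLS:
        data[name] = getattr(field, name)
    return pd.DataFrame(data)


def write_strain_csv(path, mesh: LabeledMesh, field: StrainField) -> None:
    with open(path, "w") as fh:
        fh.write(f"# center={field.center[0]:.17g},{field.center[1]:.17g}\n")
        strain_field_frame(mesh, field).to_csv(fh, index=False)


def read_strain_csv(path) -> StrainField:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        cx, cy = (float(v) for v in header.split("=")[1].split(","))
        df = pd.read_csv(fh)
    center = np.array([cx, cy])
    angles = np.arctan2(df["cy"] - cy, df["cx"] - cx).to_numpy()
    f = StrainField.from_cartesian(df["exx"].to_numpy(), df["eyy"].to_numpy(),
                                   df["exy"].to_numpy(), center, angles)
    # keep the stored derived components verbatim
    for name in _STRAIN_COLS[3:]:
        setattr(f, name, df[name].to_numpy())
    return f


# --------------------------------------------------------------------------
# summaries with provenance
# --------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_summary_json(path, payload: dict, config: dict | None = None,
                       seeds: dict | None = None) -> None:
    from . import __version__

    out = dict(payload)
    out["provenance"] = {
        "package": "athero-ifem",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "seeds": seeds or {},
    }
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True,
                                     default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
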