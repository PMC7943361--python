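"""On-disk formats: VTK legacy ASCII and PLY meshes, HDF5 state histories
and parameter fields, CSV electrode tables.

All coordinates are written in mm and times in ms; conversions to the
reporting units (cm/s for conduction velocity, cm**2 for surface area)
happen at the API boundary, not in the files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mms_model import ParameterFieldSet
from .monodomain_sim import StateHistory
from .tissue import TissueDomain, make_mesh_domain, make_sheet_domain


class ParseError(ValueError):
    """Malformed file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# VTK legacy ASCII (POLYDATA) meshes with optional point data
# ---------------------------------------------------------------------------

def write_mesh_vtk(path, domain: TissueDomain, point_data: dict | None = None):
    """Write a triangulated domain as VTK legacy ASCII POLYDATA; per-node
    scalar arrays go into POINT_DATA."""
    tris = domain.elements
    if tris.shape[1] == 4:  # quads are split for the polydata file
        tris = np.concatenate([tris[:, [0, 1, 2]], tris[:, [0, 2, 3]]])
    lines = ["# vtk DataFile Version 3.0", "rotortether surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {domain.n_nodes} float"]
    for pt in domain.positions:
        lines.append(f"{pt[0]:.9g} {pt[1]:.9g} {pt[2]:.9g}")
    lines.append(f"POLYGONS {len(tris)} {4 * len(tris)}")
    for tri in tris:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    if point_data:
        lines.append(f"POINT_DATA {domain.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{x:.9g}" for x in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_vtk(path):
    """Read a VTK legacy ASCII POLYDATA triangle mesh.

    Returns (TissueDomain, point_data dict).
    """
    toks, linenos = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if ln <= 2 and line.startswith("#"):
            continue
        for tok in line.split():
            toks.append(tok)
            linenos.append(ln)
    i = 0

    def expect(word):
        nonlocal i
        if i >= len(toks) or toks[i].upper() != word:
            got = toks[i] if i < len(toks) else "<eof>"
            ln = linenos[min(i, len(linenos) - 1)] if linenos else 0
            raise ParseError(f"line {ln}: expected {word}, got {got!r}")
        i += 1

    # skip title tokens until ASCII
    while i < len(toks) and toks[i].upper() != "ASCII":
        i += 1
    expect("ASCII")
    expect("DATASET")
    expect("POLYDATA")
    expect("POINTS")
    n = int(toks[i]); i += 2  # count, dtype
    pts = np.array(toks[i:i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    expect("POLYGONS")
    m = int(toks[i]); size = int(toks[i + 1]); i += 2
    body = np.array(toks[i:i + size], dtype=int)
    i += size
    tris = []
    j = 0
    while j < len(body):
        k = body[j]
        if k != 3:
            raise ParseError(
                f"line {linenos[i - size + j]}: only triangles supported, "
                f"got a {k}-gon")
        tris.append(body[j + 1:j + 4])
        j += k + 1
    if len(tris) != m:
        raise ParseError(f"line {linenos[i - 1]}: POLYGONS count mismatch")
    point_data = {}
    while i < len(toks):
        word = toks[i].upper()
        if word == "POINT_DATA":
            i += 2
        elif word == "SCALARS":
            name = toks[i + 1]
            i += 4  # SCALARS name type ncomp
            if toks[i].upper() == "LOOKUP_TABLE":
                i += 2
            point_data[name] = np.array(toks[i:i + n], dtype=float)
            i += n
        else:
            raise ParseError(
                f"line {linenos[i]}: unsupported section {toks[i]!r}")
    return make_mesh_domain(pts, np.asarray(tris)), point_data


# ---------------------------------------------------------------------------
# ASCII PLY meshes
# ---------------------------------------------------------------------------

def write_mesh_ply(path, domain: TissueDomain):
    tris = domain.elements
    if tris.shape[1] == 4:
        tris = np.concatenate([tris[:, [0, 1, 2]], tris[:, [0, 2, 3]]])
    lines = ["ply", "format ascii 1.0",
             f"element vertex {domain.n_nodes}",
             "property float x", "property float y", "property float z",
             f"element face {len(tris)}",
             "property list uchar int vertex_indices", "end_header"]
    for pt in domain.positions:
        lines.append(f"{pt[0]:.9g} {pt[1]:.9g} {pt[2]:.9g}")
    for tri in tris:
        lines.append(f"3 {tri[0]} {tri[1]} {tri[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_ply(path):
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError("line 1: not a PLY file")
    n_vert = n_face = None
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts == ["end_header"]:
            i += 1
            break
        i += 1
    if n_vert is None or n_face is None:
        raise ParseError(f"line {i}: header lacks vertex/face counts")
    try:
        pts = np.array([lines[i + k].split()[:3] for k in range(n_vert)],
                       dtype=float)
        faces = []
        for k in range(n_face):
            parts = lines[i + n_vert + k].split()
            if int(parts[0]) != 3:
                raise ParseError(
                    f"line {i + n_vert + k + 1}: only triangles supported")
            faces.append([int(x) for x in parts[1:4]])
    except (IndexError, ValueError) as e:
        raise ParseError(f"malformed PLY body: {e}") from e
    return make_mesh_domain(pts, np.asarray(faces))


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def _dset(group, name, data):
    # track_times off so identical content yields identical files
    group.create_dataset(name, data=data, track_times=False)


def write_history_h5(path, history: StateHistory):
    with h5py.File(path, "w", track_order=True) as f:
        _dset(f, "time", history.time)
        _dset(f, "v", history.v)
        _dset(f, "h", history.h)
        f.attrs["dt"] = history.dt
        f.attrs["sample_interval"] = history.sample_interval
        f.attrs["protocol"] = history.protocol


def read_history_h5(path) -> StateHistory:
    with h5py.File(path, "r") as f:
        return StateHistory(
            time=f["time"][:], v=f["v"][:], h=f["h"][:],
            dt=float(f.attrs["dt"]),
            sample_interval=float(f.attrs["sample_interval"]),
            protocol=str(f.attrs["protocol"]))


FIELD_NAMES = ["cv_max", "apd_max", "tau_in", "tau_out", "tau_open",
               "tau_close", "v_gate", "diffusivity"]


def write_fields_h5(path, fields: ParameterFieldSet,
                    domain: TissueDomain | None = None):
    with h5py.File(path, "w", track_order=True) as f:
        for name in FIELD_NAMES:
            _dset(f, name, getattr(fields, name))
        if domain is not None:
            g = f.create_group("domain")
            g.attrs["kind"] = domain.kind
            _dset(g, "positions", domain.positions)
            _dset(g, "elements", domain.elements)
            if domain.kind == "sheet":
                g.attrs["shape"] = domain.shape
                g.attrs["spacing"] = domain.spacing


def read_fields_h5(path):
    with h5py.File(path, "r") as f:
        fields = ParameterFieldSet(**{n: f[n][:] for n in FIELD_NAMES})
        domain = None
        if "domain" in f:
            g = f["domain"]
            if g.attrs["kind"] == "sheet":
                ny, nx = (int(x) for x in g.attrs["shape"])
                domain = make_sheet_domain(nx, ny, float(g.attrs["spacing"]))
            else:
                domain = make_mesh_domain(g["positions"][:], g["elements"][:])
    return fields, domain


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

ELECTRODE_COLUMNS = ["site_id", "x_mm", "y_mm", "z_mm", "lat_ms", "erp_ms"]


def write_electrode_csv(path, table: pd.DataFrame, s2: float | None = None):
    """One CSV per pacing protocol with the canonical header.  If the table
    holds several S2 values, ``s2`` selects which one to write."""
    if s2 is not None:
        table = table[table["s2_ms"] == s2]
    out = table[ELECTRODE_COLUMNS]
    out.to_csv(path, index=False)


def read_electrode_csv(path, s2: float = np.nan) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ELECTRODE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    df["s2_ms"] = s2
    return df


def write_ps_csv(path, records: pd.DataFrame):
    records.to_csv(path, index=False,
                   columns=["t_ms", "x_mm", "y_mm", "z_mm", "chirality",
                            "track_id"])


def write_json(path, payload: dict):
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
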