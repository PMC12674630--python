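"""Labeled-mesh file I/O.

Two dialects are supported:

* VTK legacy ASCII unstructured grid (``.vtk``) with a ``POINT_DATA`` integer
  array named ``tissue`` and the envelope radius/height recorded on the title
  line — readable by ParaView and similar viewers.
* a plain ASCII table directory (``nodes.tsv`` / ``tets.tsv`` / ``labels.tsv``
  plus ``meta.tsv``) as a lowest-common-denominator fallback.

Round trips are lossless to the printed precision (coordinates are written
with 17 significant digits, i.e. exactly for float64).
"""

from __future__ import annotations

import os

import numpy as np

from .geometry import LabeledTetMesh, TetMesh, VALID_LABELS


class MeshParseError(ValueError):
    """Malformed mesh file; the message carries the offending line number."""


# ---------------------------------------------------------------------------
# VTK legacy dialect
# ---------------------------------------------------------------------------

def _write_vtk(path: str, lm: LabeledTetMesh) -> None:
    n, e = lm.mesh.n_nodes, lm.mesh.n_tets
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"optiwrist labeled wrist mesh R={lm.radius!r} H={lm.height!r}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        np.savetxt(f, lm.mesh.nodes, fmt="%.17g")
        f.write(f"CELLS {e} {5 * e}\n")
        cells = np.column_stack([np.full(e, 4, dtype=np.int64), lm.mesh.tets])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {e}\n")
        np.savetxt(f, np.full(e, 10, dtype=np.int64), fmt="%d")
        f.write(f"POINT_DATA {n}\nSCALARS tissue int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, lm.labels, fmt="%d")


class _Lines:
    def __init__(self, path: str):
        with open(path) as f:
            self.lines = f.read().splitlines()
        self.i = 0

    def next(self) -> str:
        while self.i < len(self.lines):
            line = self.lines[self.i]
            self.i += 1
            if line.strip():
                return line
        raise MeshParseError(f"line {self.i}: unexpected end of file")

    def take_numbers(self, count: int, dtype, what: str) -> np.ndarray:
        vals: list = []
        while len(vals) < count:
            line_no = self.i
            line = self.next()
            try:
                vals.extend(dtype(tok) for tok in line.split())
            except ValueError as exc:
                raise MeshParseError(
                    f"line {line_no + 1}: bad {what} value ({exc})") from None
        if len(vals) != count:
            raise MeshParseError(
                f"line {self.i}: expected {count} {what} values, got {len(vals)}")
        return np.asarray(vals)


def _read_vtk(path: str) -> LabeledTetMesh:
    src = _Lines(path)
    src.next()                       # version header
    title = src.next()
    radius = height = float("nan")
    for tok in title.split():
        if tok.startswith("R="):
            radius = float(tok[2:])
        elif tok.startswith("H="):
            height = float(tok[2:])
    if src.next().strip().upper() != "ASCII":
        raise MeshParseError(f"line {src.i}: only ASCII VTK files are supported")
    if "UNSTRUCTURED_GRID" not in src.next().upper():
        raise MeshParseError(f"line {src.i}: expected DATASET UNSTRUCTURED_GRID")

    head = src.next().split()
    if head[0].upper() != "POINTS":
        raise MeshParseError(f"line {src.i}: expected POINTS section")
    n = int(head[1])
    nodes = src.take_numbers(3 * n, float, "coordinate").reshape(n, 3)

    head = src.next().split()
    if head[0].upper() != "CELLS":
        raise MeshParseError(f"line {src.i}: expected CELLS section")
    e = int(head[1])
    raw = src.take_numbers(int(head[2]), int, "cell index").reshape(e, -1)
    if raw.shape[1] != 5 or (raw[:, 0] != 4).any():
        raise MeshParseError(f"line {src.i}: only 4-node tetrahedral cells "
                             "are supported")
    tets = raw[:, 1:]

    head = src.next().split()
    if head[0].upper() != "CELL_TYPES":
        raise MeshParseError(f"line {src.i}: expected CELL_TYPES section")
    ctypes = src.take_numbers(e, int, "cell type")
    if (ctypes != 10).any():
        raise MeshParseError(f"line {src.i}: non-tetrahedral cell type present")

    head = src.next().split()
    if head[0].upper() != "POINT_DATA":
        raise MeshParseError(f"line {src.i}: expected POINT_DATA section")
    head = src.next().split()
    if head[0].upper() != "SCALARS" or head[1] != "tissue":
        raise MeshParseError(f"line {src.i}: expected SCALARS tissue array")
    src.next()                       # LOOKUP_TABLE
    line_no = src.i
    labels = src.take_numbers(n, int, "label")
    _validate_labels(labels, line_no)
    return LabeledTetMesh(TetMesh(nodes, tets), labels,
                          radius=radius, height=height)


def _validate_labels(labels: np.ndarray, line_no: int) -> None:
    bad = set(np.unique(labels)) - VALID_LABELS
    if bad:
        raise MeshParseError(
            f"line {line_no + 1}: invalid tissue labels {sorted(bad)}")


# ---------------------------------------------------------------------------
# TSV directory dialect
# ---------------------------------------------------------------------------

def _write_tsv(path: str, lm: LabeledTetMesh) -> None:
    os.makedirs(path, exist_ok=True)
    np.savetxt(os.path.join(path, "nodes.tsv"), lm.mesh.nodes,
               fmt="%.17g", delimiter="\t", header="x\ty\tz")
    np.savetxt(os.path.join(path, "tets.tsv"), lm.mesh.tets,
               fmt="%d", delimiter="\t", header="i\tj\tk\tl")
    np.savetxt(os.path.join(path, "labels.tsv"), lm.labels,
               fmt="%d", header="tissue")
    with open(os.path.join(path, "meta.tsv"), "w") as f:
        f.write(f"radius\t{lm.radius!r}\nheight\t{lm.height!r}\n")


def _read_tsv(path: str) -> LabeledTetMesh:
    try:
        nodes = np.loadtxt(os.path.join(path, "nodes.tsv"), ndmin=2)
        tets = np.loadtxt(os.path.join(path, "tets.tsv"), dtype=np.int64, ndmin=2)
        labels = np.loadtxt(os.path.join(path, "labels.tsv"), dtype=np.int64,
                            ndmin=1)
    except ValueError as exc:
        raise MeshParseError(f"line ?: malformed TSV mesh table ({exc})") from None
    radius = height = float("nan")
    meta_path = os.path.join(path, "meta.tsv")
    if os.path.exists(meta_path):
        with open(meta_path) as f:
            for line in f:
                key, _, val = line.partition("\t")
                if key == "radius":
                    radius = float(val)
                elif key == "height":
                    height = float(val)
    _validate_labels(labels, 0)
    return LabeledTetMesh(TetMesh(nodes, tets), labels,
                          radius=radius, height=height)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_mesh(path: str, labeled_mesh: LabeledTetMesh) -> None:
    """Write a labeled mesh; ``.vtk`` selects the VTK legacy dialect, any
    other path is treated as a TSV table directory."""
    if str(path).endswith(".vtk"):
        _write_vtk(path, labeled_mesh)
    else:
        _write_tsv(path, labeled_mesh)


def read_mesh(path: str) -> LabeledTetMesh:
    """Read a labeled mesh written by :func:`write_mesh`."""
    if os.path.isdir(path):
        return _read_tsv(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise MeshParseError("line 1: empty file")
    return _read_vtk(path)


# ---------------------------------------------------------------------------
# time-resolved measurement tables
# ---------------------------------------------------------------------------

def write_dataset(path: str, dataset) -> None:
    """Write a time-resolved dataset as a TSV table with columns
    (wavelength, source_id, detector_id, time_ps, counts); the IRF, when
    present, is stored alongside as ``<path>.irf`` (time_ps, value)."""
    import pandas as pd
    nt, n_pairs = dataset.tpsf.shape
    frame = pd.DataFrame({
        "wavelength": np.repeat(dataset.wavelength, nt * n_pairs),
        "source_id": np.tile(dataset.layout.src, nt),
        "detector_id": np.tile(dataset.layout.det, nt),
        "time_ps": np.repeat(dataset.times, n_pairs),
        "counts": dataset.tpsf.ravel(),
    })
    frame.to_csv(path, sep="\t", index=False)
    if dataset.irf is not None:
        np.savetxt(path + ".irf", np.column_stack([dataset.times, dataset.irf]),
                   delimiter="\t", header="time_ps\tvalue")


def read_dataset(path: str, layout):
    """Read a TSV measurement table written by :func:`write_dataset`."""
    import pandas as pd
    from .tdforward import TimeResolvedDataset
    frame = pd.read_csv(path, sep="\t")
    times = np.unique(frame["time_ps"].to_numpy())
    n_pairs = layout.n_pairs
    tpsf = frame["counts"].to_numpy().reshape(len(times), n_pairs)
    irf = None
    if os.path.exists(path + ".irf"):
        irf = np.loadtxt(path + ".irf", delimiter="\t")[:, 1]
    wl = float(frame["wavelength"].iloc[0])
    return TimeResolvedDataset(times=times, tpsf=tpsf, layout=layout,
                               irf=irf, wavelength=wl)
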