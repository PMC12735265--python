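"""Legacy-ASCII VTK structured-points snapshot writer/reader.

One file per snapshot, cell-centered fields written as point data located at
the cell centers (ORIGIN is the first cell center).  The legacy format is
universally readable (ParaView, VisIt, pyvista) and trivially diffable.
Axisymmetric (r,z) snapshots are written as a one-slab volume (nr, nz, 1).
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk", "read_vtk"]


def write_vtk(path, fields: dict, spacing: float, origin, comment: str = "cryosim snapshot"):
    """Write named cell fields (equal shapes, 2-D or 3-D) as structured points."""
    shapes = {f.shape for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    shape = shapes.pop()
    if len(shape) == 2:
        dims = (shape[0], shape[1], 1)
        origin3 = (origin[0], origin[1], 0.0)
    else:
        dims = shape
        origin3 = tuple(origin)
    n = int(np.prod(dims))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment.replace("\n", " ")[:250] + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write(f"ORIGIN {origin3[0]:.9g} {origin3[1]:.9g} {origin3[2]:.9g}\n")
        fh.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, field in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(field, dtype=float).reshape(dims).ravel(order="F")
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.7g")


def read_vtk(path):
    """Read a structured-points snapshot back: (fields, spacing, origin, dims).

    Understands the subset of the legacy format this package writes.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(lines)
    dims = origin = spacing = None
    fields = {}
    name = None
    values: list[float] = []
    n = 0
    for line in it:
        tok = line.split()
        if not tok:
            continue
        key = tok[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(v) for v in tok[1:4])
        elif key == "ORIGIN":
            origin = tuple(float(v) for v in tok[1:4])
        elif key == "SPACING":
            spacing = float(tok[1])
        elif key == "POINT_DATA":
            n = int(tok[1])
        elif key == "SCALARS":
            name = tok[1]
            values = []
        elif key == "LOOKUP_TABLE":
            continue
        elif name is not None:
            values.extend(float(v) for v in tok)
            if len(values) == n:
                arr = np.array(values).reshape(dims, order="F")
                if dims[2] == 1:
                    arr = arr[:, :, 0]
                fields[name] = arr
                name = None
    if dims is None or spacing is None:
        raise ValueError(f"{path} is not a structured-points VTK file")
    return fields, spacing, origin, dims
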