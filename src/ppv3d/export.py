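"""Volumetric writers: legacy ASCII VTK and long-format voxel CSV.

The VTK legacy STRUCTURED_POINTS dialect is the simplest widely supported
voxel format (ParaView, Voxler import it directly): a 10-line text header
followed by whitespace-separated scalars, x varying fastest. The CSV writer
emits one ``x,y,z,value`` row per voxel center for maximum portability.
"""

from __future__ import annotations

import numpy as np

from .voxels import PPVVolume

__all__ = ["write_vtk", "write_voxel_csv"]


def write_vtk(vol: PPVVolume, path, title: str = "ppv3d volume") -> None:
    """Write a Boolean volume as legacy ASCII VTK STRUCTURED_POINTS.

    Points are the voxel centers: ORIGIN is the grid origin offset by half a
    voxel, SPACING the voxel edge lengths, scalars 0/1 occupancy.
    """
    grid = vol.grid
    nx, ny, nz = grid.dims
    center0 = grid.origin + grid.voxel_size / 2.0
    flat = vol.occupancy.astype(np.uint8).flatten(order="F")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {center0[0]:.10g} {center0[1]:.10g} {center0[2]:.10g}\n")
        fh.write(
            f"SPACING {grid.voxel_size[0]:.10g} {grid.voxel_size[1]:.10g} "
            f"{grid.voxel_size[2]:.10g}\n"
        )
        fh.write(f"POINT_DATA {flat.size}\n")
        fh.write("SCALARS occupancy unsigned_char 1\n")
        fh.write("LOOKUP_TABLE default\n")
        for i in range(0, flat.size, 30):
            fh.write(" ".join(map(str, flat[i : i + 30])) + "\n")


def write_voxel_csv(vol: PPVVolume, path, occupied_only: bool = True) -> None:
    """Write voxel centers and occupancy as ``x,y,z,value`` rows.

    By default only occupied voxels are written (full grids are large and
    zeros carry no information); pass ``occupied_only=False`` for the
    complete grid.
    """
    grid = vol.grid
    xs, ys, zs = (grid.axis_centers(i) for i in range(3))
    with open(path, "w") as fh:
        fh.write("x,y,z,value\n")
        if occupied_only:
            idx = np.argwhere(vol.occupancy)
            for i, j, k in idx:
                fh.write(f"{float(xs[i])!r},{float(ys[j])!r},{float(zs[k])!r},1\n")
        else:
            for k in range(grid.dims[2]):
                for j in range(grid.dims[1]):
                    for i in range(grid.dims[0]):
                        v = int(vol.occupancy[i, j, k])
                        fh.write(
                            f"{float(xs[i])!r},{float(ys[j])!r},{float(zs[k])!r},{v}\n"
                        )
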