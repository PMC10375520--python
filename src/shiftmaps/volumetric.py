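"""Volumetric export of density maps (Gaussian cube and CCP4/MRC).

Both formats are understood by the usual molecular viewers, so SIM/IIM and
difference maps can be displayed as 3D contour levels over a structure.
One map (one element) per file.  Files round-trip: reading a written map
restores values within 1e-5 and the origin/spacing metadata exactly enough
to rebuild the :class:`~shiftmaps.density.GridSpec`.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .density import DensityMap, GridSpec
from .errors import FormatError, UsageError

__all__ = ["write_volumetric", "read_volumetric", "FORMATS"]

BOHR = 0.529177210903
FORMATS = ("cube", "ccp4")


def write_volumetric(dmap: DensityMap, path: str | Path, fmt: str | None = None) -> None:
    """Write a density map as ``cube`` or ``ccp4`` (MRC); *fmt* defaults to
    the file suffix (.cube / .ccp4 / .mrc / .map)."""
    path = Path(path)
    fmt = fmt or _guess_format(path)
    if fmt == "cube":
        _write_cube(dmap, path)
    elif fmt == "ccp4":
        _write_ccp4(dmap, path)
    else:
        raise UsageError(f"unsupported volumetric format {fmt!r}; use one of {FORMATS}")


def read_volumetric(path: str | Path, fmt: str | None = None) -> DensityMap:
    """Read a map written by :func:`write_volumetric`."""
    path = Path(path)
    fmt = fmt or _guess_format(path)
    if fmt == "cube":
        return _read_cube(path)
    if fmt == "ccp4":
        return _read_ccp4(path)
    raise UsageError(f"unsupported volumetric format {fmt!r}; use one of {FORMATS}")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".cube":
        return "cube"
    if suffix in (".ccp4", ".mrc", ".map"):
        return "ccp4"
    raise UsageError(f"cannot infer volumetric format from {path.name!r}")


# -- Gaussian cube -------------------------------------------------------


def _write_cube(dmap: DensityMap, path: Path) -> None:
    g = dmap.grid
    n = g.points
    origin = g.origin / BOHR
    step = g.spacing / BOHR
    lines = [
        f"shiftmaps {dmap.kind} map, element {dmap.element}",
        f"n_envs {dmap.n_envs}",
        f"{0:5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}",
        f"{n:5d} {step:12.6f} {0.0:12.6f} {0.0:12.6f}",
        f"{n:5d} {0.0:12.6f} {step:12.6f} {0.0:12.6f}",
        f"{n:5d} {0.0:12.6f} {0.0:12.6f} {step:12.6f}",
    ]
    flat = dmap.values.reshape(n * n, n)
    for row in flat:
        for k in range(0, n, 6):
            lines.append(" ".join(f"{v: .5E}" for v in row[k:k + 6]))
    path.write_text("\n".join(lines) + "\n")


def _read_cube(path: Path) -> DensityMap:
    lines = path.read_text().splitlines()
    try:
        comment, meta = lines[0], lines[1]
        natoms_line = lines[2].split()
        natoms = int(natoms_line[0])
        origin = np.array([float(x) for x in natoms_line[1:4]]) * BOHR
        ns, steps = [], []
        for i in range(3):
            parts = lines[3 + i].split()
            ns.append(int(parts[0]))
            steps.append(float(parts[1 + i]) * BOHR)
        body_start = 6 + abs(natoms)
        values = np.array(" ".join(lines[body_start:]).split(), dtype=float)
        nx, ny, nz = ns
        values = values.reshape(nx, ny, nz)
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed cube file: {exc}") from exc
    if not (nx == ny == nz and abs(steps[0] - steps[1]) < 1e-9
            and abs(steps[0] - steps[2]) < 1e-9):
        raise FormatError(f"{path}: only cubic uniform grids are supported")
    side = steps[0] * (nx - 1)
    center = tuple(origin + side / 2.0)
    element = comment.split("element")[-1].strip() if "element" in comment else "?"
    kind = comment.split()[1] if comment.startswith("shiftmaps") else "candidate"
    n_envs = int(meta.split()[1]) if meta.startswith("n_envs") else 1
    return DensityMap(grid=GridSpec(center=center, points=nx, side=side),
                      element=element, values=values, n_envs=n_envs, kind=kind)


# -- CCP4 / MRC ----------------------------------------------------------

# header words 50-52 hold the MRC2014 origin (Å); gemmi reads/writes them directly
_ORIGIN_WORDS = (50, 51, 52)


def _write_ccp4(dmap: DensityMap, path: Path) -> None:
    g = dmap.grid
    n = g.points
    grid = gemmi.FloatGrid(n, n, n)
    # treat the box as one "cell" of n * spacing so voxel spacing is exact
    grid.set_unit_cell(gemmi.UnitCell(n * g.spacing, n * g.spacing, n * g.spacing,
                                      90.0, 90.0, 90.0))
    np.asarray(grid)[...] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, val in zip(_ORIGIN_WORDS, g.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def _read_ccp4(path: Path) -> DensityMap:
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot read CCP4/MRC map: {exc}") from exc
    values = np.array(m.grid, dtype=float)
    nx, ny, nz = values.shape
    if not nx == ny == nz:
        raise FormatError(f"{path}: only cubic grids are supported")
    spacing = m.grid.unit_cell.a / nx
    origin = np.array([m.header_float(w) for w in _ORIGIN_WORDS])
    side = spacing * (nx - 1)
    center = tuple(origin + side / 2.0)
    return DensityMap(grid=GridSpec(center=center, points=nx, side=side),
                      element="?", values=values, n_envs=1, kind="candidate")
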