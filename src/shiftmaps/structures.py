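"""Crystal structures: CIF input/output and periodic environment extraction.

A :class:`CrystalStructure` is a periodic unit cell (lengths in Å, angles in
degrees) with a list of sites given in fractional coordinates.  Structures
read from CIF are expanded to P1: symmetry operators, when present, are
applied so that ``sites`` always enumerates every atom in the unit cell.

Local atomic environments — all atoms within a sphere of a given radius
around one site, including periodic images — are extracted with
:func:`expand_to_sphere`.  The replication bound is derived from the minimum
perpendicular cell widths, so the sphere is covered even for skewed cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import gemmi
import numpy as np

from .elements import SUPPORTED_ELEMENTS
from .errors import FormatError, GeometryError, ValidationError

__all__ = [
    "Site",
    "CrystalStructure",
    "LocalEnvironment",
    "read_cif",
    "write_cif",
    "expand_to_sphere",
]


@dataclass(frozen=True)
class Site:
    """One atomic site of the unit cell (element, fractional coordinate, label)."""

    element: str
    frac: tuple[float, float, float]
    label: str


@dataclass
class CrystalStructure:
    """A periodic crystal: cell parameters plus the full P1 site list.

    Parameters
    ----------
    cell_lengths : (a, b, c) in Å
    cell_angles : (alpha, beta, gamma) in degrees
    sites : the unit-cell sites (fractional coordinates, wrapped to [0, 1))
    structure_id : opaque identifier used as the database key
    """

    cell_lengths: tuple[float, float, float]
    cell_angles: tuple[float, float, float]
    sites: list[Site]
    structure_id: str = ""
    allowed_elements: frozenset[str] = field(default=SUPPORTED_ELEMENTS, repr=False)

    def __post_init__(self) -> None:
        if any(not (x > 0) for x in self.cell_lengths):
            raise ValidationError(f"{self.structure_id}: cell lengths must be > 0")
        if any(not (0.0 < a < 180.0) for a in self.cell_angles):
            raise ValidationError(f"{self.structure_id}: cell angles must be in (0, 180)")
        wrapped = []
        for s in self.sites:
            f = np.asarray(s.frac, dtype=float)
            if not np.all(np.isfinite(f)):
                raise ValidationError(f"site {s.label}: non-finite fractional coordinate")
            if s.element not in self.allowed_elements:
                raise ValidationError(f"site {s.label}: unsupported element {s.element!r}")
            wrapped.append(Site(s.element, tuple(f % 1.0), s.label))
        self.sites = wrapped

    # -- cell geometry -------------------------------------------------

    @property
    def cell_matrix(self) -> np.ndarray:
        """Lower-triangular cell matrix; rows are the lattice vectors (Å).

        Cartesian = fractional @ cell_matrix, with *a* along x and *b* in
        the xy-plane (the standard crystallographic convention).
        """
        a, b, c = self.cell_lengths
        al, be, ga = np.radians(self.cell_angles)
        cx = c * math.cos(be)
        cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz_sq = c * c - cx * cx - cy * cy
        if cz_sq <= 0:
            raise GeometryError(f"{self.structure_id}: degenerate cell angles")
        return np.array(
            [
                [a, 0.0, 0.0],
                [b * math.cos(ga), b * math.sin(ga), 0.0],
                [cx, cy, math.sqrt(cz_sq)],
            ]
        )

    @property
    def volume(self) -> float:
        """Unit-cell volume in Å³."""
        return float(abs(np.linalg.det(self.cell_matrix)))

    def frac_coords(self) -> np.ndarray:
        """(n_sites, 3) array of fractional coordinates."""
        return np.array([s.frac for s in self.sites], dtype=float).reshape(-1, 3)

    def cart_coords(self) -> np.ndarray:
        """(n_sites, 3) array of Cartesian coordinates in Å."""
        return self.frac_coords() @ self.cell_matrix

    def perpendicular_widths(self) -> np.ndarray:
        """Distance between opposite cell faces along each axis (Å)."""
        m = self.cell_matrix
        v = abs(np.linalg.det(m))
        if v < 1e-9:
            raise GeometryError(f"{self.structure_id}: near-zero cell volume")
        widths = np.empty(3)
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            widths[i] = v / np.linalg.norm(np.cross(m[j], m[k]))
        return widths

    def elements(self) -> list[str]:
        return [s.element for s in self.sites]


@dataclass
class LocalEnvironment:
    """Atoms within the extraction sphere of one site, in Cartesian Å.

    ``coords`` are absolute positions in the parent structure's frame;
    ``site_indices[i]`` is the unit-cell site of which atom *i* is a
    periodic image.  ``center_index`` points at the (zero-shift) image of
    the central site itself.
    """

    elements: list[str]
    coords: np.ndarray
    center_index: int
    site_indices: np.ndarray
    source: tuple[str, int]

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def center(self) -> np.ndarray:
        return self.coords[self.center_index]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LocalEnvironment":
        """Return a copy with ``coords @ R.T + t`` applied."""
        return LocalEnvironment(
            elements=list(self.elements),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            center_index=self.center_index,
            site_indices=self.site_indices.copy(),
            source=self.source,
        )


# -- CIF input/output ----------------------------------------------------


def read_cif(path: str | Path, structure_id: str | None = None,
             allowed_elements: frozenset[str] = SUPPORTED_ELEMENTS) -> CrystalStructure:
    """Read one crystal block from a CIF file, expanded to P1.

    Symmetry operators (space-group name or explicit symop list) are applied
    so the returned structure lists every site in the unit cell.  Partial
    occupancy / disorder is rejected: the density pipeline assumes ordered
    sites and silently accepting fractional occupancies would corrupt the
    accumulated maps.
    """
    path = Path(path)
    try:
        small = gemmi.read_small_structure(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise FormatError(f"{path}: CIF parse failure: {exc}") from exc
    if not small.sites:
        raise FormatError(f"{path}: no atom sites found (empty or invalid CIF block)")
    cell = small.cell
    if cell.a <= 0 or cell.b <= 0 or cell.c <= 0:
        raise FormatError(f"{path}: missing or invalid cell parameters")
    for s in small.sites:
        if s.disorder_group not in (0, None) or abs(s.occ - 1.0) > 1e-6:
            raise ValidationError(
                f"{path}: site {s.label} has partial occupancy/disorder; "
                "only ordered structures are supported"
            )
    expanded = small.get_all_unit_cell_sites()
    sites = []
    for i, s in enumerate(expanded):
        el = str(s.type_symbol)
        if el not in allowed_elements:
            raise ValidationError(f"{path}: unsupported element {el!r} at site {s.label}")
        f = s.fract
        sites.append(Site(el, (f.x % 1.0, f.y % 1.0, f.z % 1.0), s.label or f"{el}{i}"))
    return CrystalStructure(
        cell_lengths=(cell.a, cell.b, cell.c),
        cell_angles=(cell.alpha, cell.beta, cell.gamma),
        sites=sites,
        structure_id=structure_id if structure_id is not None else path.stem,
        allowed_elements=allowed_elements,
    )


def write_cif(structure: CrystalStructure, path: str | Path) -> None:
    """Write the structure as a P1 CIF file."""
    a, b, c = structure.cell_lengths
    al, be, ga = structure.cell_angles
    lines = [
        f"data_{structure.structure_id or 'crystal'}",
        f"_cell_length_a {a:.6f}",
        f"_cell_length_b {b:.6f}",
        f"_cell_length_c {c:.6f}",
        f"_cell_angle_alpha {al:.6f}",
        f"_cell_angle_beta {be:.6f}",
        f"_cell_angle_gamma {ga:.6f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for s in structure.sites:
        x, y, z = s.frac
        lines.append(f"{s.label} {s.element} {x:.8f} {y:.8f} {z:.8f} 1.0")
    Path(path).write_text("\n".join(lines) + "\n")


# -- periodic sphere extraction ------------------------------------------


def expand_to_sphere(structure: CrystalStructure, center_site: int,
                     radius: float) -> LocalEnvironment:
    """All periodic image atoms within *radius* Å of site *center_site*.

    The unit cell is replicated ``±(ceil(radius / w_min_axis) + 1)`` cells
    along each axis, where w_axis is the perpendicular width of the cell
    along that axis — enough to guarantee that no image inside the sphere is
    missed, for arbitrarily skewed cells.  The center atom itself is
    included (distance 0).
    """
    if not 0 <= center_site < len(structure.sites):
        raise ValidationError(f"center site index {center_site} out of range")
    if not radius > 0:
        raise ValidationError("radius must be > 0")
    widths = structure.perpendicular_widths()
    reps = [int(math.ceil(radius / w)) + 1 for w in widths]
    m = structure.cell_matrix
    frac = structure.frac_coords()
    center = frac[center_site] @ m
    els = structure.elements()

    out_el: list[str] = []
    out_xyz: list[np.ndarray] = []
    out_idx: list[int] = []
    center_index = -1
    for shift in product(*(range(-n, n + 1) for n in reps)):
        xyz = (frac + np.asarray(shift, dtype=float)) @ m
        d = np.linalg.norm(xyz - center, axis=1)
        keep = np.nonzero(d <= radius)[0]
        for i in keep:
            if i == center_site and shift == (0, 0, 0):
                center_index = len(out_el)
            out_el.append(els[i])
            out_xyz.append(xyz[i])
            out_idx.append(i)
    return LocalEnvironment(
        elements=out_el,
        coords=np.array(out_xyz).reshape(-1, 3),
        center_index=center_index,
        site_indices=np.array(out_idx, dtype=int),
        source=(structure.structure_id, center_site),
    )
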