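"""Rigid alignment of local environments and 3D Gaussian density maps.

Selected environments are superposed onto a reference conformation by
minimizing the RMSD between 3–4 anchor atoms (Kabsch algorithm, proper
rotations only — a mirror image is never applied).  Per-element atomic
density maps are then accumulated by placing an unnormalized unit-amplitude
3D Gaussian of width σ = 0.5 Å at every atom position and averaging over
environments, so that an atom present at the same position in *all*
environments produces a map value of 1 there.  The default grid is
31×31×31 points over a 12 Å cube centered at the queried site (0.4 Å
sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError, ValidationError
from .structures import LocalEnvironment

__all__ = [
    "GridSpec",
    "DensityMap",
    "rigid_align",
    "anchor_correspondence",
    "align_environment",
    "accumulate_density",
    "difference_map",
    "SIGMA_SPACE",
]

#: default spatial Gaussian width (standard deviation), Å
SIGMA_SPACE = 0.5


@dataclass(frozen=True)
class GridSpec:
    """Cubic evaluation grid: *points* per axis spanning *side* Å, centered
    at the queried site (Cartesian Å)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    points: int = 31
    side: float = 12.0

    def __post_init__(self) -> None:
        if self.points < 2:
            raise ValidationError("grid needs at least 2 points per axis")
        if not self.side > 0:
            raise ValidationError("grid side must be > 0")

    @property
    def spacing(self) -> float:
        """Distance between adjacent grid points, Å (default 12/30 = 0.4)."""
        return self.side / (self.points - 1)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        half = self.side / 2.0
        return tuple(np.linspace(c[i] - half, c[i] + half, self.points) for i in range(3))

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float) - self.side / 2.0


@dataclass
class DensityMap:
    """Per-element 3D atomic density on a :class:`GridSpec`.

    ``kind`` is one of ``iim``, ``sim``, ``difference``, ``candidate``.
    IIM/SIM/candidate values lie in [0, n_coincident]; difference maps may
    be negative.
    """

    grid: GridSpec
    element: str
    values: np.ndarray
    n_envs: int = 1
    kind: str = "candidate"

    def __post_init__(self) -> None:
        expected = (self.grid.points,) * 3
        if self.values.shape != expected:
            raise ValidationError(f"values shape {self.values.shape} != grid {expected}")

    def same_grid(self, other: "DensityMap") -> bool:
        return self.grid == other.grid


# -- rigid-body superposition --------------------------------------------


def rigid_align(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper rotation R and translation t minimizing RMSD of P onto Q.

    Kabsch algorithm; the determinant of R is forced to +1, so a chiral
    point set is never superposed onto its mirror image.  Returns
    ``(R, t, rmsd)`` with the convention ``P_aligned = P @ R.T + t``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValidationError("anchor coordinate arrays must both be (n, 3)")
    if len(P) < 3:
        raise GeometryError("at least 3 anchor atoms are required")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise GeometryError("anchor atoms are collinear; rotation is underdetermined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - cp @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def anchor_correspondence(query_anchor_coords: np.ndarray,
                          query_anchor_nodes: list,
                          db_node_coords: dict,
                          mappings: list[dict]):
    """Pick the witness isomorphism that aligns the anchors best.

    Local symmetry (methyl rotors, equivalent ring positions) yields several
    witness isomorphisms; each maps the query anchor atoms to a different
    set of database atoms.  Every candidate pairing is aligned and the one
    with the lowest anchor RMSD is kept.

    Parameters
    ----------
    query_anchor_coords : (n_anchor, 3) reference-frame coordinates
    query_anchor_nodes : graph nodes of the anchors in the query descriptor
    db_node_coords : db graph node -> unwrapped Cartesian coordinate
    mappings : witness isomorphisms (query node -> db node)

    Returns ``(R, t, rmsd, mapping)`` transforming the database environment
    into the reference frame.
    """
    if not mappings:
        raise ConfigurationError("no witness isomorphism provided")
    best = None
    for mp in mappings:
        try:
            db_nodes = [mp[a] for a in query_anchor_nodes]
        except KeyError as exc:
            raise ConfigurationError(
                f"anchor atom {exc} is outside the descriptor depth; choose anchors "
                "within w bonds of the queried site") from None
        Q_coords = np.array([db_node_coords[n] for n in db_nodes])
        # align db anchors onto query anchors: transform maps db frame -> reference
        R, t, rmsd = rigid_align(Q_coords, query_anchor_coords)
        if best is None or rmsd < best[2] - 1e-12:
            best = (R, t, rmsd, mp)
    return best


def align_environment(env: LocalEnvironment, R: np.ndarray,
                      t: np.ndarray) -> LocalEnvironment:
    """Apply a rigid transform to a whole extracted environment."""
    return env.transformed(R, t)


# -- density accumulation ------------------------------------------------


def _add_gaussians(values: np.ndarray, grid: GridSpec, positions: np.ndarray,
                   sigma: float) -> None:
    """Accumulate unit-amplitude Gaussians at *positions* into *values*.

    The isotropic Gaussian factorizes along the axes, so each atom costs
    three 1D evaluations and one outer product (einsum over all atoms).
    """
    if len(positions) == 0:
        return
    ax, ay, az = grid.axes()
    inv = 1.0 / (2.0 * sigma * sigma)
    gx = np.exp(-inv * (ax[None, :] - positions[:, 0:1]) ** 2)
    gy = np.exp(-inv * (ay[None, :] - positions[:, 1:2]) ** 2)
    gz = np.exp(-inv * (az[None, :] - positions[:, 2:3]) ** 2)
    values += np.einsum("ax,ay,az->xyz", gx, gy, gz, optimize=True)


def accumulate_density(envs: list[LocalEnvironment], grid: GridSpec, element: str,
                       sigma_space: float = SIGMA_SPACE,
                       kind: str = "candidate") -> DensityMap:
    """Average per-element Gaussian density of aligned environments.

    ``values(r) = (1/n_envs) Σ_envs Σ_atoms exp(−|r − r_a|² / (2 σ²))`` over
    atoms of *element*; all atoms of each 7 Å environment contribute, even
    those outside the grid box (their contribution decays to nothing within
    a few σ, and including them avoids edge discontinuities).  An element
    absent from every environment yields an all-zero map.
    """
    if not envs:
        raise ValidationError("need at least one environment")
    if not sigma_space > 0:
        raise ValidationError("sigma_space must be > 0")
    values = np.zeros((grid.points,) * 3)
    for env in envs:
        mask = np.array([el == element for el in env.elements], dtype=bool)
        _add_gaussians(values, grid, env.coords[mask], sigma_space)
    values /= len(envs)
    return DensityMap(grid=grid, element=element, values=values,
                      n_envs=len(envs), kind=kind)


def difference_map(sim: DensityMap, iim: DensityMap, noise_floor: float = 0.01,
                   reverse: bool = False) -> DensityMap:
    """SIM − IIM with small-magnitude noise suppressed.

    Voxels with ``|sim − iim| < noise_floor`` are set to exactly 0.
    Positive values mark density promoted by the chemical shift constraint;
    ``reverse=True`` returns IIM − SIM instead (to highlight interactions
    that the shift makes *less* likely than average).
    """
    if sim.grid != iim.grid or sim.element != iim.element:
        raise ValidationError("difference_map requires identical grids and elements")
    diff = sim.values - iim.values
    if reverse:
        diff = -diff
    diff = np.where(np.abs(diff) < noise_floor, 0.0, diff)
    return DensityMap(grid=sim.grid, element=sim.element, values=diff,
                      n_envs=min(sim.n_envs, iim.n_envs), kind="difference")
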