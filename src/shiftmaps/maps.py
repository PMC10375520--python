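"""End-to-end construction of SIMs and IIMs for query sites.

Given an environment database, a reference conformation of the query
molecule and an assigned experimental shift, this module:

1. finds the working descriptor depth (start at w = 6, reduce until more
   than ``min_matches`` database matches exist),
2. selects ``n_select`` matching environments either at random (IIM) or
   targeted at the experimental shift (SIM; 1D for a single nucleus, 2D
   for a bonded C–H pair),
3. extracts each 7 Å local environment, aligns it onto the reference
   conformation through its anchor atoms (best witness isomorphism), and
4. accumulates per-element Gaussian density maps on a 31³ grid of 12 Å
   sides centered at the queried site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .covalent import (CovalentDescriptor, adaptive_depth, build_descriptor,
                       iter_isomorphisms, perceive_bonds, unwrap_molecule)
from .density import (GridSpec, accumulate_density, anchor_correspondence,
                      DensityMap, SIGMA_SPACE)
from .envdb import (DEFAULT_SIGMA, EnvironmentDatabase, SelectionSpec,
                    select_by_shift_1d, select_by_shift_2d, select_random)
from .errors import ConfigurationError, ValidationError
from .structures import CrystalStructure, LocalEnvironment, expand_to_sphere

__all__ = ["MapConfig", "QuerySite", "build_site_maps", "aligned_environment",
           "site_elements"]

# cap on witness isomorphisms enumerated per environment (methyl/phenyl
# symmetry gives a handful; larger counts add nothing but cost)
_MAX_ISOMORPHISMS = 48


@dataclass(frozen=True)
class MapConfig:
    """Tunable parameters of the map pipeline (defaults sized for a
    production-scale database; scale n_select/min_matches down for toy ones)."""

    n_select: int = 1000
    min_matches: int = 3000
    w_start: int = 6
    radius: float = 7.0
    grid_points: int = 31
    grid_side: float = 12.0
    sigma_space: float = SIGMA_SPACE
    noise_floor: float = 0.01
    sigma_by_nucleus: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    bond_scale: float = 1.15


@dataclass
class QuerySite:
    """One queried atomic site of the reference molecule.

    ``site_index`` indexes the reference structure's site list; ``anchors``
    are 3–4 site indices (within the descriptor, mutually close) used for
    rigid superposition.  For a bonded C–H pair query, ``site_index`` is the
    carbon and ``pair_h_index`` its bonded proton.
    """

    label: str
    site_index: int
    nucleus: str
    experimental_shifts: tuple[float, ...]
    anchors: tuple[int, ...]
    ambiguous: bool = False
    pair_h_index: int | None = None
    #: set for rigid motifs (phenyl rings, carboxylic acids) whose anchors may
    #: legitimately be more than two bonds apart
    rigid_anchors: bool = False

    def __post_init__(self) -> None:
        if not 3 <= len(self.anchors) <= 4:
            raise ConfigurationError(
                f"site {self.label}: need 3-4 anchor atoms, got {len(self.anchors)}")
        n_shift = 2 if self.pair_h_index is not None else 1
        if len(self.experimental_shifts) != n_shift:
            raise ValidationError(
                f"site {self.label}: expected {n_shift} experimental shift(s)")


def site_elements(db: EnvironmentDatabase, entry_ids) -> list[str]:
    """Sorted union of elements over the structures behind the given entries."""
    els: set[str] = set()
    for eid in entry_ids:
        e = db.entries[eid]
        els.update(db.structures[e.structure_id].elements())
    return sorted(els)


def _reference_frame(structure: CrystalStructure, graph: nx.Graph, qsite: QuerySite):
    """Unwrapped molecule coordinates + anchor coordinates of the query site."""
    coords = unwrap_molecule(structure, graph, qsite.site_index)
    missing = [a for a in qsite.anchors if a not in coords]
    if missing:
        raise ConfigurationError(
            f"site {qsite.label}: anchor(s) {missing} are not in the molecule")
    anchor_coords = np.array([coords[a] for a in qsite.anchors])
    if not qsite.rigid_anchors:
        for i, a in enumerate(qsite.anchors):
            for b in qsite.anchors[i + 1:]:
                try:
                    d = nx.shortest_path_length(graph, a, b)
                except nx.NetworkXNoPath:
                    d = np.inf
                if d > 2:
                    warnings.warn(
                        f"site {qsite.label}: anchors {a} and {b} are {d} bonds "
                        "apart; distant anchors are only safe for rigid motifs "
                        "(set rigid_anchors=True)", stacklevel=3)
    return coords, anchor_coords


def aligned_environment(structure: CrystalStructure, graph: nx.Graph,
                        site_index: int, query_descriptor: CovalentDescriptor,
                        query_anchor_nodes, query_anchor_coords,
                        site_descriptor: CovalentDescriptor,
                        radius: float = 7.0) -> tuple[LocalEnvironment, float]:
    """Extract the 7 Å environment of a site and align it onto the reference.

    All witness isomorphisms between the query descriptor and the site's own
    descriptor are enumerated; the anchor pairing with the lowest RMSD wins.
    Returns the transformed environment and that RMSD.
    """
    mappings = []
    for mp in iter_isomorphisms(query_descriptor, site_descriptor):
        mappings.append(mp)
        if len(mappings) >= _MAX_ISOMORPHISMS:
            break
    if not mappings:
        raise ValidationError(
            f"{structure.structure_id}/{site_index}: descriptor does not match the query")
    mol_coords = unwrap_molecule(structure, graph, site_index)
    R, t, rmsd, _ = anchor_correspondence(query_anchor_coords, list(query_anchor_nodes),
                                          mol_coords, mappings)
    env = expand_to_sphere(structure, site_index, radius)
    return env.transformed(R, t), rmsd


def _pair_entries(db: EnvironmentDatabase, matches_with_mappings, h_node):
    """(entry_id, δ13C, δ1H) triples for matched C entries with a bonded-H shift."""
    out = []
    for eid, mapping in matches_with_mappings:
        e = db.entries[eid]
        db_h = mapping.get(h_node)
        if db_h is None:
            continue
        h_entry = db.entry_by_site(e.structure_id, db_h)
        if h_entry is None:
            continue
        out.append((eid, e.shift.predicted_shift, h_entry.shift.predicted_shift))
    return out


def build_site_maps(db: EnvironmentDatabase, ref_structure: CrystalStructure,
                    qsite: QuerySite, mode: str, config: MapConfig = MapConfig(),
                    rng: np.random.Generator | None = None,
                    ref_graph: nx.Graph | None = None,
                    elements: list[str] | None = None) -> dict[str, DensityMap]:
    """Build the per-element density maps for one query site.

    mode ``"iim"`` selects environments at random; ``"sim"`` targets the
    assigned experimental shift(s).  Returns element -> DensityMap.
    """
    if mode not in ("iim", "sim"):
        raise ValidationError(f"mode must be 'iim' or 'sim', got {mode!r}")
    rng = np.random.default_rng() if rng is None else rng
    graph = perceive_bonds(ref_structure, scale=config.bond_scale) \
        if ref_graph is None else ref_graph
    el = ref_structure.sites[qsite.site_index].element
    if el != qsite.nucleus:
        raise ValidationError(f"site {qsite.label}: nucleus {qsite.nucleus!r} "
                              f"does not match element {el!r}")

    def builder(w: int) -> CovalentDescriptor:
        return build_descriptor(graph, qsite.site_index, w)

    w, matches, _ = adaptive_depth(db, builder, w_start=config.w_start,
                                   min_matches=config.min_matches)
    qdesc = builder(w)
    missing_anchor = [a for a in qsite.anchors if a not in qdesc.graph]
    if missing_anchor:
        raise ConfigurationError(
            f"site {qsite.label}: anchors {missing_anchor} are outside the "
            f"descriptor at working depth w={w}")
    matches_mapped = db.query_with_mappings(qdesc)

    if qsite.pair_h_index is not None:
        pair_entries = _pair_entries(db, matches_mapped, qsite.pair_h_index)
        if mode == "sim":
            tc, th = qsite.experimental_shifts
            spec = SelectionSpec(mode="shift_2d", n=config.n_select,
                                 targets=(tc, th),
                                 widths=(config.sigma_by_nucleus["C"],
                                         config.sigma_by_nucleus["H"]))
            selected = select_by_shift_2d(pair_entries, spec, rng=rng)
        else:
            spec = SelectionSpec(mode="random", n=config.n_select)
            selected = select_random([e[0] for e in pair_entries], spec, rng=rng)
    else:
        if mode == "sim":
            (target,) = qsite.experimental_shifts
            spec = SelectionSpec(mode="shift_1d", n=config.n_select,
                                 targets=(target,),
                                 widths=(config.sigma_by_nucleus[qsite.nucleus],))
            entries_1d = [(eid, db.entries[eid].shift.predicted_shift)
                          for eid, _ in matches_mapped]
            selected = select_by_shift_1d(entries_1d, spec, rng=rng)
        else:
            spec = SelectionSpec(mode="random", n=config.n_select)
            selected = select_random([eid for eid, _ in matches_mapped], spec, rng=rng)

    _, anchor_coords = _reference_frame(ref_structure, graph, qsite)
    envs = []
    for eid in selected:
        e = db.entries[eid]
        st = db.structures[e.structure_id]
        g = db.graph(e.structure_id)
        sdesc = db.descriptor(e.structure_id, e.site_index, w)
        env, _ = aligned_environment(st, g, e.site_index, qdesc, qsite.anchors,
                                     anchor_coords, sdesc, radius=config.radius)
        envs.append(env)

    center = tuple(ref_structure.cart_coords()[qsite.site_index])
    grid = GridSpec(center=center, points=config.grid_points, side=config.grid_side)
    if elements is None:
        els: set[str] = set()
        for env in envs:
            els.update(env.elements)
        elements = sorted(els)
    kind = "sim" if mode == "sim" else "iim"
    return {el_: accumulate_density(envs, grid, el_, sigma_space=config.sigma_space,
                                    kind=kind)
            for el_ in elements}
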