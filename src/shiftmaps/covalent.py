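"""Covalent environment descriptors on molecular bond graphs.

The descriptor of an atomic site is the labelled graph of all atoms within
*w* covalent bonds of the site — atoms as nodes (element labels only, no
bond orders, no geometry), covalent bonds as edges.  Two sites match when
an element-preserving graph isomorphism maps one descriptor onto the other
with center onto center.  Because the descriptor is purely two-dimensional,
database searches need neither the conformation of the query molecule nor
any knowledge of crystal packing.

Bond perception uses the standard crystallographic heuristic: atoms are
bonded when their minimum-image distance is below ``scale`` times the sum
of their covalent radii (default scale 1.15).  Bonds are intramolecular
only: each connected component of the bond graph is one molecule, and
descriptor graphs never cross to neighbouring molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import networkx as nx
import numpy as np

from .elements import covalent_radius
from .errors import ShiftmapsError, ValidationError
from .structures import CrystalStructure

__all__ = [
    "perceive_bonds",
    "build_descriptor",
    "descriptors_match",
    "iter_isomorphisms",
    "adaptive_depth",
    "unwrap_molecule",
    "CovalentDescriptor",
]

_SHIFTS = np.array(list(product((-1, 0, 1), repeat=3)), dtype=float)


def perceive_bonds(structure: CrystalStructure, scale: float = 1.15,
                   radius_table: dict[str, float] | None = None) -> nx.Graph:
    """Build the molecular bond graph of a crystal's unit-cell sites.

    Nodes are site indices with an ``element`` attribute; an edge carries the
    lattice ``shift`` (triple) of the periodic image of the second node that
    realizes the bond, so molecules can later be unwrapped across cell
    boundaries.  Hydrogens with degree != 1 and isolated atoms in multi-atom
    structures trigger warnings, not errors.
    """
    g = nx.Graph()
    els = structure.elements()
    for i, el in enumerate(els):
        g.add_node(i, element=el)
    frac = structure.frac_coords()
    m = structure.cell_matrix
    radii = np.array([covalent_radius(el, radius_table) for el in els])
    n = len(els)
    for i in range(n):
        for j in range(i + 1, n):
            diff = frac[j] - frac[i]
            # wrap to the nearest cell, then scan the 27 neighbour shifts
            base = diff - np.round(diff)
            cand = (base + _SHIFTS) @ m
            d = np.linalg.norm(cand, axis=1)
            k = int(np.argmin(d))
            if d[k] <= scale * (radii[i] + radii[j]):
                # lattice shift applied to j so its image is the bonded one:
                # displacement i -> j_image is frac[j] + shift - frac[i]
                shift = tuple(int(x) for x in np.round(base + _SHIFTS[k] - diff))
                g.add_edge(i, j, shift=shift, distance=float(d[k]))
    if n > 1:
        for i in range(n):
            deg = g.degree(i)
            if els[i] == "H" and deg != 1:
                warnings.warn(f"{structure.structure_id}: H site {i} has degree {deg}",
                              stacklevel=2)
            elif deg == 0:
                warnings.warn(f"{structure.structure_id}: site {i} ({els[i]}) has no bonds",
                              stacklevel=2)
    return g


def unwrap_molecule(structure: CrystalStructure, graph: nx.Graph,
                    root: int) -> dict[int, np.ndarray]:
    """Cartesian coordinates of the molecule containing *root*, unwrapped.

    Coordinates are propagated by breadth-first search along bonds using the
    minimum-image lattice shifts recorded during bond perception, so the
    molecule is contiguous even when it crosses cell boundaries.  The root
    atom sits at its unit-cell position.
    """
    frac = structure.frac_coords()
    m = structure.cell_matrix
    pos_frac = {root: frac[root].copy()}
    queue = [root]
    while queue:
        i = queue.pop(0)
        for j in graph.neighbors(i):
            if j in pos_frac:
                continue
            # edge shift is stored in the (low index -> high index) orientation
            shift = np.asarray(graph.edges[min(i, j), max(i, j)]["shift"], dtype=float)
            sij = shift if i < j else -shift
            pos_frac[j] = pos_frac[i] + (frac[j] - frac[i] + sij)
            queue.append(j)
    return {k: v @ m for k, v in pos_frac.items()}


@dataclass
class CovalentDescriptor:
    """Bond-graph neighbourhood of one site to depth *w* (the database key)."""

    center: int
    w: int
    graph: nx.Graph
    canonical_key: str

    def nodes(self) -> set[int]:
        return set(self.graph.nodes)


def _wl_key(graph: nx.Graph, center, w: int) -> str:
    h = nx.weisfeiler_lehman_graph_hash(
        graph, node_attr="_wl", iterations=max(2, min(w, 6))
    )
    return f"w{w}:{h}"


def build_descriptor(graph: nx.Graph, center, w: int) -> CovalentDescriptor:
    """Descriptor of *center*: the induced subgraph of atoms ≤ *w* bonds away.

    The canonical key is a Weisfeiler–Lehman hash over element labels (with
    the center marked), used as an O(1) database prefilter; equality of keys
    is always confirmed by explicit isomorphism before a match is accepted.
    """
    if center not in graph:
        raise LookupError(f"center node {center!r} not in graph")
    if w < 1:
        raise ValidationError("descriptor depth w must be >= 1")
    dists = nx.single_source_shortest_path_length(graph, center, cutoff=w)
    sub = graph.subgraph(dists).copy()
    for n in sub.nodes:
        sub.nodes[n]["_wl"] = ("*" if n == center else "") + sub.nodes[n]["element"]
    return CovalentDescriptor(center=center, w=w, graph=sub,
                              canonical_key=_wl_key(sub, center, w))


def _node_match(a: dict, b: dict) -> bool:
    return a["_wl"] == b["_wl"]


def iter_isomorphisms(d1: CovalentDescriptor, d2: CovalentDescriptor):
    """Yield every center-preserving, element-preserving isomorphism d1 → d2."""
    gm = nx.isomorphism.GraphMatcher(d1.graph, d2.graph, node_match=_node_match)
    yield from gm.isomorphisms_iter()


def descriptors_match(d1: CovalentDescriptor, d2: CovalentDescriptor):
    """Whether two descriptors are isomorphic (center to center).

    Returns ``(flag, mapping)``: one witness node mapping d1 → d2 when
    matching, else ``(False, None)``.  Both descriptors must have been built
    at the same depth.
    """
    if d1.w != d2.w:
        raise ValidationError(f"descriptor depths differ: {d1.w} != {d2.w}")
    if len(d1.graph) != len(d2.graph) or d1.canonical_key != d2.canonical_key:
        # WL hash equality is necessary for isomorphism (it is a graph invariant)
        return False, None
    for mapping in iter_isomorphisms(d1, d2):
        return True, mapping
    return False, None


def adaptive_depth(db, descriptor_builder, w_start: int = 6, min_matches: int = 3000):
    """Deepest descriptor depth with enough database matches.

    Starting from ``w_start``, the depth is reduced until the match count
    exceeds ``min_matches`` (match counts are monotonically non-increasing
    in *w*, so the first depth that satisfies the threshold while descending
    is the largest one).  If even w=1 falls short, its matches are returned
    with ``enough=False``; zero matches at w=1 is an error.

    Parameters
    ----------
    db : an object with ``query(descriptor) -> list of entry ids``
    descriptor_builder : callable ``w -> CovalentDescriptor`` for the query site
    """
    if w_start < 1:
        raise ValidationError("w_start must be >= 1")
    for w in range(w_start, 0, -1):
        matches = db.query(descriptor_builder(w))
        if len(matches) > min_matches:
            return w, matches, True
    if not matches:
        raise ShiftmapsError("no database match for the query site even at w=1")
    warnings.warn(
        f"only {len(matches)} matches at w=1 (< {min_matches} requested)",
        stacklevel=2,
    )
    return 1, matches, False
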