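"""Candidate crystal scoring against SIM − IIM difference maps.

Each query site's score for a candidate crystal is the overlap

    s_i = Σ_elements Σ_grid  G_i^cand(r) · [G_i^SIM(r) − G_i^IIM(r)]

where the difference map has voxels of magnitude < 0.01 zeroed to suppress
noise, and G_i^cand is the candidate's own local environment rendered with
the same Gaussian kernel (a single environment, so an atom contributes 1
at its position).  Positive s_i: the candidate's packing around that site
is promoted by the experimental shift; zero: shift-indifferent; negative:
disfavoured.

The global candidate score is the mean of s_i over unambiguously assigned
sites, and scores are normalized across a candidate set by subtracting the
set mean, so only between-candidate variation remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .covalent import build_descriptor, descriptors_match, perceive_bonds
from .density import DensityMap, accumulate_density, difference_map
from .envdb import EnvironmentDatabase
from .errors import AssignmentError, ShiftmapsError, ValidationError
from .maps import MapConfig, QuerySite, aligned_environment, build_site_maps
from .structures import CrystalStructure

__all__ = [
    "ScoreReport",
    "candidate_site_map",
    "site_score",
    "global_score",
    "normalize_scores",
    "flag_ambiguous_sites",
    "rank_candidates",
]


@dataclass
class ScoreReport:
    """Per-site and global scores of one candidate crystal."""

    candidate_id: str
    per_site: list[tuple[str, float]] = field(default_factory=list)
    excluded_sites: list[tuple[str, str]] = field(default_factory=list)
    global_score: float = float("nan")
    normalized_score: float = float("nan")
    rank: int = -1


def candidate_site_map(candidate: CrystalStructure, site_index: int,
                       query_descriptor, query_anchors, query_anchor_coords,
                       grid, element: str, config: MapConfig = MapConfig(),
                       graph: nx.Graph | None = None) -> DensityMap:
    """Density map of a single candidate environment (n_envs = 1).

    The candidate site's 7 Å environment is extracted, anchor-aligned onto
    the reference conformation, and rendered with the same Gaussian kernel
    and grid as the SIM/IIM, so overlaps are directly comparable.
    """
    g = perceive_bonds(candidate, scale=config.bond_scale) if graph is None else graph
    try:
        sdesc = build_descriptor(g, site_index, query_descriptor.w)
    except LookupError as exc:
        raise AssignmentError(f"{candidate.structure_id}: site {site_index} "
                              "not found") from exc
    ok, _ = descriptors_match(query_descriptor, sdesc)
    if not ok:
        raise AssignmentError(
            f"{candidate.structure_id}/{site_index}: covalent descriptor does not "
            "match the query site")
    env, _ = aligned_environment(candidate, g, site_index, query_descriptor,
                                 query_anchors, query_anchor_coords, sdesc,
                                 radius=config.radius)
    return accumulate_density([env], grid, element, sigma_space=config.sigma_space,
                              kind="candidate")


def site_score(cand_maps: dict[str, DensityMap], sim_maps: dict[str, DensityMap],
               iim_maps: dict[str, DensityMap], noise_floor: float = 0.01) -> float:
    """Overlap of the candidate maps with the thresholded SIM − IIM difference.

    Summed over every element channel present in both the SIM/IIM pair and
    the candidate (a channel missing on either side contributes zero).
    """
    total = 0.0
    for el in sorted(set(sim_maps) & set(iim_maps)):
        diff = difference_map(sim_maps[el], iim_maps[el], noise_floor=noise_floor)
        cand = cand_maps.get(el)
        if cand is None:
            continue
        if cand.grid != diff.grid:
            raise ValidationError(f"element {el}: candidate and SIM/IIM grids differ")
        total += float(np.sum(cand.values * diff.values))
    return total


def global_score(per_site: list[tuple[str, float]],
                 ambiguous: dict[str, bool] | None = None):
    """Mean score over unambiguous sites; ambiguous sites are excluded.

    Returns ``(mean, excluded)`` where *excluded* lists (label, reason).
    """
    ambiguous = ambiguous or {}
    included, excluded = [], []
    for label, s in per_site:
        if ambiguous.get(label, False):
            excluded.append((label, "ambiguous"))
        else:
            included.append(s)
    if not included:
        raise ShiftmapsError("no unambiguous site score to average")
    return float(np.mean(included)), excluded


def normalize_scores(scores: list[float]) -> list[float]:
    """Subtract the candidate-set mean from each global score.

    Removes any systematic offset common to the whole set; the outputs sum
    to zero and preserve the ordering.  A single candidate passes through
    unchanged (there is no set mean to remove).
    """
    if len(scores) < 2:
        import warnings
        warnings.warn("normalize_scores with fewer than 2 candidates is a no-op",
                      stacklevel=2)
        return list(scores)
    mean = float(np.mean(scores))
    return [s - mean for s in scores]


def flag_ambiguous_sites(graph: nx.Graph, assignments: dict[int, float],
                         w: int = 6) -> dict[int, bool]:
    """Sites whose descriptor is shared by atoms with different assigned shifts.

    A site is ambiguous iff at least one other atom of the molecule has an
    isomorphic descriptor at the working depth but carries a *different*
    experimental shift — the 2D descriptor then cannot be mapped onto a 3D
    site without knowing the crystal structure (CH₂ protons, symmetric
    aromatic positions).

    *assignments* maps site index -> experimental shift.
    """
    descs = {i: build_descriptor(graph, i, w) for i in assignments}
    flags = {i: False for i in assignments}
    items = sorted(assignments)
    for a_pos, i in enumerate(items):
        for j in items[a_pos + 1:]:
            if graph.nodes[i]["element"] != graph.nodes[j]["element"]:
                continue
            if abs(assignments[i] - assignments[j]) < 1e-9:
                continue
            ok, _ = descriptors_match(descs[i], descs[j])
            if ok:
                flags[i] = flags[j] = True
    return flags


def rank_candidates(db: EnvironmentDatabase, ref_structure: CrystalStructure,
                    qsites: list[QuerySite], candidates: list[CrystalStructure],
                    config: MapConfig = MapConfig(),
                    seed: int | None = None) -> list[ScoreReport]:
    """Score and rank candidate crystals against SIM − IIM difference maps.

    SIM and IIM maps are built once per query site and reused for every
    candidate.  Candidates whose covalent graph lacks a match for some query
    site have that site excluded (reported, not fatal).  The report list is
    sorted by normalized score, descending; ties keep ascending candidate id
    order.  Deterministic for a fixed seed.
    """
    if not candidates:
        raise ValidationError("no candidate structures given")
    usable = [q for q in qsites if not q.ambiguous]
    if not usable:
        raise ShiftmapsError("all query sites are flagged ambiguous")
    rng = np.random.default_rng(seed)
    ref_graph = perceive_bonds(ref_structure, scale=config.bond_scale)

    # per-site reference data: descriptor at working depth, anchors, maps
    site_ctx = {}
    for q in sorted(usable, key=lambda q: q.label):
        sim = build_site_maps(db, ref_structure, q, "sim", config=config, rng=rng,
                              ref_graph=ref_graph)
        iim = build_site_maps(db, ref_structure, q, "iim", config=config, rng=rng,
                              ref_graph=ref_graph)
        # working depth actually used for this site (recompute cheaply)
        from .covalent import adaptive_depth, unwrap_molecule

        def builder(w, _q=q):
            return build_descriptor(ref_graph, _q.site_index, w)

        w, _, _ = adaptive_depth(db, builder, w_start=config.w_start,
                                 min_matches=config.min_matches)
        qdesc = builder(w)
        mol_coords = unwrap_molecule(ref_structure, ref_graph, q.site_index)
        anchor_coords = np.array([mol_coords[a] for a in q.anchors])
        grid = next(iter(sim.values())).grid
        site_ctx[q.label] = (q, qdesc, anchor_coords, grid, sim, iim)

    reports = []
    for cand in candidates:
        cand_graph = perceive_bonds(cand, scale=config.bond_scale)
        report = ScoreReport(candidate_id=cand.structure_id)
        for label in sorted(site_ctx):
            q, qdesc, anchor_coords, grid, sim, iim = site_ctx[label]
            # all candidate sites matching the query descriptor (symmetry copies)
            matching = []
            for idx in range(len(cand.sites)):
                if cand.sites[idx].element != q.nucleus:
                    continue
                sdesc = build_descriptor(cand_graph, idx, qdesc.w)
                ok, _ = descriptors_match(qdesc, sdesc)
                if ok:
                    matching.append(idx)
            if not matching:
                report.excluded_sites.append((label, "no descriptor match"))
                continue
            scores = []
            for idx in matching:
                cand_maps = {
                    el: candidate_site_map(cand, idx, qdesc, q.anchors, anchor_coords,
                                           grid, el, config=config, graph=cand_graph)
                    for el in sim
                }
                scores.append(site_score(cand_maps, sim, iim,
                                         noise_floor=config.noise_floor))
            report.per_site.append((label, float(np.mean(scores))))
        if report.per_site:
            report.global_score, _ = global_score(report.per_site)
        else:
            report.excluded_sites.append(("*", "no scorable site"))
            report.global_score = float("nan")
        reports.append(report)

    valid = [r for r in reports if np.isfinite(r.global_score)]
    normed = normalize_scores([r.global_score for r in valid]) if len(valid) >= 2 \
        else [r.global_score for r in valid]
    for r, ns in zip(valid, normed):
        r.normalized_score = ns
    reports.sort(key=lambda r: (-(r.normalized_score
                                  if np.isfinite(r.normalized_score) else -np.inf),
                                r.candidate_id))
    for rank, r in enumerate(reports, start=1):
        r.rank = rank
    return reports
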