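"""Synthetic crystal databases with a controllable shift–structure coupling.

The real pipeline runs against a large experimental structure database with
machine-learned shift predictions; neither is reproducible at desk scale.
This module generates small periodic crystals of rigid molecules (formic
acid, optionally formaldehyde as a non-protic decoy species) packed in
three hydrogen-bond motifs:

* ``dimer``   — the classic carboxylic-acid R₂²(8) double hydrogen bond
  (two molecules related by inversion, H···O = 1.75 Å),
* ``chain``   — a catemer: each OH donates to the carbonyl oxygen of the
  next molecule along one cell axis,
* ``isolated``— a single molecule in a padded cell, no intermolecular
  contact.

Pseudo-shifts follow a step model: class base value, plus a fixed increment
Δ when the proton has an intermolecular acceptor oxygen within a cutoff,
plus Gaussian noise.  This is the minimal structure–shift coupling that
makes a shift-targeted environment selection (SIM) differ from a random
one (IIM), so every downstream stage can be exercised and checked against
ground-truth motif labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covalent import perceive_bonds, unwrap_molecule
from .envdb import EnvironmentDatabase, build_database
from .errors import ValidationError
from .maps import QuerySite
from .shifts import ShiftRecord
from .structures import CrystalStructure, Site, expand_to_sphere

__all__ = [
    "FixtureSpec",
    "generate_toy_crystals",
    "pseudo_shift",
    "make_candidate_set",
    "make_fixture_database",
    "acid_proton_query",
    "FORMIC_ACID",
    "ACCEPTOR_OFFSET",
]

# rigid planar formic acid, Å (z = 0); order: C, O(carbonyl), O(hydroxyl), HC, HO
FORMIC_ACID = {
    "elements": ["C", "O", "O", "H", "H"],
    "labels": ["C1", "O1", "O2", "H1", "H2"],
    "coords": np.array([
        [0.000, 0.000, 0.0],
        [1.220, 0.000, 0.0],
        [-0.769, 1.098, 0.0],
        [-0.465, -0.997, 0.0],
        [-0.159, 1.853, 0.0],
    ]),
}

# O-H bond direction of the acid proton (unit vector, in-plane)
_OH_DIR = np.array([0.629, 0.778, 0.0])
_OH_DIR = _OH_DIR / np.linalg.norm(_OH_DIR)

#: designed H···O hydrogen-bond length, Å
HBOND_LENGTH = 1.75

#: acceptor-O position relative to the acid proton in the aligned frame
ACCEPTOR_OFFSET = HBOND_LENGTH * _OH_DIR

# rigid formaldehyde (decoy species without an OH proton)
FORMALDEHYDE = {
    "elements": ["C", "O", "H", "H"],
    "labels": ["C1", "O1", "H1", "H2"],
    "coords": np.array([
        [0.000, 0.000, 0.0],
        [1.210, 0.000, 0.0],
        [-0.545, 0.944, 0.0],
        [-0.545, -0.944, 0.0],
    ]),
}

# catemer chain geometry: molecule B is A mirrored in x and offset so each OH
# donates to the next carbonyl along the chain axis (y); the chain repeat is
# the second molecule's H-bond closing onto the next cell image
_CHAIN_OFFSET = np.array([2.162, 3.214, 0.0])
_CHAIN_REPEAT = 6.428  # Å along y


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic database.

    Shift model: shift = base(site class) + Δ·[intermolecular acceptor O
    within ``hbond_cutoff``] + N(0, noise).  Prediction uncertainties are
    fixed at 0.5 ppm (¹H) and 5 ppm (¹³C), the widths used for selection.
    """

    n_structures: int = 100
    dimer_fraction: float = 0.4
    chain_fraction: float = 0.2
    isolated_fraction: float = 0.4
    base_shifts: dict = field(default_factory=lambda: {"H_O": 6.0, "H_C": 8.0,
                                                       "C": 165.0})
    hbond_delta: float = 4.0
    noise: float = 0.2
    hbond_cutoff: float = 2.0
    cell_min: float = 12.0
    cell_max: float = 15.0
    decoy_species_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.dimer_fraction + self.chain_fraction + self.isolated_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("motif fractions must sum to 1")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")
        if not 0 <= self.decoy_species_fraction <= 1:
            raise ValidationError("decoy_species_fraction must be in [0, 1]")
        if not self.cell_min <= self.cell_max:
            raise ValidationError("cell_min must be <= cell_max")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _assemble(template: dict, copies: list[np.ndarray]) -> tuple[list[str], list[str], np.ndarray]:
    els, labels, blocks = [], [], []
    for m, xyz in enumerate(copies):
        els.extend(template["elements"])
        labels.extend(f"{lab}_{m}" for lab in template["labels"])
        blocks.append(xyz)
    return els, labels, np.vstack(blocks)


def _finalize(els, labels, xyz, cell, structure_id) -> CrystalStructure:
    m = np.diag(cell)
    centroid = xyz.mean(axis=0)
    shifted = xyz - centroid + np.asarray(cell) / 2.0
    frac = shifted @ np.linalg.inv(m)
    sites = [Site(e, tuple(f), lab) for e, f, lab in zip(els, frac, labels)]
    return CrystalStructure(cell_lengths=tuple(cell), cell_angles=(90.0, 90.0, 90.0),
                            sites=sites, structure_id=structure_id)


def _build_motif(motif: str, cell_lengths, rot: np.ndarray,
                 structure_id: str) -> CrystalStructure:
    A = FORMIC_ACID["coords"]
    if motif == "dimer":
        center = np.array([1.081, 1.607, 0.0])
        B = 2.0 * center - A  # inversion-related partner
        els, labels, xyz = _assemble(FORMIC_ACID, [A, B])
        xyz = (xyz - xyz.mean(axis=0)) @ rot.T + xyz.mean(axis=0)
        return _finalize(els, labels, xyz, cell_lengths, structure_id)
    if motif == "chain":
        B = A * np.array([-1.0, 1.0, 1.0]) + _CHAIN_OFFSET
        els, labels, xyz = _assemble(FORMIC_ACID, [A, B])
        cell = (cell_lengths[0], _CHAIN_REPEAT, cell_lengths[2])
        return _finalize(els, labels, xyz, cell, structure_id)
    if motif == "isolated":
        xyz = (A - A.mean(axis=0)) @ rot.T + A.mean(axis=0)
        els, labels, _xyz = _assemble(FORMIC_ACID, [xyz])
        return _finalize(els, labels, _xyz, cell_lengths, structure_id)
    if motif == "decoy_species":
        X = FORMALDEHYDE["coords"]
        xyz = (X - X.mean(axis=0)) @ rot.T + X.mean(axis=0)
        els, labels, _xyz = _assemble(FORMALDEHYDE, [xyz])
        return _finalize(els, labels, _xyz, cell_lengths, structure_id)
    raise ValidationError(f"unknown motif {motif!r}")


def generate_toy_crystals(spec: FixtureSpec,
                          rng: np.random.Generator | None = None):
    """Generate the synthetic database structures and their motif labels.

    Motif counts follow the spec fractions deterministically (largest-
    remainder rounding); the per-structure order, cell sizes and molecular
    orientations are drawn from the seeded generator.  Returns
    ``(structures, labels)`` with ``labels[i]`` in
    {dimer, chain, isolated, decoy_species}.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_structures
    n_decoy = int(round(spec.decoy_species_fraction * n))
    n_formic = n - n_decoy
    counts = {
        "dimer": int(round(spec.dimer_fraction * n_formic)),
        "chain": int(round(spec.chain_fraction * n_formic)),
    }
    counts["isolated"] = n_formic - counts["dimer"] - counts["chain"]
    if counts["isolated"] < 0:
        raise ValidationError("motif fractions round to more structures than requested")
    motifs = (["dimer"] * counts["dimer"] + ["chain"] * counts["chain"]
              + ["isolated"] * counts["isolated"] + ["decoy_species"] * n_decoy)
    rng.shuffle(motifs)
    structures, labels = [], []
    for i, motif in enumerate(motifs):
        cell = tuple(rng.uniform(spec.cell_min, spec.cell_max, size=3))
        rot = _random_rotation(rng)
        st = _build_motif(motif, cell, rot, structure_id=f"syn{i:04d}")
        structures.append(st)
        labels.append(motif)
    return structures, labels


def _intermolecular_acceptor_distance(structure: CrystalStructure, graph,
                                      site_index: int, search_radius: float) -> float:
    """Distance from a site to the nearest O/N atom of another molecule
    (periodic images of the same molecule count as intermolecular)."""
    env = expand_to_sphere(structure, site_index, search_radius)
    own = unwrap_molecule(structure, graph, site_index)
    center = env.center
    best = np.inf
    for k in range(len(env)):
        if env.elements[k] not in ("O", "N"):
            continue
        parent = int(env.site_indices[k])
        pos = env.coords[k]
        if parent in own and np.linalg.norm(pos - own[parent]) < 1e-3:
            continue  # the molecule's own atom, not an intermolecular contact
        best = min(best, float(np.linalg.norm(pos - center)))
    return best


def _site_class(graph, site_index: int) -> str:
    el = graph.nodes[site_index]["element"]
    if el == "C":
        return "C"
    if el == "H":
        nb = [graph.nodes[j]["element"] for j in graph.neighbors(site_index)]
        return "H_O" if "O" in nb else "H_C"
    raise ValidationError(f"pseudo-shifts are defined for H and C sites only "
                          f"(site {site_index} is {el})")


def pseudo_shift(structure: CrystalStructure, site_index: int, spec: FixtureSpec,
                 rng: np.random.Generator | None = None,
                 graph=None) -> ShiftRecord:
    """Pseudo-shift of one H or C site under the step model.

    shift = base(class) + Δ·[nearest intermolecular acceptor within cutoff]
    + N(0, noise); the uncertainty is the per-nucleus selection width
    (0.5 ppm ¹H, 5 ppm ¹³C).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    g = perceive_bonds(structure) if graph is None else graph
    cls = _site_class(g, site_index)
    base = spec.base_shifts[cls]
    d = _intermolecular_acceptor_distance(structure, g, site_index,
                                          search_radius=spec.hbond_cutoff + 1.0)
    bonded = d <= spec.hbond_cutoff
    value = base + (spec.hbond_delta if bonded else 0.0)
    if spec.noise > 0:
        value += rng.normal(0.0, spec.noise)
    nucleus = g.nodes[site_index]["element"]
    return ShiftRecord(structure.structure_id, site_index, nucleus, float(value),
                       0.5 if nucleus == "H" else 5.0)


def make_fixture_database(spec: FixtureSpec, w_max: int = 6):
    """Generate structures, pseudo-shift every H/C site, and build the database.

    Returns ``(db, labels)`` with the motif label per structure.
    """
    rng = np.random.default_rng(spec.seed)
    structures, labels = generate_toy_crystals(spec, rng=rng)
    records = []
    for st in structures:
        g = perceive_bonds(st)
        for i, site in enumerate(st.sites):
            if site.element in ("H", "C"):
                records.append(pseudo_shift(st, i, spec, rng=rng, graph=g))
    db = build_database(structures, records, w_max=w_max)
    return db, labels


def make_candidate_set(spec: FixtureSpec, n_decoys: int = 9,
                       include_truth: bool = True,
                       rng: np.random.Generator | None = None):
    """A candidate set for ranking: one H-bonded dimer plus isolated decoys.

    Candidate ids are shuffled (seeded), so the ground-truth candidate's
    position in the id order carries no information.  Returns
    ``(candidates, truth_id)``; ``truth_id`` is None when the true motif is
    absent from the set.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    builds = []
    if include_truth:
        builds.append("dimer")
    builds.extend(["isolated"] * n_decoys)
    rng.shuffle(builds)
    candidates, truth_id = [], None
    for i, motif in enumerate(builds):
        cell = tuple(rng.uniform(spec.cell_min, spec.cell_max, size=3))
        rot = _random_rotation(rng)
        st = _build_motif(motif, cell, rot, structure_id=f"cand{i:02d}")
        candidates.append(st)
        if motif == "dimer":
            truth_id = st.structure_id
    return candidates, truth_id


def acid_proton_query(spec: FixtureSpec, hbonded: bool = True) -> QuerySite:
    """Query description of the formic-acid OH proton on an isolated reference.

    For a reference structure built with motif ``isolated`` the molecule
    sites are [C, O, O, HC, HO]; the acid proton is index 4 with anchors
    (HO, O2, C).  The experimental shift is the model's noise-free value for
    an H-bonded (or free) acid proton.
    """
    shift = spec.base_shifts["H_O"] + (spec.hbond_delta if hbonded else 0.0)
    return QuerySite(label="H2", site_index=4, nucleus="H",
                     experimental_shifts=(shift,), anchors=(4, 2, 0))
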