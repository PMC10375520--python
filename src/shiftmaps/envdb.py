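"""The environment database and shift-constrained environment selection.

Every ¹H/¹³C site with a predicted shift becomes one database entry, keyed
by its covalent environment descriptor at depths w = 1..w_max.  Queries
prefilter on the canonical key and confirm every candidate by explicit
graph isomorphism.

Three selection modes produce the environment subsets that the density
maps are built from:

* ``select_random`` — uniform without replacement; yields the
  shift-independent interaction map (IIM) baseline.
* ``select_by_shift_1d`` — repeatedly draw x ~ N(δ_exp, σ) and take the
  still-unselected entry whose predicted shift is nearest to the draw;
  yields the shift-dependent interaction map (SIM) ensemble.
* ``select_by_shift_2d`` — the same for bonded C–H pairs, drawing from an
  axis-aligned 2D Gaussian (σ_13C, σ_1H) and minimizing the σ-normalized
  distance :func:`shift_distance_2d`.

Defaults: 1000 environments per map, selection widths σ = 0.5 ppm (¹H)
and 5 ppm (¹³C) — the typical prediction uncertainties.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .covalent import CovalentDescriptor, build_descriptor, descriptors_match, perceive_bonds
from .errors import InsufficientMatchesError, ValidationError
from .shifts import ShiftRecord
from .structures import CrystalStructure, Site

__all__ = [
    "SelectionSpec",
    "DatabaseEntry",
    "EnvironmentDatabase",
    "build_database",
    "select_random",
    "select_by_shift_1d",
    "select_by_shift_2d",
    "shift_distance_2d",
    "DEFAULT_SIGMA",
]

SCHEMA_VERSION = 1

#: default selection width (ppm) per nucleus — the shift-prediction uncertainty
DEFAULT_SIGMA = {"H": 0.5, "C": 5.0}


@dataclass
class SelectionSpec:
    """How to select an environment subset.

    mode: ``random`` | ``shift_1d`` | ``shift_2d``;
    targets/widths in ppm (two of each for shift_2d, ¹³C first).
    """

    mode: str = "random"
    n: int = 1000
    targets: tuple[float, ...] = ()
    widths: tuple[float, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("random", "shift_1d", "shift_2d"):
            raise ValidationError(f"unknown selection mode {self.mode!r}")
        if self.n < 1:
            raise ValidationError("selection size n must be >= 1")
        if any(not (w > 0) for w in self.widths):
            raise ValidationError("selection widths must be > 0")
        if self.mode == "shift_1d" and len(self.targets) != 1:
            raise ValidationError("shift_1d needs exactly one target shift")
        if self.mode == "shift_2d" and len(self.targets) != 2:
            raise ValidationError("shift_2d needs exactly two target shifts (13C, 1H)")


@dataclass
class DatabaseEntry:
    """One (structure, site) instance with its predicted shift and keys."""

    entry_id: int
    structure_id: str
    site_index: int
    shift: ShiftRecord
    keys: dict[int, str]  # w -> canonical descriptor key


class EnvironmentDatabase:
    """Structures, per-site predicted shifts, and the descriptor key index."""

    def __init__(self, structures: dict[str, CrystalStructure],
                 entries: list[DatabaseEntry], w_max: int = 6,
                 bond_scale: float = 1.15):
        self.structures = structures
        self.entries = entries
        self.w_max = w_max
        self.bond_scale = bond_scale
        self._graphs: dict[str, nx.Graph] = {}
        self._descriptors: dict[tuple[str, int, int], CovalentDescriptor] = {}
        self.index: dict[tuple[int, str], list[int]] = {}
        for e in entries:
            for w, key in e.keys.items():
                self.index.setdefault((w, key), []).append(e.entry_id)

    def __len__(self) -> int:
        return len(self.entries)

    def graph(self, structure_id: str) -> nx.Graph:
        if structure_id not in self._graphs:
            self._graphs[structure_id] = perceive_bonds(
                self.structures[structure_id], scale=self.bond_scale)
        return self._graphs[structure_id]

    def descriptor(self, structure_id: str, site_index: int, w: int) -> CovalentDescriptor:
        key = (structure_id, site_index, w)
        if key not in self._descriptors:
            self._descriptors[key] = build_descriptor(self.graph(structure_id),
                                                      site_index, w)
        return self._descriptors[key]

    def entry_by_site(self, structure_id: str, site_index: int) -> DatabaseEntry | None:
        for e in self.entries:  # small databases; linear scan is fine
            if e.structure_id == structure_id and e.site_index == site_index:
                return e
        return None

    # -- querying ------------------------------------------------------

    def query(self, descriptor: CovalentDescriptor) -> list[int]:
        """Entry ids whose descriptor at the same w is isomorphic to the query.

        Key prefilter, isomorphism confirmation, ascending entry id order.
        """
        w = descriptor.w
        if w > self.w_max:
            raise ValidationError(f"query depth {w} exceeds database w_max {self.w_max}")
        out = []
        for eid in self.index.get((w, descriptor.canonical_key), ()):
            e = self.entries[eid]
            ok, _ = descriptors_match(descriptor, self.descriptor(e.structure_id,
                                                                  e.site_index, w))
            if ok:
                out.append(eid)
        return sorted(out)

    def query_with_mappings(self, descriptor: CovalentDescriptor):
        """Like :meth:`query` but also returns one witness mapping per entry."""
        out = []
        for eid in self.index.get((descriptor.w, descriptor.canonical_key), ()):
            e = self.entries[eid]
            ok, mapping = descriptors_match(
                descriptor, self.descriptor(e.structure_id, e.site_index, descriptor.w))
            if ok:
                out.append((eid, mapping))
        return sorted(out, key=lambda t: t[0])

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the database as a JSON container (gzipped for ``.gz`` paths)."""
        doc = {
            "schema_version": SCHEMA_VERSION,
            "w_max": self.w_max,
            "bond_scale": self.bond_scale,
            "structures": {
                sid: {
                    "cell_lengths": list(st.cell_lengths),
                    "cell_angles": list(st.cell_angles),
                    "sites": [[s.element, list(s.frac), s.label] for s in st.sites],
                }
                for sid, st in self.structures.items()
            },
            "entries": [
                {
                    "structure_id": e.structure_id,
                    "site_index": e.site_index,
                    "nucleus": e.shift.nucleus,
                    "shift_ppm": e.shift.predicted_shift,
                    "uncertainty_ppm": e.shift.uncertainty,
                }
                for e in self.entries
            ],
        }
        path = Path(path)
        data = json.dumps(doc).encode()
        if path.suffix == ".gz":
            with gzip.open(path, "wb") as fh:
                fh.write(data)
        else:
            path.write_bytes(data)

    @classmethod
    def load(cls, path: str | Path) -> "EnvironmentDatabase":
        """Load a saved database; the key index is rebuilt from scratch."""
        path = Path(path)
        if path.suffix == ".gz":
            with gzip.open(path, "rb") as fh:
                doc = json.loads(fh.read())
        else:
            doc = json.loads(path.read_bytes())
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValidationError(f"unsupported database schema: {doc.get('schema_version')}")
        structures = {
            sid: CrystalStructure(
                cell_lengths=tuple(d["cell_lengths"]),
                cell_angles=tuple(d["cell_angles"]),
                sites=[Site(el, tuple(fr), lab) for el, fr, lab in d["sites"]],
                structure_id=sid,
            )
            for sid, d in doc["structures"].items()
        }
        records = [
            ShiftRecord(e["structure_id"], e["site_index"], e["nucleus"],
                        e["shift_ppm"], e["uncertainty_ppm"])
            for e in doc["entries"]
        ]
        return build_database(structures, records, w_max=doc["w_max"],
                              bond_scale=doc["bond_scale"])


def build_database(structures, shift_records: list[ShiftRecord], w_max: int = 6,
                   bond_scale: float = 1.15) -> EnvironmentDatabase:
    """Index every ¹H/¹³C site carrying a shift record under its descriptor keys.

    *structures* is a mapping id -> CrystalStructure or an iterable of
    structures with unique ``structure_id``.
    """
    if not isinstance(structures, dict):
        structures = {st.structure_id: st for st in structures}
    db = EnvironmentDatabase(structures, [], w_max=w_max, bond_scale=bond_scale)
    seen: set[tuple[str, int]] = set()
    entries: list[DatabaseEntry] = []
    for rec in shift_records:
        if rec.structure_id not in structures:
            raise ValidationError(f"shift record references unknown structure "
                                  f"{rec.structure_id!r}")
        st = structures[rec.structure_id]
        if not 0 <= rec.site_index < len(st.sites):
            raise ValidationError(f"{rec.structure_id}: site index {rec.site_index} "
                                  "out of range")
        el = st.sites[rec.site_index].element
        if el != rec.nucleus:
            raise ValidationError(f"{rec.structure_id}/{rec.site_index}: nucleus "
                                  f"{rec.nucleus!r} does not match site element {el!r}")
        key = (rec.structure_id, rec.site_index)
        if key in seen:
            raise ValidationError(f"duplicate shift record for {key}")
        seen.add(key)
        keys = {w: db.descriptor(rec.structure_id, rec.site_index, w).canonical_key
                for w in range(1, w_max + 1)}
        entries.append(DatabaseEntry(len(entries), rec.structure_id, rec.site_index,
                                     rec, keys))
    return EnvironmentDatabase(structures, entries, w_max=w_max, bond_scale=bond_scale)


# -- selection -----------------------------------------------------------


def _check_size(n_avail: int, n: int) -> None:
    if n_avail < n:
        raise InsufficientMatchesError(
            f"requested {n} environments but only {n_avail} matches are available")


def select_random(entry_ids: list[int], spec: SelectionSpec,
                  rng: np.random.Generator | None = None) -> list[int]:
    """Uniform sample of *n* distinct entries (the IIM ensemble)."""
    if spec.mode != "random":
        raise ValidationError("select_random requires mode='random'")
    _check_size(len(entry_ids), spec.n)
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    ids = np.sort(np.asarray(entry_ids))
    picked = rng.choice(ids, size=spec.n, replace=False)
    return sorted(int(i) for i in picked)


def _nearest_unselected(values: np.ndarray, ids: np.ndarray, available: np.ndarray,
                        x: float) -> int:
    """Index (into the arrays) of the available value nearest x; ties -> lowest id."""
    d = np.abs(values - x)
    d[~available] = np.inf
    best = d.min()
    cand = np.nonzero(d <= best)[0]
    if len(cand) > 1:
        cand = cand[np.argsort(ids[cand], kind="stable")]
    return int(cand[0])


def select_by_shift_1d(entries, spec: SelectionSpec,
                       rng: np.random.Generator | None = None) -> list[int]:
    """Shift-targeted selection (the SIM ensemble).

    *entries* is a sequence of ``(entry_id, shift_ppm)``.  For each of *n*
    draws x ~ N(δ_exp, σ) the not-yet-selected entry with the predicted
    shift closest to x is taken (ties broken by ascending entry id).
    """
    if spec.mode != "shift_1d":
        raise ValidationError("select_by_shift_1d requires mode='shift_1d'")
    entries = sorted(entries, key=lambda t: t[0])
    _check_size(len(entries), spec.n)
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    (target,) = spec.targets
    (sigma,) = spec.widths
    ids = np.array([e[0] for e in entries])
    shifts = np.array([e[1] for e in entries], dtype=float)
    available = np.ones(len(ids), dtype=bool)
    out = []
    for _ in range(spec.n):
        x = rng.normal(target, sigma)
        k = _nearest_unselected(shifts, ids, available, x)
        available[k] = False
        out.append(int(ids[k]))
    return out


def shift_distance_2d(delta_c_env: float, delta_h_env: float,
                      point: tuple[float, float],
                      sigma_c: float = 5.0, sigma_h: float = 0.5) -> float:
    """σ-normalized distance between a C–H shift pair and a 2D point (c, h).

    ``d = sqrt(((c − δ13C_env)/σ13C)² + ((h − δ1H_env)/σ1H)²)`` — the metric
    under which "the environment with the closest correlated chemical shift"
    is selected.
    """
    if not (sigma_c > 0 and sigma_h > 0):
        raise ValidationError("selection widths must be > 0")
    c, h = point
    return math.hypot((c - delta_c_env) / sigma_c, (h - delta_h_env) / sigma_h)


def select_by_shift_2d(entries, spec: SelectionSpec,
                       rng: np.random.Generator | None = None) -> list[int]:
    """2D shift-targeted selection for bonded C–H pairs.

    *entries* is a sequence of ``(entry_id, delta_13C, delta_1H)``.  Each of
    the *n* draws comes from the axis-aligned 2D Gaussian centered on
    (δ13C_exp, δ1H_exp); the unselected entry minimizing
    :func:`shift_distance_2d` to the draw is taken.
    """
    if spec.mode != "shift_2d":
        raise ValidationError("select_by_shift_2d requires mode='shift_2d'")
    entries = sorted(entries, key=lambda t: t[0])
    _check_size(len(entries), spec.n)
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    tc, th = spec.targets
    sc, sh = spec.widths
    ids = np.array([e[0] for e in entries])
    dc = np.array([e[1] for e in entries], dtype=float)
    dh = np.array([e[2] for e in entries], dtype=float)
    available = np.ones(len(ids), dtype=bool)
    out = []
    for _ in range(spec.n):
        c = rng.normal(tc, sc)
        h = rng.normal(th, sh)
        d = np.hypot((c - dc) / sc, (h - dh) / sh)
        d[~available] = np.inf
        best = d.min()
        cand = np.nonzero(d <= best)[0]
        if len(cand) > 1:
            cand = cand[np.argsort(ids[cand], kind="stable")]
        k = int(cand[0])
        available[k] = False
        out.append(int(ids[k]))
    return out
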