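"""Shared fixtures: reference molecules, a small synthetic database, and a
brute-force labeled-isomorphism oracle independent of the VF2 path."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from shiftmaps.maps import MapConfig
from shiftmaps.synthetic import FixtureSpec, acid_proton_query, make_fixture_database
from shiftmaps.synthetic import _build_motif  # noqa: F401  (reused in tests)


@pytest.fixture(autouse=True)
def _quiet_hydrogen_warnings():
    # fixture molecules are chemically sane; silence only our own warnings
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    """Default study conditions: Δ = 4 ppm, noise 0.2 ppm, 60-structure db."""
    return FixtureSpec(n_structures=60, seed=202)


@pytest.fixture(scope="session")
def toy_db(fixture_spec):
    db, labels = make_fixture_database(fixture_spec)
    return db, labels


@pytest.fixture(scope="session")
def reference_molecule():
    """Isolated formic-acid reference conformation (sites C,O,O,HC,HO)."""
    return _build_motif("isolated", (13.0, 13.0, 13.0), np.eye(3), "ref")


@pytest.fixture(scope="session")
def acid_query(fixture_spec):
    return acid_proton_query(fixture_spec, hbonded=True)


@pytest.fixture(scope="session")
def test_config() -> MapConfig:
    """Pipeline constants scaled to the toy database size."""
    return MapConfig(n_select=30, min_matches=10)


def brute_force_isomorphism(g1, center1, g2, center2) -> bool:
    """Exhaustive backtracking search for an element- and center-preserving
    graph isomorphism; independent of networkx's VF2 implementation."""
    n1, n2 = sorted(g1.nodes), sorted(g2.nodes)
    if len(n1) != len(n2):
        return False
    e1 = sorted(g1.nodes[v]["element"] for v in n1)
    e2 = sorted(g2.nodes[v]["element"] for v in n2)
    if e1 != e2:
        return False
    order = [center1] + [v for v in n1 if v != center1]

    def extend(mapping: dict) -> bool:
        if len(mapping) == len(order):
            return True
        v = order[len(mapping)]
        used = set(mapping.values())
        for w in n2:
            if w in used:
                continue
            if g1.nodes[v]["element"] != g2.nodes[w]["element"]:
                continue
            if v == center1 and w != center2:
                continue
            if v != center1 and w == center2:
                continue
            ok = True
            for u, mu in mapping.items():
                if g1.has_edge(v, u) != g2.has_edge(w, mu):
                    ok = False
                    break
            if ok:
                mapping[v] = w
                if extend(mapping):
                    return True
                del mapping[v]
        return False

    if g1.degree(center1) != g2.degree(center2):
        return False
    return extend({center1: center2})
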