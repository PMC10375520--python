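"""Database build/query and random vs shift-targeted environment selection."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from shiftmaps.covalent import build_descriptor, descriptors_match, perceive_bonds
from shiftmaps.envdb import (EnvironmentDatabase, SelectionSpec, build_database,
                             select_by_shift_1d, select_by_shift_2d, select_random,
                             shift_distance_2d)
from shiftmaps.errors import InsufficientMatchesError, ValidationError
from shiftmaps.shifts import ShiftRecord
from shiftmaps.synthetic import FixtureSpec, generate_toy_crystals, pseudo_shift


@pytest.fixture(scope="module")
def mini_db():
    spec = FixtureSpec(n_structures=8, seed=5)
    structures, _ = generate_toy_crystals(spec)
    rng = np.random.default_rng(5)
    records = []
    for st in structures:
        g = perceive_bonds(st)
        for i, s in enumerate(st.sites):
            if s.element in ("H", "C"):
                records.append(pseudo_shift(st, i, spec, rng=rng, graph=g))
    return build_database(structures, records), structures, records


class TestBuildDatabase:
    def test_entry_count_equals_record_count(self, mini_db):
        db, _, records = mini_db
        assert len(db) == len(records)

    def test_duplicate_record_rejected(self, mini_db):
        _, structures, records = mini_db
        with pytest.raises(ValidationError, match="duplicate"):
            build_database(structures, records + [records[0]])

    def test_dangling_structure_id_rejected(self, mini_db):
        _, structures, _ = mini_db
        bad = [ShiftRecord("nope", 0, "H", 5.0, 0.5)]
        with pytest.raises(ValidationError, match="unknown structure"):
            build_database(structures, bad)

    def test_empty_shift_table_gives_empty_db(self, mini_db):
        _, structures, _ = mini_db
        db = build_database(structures, [])
        assert len(db) == 0
        g = perceive_bonds(structures[0])
        assert db.query(build_descriptor(g, 4, 2)) == []

    def test_save_load_round_trip_rebuilds_index(self, mini_db, tmp_path):
        db, _, _ = mini_db
        p = tmp_path / "db.json.gz"
        db.save(p)
        back = EnvironmentDatabase.load(p)
        assert len(back) == len(db)
        assert back.index == db.index


class TestQuery:
    def test_query_matches_exhaustive_scan(self, mini_db):
        """Key-prefiltered query equals a full isomorphism scan over entries."""
        db, structures, _ = mini_db
        g = perceive_bonds(structures[0])
        for center in (0, 4):  # a carbon and the acid proton
            for w in (1, 2, 4):
                qdesc = build_descriptor(g, center, w)
                got = db.query(qdesc)
                want = []
                for e in db.entries:
                    d = db.descriptor(e.structure_id, e.site_index, w)
                    ok, _ = descriptors_match(qdesc, d)
                    if ok:
                        want.append(e.entry_id)
                assert got == sorted(want)

    def test_results_are_sorted_ids(self, mini_db):
        db, structures, _ = mini_db
        g = perceive_bonds(structures[0])
        ids = db.query(build_descriptor(g, 4, 3))
        assert ids == sorted(ids)
        assert len(ids) > 0


class TestSelectRandom:
    def test_deterministic_distinct_subset(self):
        ids = list(range(100, 400))
        spec = SelectionSpec(mode="random", n=100)
        a = select_random(ids, spec, rng=np.random.default_rng(3))
        b = select_random(ids, spec, rng=np.random.default_rng(3))
        assert a == b
        assert len(set(a)) == 100
        assert set(a) <= set(ids)

    def test_full_set_when_n_equals_size(self):
        ids = [5, 9, 2]
        got = select_random(ids, SelectionSpec(mode="random", n=3),
                            rng=np.random.default_rng(0))
        assert sorted(got) == sorted(ids)

    def test_oversized_request_raises(self):
        with pytest.raises(InsufficientMatchesError, match="only 2"):
            select_random([1, 2], SelectionSpec(mode="random", n=3),
                          rng=np.random.default_rng(0))

    def test_uniformity_chi_square(self):
        """Aggregate pick counts over 500 seeded repetitions are uniform."""
        ids = list(range(40))
        spec = SelectionSpec(mode="random", n=10)
        counts = np.zeros(40)
        for seed in range(500):
            for i in select_random(ids, spec, rng=np.random.default_rng(seed)):
                counts[i] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestSelect1D:
    def test_overwhelmingly_prefers_near_entry(self):
        # entries at 1.0 and 9.0 ppm; target 1.2, sigma 0.5: picking the far
        # one needs a draw beyond 5.0, probability Phi(-7.6) ~ 1e-14
        entries = [(0, 1.0), (1, 9.0)]
        spec = SelectionSpec(mode="shift_1d", n=1, targets=(1.2,), widths=(0.5,))
        hits = sum(select_by_shift_1d(entries, spec,
                                      rng=np.random.default_rng(s))[0] == 0
                   for s in range(200))
        assert hits >= 195

    def test_all_equal_shifts_degenerates_to_id_order(self):
        entries = [(i, 5.0) for i in range(10)]
        spec = SelectionSpec(mode="shift_1d", n=4, targets=(7.0,), widths=(1.0,))
        got = select_by_shift_1d(entries, spec, rng=np.random.default_rng(1))
        assert got == [0, 1, 2, 3]

    def test_sigma_to_zero_limit_is_nearest_sort(self):
        rng = np.random.default_rng(8)
        shifts = rng.uniform(0.0, 10.0, 50)
        entries = list(enumerate(shifts))
        target = 4.2
        spec = SelectionSpec(mode="shift_1d", n=12, targets=(target,),
                             widths=(1e-12,))
        got = select_by_shift_1d(entries, spec, rng=np.random.default_rng(0))
        want = sorted(range(50), key=lambda i: (abs(shifts[i] - target), i))[:12]
        assert sorted(got) == sorted(want)

    def test_selection_statistics_track_target(self):
        """On a dense symmetric pool the selected-shift mean approaches the
        target within 3σ/√n and the spread approaches σ within 20%."""
        rng = np.random.default_rng(123)
        pool = rng.uniform(0.0, 20.0, 20000)
        entries = list(enumerate(pool))
        target, sigma, n = 10.0, 0.5, 400
        spec = SelectionSpec(mode="shift_1d", n=n, targets=(target,),
                             widths=(sigma,))
        picked = select_by_shift_1d(entries, spec, rng=np.random.default_rng(9))
        sel = pool[np.array(picked)]
        assert abs(sel.mean() - target) < 3 * sigma / math.sqrt(n)
        assert abs(sel.std(ddof=1) - sigma) / sigma < 0.20

    def test_no_duplicates(self):
        entries = [(i, float(i)) for i in range(30)]
        spec = SelectionSpec(mode="shift_1d", n=20, targets=(15.0,), widths=(5.0,))
        got = select_by_shift_1d(entries, spec, rng=np.random.default_rng(2))
        assert len(set(got)) == len(got) == 20


class TestShiftDistance2D:
    def test_zero_at_identity(self):
        assert shift_distance_2d(120.0, 7.0, (120.0, 7.0), 5.0, 0.5) == 0.0

    def test_single_axis_normalization(self):
        assert shift_distance_2d(125.0, 7.0, (120.0, 7.0), 5.0, 0.5) == pytest.approx(1.0)

    def test_both_axes_add_in_quadrature(self):
        d = shift_distance_2d(125.0, 7.5, (120.0, 7.0), 5.0, 0.5)
        assert d == pytest.approx(math.sqrt(2.0))

    def test_sign_symmetric(self):
        a = shift_distance_2d(118.0, 6.6, (120.0, 7.0), 5.0, 0.5)
        b = shift_distance_2d(122.0, 7.4, (120.0, 7.0), 5.0, 0.5)
        assert a == pytest.approx(b)


class TestSelect2D:
    def test_single_entry(self):
        spec = SelectionSpec(mode="shift_2d", n=1, targets=(120.0, 7.0),
                             widths=(5.0, 0.5))
        got = select_by_shift_2d([(3, 119.0, 7.1)], spec,
                                 rng=np.random.default_rng(0))
        assert got == [3]

    def test_separated_entries_prefer_near(self):
        entries = [(0, 120.0, 7.0), (1, 20.0, 1.0)]
        spec = SelectionSpec(mode="shift_2d", n=1, targets=(118.0, 6.8),
                             widths=(5.0, 0.5))
        hits = sum(select_by_shift_2d(entries, spec,
                                      rng=np.random.default_rng(s))[0] == 0
                   for s in range(200))
        assert hits >= 195

    def test_sigma_to_zero_limit_is_distance_sort(self):
        rng = np.random.default_rng(4)
        entries = [(i, float(c), float(h))
                   for i, (c, h) in enumerate(zip(rng.uniform(0, 200, 40),
                                                  rng.uniform(0, 12, 40)))]
        target = (110.0, 6.0)
        spec = SelectionSpec(mode="shift_2d", n=10, targets=target,
                             widths=(1e-12, 1e-13))
        got = select_by_shift_2d(entries, spec, rng=np.random.default_rng(0))
        want = sorted(entries,
                      key=lambda e: (shift_distance_2d(e[1], e[2], target, 5.0, 0.5), e[0]))
        assert sorted(got) == sorted(e[0] for e in want[:10])


class TestSelectionSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(mode="bogus"),
        dict(mode="random", n=0),
        dict(mode="shift_1d", targets=(1.0,), widths=(0.0,)),
        dict(mode="shift_1d", targets=()),
        dict(mode="shift_2d", targets=(1.0,), widths=(1.0, 1.0)),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SelectionSpec(**kwargs)
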