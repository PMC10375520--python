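"""Rigid superposition, Gaussian density accumulation, difference maps,
and volumetric file round-trips."""

from __future__ import annotations

import math

import numpy as np
import pytest

from shiftmaps.density import (DensityMap, GridSpec, accumulate_density,
                               anchor_correspondence, difference_map, rigid_align)
from shiftmaps.errors import GeometryError, UsageError, ValidationError
from shiftmaps.structures import LocalEnvironment
from shiftmaps.volumetric import read_volumetric, write_volumetric


def env_with_atoms(elements, coords) -> LocalEnvironment:
    coords = np.asarray(coords, dtype=float)
    return LocalEnvironment(elements=list(elements), coords=coords,
                            center_index=0,
                            site_indices=np.arange(len(elements)),
                            source=("syn", 0))


def horn_quaternion_align(P, Q):
    """Independent closed-form superposition (Horn's quaternion method)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(N)
    q = vecs[:, np.argmax(vals)]
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    # Horn convention rotates column vectors: rmsd of R @ p vs q
    return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))


class TestRigidAlign:
    def test_identity(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        R, t, rmsd = rigid_align(P, P)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0.0, atol=1e-10)
        assert rmsd < 1e-12

    def test_recovers_90_degree_z_rotation(self):
        rot = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        P = np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0.5]])
        Q = P @ rot.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = rigid_align(P, Q)
        assert np.allclose(R, rot, atol=1e-8)
        assert rmsd < 1e-10
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_mirror_of_chiral_set_keeps_proper_rotation(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(4, 3))
        Q = P * np.array([1.0, 1.0, -1.0])  # reflection
        R, t, rmsd = rigid_align(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 1e-3  # a proper rotation cannot reach the mirror image

    def test_collinear_anchors_rejected(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(GeometryError, match="collinear"):
            rigid_align(P, P + 1.0)

    def test_agrees_with_quaternion_method_on_random_sets(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(3, 8))
            P = rng.normal(size=(n, 3))
            Q = rng.normal(size=(n, 3))
            _, _, rmsd = rigid_align(P, Q)
            assert rmsd == pytest.approx(horn_quaternion_align(P, Q), abs=1e-8)


class TestAnchorCorrespondence:
    def test_identity_pairing(self):
        coords = {0: np.zeros(3), 1: np.array([1.0, 0, 0]), 2: np.array([0, 1.0, 0])}
        R, t, rmsd, mp = anchor_correspondence(
            np.array([coords[0], coords[1], coords[2]]), [0, 1, 2], coords,
            [{0: 0, 1: 1, 2: 2}])
        assert rmsd < 1e-12
        assert mp == {0: 0, 1: 1, 2: 2}

    def test_lowest_rmsd_mapping_wins(self):
        # methyl-rotor-like: three equivalent pairings, one aligns exactly
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, 0.9, 0], [0.5, 0.3, 0.8]])
        coords = {i: base[i] for i in range(4)}
        good = {i: i for i in range(4)}
        bad = {0: 0, 1: 2, 2: 3, 3: 1}
        R, t, rmsd, mp = anchor_correspondence(base, [0, 1, 2, 3], coords,
                                               [bad, good])
        assert mp == good
        assert rmsd < 1e-12

    def test_missing_anchor_in_mapping_is_configuration_error(self):
        from shiftmaps.errors import ConfigurationError
        with pytest.raises(ConfigurationError, match="outside the descriptor"):
            anchor_correspondence(np.zeros((3, 3)), [0, 1, 9],
                                  {0: np.zeros(3)}, [{0: 0, 1: 1}])


class TestAccumulateDensity:
    def test_always_present_atom_gives_value_one(self):
        grid = GridSpec()
        envs = [env_with_atoms(["H"], [[0.0, 0.0, 0.0]]) for _ in range(10)]
        dmap = accumulate_density(envs, grid, "H")
        c = grid.points // 2
        assert dmap.values[c, c, c] == pytest.approx(1.0, abs=1e-6)

    def test_adjacent_voxel_closed_form(self):
        grid = GridSpec()
        dmap = accumulate_density([env_with_atoms(["H"], [[0.0, 0.0, 0.0]])],
                                  grid, "H")
        c = grid.points // 2
        expected = math.exp(-(0.4 ** 2) / (2 * 0.25))
        assert dmap.values[c + 1, c, c] == pytest.approx(expected, abs=1e-9)

    def test_absent_element_gives_zero_map(self):
        dmap = accumulate_density([env_with_atoms(["H"], [[0.0, 0.0, 0.0]])],
                                  GridSpec(), "N")
        assert dmap.values.max() == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        envs = [env_with_atoms(["H", "O"], rng.normal(scale=2.0, size=(2, 3)))
                for _ in range(6)]
        grid = GridSpec(points=15, side=8.0)
        a = accumulate_density(envs, grid, "H").values
        b = accumulate_density(envs[::-1], grid, "H").values
        assert np.allclose(a, b, atol=1e-12, rtol=0)

    def test_mass_bound(self):
        """Integrated density per environment cannot exceed the analytic
        Gaussian mass per atom of that element."""
        rng = np.random.default_rng(11)
        n_atoms = 4
        envs = [env_with_atoms(["H"] * n_atoms, rng.normal(scale=1.5, size=(n_atoms, 3)))
                for _ in range(5)]
        grid = GridSpec(points=31, side=12.0)
        dmap = accumulate_density(envs, grid, "H")
        total = dmap.values.sum() * grid.spacing ** 3
        bound = n_atoms * (2 * math.pi * 0.25) ** 1.5
        assert total <= bound * 1.001

    def test_default_grid_spacing(self):
        assert GridSpec().spacing == pytest.approx(0.4)


class TestDifferenceMap:
    def grid_pair(self):
        grid = GridSpec(points=5, side=2.0)
        z = np.zeros((5, 5, 5))
        return grid, z

    def test_equal_maps_give_zero(self):
        grid, z = self.grid_pair()
        m = DensityMap(grid, "H", z + 0.3, 10, "sim")
        d = difference_map(m, DensityMap(grid, "H", z + 0.3, 10, "iim"))
        assert np.all(d.values == 0.0)

    def test_noise_floor_zeroes_small_values(self):
        grid, z = self.grid_pair()
        sim = z.copy(); sim[0, 0, 0] = 0.005; sim[1, 1, 1] = 0.15
        d = difference_map(DensityMap(grid, "H", sim, 1, "sim"),
                           DensityMap(grid, "H", z, 1, "iim"))
        assert d.values[0, 0, 0] == 0.0
        assert d.values[1, 1, 1] == pytest.approx(0.15)

    def test_reverse_flag_flips_sign(self):
        grid, z = self.grid_pair()
        sim = z.copy(); sim[2, 2, 2] = 0.4
        fwd = difference_map(DensityMap(grid, "H", sim, 1, "sim"),
                             DensityMap(grid, "H", z, 1, "iim"))
        rev = difference_map(DensityMap(grid, "H", sim, 1, "sim"),
                             DensityMap(grid, "H", z, 1, "iim"), reverse=True)
        assert np.array_equal(rev.values, -fwd.values)

    def test_grid_mismatch_rejected(self):
        grid, z = self.grid_pair()
        other = GridSpec(points=5, side=4.0)
        with pytest.raises(ValidationError):
            difference_map(DensityMap(grid, "H", z, 1, "sim"),
                           DensityMap(other, "H", z, 1, "iim"))


class TestVolumetric:
    @pytest.mark.parametrize("fmt,suffix", [("cube", ".cube"), ("ccp4", ".ccp4")])
    def test_round_trip(self, tmp_path, fmt, suffix):
        rng = np.random.default_rng(0)
        grid = GridSpec(center=(1.0, -2.0, 0.5), points=31, side=12.0)
        dmap = DensityMap(grid, "O", rng.random((31, 31, 31)), 50, "sim")
        p = tmp_path / f"map{suffix}"
        write_volumetric(dmap, p, fmt)
        back = read_volumetric(p, fmt)
        assert np.abs(back.values - dmap.values).max() < 1e-5
        assert np.allclose(back.grid.center, grid.center, atol=1e-4)
        assert back.grid.spacing == pytest.approx(grid.spacing, abs=1e-6)

    def test_zero_and_single_voxel(self, tmp_path):
        grid = GridSpec(points=31)
        z = np.zeros((31, 31, 31))
        p = tmp_path / "zero.cube"
        write_volumetric(DensityMap(grid, "H", z, 1), p)
        assert read_volumetric(p).values.max() == 0.0
        z[3, 4, 5] = 1.0
        p2 = tmp_path / "one.mrc"
        write_volumetric(DensityMap(grid, "H", z, 1), p2)
        back = read_volumetric(p2)
        assert back.values[3, 4, 5] == pytest.approx(1.0, abs=1e-6)

    def test_unknown_format_rejected(self, tmp_path):
        grid = GridSpec(points=5, side=2.0)
        dmap = DensityMap(grid, "H", np.zeros((5, 5, 5)), 1)
        with pytest.raises(UsageError):
            write_volumetric(dmap, tmp_path / "m.xyz", "dx")
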