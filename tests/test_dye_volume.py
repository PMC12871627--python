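"""Accessible-volume dye sampling against brute-force grid oracles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from fretpipe.dye_volume import (
    CLASH_PROBE,
    BuriedSiteError,
    DyeSite,
    ResidueLookupError,
    StructureModel,
    mean_dye_distance,
    sample_dye_positions,
)


def make_structure(atoms):
    """atoms: list of (chain, res_id, atom_name, element, xyz)."""
    return StructureModel(
        chain=np.array([a[0] for a in atoms]),
        res_id=np.array([a[1] for a in atoms]),
        atom_name=np.array([a[2] for a in atoms]),
        element=np.array([a[3] for a in atoms]),
        coord=np.array([a[4] for a in atoms], dtype=float),
    )


def single_site(xyz=(0.0, 0.0, 0.0), chain="A", res=1):
    return [(chain, res, "CB", "C", xyz)]


def wall(x0, span=25.0, spacing=1.0, chain="W", res=999):
    """Dense plane of atoms at x = x0 (separate residue, so it clashes)."""
    ys = np.arange(-span, span + spacing, spacing)
    zs = np.arange(-span, span + spacing, spacing)
    atoms = []
    for y in ys:
        for z in zs:
            atoms.append((chain, res, "X", "C", (x0, y, z)))
    return atoms


def grid_accessible(origin, reach, clash_coords, min_dist, spacing=0.25):
    """Brute-force accessible volume on a dense grid, same clash rule."""
    ax = np.arange(-reach, reach + spacing, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + np.asarray(origin)
    inside = np.linalg.norm(pts - origin, axis=1) <= reach
    pts = pts[inside]
    if len(clash_coords):
        d, _ = cKDTree(clash_coords).query(pts, k=1)
        pts = pts[d >= min_dist]
    return pts


class TestSampling:
    def test_unobstructed_samples_within_reach(self):
        structure = make_structure(single_site())
        site = DyeSite("A", 1, linker_length=10.0, n_samples=500, seed=0)
        pts = sample_dye_positions(structure, site)
        assert len(pts) == 500
        assert np.all(np.linalg.norm(pts, axis=1) <= 10.0 + 1e-9)

    def test_deterministic_under_seed(self):
        structure = make_structure(single_site())
        site = DyeSite("A", 1, linker_length=10.0, n_samples=100, seed=5)
        assert np.array_equal(
            sample_dye_positions(structure, site), sample_dye_positions(structure, site)
        )

    def test_buried_site_raises(self):
        # attachment fully enclosed by a dense shell of atoms
        atoms = single_site()
        rng = np.random.default_rng(0)
        for i in range(800):
            v = rng.normal(size=3)
            v = 6.0 * v / np.linalg.norm(v)
            atoms.append(("S", 100 + i, "X", "C", tuple(v)))
        structure = make_structure(atoms)
        site = DyeSite("A", 1, linker_length=10.0, dye_radius=5.0, n_samples=50, seed=1)
        with pytest.raises(BuriedSiteError):
            sample_dye_positions(structure, site, max_attempts=20000)

    def test_missing_residue_raises(self):
        structure = make_structure(single_site())
        with pytest.raises(ResidueLookupError):
            sample_dye_positions(structure, DyeSite("A", 99))

    def test_half_space_occlusion_matches_grid_centroid(self):
        # atom wall at x=4: accessible centroid shifts away from the wall
        site = DyeSite("A", 1, linker_length=10.0, dye_radius=3.0, n_samples=4000, seed=2)
        atoms = single_site() + wall(4.0)
        structure = make_structure(atoms)
        pts = sample_dye_positions(structure, site, max_attempts=10_000_000)
        wall_coords = np.array([a[4] for a in wall(4.0)], dtype=float)
        oracle = grid_accessible(
            (0, 0, 0), 10.0, wall_coords, min_dist=3.0 + CLASH_PROBE
        )
        assert pts.mean(axis=0)[0] < -0.5  # displaced away from the wall
        assert np.linalg.norm(pts.mean(axis=0) - oracle.mean(axis=0)) < 0.5


class TestMeanDistance:
    def test_point_dye_limit(self):
        atoms = single_site((0, 0, 0), "A", 1) + single_site((50, 0, 0), "B", 2)
        structure = make_structure(atoms)
        sa = DyeSite("A", 1, linker_length=1e-6, n_samples=20, seed=0)
        sb = DyeSite("B", 2, linker_length=1e-6, n_samples=20, seed=1)
        mean_nm, sd_nm = mean_dye_distance(structure, sa, sb)
        assert mean_nm == pytest.approx(5.0, abs=1e-6)

    def test_triangle_inequality_bounds(self):
        atoms = single_site((0, 0, 0), "A", 1) + single_site((50, 0, 0), "B", 2)
        structure = make_structure(atoms)
        sa = DyeSite("A", 1, linker_length=12.0, n_samples=200, seed=0)
        sb = DyeSite("B", 2, linker_length=12.0, n_samples=200, seed=1)
        mean_nm, _ = mean_dye_distance(structure, sa, sb)
        assert 5.0 - 2 * 1.2 <= mean_nm <= 5.0 + 2 * 1.2

    def test_symmetric_in_site_order(self):
        atoms = single_site((0, 0, 0), "A", 1) + single_site((30, 5, 0), "B", 2)
        structure = make_structure(atoms)
        sa = DyeSite("A", 1, linker_length=8.0, n_samples=150, seed=3)
        sb = DyeSite("B", 2, linker_length=8.0, n_samples=150, seed=4)
        assert mean_dye_distance(structure, sa, sb)[0] == pytest.approx(
            mean_dye_distance(structure, sb, sa)[0]
        )

    def test_two_wall_fixture_matches_grid_oracle(self):
        # both sites half-occluded: MC mean distance within 1 A of grid oracle
        atoms = (
            single_site((0, 0, 0), "A", 1)
            + single_site((40, 0, 0), "B", 2)
            + wall(5.0, chain="W", res=900)
            + wall(35.0, chain="V", res=901)
        )
        structure = make_structure(atoms)
        sa = DyeSite("A", 1, linker_length=9.0, dye_radius=2.0, n_samples=900, seed=5)
        sb = DyeSite("B", 2, linker_length=9.0, dye_radius=2.0, n_samples=900, seed=6)
        mean_nm, _ = mean_dye_distance(structure, sa, sb)

        min_dist = 2.0 + CLASH_PROBE
        wall_a = np.array([a[4] for a in wall(5.0)], dtype=float)
        wall_b = np.array([a[4] for a in wall(35.0)], dtype=float)
        clash = np.vstack([wall_a, wall_b])
        ga = grid_accessible((0, 0, 0), 9.0, clash, min_dist, spacing=0.6)
        gb = grid_accessible((40, 0, 0), 9.0, clash, min_dist, spacing=0.6)
        # mean cross-pair distance between the two accessible grids
        rng = np.random.default_rng(0)
        ia = rng.integers(0, len(ga), 200_000)
        ib = rng.integers(0, len(gb), 200_000)
        oracle_nm = np.linalg.norm(ga[ia] - gb[ib], axis=1).mean() / 10.0
        assert abs(mean_nm - oracle_nm) < 0.1  # 1 angstrom

    def test_rigid_motion_invariance(self):
        # full residues so a local frame exists; rotation+translation of the
        # structure leaves the mean distance unchanged under seed re-use
        def residue(chain, res, base):
            base = np.asarray(base, float)
            return [
                (chain, res, "N", "N", tuple(base + [0.0, 1.4, 0.0])),
                (chain, res, "CA", "C", tuple(base)),
                (chain, res, "C", "C", tuple(base + [1.0, -1.0, 0.3])),
                (chain, res, "CB", "C", tuple(base + [1.5, 0.0, 0.0])),
            ]

        atoms = residue("A", 1, (0, 0, 0)) + residue("B", 2, (45, 3, -2))
        structure = make_structure(atoms)
        sa = DyeSite("A", 1, linker_length=8.0, n_samples=200, seed=7)
        sb = DyeSite("B", 2, linker_length=8.0, n_samples=200, seed=8)
        d0 = mean_dye_distance(structure, sa, sb)[0]

        theta = 0.9
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = structure.transformed(rot, np.array([12.0, -7.0, 30.0]))
        d1 = mean_dye_distance(moved, sa, sb)[0]
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_standard_error_shrinks_with_samples(self):
        atoms = single_site((0, 0, 0), "A", 1) + single_site((30, 0, 0), "B", 2)
        structure = make_structure(atoms)

        def spread(n, n_rep=12):
            vals = [
                mean_dye_distance(
                    structure,
                    DyeSite("A", 1, linker_length=10.0, n_samples=n, seed=100 + r),
                    DyeSite("B", 2, linker_length=10.0, n_samples=n, seed=200 + r),
                )[0]
                for r in range(n_rep)
            ]
            return np.std(vals)

        assert spread(400) < spread(25)
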