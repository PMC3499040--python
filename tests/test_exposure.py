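"""SASA, polar accessibility, H-bond counts, half-sphere exposure, depth."""

import math

import numpy as np
import pytest

from zincsite.exposure import (PROBE_RADIUS, VDW_RADII, all_polar_abs,
                               compute_exposure, half_sphere_exposure,
                               hbond_counts, residue_depths, shrake_rupley)
from zincsite.structure import Atom, ProteinChain, Residue


def _res(chain_id, idx, res_type, named_atoms):
    atoms = [Atom(name=n, element=e, coords=c) for n, e, c in named_atoms]
    return Residue(chain_id=chain_id, seq_index=idx, res_type=res_type, atoms=atoms)


class TestSasa:
    def test_isolated_carbon_matches_sphere_area(self):
        areas = shrake_rupley(np.zeros((1, 3)), ["C"])
        expected = 4 * math.pi * (VDW_RADII["C"] + PROBE_RADIUS) ** 2
        assert areas[0] == pytest.approx(expected, rel=0.02)

    def test_caged_atom_is_buried(self):
        # surround a carbon with a dense shell of carbons at 2.5 A
        phi = np.linspace(0, math.pi, 12)[1:-1]
        theta = np.linspace(0, 2 * math.pi, 24, endpoint=False)
        shell = [(2.5 * math.sin(p) * math.cos(t), 2.5 * math.sin(p) * math.sin(t),
                  2.5 * math.cos(p)) for p in phi for t in theta]
        shell += [(0, 0, 2.5), (0, 0, -2.5)]
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        areas = shrake_rupley(coords, ["C"] * len(coords))
        assert areas[0] == 0.0

    def test_distant_atoms_are_independent(self):
        areas = shrake_rupley(np.array([[0.0, 0, 0], [50.0, 0, 0]]), ["C", "C"])
        assert areas[0] == pytest.approx(areas[1])
        single = shrake_rupley(np.zeros((1, 3)), ["C"])[0]
        assert areas[0] == pytest.approx(single)

    def test_rigid_motion_invariance_with_corotated_lattice(self, rng):
        coords = rng.uniform(-4, 4, size=(20, 3))
        elements = ["C", "N", "O", "S"] * 5
        base = shrake_rupley(coords, elements)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = coords @ q.T + np.array([10.0, -3.0, 7.0])
        rotated = shrake_rupley(moved, elements, orientation=q)
        np.testing.assert_allclose(rotated, base, rtol=1e-6)
        # without co-rotating the lattice the total area still agrees closely
        plain = shrake_rupley(moved, elements)
        assert plain.sum() == pytest.approx(base.sum(), rel=0.02)

    def test_unknown_element_gets_default_radius(self):
        areas = shrake_rupley(np.zeros((1, 3)), ["ZZ"])
        assert areas[0] == pytest.approx(4 * math.pi * (1.8 + PROBE_RADIUS) ** 2,
                                         rel=0.02)


class TestPolarSideChain:
    def test_glycine_has_no_polar_side_chain(self):
        res = _res("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0)),
                                   ("C", "C", (2.2, 1.2, 0)), ("O", "O", (3.2, 1.2, 0))])
        sasa = {id(a): 10.0 for a in res.atoms}
        assert all_polar_abs(res, sasa) == 0.0

    def test_isolated_asp_sums_carboxylate_oxygens(self):
        res = _res("A", 1, "ASP", [
            ("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0)),
            ("CG", "C", (2.5, 1.0, 0)), ("OD1", "O", (30.0, 0, 0)),
            ("OD2", "O", (-30.0, 0, 0))])
        coords = np.array([a.coords for a in res.atoms])
        areas = shrake_rupley(coords, [a.element for a in res.atoms])
        sasa = {id(a): areas[i] for i, a in enumerate(res.atoms)}
        sphere_o = 4 * math.pi * (VDW_RADII["O"] + PROBE_RADIUS) ** 2
        assert all_polar_abs(res, sasa) == pytest.approx(2 * sphere_o, rel=0.02)


class TestHbonds:
    def _chain(self, pairs):
        residues = [_res("A", i + 1, "SER", atoms) for i, atoms in enumerate(pairs)]
        return ProteinChain("A", residues)

    def test_single_pair_counts_once_for_each(self):
        chain = self._chain([[("N", "N", (0, 0, 0))], [("O", "O", (2.9, 0, 0))]])
        counts = hbond_counts([chain])
        assert counts["A:1"] == 1 and counts["A:2"] == 1

    def test_above_cutoff_is_zero(self):
        chain = self._chain([[("N", "N", (0, 0, 0))], [("O", "O", (3.8, 0, 0))]])
        assert hbond_counts([chain]) == {"A:1": 0, "A:2": 0}

    def test_one_acceptor_two_donors(self):
        chain = self._chain([[("O", "O", (0, 0, 0))],
                             [("N", "N", (2.8, 0, 0))],
                             [("N", "N", (0, 3.0, 0))]])
        counts = hbond_counts([chain])
        assert counts["A:1"] == 2
        assert counts["A:2"] == 1 and counts["A:3"] == 1


class TestHalfSphereExposure:
    def _two_residue_chain(self, neighbor_ca):
        # residue 1 at origin with CB along +x; neighbor residue's CA given
        r1 = _res("A", 1, "ALA", [("N", "N", (-1.4, 0.2, 0)), ("CA", "C", (0, 0, 0)),
                                  ("C", "C", (1.1, 1.1, 0)), ("CB", "C", (1.53, 0, 0))])
        r2 = _res("A", 2, "ALA", [("N", "N", tuple(np.add(neighbor_ca, (-1.4, 0, 0)))),
                                  ("CA", "C", neighbor_ca),
                                  ("C", "C", tuple(np.add(neighbor_ca, (1.1, 1.1, 0)))),
                                  ("CB", "C", tuple(np.add(neighbor_ca, (0.5, 1.4, 0))))])
        return ProteinChain("A", [r1, r2])

    def test_neighbor_in_upper_half_sphere(self):
        hse = half_sphere_exposure(self._two_residue_chain((5.0, 0.0, 0.0)))
        hseau, hsead, _, _, cn = hse["A:1"]
        assert (hseau, hsead, cn) == (1, 0, 1)

    def test_neighbor_in_lower_half_sphere(self):
        hse = half_sphere_exposure(self._two_residue_chain((-5.0, 0.0, 0.0)))
        hseau, hsead, _, _, cn = hse["A:1"]
        assert (hseau, hsead, cn) == (0, 1, 1)

    def test_neighbor_outside_radius(self):
        hse = half_sphere_exposure(self._two_residue_chain((14.0, 0.0, 0.0)))
        assert hse["A:1"][4] == 0

    def test_up_down_sum_equals_cn_everywhere(self, small_structures):
        for st in small_structures:
            for chain in st.chains:
                for hseau, hsead, _, _, cn in half_sphere_exposure(chain).values():
                    assert hseau + hsead == cn

    def test_cn_monotone_in_radius(self, small_structures):
        chain = small_structures[0].chains[0]
        cn_small = [v[4] for v in half_sphere_exposure(chain, radius=8.0).values()]
        cn_large = [v[4] for v in half_sphere_exposure(chain, radius=13.0).values()]
        assert all(a <= b for a, b in zip(cn_small, cn_large))


class TestResidueDepth:
    def test_exposed_atom_has_near_zero_depth(self):
        res = _res("A", 1, "ALA", [("CA", "C", (0, 0, 0))])
        chain = ProteinChain("A", [res])
        _, surface = shrake_rupley(np.zeros((1, 3)), ["C"], return_surface=True)
        depths = residue_depths([chain], surface)
        rd, rda = depths["A:1"]
        assert rd == pytest.approx(VDW_RADII["C"] + PROBE_RADIUS, abs=0.2)
        assert rd == rda  # single-atom residue

    def test_center_of_ball_depth_matches_radius(self):
        # a dense grid ball of carbons, radius 10 A, atom at the center:
        # the surface sits one solvent-extended radius beyond the hull
        grid = np.arange(-10, 10.1, 2.0)
        pts = np.array([(x, y, z) for x in grid for y in grid for z in grid
                        if x * x + y * y + z * z <= 100.0])
        _, surface = shrake_rupley(pts, ["C"] * len(pts), return_surface=True)
        center_res = _res("A", 1, "ALA", [("CA", "C", (0, 0, 0))])
        chain = ProteinChain("A", [center_res])
        rd, rda = residue_depths([chain], surface)["A:1"]
        hull = 10.0 + VDW_RADII["C"] + PROBE_RADIUS
        assert rda == pytest.approx(hull, abs=2.5)
        assert rd == rda

    def test_empty_surface_gives_zero(self):
        res = _res("A", 1, "ALA", [("CA", "C", (0, 0, 0))])
        chain = ProteinChain("A", [res])
        assert residue_depths([chain], np.empty((0, 3)))["A:1"] == (0.0, 0.0)


class TestAggregate:
    def test_full_structure_records(self, small_structures):
        st = small_structures[0]
        records = compute_exposure(st.chains, n_sphere_points=240)
        assert len(records) == len(st.chains[0])
        for rec in records.values():
            assert rec.sasa_total >= 0
            assert rec.hseau + rec.hsead == rec.cn
            assert rec.rd >= 0 and rec.rda >= 0
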