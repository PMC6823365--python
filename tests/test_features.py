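import numpy as np
import pytest

from groovekit import features as feat
from groovekit import synthetic
from groovekit.model_io import SelectionError, select
from groovekit.synthetic import ToyGrooveSpec

from .conftest import brute_force_min_distance, ring_layout


def _rigid(coords, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return coords @ q.T + rng.uniform(-30, 30, 3)


def _transformed(structure, seed=0):
    return structure.with_coords(_rigid(structure.coords, seed))


class TestMinResidueDistance:
    def test_two_single_atom_residues(self):
        from groovekit.model_io import AtomRecord, Structure

        atoms = [
            AtomRecord(1, "CA", "GLY", "A", 1, np.array([0.0, 0, 0]), "C"),
            AtomRecord(2, "CA", "GLY", "A", 2, np.array([4.0, 0, 0]), "C"),
        ]
        s = Structure(atoms)
        assert feat.min_residue_distance(s, ("A", 1), ("A", 2)) == pytest.approx(4.0)

    def test_matches_brute_force(self, groove_structure):
        s = groove_structure
        for ra, rb in [(302, 343), (333, 439), (337, 447)]:
            ia = select(s, "A", [ra], "heavy").indices
            ib = select(s, "A", [rb], "heavy").indices
            oracle = brute_force_min_distance(s, ia, ib)
            assert feat.min_residue_distance(s, ("A", ra), ("A", rb)) == (
                pytest.approx(oracle, abs=1e-12)
            )

    def test_engaged_frame_at_3p2(self):
        from groovekit.model_io import AtomRecord, Structure

        atoms = [
            AtomRecord(1, "CD1", "LEU", "A", 302, np.array([0.0, 0, 0]), "C"),
            AtomRecord(2, "CD1", "ILE", "A", 343, np.array([3.2, 0, 0]), "C"),
        ]
        s = Structure(atoms)
        d = feat.min_residue_distance(s, ("A", 302), ("A", 343))
        assert d == pytest.approx(3.2, abs=1e-9)
        assert d < feat.TM3_TM4_CUTOFF


class TestGluArgDistance:
    def test_hand_placed_minimum(self):
        from groovekit.model_io import AtomRecord, Structure

        def res(resnum, resname, names, base):
            return [
                AtomRecord(0, n, resname, "A", resnum,
                           np.array(base) + [0.0, 0.6 * i, 0.0], n[0])
                for i, n in enumerate(names)
            ]

        atoms = res(313, "GLU", ["CA", "OE1", "OE2"], [0, 0, 0])
        atoms += res(432, "ARG", ["CA", "NE", "NH1", "NH2"], [3.0, 0.6, 0.0])
        s = Structure(atoms)
        # closest admissible pair: OE2 (0, 1.2, 0) vs NE (3.0, 1.2, 0) -> 3.0
        assert feat.glu_arg_distance(s, ("A", 313), ("A", 432)) == pytest.approx(
            3.0, abs=1e-9
        )

    def test_truncated_sidechain_errors(self):
        from groovekit.model_io import AtomRecord, Structure

        atoms = [
            AtomRecord(1, "CA", "GLU", "A", 313, np.array([0.0, 0, 0]), "C"),
            AtomRecord(2, "NE", "ARG", "A", 432, np.array([3.0, 0, 0]), "N"),
            AtomRecord(3, "CA", "ARG", "A", 432, np.array([3.5, 0, 0]), "C"),
        ]
        s = Structure(atoms)
        with pytest.raises(SelectionError, match="OE1"):
            feat.glu_arg_distance(s, ("A", 313), ("A", 432))

    def test_backbone_oxygen_flag(self, groove_structure):
        d_side = feat.glu_arg_distance(groove_structure, ("A", 313), ("A", 432))
        d_back = feat.glu_arg_distance(groove_structure, ("A", 313), ("A", 432),
                                       use_backbone_oxygen=True)
        assert d_side != pytest.approx(d_back)


class TestFeatureVector:
    def test_hand_computed_values(self, groove_structure):
        fv = feat.feature_vector(groove_structure)
        s = groove_structure
        expected = [
            feat.min_residue_distance(s, ("A", 333), ("A", 439)),
            feat.min_residue_distance(s, ("A", 439), ("A", 432)),
            feat.glu_arg_distance(s, ("A", 313), ("A", 432)),
            feat.glu_arg_distance(s, ("A", 318), ("A", 432)),
        ]
        np.testing.assert_allclose(fv.as_array()[:4], expected, atol=1e-12)

    def test_rigid_motion_invariance(self, groove_structure):
        fv0 = feat.feature_vector(groove_structure).as_array()
        fv1 = feat.feature_vector(_transformed(groove_structure, 5)).as_array()
        np.testing.assert_allclose(fv0, fv1, atol=1e-9)


class TestClassifyGroove:
    @pytest.mark.parametrize(
        "d,expected", [(7.0, True), (8.5, True), (12.0, False)]
    )
    def test_occlusion_cutoff(self, d, expected):
        fv = feat.GrooveFeatures(5, 5, 5, 5, d)
        assert feat.classify_groove(fv).occluded is expected

    def test_scripted_trajectory_labels_recovered(self, groove_spec):
        script = [True, False, True, True, False]
        ref, frames = synthetic.make_groove_trajectory(groove_spec, script)
        labels = []
        for f in frames:
            s = ref.with_coords(f.coords)
            fv = feat.feature_vector(s)
            labels.append(feat.classify_groove(fv).occluded)
        assert labels == script


class TestWaterCounting:
    def _with_waters(self, positions):
        spec = ToyGrooveSpec(residue_positions=ring_layout(),
                             water_positions=positions)
        return synthetic.make_toy_groove(spec)

    def _sidechain_atom(self, s, resnum):
        idx = select(s, "A", [resnum], "sidechain_heavy").indices
        return s.atoms[idx[0]].coords

    def test_water_at_2p9_counted(self):
        s0 = synthetic.make_toy_groove(ToyGrooveSpec(residue_positions=ring_layout()))
        target = self._sidechain_atom(s0, 337)
        s = self._with_waters([target + np.array([2.9, 0.0, 0.0])])
        hc = feat.count_region_waters(s, "groove")
        assert hc.n_groove_waters == 1

    def test_water_at_3p1_not_counted(self):
        s0 = synthetic.make_toy_groove(ToyGrooveSpec(residue_positions=ring_layout()))
        target = self._sidechain_atom(s0, 337)
        # 3.1 Å from residue 337's first sidechain atom and far from others
        # 40 Å above the groove: farther than 3 Å from every lining atom
        s = self._with_waters([target + np.array([0.0, 0.0, 40.0])])
        hc = feat.count_region_waters(s, "groove")
        assert hc.n_groove_waters == 0

    def test_slab_count_matches_oracle(self, groove_spec):
        s0 = synthetic.make_toy_groove(groove_spec)
        z381 = groove_spec.residue_positions[381][2]
        z436 = groove_spec.residue_positions[436][2]
        z_lo, z_hi = sorted([z381, z436])
        rng = np.random.default_rng(11)
        inside = [np.array([30.0 + i, 30.0, rng.uniform(z_lo, z_hi)])
                  for i in range(12)]
        outside = [np.array([30.0 + i, 35.0, z_hi + 5.0 + i]) for i in range(7)]
        spec = ToyGrooveSpec(residue_positions=groove_spec.residue_positions,
                             water_positions=inside + outside)
        s = synthetic.make_toy_groove(spec)
        hc = feat.count_region_waters(s, "slab")
        assert hc.n_slab_waters == 12

    def test_groove_count_matches_brute_force(self, groove_spec):
        rng = np.random.default_rng(2)
        waters = [rng.uniform(-15, 15, 3) for _ in range(40)]
        spec = ToyGrooveSpec(residue_positions=groove_spec.residue_positions,
                             water_positions=waters)
        s = synthetic.make_toy_groove(spec)
        lining_idx = []
        for r in feat.GROOVE_LINING_RESIDUES:
            if s.has_residue("A", r):
                lining_idx += list(select(s, "A", [r], "sidechain_heavy").indices)
        lining = np.array([s.atoms[i].coords for i in lining_idx])
        count = 0
        for w in waters:
            if np.min(np.linalg.norm(lining - w, axis=1)) <= 3.0:
                count += 1
        present = [r for r in feat.GROOVE_LINING_RESIDUES if s.has_residue("A", r)]
        hc = feat.count_region_waters(s, "groove", lining_residues=present)
        assert hc.n_groove_waters == count

    def test_no_waters_returns_zero(self, groove_structure):
        present = [r for r in feat.GROOVE_LINING_RESIDUES
                   if groove_structure.has_residue("A", r)]
        hc = feat.count_region_waters(groove_structure, "groove",
                                      lining_residues=present)
        assert hc.n_groove_waters == 0

    def test_monotone_in_radius(self, groove_spec):
        rng = np.random.default_rng(8)
        waters = [rng.uniform(-16, 16, 3) for _ in range(30)]
        spec = ToyGrooveSpec(residue_positions=groove_spec.residue_positions,
                             water_positions=waters)
        s = synthetic.make_toy_groove(spec)
        present = [r for r in feat.GROOVE_LINING_RESIDUES if s.has_residue("A", r)]
        counts = [
            feat.count_region_waters(s, "groove", radius=r,
                                     lining_residues=present).n_groove_waters
            for r in (2.0, 3.0, 4.0, 6.0)
        ]
        assert counts == sorted(counts)


class TestLipidPenetration:
    def _structure_with_lipid(self, head, tail):
        spec = ToyGrooveSpec(
            residue_positions=ring_layout(),
            lipid_chains=[{"head": head, "tail": tail}],
        )
        return synthetic.make_toy_groove(spec)

    def _interior_anchor(self):
        positions = ring_layout()
        return positions[381]

    def test_fully_outside(self):
        far = [[200.0 + i, 200.0, 200.0] for i in range(2)]
        tail = [[210.0 + i, 210.0, 210.0] for i in range(8)]
        s = self._structure_with_lipid(far, tail)
        present = [r for r in feat.GROOVE_INTERIOR_RESIDUES if s.has_residue("A", r)]
        lp = feat.lipid_penetration(s, interior_residues=present)
        assert lp.head_fraction == 0.0 and lp.tail_fraction == 0.0

    def test_half_tail_inside(self):
        anchor = self._interior_anchor()
        tail_in = [(anchor + [2.0, 0.5 * i, 0.0]).tolist() for i in range(4)]
        tail_out = [[150.0 + i, 150.0, 150.0] for i in range(4)]
        head = [[160.0, 160.0, 160.0], [161.0, 160.0, 160.0]]
        s = self._structure_with_lipid(head, tail_in + tail_out)
        present = [r for r in feat.GROOVE_INTERIOR_RESIDUES if s.has_residue("A", r)]
        lp = feat.lipid_penetration(s, interior_residues=present)
        assert lp.tail_fraction == pytest.approx(0.5)
        assert lp.head_fraction == 0.0

    def test_all_tail_inside_fraction_one(self):
        anchor = self._interior_anchor()
        tail = [(anchor + [2.0, 0.6 * i, 0.0]).tolist() for i in range(8)]
        head = [[160.0, 160.0, 160.0], [161.0, 160.0, 160.0]]
        s = self._structure_with_lipid(head, tail)
        present = [r for r in feat.GROOVE_INTERIOR_RESIDUES if s.has_residue("A", r)]
        lp = feat.lipid_penetration(s, interior_residues=present)
        assert lp.tail_fraction == 1.0
        assert lp.per_lipid[0][3] == 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        head = [rng.uniform(-15, 15, 3).tolist() for _ in range(2)]
        tail = [rng.uniform(-15, 15, 3).tolist() for _ in range(8)]
        s = self._structure_with_lipid(head, tail)
        present = [r for r in feat.GROOVE_INTERIOR_RESIDUES if s.has_residue("A", r)]
        interior_idx = []
        for r in present:
            interior_idx += list(select(s, "A", [r], "sidechain_heavy").indices)
        interior = np.array([s.atoms[i].coords for i in interior_idx])

        def frac(points):
            hits = sum(
                1 for p in points
                if np.min(np.linalg.norm(interior - np.array(p), axis=1)) <= 5.0
            )
            return hits / len(points)

        lp = feat.lipid_penetration(s, interior_residues=present)
        assert lp.head_fraction == pytest.approx(frac(head))
        assert lp.tail_fraction == pytest.approx(frac(tail))

    def test_unknown_lipid_name_errors(self):
        spec = ToyGrooveSpec(
            residue_positions=ring_layout(),
            lipid_chains=[{"resname": "XXX",
                           "head": [[50.0, 50.0, 50.0]],
                           "tail": [[52.0, 50.0, 50.0]]}],
        )
        s = synthetic.make_toy_groove(spec)
        with pytest.raises(ValueError, match="supported"):
            feat.lipid_penetration(s, lipid_resnames=["XXX"])

    def test_rigid_motion_invariance(self):
        anchor = self._interior_anchor()
        tail = [(anchor + [2.0, 0.6 * i, 0.0]).tolist() for i in range(8)]
        head = [[60.0, 60.0, 60.0], [61.0, 60.0, 60.0]]
        s = self._structure_with_lipid(head, tail)
        present = [r for r in feat.GROOVE_INTERIOR_RESIDUES if s.has_residue("A", r)]
        lp0 = feat.lipid_penetration(s, interior_residues=present)
        lp1 = feat.lipid_penetration(_transformed(s, 9), interior_residues=present)
        assert lp0.head_fraction == pytest.approx(lp1.head_fraction, abs=1e-9)
        assert lp0.tail_fraction == pytest.approx(lp1.tail_fraction, abs=1e-9)
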