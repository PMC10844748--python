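"""Structure I/O, crosslink restraints, superposition, remapping, contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from methylquant.structcheck import (
    Atom,
    CrosslinkPair,
    DomainRange,
    StructureModel,
    ca_distance,
    evaluate_crosslinks,
    polar_contacts,
    pocket_residues,
    read_structure,
    remap_conformation,
    superpose,
    write_structure,
)

PDB_SINGLE = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.000   3.400   3.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.500   4.400   3.500  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C
HETATM    4  O   HOH A 100       7.000   7.000   7.000  1.00  0.00           O
END
"""


def ca_model(positions, chain="A"):
    atoms = [
        Atom(chain, i + 1, "ALA", "CA", "C", tuple(map(float, p)))
        for i, p in enumerate(positions)
    ]
    return StructureModel(atoms)


class TestReadWrite:
    def test_single_residue_roundtrip(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(PDB_SINGLE)
        model = read_structure(p)
        assert len(model) == 4
        assert model.xyz("A", 1, "CA").tolist() == [2.5, 2.0, 3.0]
        out = tmp_path / "out.pdb"
        write_structure(model, out)
        again = read_structure(out)
        assert np.allclose(again.coords, model.coords, atol=1e-3)

    def test_altloc_highest_occupancy_kept_and_water_dropped(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        model = read_structure(p)
        assert model.xyz("A", 1, "CA")[0] == pytest.approx(1.0)
        assert not model.has_atom("A", 100, "O")


class TestCaDistance:
    def test_self_distance_zero(self):
        model = ca_model([(0, 0, 0), (3, 4, 0)])
        assert ca_distance(model, ("A", 1), ("A", 1)) == 0.0

    def test_pythagorean_triple(self):
        model = ca_model([(0, 0, 0), (3, 4, 0)])
        assert ca_distance(model, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_symmetry(self, toy_complex):
        model = toy_complex["model"]
        a, b = ("A", 3), ("B", 2)
        assert ca_distance(model, a, b) == ca_distance(model, b, a)

    def test_missing_ca_names_site(self):
        model = ca_model([(0, 0, 0)])
        with pytest.raises(KeyError, match="A:9"):
            ca_distance(model, ("A", 1), ("A", 9))


class TestEvaluateCrosslinks:
    def test_boundary_inclusive_at_30(self):
        model = ca_model(
            [(0, 0, 0), (10, 0, 0), (29.9, 0, 0), (30.0, 0, 0), (30.1, 0, 0)]
        )
        pairs = [CrosslinkPair(("A", 1), ("A", k)) for k in (2, 3, 4, 5)]
        results, summary = evaluate_crosslinks(model, pairs)
        assert [r.satisfied for r in results] == [True, True, True, False]
        assert (summary["n_satisfied"], summary["n_violated"]) == (3, 1)

    def test_planted_counts_match_construction(self, toy_complex):
        results, summary = evaluate_crosslinks(
            toy_complex["model"], toy_complex["pairs"]
        )
        for got, expected in zip(results, toy_complex["expected"]):
            assert got.ca_distance == pytest.approx(expected.ca_distance, abs=1e-6)
            assert got.satisfied == expected.satisfied
        assert summary["n_satisfied"] == 2 and summary["n_violated"] == 1

    def test_pair_order_permutation_invariant(self, toy_complex):
        pairs = toy_complex["pairs"]
        _, s1 = evaluate_crosslinks(toy_complex["model"], pairs)
        _, s2 = evaluate_crosslinks(toy_complex["model"], pairs[::-1])
        assert (s1["n_satisfied"], s1["n_violated"]) == (
            s2["n_satisfied"], s2["n_violated"]
        )

    def test_unresolvable_site_reported_not_dropped(self, toy_complex):
        pairs = toy_complex["pairs"] + [CrosslinkPair(("A", 999), ("B", 1))]
        results, summary = evaluate_crosslinks(toy_complex["model"], pairs)
        assert len(results) == len(toy_complex["pairs"])
        assert len(summary["errors"]) == 1 and "999" in summary["errors"][0]


class TestSuperpose:
    def zigzag(self, n=12):
        return ca_model([(i * 3.8, i % 2, 0.2 * (i % 3)) for i in range(n)])

    def test_self_superposition_identity(self):
        model = self.zigzag()
        res = superpose(model, model, "A")
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_translation_recovered(self):
        model = self.zigzag()
        moved = model.transformed(np.eye(3), np.array([5.0, -3.0, 2.0]))
        res = superpose(moved, model, "A")
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.translation, [-5.0, 3.0, -2.0], atol=1e-9)

    def test_known_rotation_recovered(self, rng):
        model = self.zigzag()
        for _ in range(5):
            rot = Rotation.random(random_state=rng).as_matrix()
            moved = model.transformed(rot, np.zeros(3))
            res = superpose(moved, model, "A")
            assert np.allclose(res.rotation @ rot, np.eye(3), atol=1e-6)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)
            assert res.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_rmsd_invariant_under_rigid_pretransform(self, rng):
        model = self.zigzag()
        noisy = model.with_coords(model.coords + rng.normal(0, 0.5, (12, 3)))
        base = superpose(noisy, model, "A").rmsd
        rot = Rotation.random(random_state=rng).as_matrix()
        pre = noisy.transformed(rot, np.array([1.0, 2.0, 3.0]))
        assert superpose(pre, model, "A").rmsd == pytest.approx(base, abs=1e-6)

    def test_agrees_with_scipy_align_vectors(self, rng):
        # independent route: scipy's own least-squares rotation solver on
        # the centred point sets must give the same rotation and rmsd
        model = self.zigzag()
        noisy = model.with_coords(
            model.coords @ Rotation.random(random_state=rng).as_matrix().T
            + rng.normal(0, 0.4, (12, 3)) + [4.0, 0.0, -2.0]
        )
        res = superpose(noisy, model, "A")
        a = noisy.coords - noisy.coords.mean(axis=0)
        b = model.coords - model.coords.mean(axis=0)
        rot, rssd = Rotation.align_vectors(b, a)
        assert np.allclose(res.rotation, rot.as_matrix(), atol=1e-8)
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_collinear_selection_flagged(self):
        line = ca_model([(i * 3.8, 0, 0) for i in range(6)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(line, line, "A")

    def test_too_few_atoms(self):
        model = ca_model([(0, 0, 0), (1, 1, 0)])
        with pytest.raises(ValueError, match=">= 3"):
            superpose(model, model, "A")


class TestRemapConformation:
    def test_reference_equals_model_is_noop(self, toy_complex):
        model = toy_complex["model"]
        out = remap_conformation(
            model, toy_complex["hinge"], toy_complex["anchor"], model
        )
        assert np.allclose(out.coords, model.coords, atol=1e-6)

    def test_hinge_geometry_reproduced(self, toy_complex):
        model, reference = toy_complex["model"], toy_complex["reference"]
        out = remap_conformation(
            model, toy_complex["hinge"], toy_complex["anchor"], reference
        )
        mask = out.mask("A")
        assert np.allclose(out.coords[mask], reference.coords[mask], atol=1e-6)

    def test_planted_hinge_angle_within_one_degree(self, toy_complex):
        spec = toy_complex["spec"]
        out = remap_conformation(
            toy_complex["model"], toy_complex["hinge"], toy_complex["anchor"],
            toy_complex["reference"],
        )

        def domain_axis(m, resnums):
            pts = np.array([m.xyz("A", r, "CA") for r in resnums])
            v = pts[-1] - pts[0]
            return v / np.linalg.norm(v)

        d1 = toy_complex["hinge"].resnums()
        d2 = toy_complex["anchor"].resnums()
        cosang = float(np.dot(domain_axis(out, d1), domain_axis(out, d2)))
        angle = np.degrees(np.arccos(np.clip(abs(cosang), -1, 1)))
        # the reference bends domain 1 by hinge_angle relative to domain 2
        assert angle == pytest.approx(180 - spec.hinge_angle, abs=1.0) or \
            angle == pytest.approx(spec.hinge_angle, abs=1.0)

    def test_idempotent(self, toy_complex):
        args = (toy_complex["hinge"], toy_complex["anchor"],
                toy_complex["reference"])
        once = remap_conformation(toy_complex["model"], *args)
        twice = remap_conformation(once, *args)
        assert np.allclose(twice.coords, once.coords, atol=1e-6)

    def test_anchor_internal_distances_preserved(self, toy_complex):
        model = toy_complex["model"]
        out = remap_conformation(
            model, toy_complex["hinge"], toy_complex["anchor"],
            toy_complex["reference"],
        )
        nums = toy_complex["anchor"].resnums()
        for i, j in [(0, 3), (2, 8), (1, 11)]:
            before = ca_distance(model, ("A", nums[i]), ("A", nums[j]))
            after = ca_distance(out, ("A", nums[i]), ("A", nums[j]))
            assert after == pytest.approx(before, abs=1e-9)


def brute_force_polar(model, chain_a, chain_b, cutoff):
    best = {}
    for a in model.atoms:
        if a.chain != chain_a or a.element not in ("N", "O"):
            continue
        for b in model.atoms:
            if b.chain != chain_b or b.element not in ("N", "O"):
                continue
            d = float(np.linalg.norm(np.array(a.xyz) - np.array(b.xyz)))
            key = ((a.chain, a.resnum), (b.chain, b.resnum))
            if key not in best or d < best[key]:
                best[key] = d
    return {k: v for k, v in best.items() if v <= cutoff}


class TestContacts:
    def two_chain_fixture(self, rng, n=50):
        names = ["N", "CA", "C", "O", "CB"]
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
        atoms = []
        for chain, offset in (("A", 0.0), ("B", 3.0)):
            for i in range(n // 10):
                base = rng.uniform(0, 10, 3) + offset
                for j, name in enumerate(names):
                    atoms.append(
                        Atom(chain, i + 1, "ALA", name, elements[name],
                             tuple(base + 0.8 * rng.normal(size=3)))
                    )
        return StructureModel(atoms)

    def test_backbone_polar_pair_within_cutoff(self):
        atoms = [
            Atom("A", 1, "ALA", "N", "N", (0, 0, 0)),
            Atom("A", 1, "ALA", "CA", "C", (1.5, 0, 0)),
            Atom("B", 5, "GLY", "O", "O", (0, 3.0, 0)),
        ]
        contacts = polar_contacts(StructureModel(atoms), "A", "B")
        assert len(contacts) == 1
        assert contacts[0]["distance"] == pytest.approx(3.0)

    def test_pair_beyond_cutoff_excluded(self):
        atoms = [
            Atom("A", 1, "ALA", "N", "N", (0, 0, 0)),
            Atom("B", 5, "GLY", "O", "O", (0, 4.0, 0)),
        ]
        assert polar_contacts(StructureModel(atoms), "A", "B", cutoff=3.5) == []

    def test_matches_brute_force_on_random_toy(self, rng):
        model = self.two_chain_fixture(rng)
        got = polar_contacts(model, "A", "B", cutoff=6.0)
        expected = brute_force_polar(model, "A", "B", 6.0)
        assert {(c["residue_a"], c["residue_b"]) for c in got} == set(expected)
        for c in got:
            assert c["distance"] == pytest.approx(
                expected[(c["residue_a"], c["residue_b"])]
            )

    def test_pocket_inclusion_and_exclusion(self):
        atoms = [
            Atom("B", 1, "PHE", "CB", "C", (0, 0, 0)),
            Atom("B", 1, "PHE", "CA", "C", (0, 0, 1.5)),
            Atom("A", 10, "ILE", "CD1", "C", (4.0, 0, 0)),
            Atom("A", 20, "VAL", "CG1", "C", (5.0, 0, 0)),
        ]
        hits = pocket_residues(StructureModel(atoms), ("B", 1), cutoff=4.5)
        assert [h["residue"] for h in hits] == [("A", 10)]

    def test_pocket_glycine_probe_uses_ca(self):
        atoms = [
            Atom("B", 1, "GLY", "CA", "C", (0, 0, 0)),
            Atom("B", 1, "GLY", "N", "N", (0, 0, 1.5)),
            Atom("A", 3, "ALA", "CB", "C", (3.0, 0, 0)),
        ]
        hits = pocket_residues(StructureModel(atoms), ("B", 1), cutoff=4.5)
        assert [h["residue"] for h in hits] == [("A", 3)]

    def test_pocket_matches_brute_force(self, rng):
        model = self.two_chain_fixture(rng)
        hits = pocket_residues(model, ("B", 2), cutoff=7.0)
        probe_atoms = [
            a for a in model.atoms
            if a.chain == "B" and a.resnum == 2 and a.name == "CB"
        ]
        expected = {}
        for p in probe_atoms:
            for a in model.atoms:
                if a.chain == "B":
                    continue
                d = float(np.linalg.norm(np.array(p.xyz) - np.array(a.xyz)))
                key = (a.chain, a.resnum)
                if key not in expected or d < expected[key]:
                    expected[key] = d
        expected = {k: v for k, v in expected.items() if v <= 7.0}
        assert {h["residue"] for h in hits} == set(expected)
        assert [h["min_distance"] for h in hits] == sorted(
            h["min_distance"] for h in hits
        )

    def test_missing_probe_raises(self, toy_complex):
        with pytest.raises(KeyError):
            pocket_residues(toy_complex["model"], ("B", 999))

    def test_same_chain_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            polar_contacts(toy_complex["model"], "A", "A")
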