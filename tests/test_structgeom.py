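"""Interface geometry: minimum distances, contacts, COM, interface PAE."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pepevo import (
    ContactSet,
    PredictedComplex,
    Structure3D,
    ca_center_of_mass,
    cb_contacts,
    contact_similarity,
    delta_com,
    interface_pae_mean,
    min_distances_peptide_to_receptor,
    min_distances_target_to_peptide,
    receptor_target_atoms,
)
from conftest import random_complex, random_rotation


def make_struct(atoms, chain="A"):
    """atoms: list of (resid, atomname, xyz); resname fixed (ALA)."""
    return Structure3D(
        [chain] * len(atoms),
        [a[0] for a in atoms],
        ["ALA"] * len(atoms),
        [a[1] for a in atoms],
        np.asarray([a[2] for a in atoms], dtype=float),
    )


def simple_complex(rec_atoms, pep_atoms, plddt=None, pae=None):
    rec = make_struct(rec_atoms, chain="A")
    pep = make_struct(pep_atoms, chain="B")
    if plddt is None:
        plddt = [80.0] * pep.n_residues
    return PredictedComplex(rec, pep, plddt, pae=pae)


class TestMinDistances:
    def test_two_atom_toy(self):
        cx = simple_complex(
            [(1, "CA", (0, 0, 0))],
            [(1, "CA", (3, 0, 0)), (1, "CB", (0, 5, 0))],
        )
        assert min_distances_peptide_to_receptor(cx) == pytest.approx([3.0, 5.0])

    def test_coincident_atom_gives_zero(self):
        cx = simple_complex([(1, "CA", (1, 2, 3))], [(1, "CA", (1, 2, 3))])
        assert min_distances_peptide_to_receptor(cx)[0] == 0.0

    def test_target_to_peptide_toy(self):
        pep = make_struct([(1, "CA", (3, 0, 0)), (1, "CB", (0, 5, 0))], chain="B")
        di = min_distances_target_to_peptide(np.array([[0.0, 0.0, 0.0]]), pep)
        assert di == pytest.approx([3.0])

    def test_empty_target_set_rejected(self):
        pep = make_struct([(1, "CA", (0, 0, 0))], chain="B")
        with pytest.raises(ValueError):
            min_distances_target_to_peptide(np.empty((0, 3)), pep)
        cx = simple_complex([(1, "CA", (0, 0, 0))], [(1, "CA", (1, 0, 0))])
        with pytest.raises(ValueError):
            min_distances_peptide_to_receptor(cx, receptor_subset=np.empty((0, 3)))

    def test_agrees_with_brute_force_on_random_toys(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            cx = random_complex(rng)
            dj = min_distances_peptide_to_receptor(cx)
            brute = [
                min(np.linalg.norm(p - r) for r in cx.receptor.coords)
                for p in cx.peptide.coords
            ]
            np.testing.assert_allclose(dj, brute, atol=1e-9)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(7)
        cx = random_complex(rng)
        dj = min_distances_peptide_to_receptor(cx)
        R, t = random_rotation(rng), rng.normal(0, 20, 3)
        moved = PredictedComplex(
            cx.receptor.transformed(R, t), cx.peptide.transformed(R, t), cx.peptide_plddt
        )
        np.testing.assert_allclose(min_distances_peptide_to_receptor(moved), dj, atol=1e-9)

    def test_subset_min_cannot_be_smaller_than_full_min(self):
        rng = np.random.default_rng(8)
        cx = random_complex(rng)
        targets = receptor_target_atoms(cx, cutoff=30.0)
        if len(targets) == 0:
            pytest.skip("no interface in this draw")
        dj_full = min_distances_peptide_to_receptor(cx).mean()
        dj_sub = min_distances_peptide_to_receptor(cx, targets.coords).mean()
        assert dj_sub >= dj_full - 1e-12


class TestTargetAtoms:
    def test_cutoff_is_strict(self):
        inside = simple_complex(
            [(1, "CA", (0, 0, 0)), (1, "CB", (0, 0, 0))],
            [(1, "CA", (7.9, 0, 0)), (1, "CB", (7.9, 0, 0))],
        )
        assert len(receptor_target_atoms(inside)) == 1
        outside = simple_complex(
            [(1, "CA", (0, 0, 0)), (1, "CB", (0, 0, 0))],
            [(1, "CA", (8.1, 0, 0)), (1, "CB", (8.1, 0, 0))],
        )
        assert len(receptor_target_atoms(outside)) == 0

    def test_three_residue_receptor_brute_force(self):
        rec = [(i + 1, "CB", (10.0 * i, 0, 0)) for i in range(3)]
        rec += [(i + 1, "CA", (10.0 * i, 1, 0)) for i in range(3)]
        # peptide Cb at x=6: 6 A from residue 1, 4 A from residue 2, 14 A from 3
        cx = simple_complex(rec, [(1, "CB", (6, 0, 0)), (1, "CA", (6, 1, 0))])
        assert receptor_target_atoms(cx).residue_ids == (1, 2)
        # at x=-2 only residue 1 is within the strict 8 A cutoff
        cx = simple_complex(rec, [(1, "CB", (-2, 0, 0)), (1, "CA", (-2, 1, 0))])
        assert receptor_target_atoms(cx).residue_ids == (1,)

    def test_glycine_falls_back_to_ca(self):
        rec = Structure3D(["A"], [1], ["GLY"], ["CA"], [[0.0, 0.0, 0.0]])
        pep = make_struct([(1, "CB", (5, 0, 0)), (1, "CA", (5, 1, 0))], chain="B")
        cx = PredictedComplex(rec, pep, [90.0])
        assert len(receptor_target_atoms(cx)) == 1


class TestCentersOfMass:
    @pytest.mark.parametrize(
        "cas,expected",
        [
            ([(1, 2, 3)], (1, 2, 3)),
            ([(0, 0, 0), (2, 0, 0)], (1, 0, 0)),
            ([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)], (0.25, 0.25, 0.25)),
        ],
    )
    def test_ca_com_examples(self, cas, expected):
        pep = make_struct([(i + 1, "CA", c) for i, c in enumerate(cas)], chain="B")
        np.testing.assert_allclose(ca_center_of_mass(pep), expected)

    def test_no_ca_raises(self):
        pep = make_struct([(1, "CB", (0, 0, 0))], chain="B")
        with pytest.raises(ValueError):
            ca_center_of_mass(pep)

    def test_delta_com_three_four_five(self):
        a = make_struct([(1, "CA", (0, 0, 0))], chain="B")
        b = make_struct([(1, "CA", (3, 4, 0))], chain="B")
        assert delta_com(a, b) == pytest.approx(5.0)
        assert delta_com(a, a) == 0.0
        assert delta_com(b, a) == delta_com(a, b)

    def test_delta_com_matches_brute_force(self):
        rng = np.random.default_rng(5)
        from conftest import random_structure

        a, b = random_structure(rng, 6, "B"), random_structure(rng, 6, "B")
        ca = lambda s: s.coords[s.atomname == "CA"].mean(axis=0)
        assert delta_com(a, b) == pytest.approx(float(np.linalg.norm(ca(a) - ca(b))), abs=1e-9)


class TestContacts:
    def test_distant_chains_no_contacts(self):
        cx = simple_complex([(1, "CB", (0, 0, 0))], [(1, "CB", (30, 0, 0))])
        assert len(cb_contacts(cx)) == 0

    def test_single_pair_at_seven_angstrom(self):
        cx = simple_complex(
            [(1, "CB", (0, 0, 0)), (2, "CB", (20, 0, 0))],
            [(1, "CB", (7, 0, 0))],
        )
        assert cb_contacts(cx).pairs == frozenset({(1, 1)})

    def test_contacts_invariant_under_rigid_transform(self):
        rng = np.random.default_rng(9)
        cx = random_complex(rng, separation=3.0)
        base = cb_contacts(cx)
        R, t = random_rotation(rng), rng.normal(0, 15, 3)
        moved = PredictedComplex(
            cx.receptor.transformed(R, t), cx.peptide.transformed(R, t), cx.peptide_plddt
        )
        assert cb_contacts(moved).pairs == base.pairs


class TestContactSimilarity:
    def test_published_style_count_fraction(self):
        # 15 design contacts against a 65-contact reference -> 0.23
        design = ContactSet(frozenset((r, 1) for r in range(15)))
        wt = ContactSet(frozenset((r, p) for r in range(13) for p in range(5)))
        n, match, frac = contact_similarity(design, wt)
        assert n == 15 and len(wt.pairs) == 65
        assert frac == pytest.approx(15 / 65)
        assert round(frac, 2) == 0.23

    def test_self_similarity_is_identity(self):
        x = ContactSet(frozenset({(1, 1), (2, 1), (3, 2)}))
        assert contact_similarity(x, x) == (3, 3, 1.0)

    def test_disjoint_receptor_residues_no_match(self):
        a = ContactSet(frozenset({(1, 1)}))
        b = ContactSet(frozenset({(2, 1)}))
        assert contact_similarity(a, b)[1] == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            contact_similarity(ContactSet(frozenset({(1, 1)})), ContactSet(frozenset()))


class TestInterfacePAE:
    def test_constant_matrix(self):
        pae = np.full((2, 2), 7.0)
        cx = simple_complex([(1, "CB", (0, 0, 0))], [(1, "CB", (3, 0, 0))], pae=pae)
        mean, fallback = interface_pae_mean(cx)
        assert mean == pytest.approx(7.0) and not fallback

    def test_hand_mean_of_off_diagonal_blocks(self):
        # receptor residues 1-2, peptide residue 1; inter-chain entries 4,6,5,5
        pae = np.zeros((3, 3))
        pae[0, 2], pae[1, 2] = 4.0, 6.0  # receptor -> peptide
        pae[2, 0], pae[2, 1] = 5.0, 5.0  # peptide -> receptor
        cx = simple_complex(
            [(1, "CB", (0, 0, 0)), (2, "CB", (3, 0, 0))],
            [(1, "CB", (1.5, 0, 0))],
            pae=pae,
        )
        mean, fallback = interface_pae_mean(cx)
        assert mean == pytest.approx(5.0) and not fallback

    def test_intra_chain_entries_ignored(self):
        pae = np.zeros((3, 3))
        pae[0, 2] = pae[1, 2] = pae[2, 0] = pae[2, 1] = 3.0
        cx = simple_complex(
            [(1, "CB", (0, 0, 0)), (2, "CB", (3, 0, 0))],
            [(1, "CB", (1.5, 0, 0))],
            pae=pae,
        )
        ref, _ = interface_pae_mean(cx)
        pae2 = pae.copy()
        pae2[0, 1] = pae2[1, 0] = 25.0  # intra-receptor perturbation
        cx2 = simple_complex(
            [(1, "CB", (0, 0, 0)), (2, "CB", (3, 0, 0))],
            [(1, "CB", (1.5, 0, 0))],
            pae=pae2,
        )
        assert interface_pae_mean(cx2)[0] == ref

    def test_no_contact_fallback_flagged(self):
        pae = np.full((2, 2), 4.0)
        cx = simple_complex([(1, "CB", (0, 0, 0))], [(1, "CB", (50, 0, 0))], pae=pae)
        mean, fallback = interface_pae_mean(cx)
        assert fallback and mean == pytest.approx(4.0)

    def test_missing_pae_rejected(self):
        cx = simple_complex([(1, "CB", (0, 0, 0))], [(1, "CB", (3, 0, 0))])
        with pytest.raises(ValueError):
            interface_pae_mean(cx)
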