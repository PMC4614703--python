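"""Structure loading and Cα-to-cofactor distance geometry."""

import math

import numpy as np
import pytest

from flavoscore.fixtures import (
    LigandAtomSpec,
    ResidueSpec,
    StructureSpec,
    random_structure_spec,
    spec_min_distance,
)
from flavoscore.structure import (
    FES_SELECTOR,
    FMN_SELECTOR,
    LigandSelector,
    StructureError,
    distance_profile,
    min_distance_to_ligand,
)

FMN_ONLY = LigandSelector(frozenset({"FMN"}))


class TestLoadStructure:
    def test_fixture_round_trip(self, load_spec, three_residue_spec):
        model = load_spec(three_residue_spec)
        assert model.ca_residue_numbers() == [1, 2, 3]
        ca2 = model.ca_atom(2)
        assert (ca2.x, ca2.y, ca2.z) == (3.8, 0.0, 0.0)

    def test_missing_chain_lists_available(self, load_spec, three_residue_spec):
        with pytest.raises(StructureError, match="available chains"):
            load_spec(three_residue_spec, chain="Z")

    def test_altloc_collapsed_to_highest_occupancy(
        self, load_spec, three_residue_spec
    ):
        model = load_spec(three_residue_spec, altloc_residues=(1,))
        ca1 = model.ca_atom(1)
        # conformer A (occupancy 0.60) sits at the spec coordinate
        assert ca1.x == pytest.approx(0.0)

    def test_hetero_atoms_kept_from_other_chains(
        self, load_spec, three_residue_spec
    ):
        model = load_spec(three_residue_spec)
        names = {a.res_name for a in model.hetero_atoms()}
        assert names == {"FMN", "SF4"}


class TestMinDistance:
    def test_coincident_ligand_gives_zero(self, load_spec):
        spec = StructureSpec(
            residues=(ResidueSpec(1, 1.5, 2.5, 3.5),),
            ligand_atoms=(LigandAtomSpec("FMN", "C1", 1.5, 2.5, 3.5),),
        )
        model = load_spec(spec)
        assert min_distance_to_ligand(model, 1, FMN_ONLY) == pytest.approx(0.0)

    def test_minimum_of_two_ligand_atoms(self, load_spec):
        spec = StructureSpec(
            residues=(ResidueSpec(1, 0.0, 0.0, 0.0),),
            ligand_atoms=(
                LigandAtomSpec("FMN", "C1", 3.0, 4.0, 0.0),
                LigandAtomSpec("FMN", "C2", 6.0, 8.0, 0.0),
            ),
        )
        model = load_spec(spec)
        assert min_distance_to_ligand(model, 1, FMN_ONLY) == pytest.approx(5.0)

    def test_missing_ca_raises(self, load_spec, three_residue_spec):
        model = load_spec(three_residue_spec)
        with pytest.raises(StructureError, match="no CA"):
            min_distance_to_ligand(model, 99, FMN_ONLY)

    def test_no_matching_ligand_raises(self, load_spec, three_residue_spec):
        model = load_spec(three_residue_spec)
        with pytest.raises(StructureError, match="no ligand"):
            min_distance_to_ligand(model, 1, LigandSelector(frozenset({"HEM"})))

    def test_matches_bruteforce_oracle_on_random_fixture(self, load_spec, rng):
        spec = random_structure_spec(rng, n_residues=12, n_fmn=8, n_fes=6)
        model = load_spec(spec)
        for res in (1, 5, 12):
            got = min_distance_to_ligand(model, res, FMN_ONLY)
            assert got == pytest.approx(
                spec_min_distance(spec, res, "FMN"), abs=1e-9
            )

    def test_rigid_transform_leaves_distances_unchanged(self, load_spec, rng):
        spec = random_structure_spec(rng, n_residues=8, n_fmn=4, n_fes=3)
        # rotation about z by 30 degrees plus a translation
        c, s = math.cos(math.pi / 6), math.sin(math.pi / 6)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        t = np.array([7.0, -3.0, 11.0])

        def move(x, y, z):
            v = R @ np.array([x, y, z]) + t
            return tuple(round(float(u), 3) for u in v)

        moved = StructureSpec(
            residues=tuple(
                ResidueSpec(r.res_num, *move(r.x, r.y, r.z)) for r in spec.residues
            ),
            ligand_atoms=tuple(
                LigandAtomSpec(a.res_name, a.atom_name, *move(a.x, a.y, a.z),
                               element=a.element, res_num=a.res_num)
                for a in spec.ligand_atoms
            ),
        )
        m1 = load_spec(spec, name="orig.pdb")
        m2 = load_spec(moved, name="moved.pdb")
        for res in (1, 4, 8):
            d1 = min_distance_to_ligand(m1, res, FMN_ONLY)
            d2 = min_distance_to_ligand(m2, res, FMN_ONLY)
            # fixture coordinates are rounded to PDB's 1e-3 precision
            assert d2 == pytest.approx(d1, abs=5e-3)

    def test_adding_ligand_atom_never_increases_distance(self, load_spec, rng):
        spec = random_structure_spec(rng, n_residues=6, n_fmn=3, n_fes=2)
        extra = spec.ligand_atoms + (
            LigandAtomSpec("FMN", "C99", 25.0, 25.0, 25.0),
        )
        bigger = StructureSpec(residues=spec.residues, ligand_atoms=extra)
        m1 = load_spec(spec, name="a.pdb")
        m2 = load_spec(bigger, name="b.pdb")
        for res in range(1, 7):
            assert (
                min_distance_to_ligand(m2, res, FMN_ONLY)
                <= min_distance_to_ligand(m1, res, FMN_ONLY) + 1e-12
            )


class TestDistanceProfile:
    def test_one_record_per_residue_ascending(self, load_spec, three_residue_spec):
        model = load_spec(three_residue_spec)
        records = distance_profile(model)
        assert [r.res_num for r in records] == [1, 2, 3]
        assert records[0].d_fmn == pytest.approx(5.0)
        assert records[0].d_fes == pytest.approx(12.0)

    def test_identical_selectors_give_identical_columns(self, load_spec, rng):
        spec = random_structure_spec(rng, n_residues=5, n_fmn=4, n_fes=1)
        model = load_spec(spec)
        fmn_as_both = distance_profile(model, FMN_ONLY, FMN_ONLY)
        for r in fmn_as_both:
            assert r.d_fmn == r.d_fes

    def test_nearest_copy_policy_ignores_distant_cofactor_copy(self, load_spec):
        # two SF4 copies: one adjacent to the chain, one far away on another
        # residue; the far one must not shadow the near one, and with the
        # nearest-copy policy only the near copy's atoms are measured
        spec = StructureSpec(
            residues=(ResidueSpec(1, 0.0, 0.0, 0.0),
                      ResidueSpec(2, 20.0, 0.0, 0.0)),
            ligand_atoms=(
                LigandAtomSpec("SF4", "FE1", 0.0, 3.0, 0.0, element="FE",
                               res_num=901),
                LigandAtomSpec("SF4", "FE1", 20.0, 4.0, 0.0, element="FE",
                               res_num=902),
            ),
        )
        model = load_spec(spec)
        d = min_distance_to_ligand(model, 2, FES_SELECTOR)
        # copy 901 is nearest to the chain overall (3 Å from residue 1), so
        # only its atoms are measured even though copy 902 is closer to res 2
        assert d == pytest.approx(math.dist((20, 0, 0), (0, 3, 0)), abs=1e-6)
        d_all = min_distance_to_ligand(
            model, 2, LigandSelector(frozenset({"SF4"}), copy_policy="all")
        )
        assert d_all == pytest.approx(4.0, abs=1e-6)
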