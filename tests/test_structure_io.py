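"""Unit tests for SHELX/CIF parsing, writing, and the coordinate contract."""

import gemmi
import numpy as np
import pytest

import disorderkit as dk
from disorderkit.structure_io import (FormatError, decode_sof, encode_sof,
                                      expand_operations, parse_symop,
                                      write_cif)

MINIMAL_INS = """\
TITL test
CELL 0.71073 7.0 8.0 9.0 90.0 102.0 90.0
ZERR 1 0.001 0.001 0.001 0.01 0.01 0.01
LATT {latt}
{symm}SFAC C H N O
UNIT 12 28 4 4
FVAR 1.0 0.6
{atoms}HKLF 4
END
"""


def make_ins(latt=-1, symm="", atoms="C1 1 0.1 0.2 0.3 11.0 0.03\n"):
    return MINIMAL_INS.format(latt=latt, symm=symm, atoms=atoms)


class TestSymmetryParsing:
    def test_symm_card_transcription(self):
        op = parse_symop("-X, 1/2+Y, -Z")
        assert (op.rot == np.diag([-1, 1, -1])).all()
        assert np.allclose(op.trans, [0.0, 0.5, 0.0])

    def test_identity_triplet(self):
        assert parse_symop("x,y,z").is_identity

    def test_malformed_symm_raises(self):
        with pytest.raises(FormatError):
            parse_symop("x, y, frog")

    @pytest.mark.parametrize("latt,n_ops", [(-1, 1), (1, 2), (-2, 2),
                                            (2, 4), (-5, 2), (7, 4)])
    def test_latt_expansion_counts(self, latt, n_ops):
        s = dk.parse_shelx(make_ins(latt=latt))
        assert len(s.operations) == n_ops

    def test_p21c_matches_reference_spacegroup(self):
        """LATT 1 + the 2_1/c screw generator must expand to the same four
        operators gemmi lists for P 21/c."""
        s = dk.parse_shelx(make_ins(latt=1, symm="SYMM -X, 1/2+Y, 1/2-Z\n"))
        ours = {op.triplet().replace(" ", "").replace("+", "")
                for op in s.operations}
        sg = gemmi.find_spacegroup_by_name("P21/c")
        ref = {op.triplet().replace("+", "") for op in sg.operations()}
        assert ours == ref

    def test_operator_closure(self, propionamide):
        """Composing any two expanded operators stays in the set (mod
        lattice translations)."""
        for structure_ops in (propionamide.operations,
                              expand_operations([], 1)):
            for a in structure_ops:
                for b in structure_ops:
                    c = a.compose(b)
                    assert any(c == op for op in structure_ops)


class TestShelxAtoms:
    def test_missing_cell_raises(self):
        with pytest.raises(FormatError):
            dk.parse_shelx("TITL no cell\nSFAC C\nEND\n")

    def test_bad_sfac_index_raises(self):
        with pytest.raises(dk.structure_io.ElementError):
            dk.parse_shelx(make_ins(atoms="C1 9 0.1 0.2 0.3 11.0\n"))

    def test_part_and_resi_tracking(self):
        atoms = ("C1 1 0.1 0.2 0.3 11.0 0.03\n"
                 "PART 1\n"
                 "H1 2 0.2 0.3 0.4 21.0 0.05\n"
                 "PART 2\n"
                 "RESI 5\n"
                 "H1B 2 0.3 0.4 0.5 -21.0 0.05\n"
                 "PART 0\n")
        s = dk.parse_shelx(make_ins(atoms=atoms))
        c1, h1, h1b = s.sites
        assert (c1.part, h1.part, h1b.part) == (0, 1, 2)
        assert h1b.residue == 5
        assert h1.free_variable_ref == 2
        assert h1.occupancy == pytest.approx(0.6)
        assert h1b.free_variable_ref == -2
        assert h1b.occupancy == pytest.approx(0.4)

    @pytest.mark.parametrize("code,fvar,occ,ref", [
        (11.0, [1.0], 1.0, None),      # fixed, full
        (10.5, [1.0], 0.5, None),      # fixed, half
        (0.25, [1.0], 0.25, None),     # plain value
        (21.0, [1.0, 0.7], 0.7, 2),    # fv2
        (-21.0, [1.0, 0.7], 0.3, -2),  # 1 - fv2
        (30.5, [1.0, 0.7, 0.4], 0.2, 3),
    ])
    def test_sof_decoding(self, code, fvar, occ, ref):
        got_occ, got_ref, _ = decode_sof(code, fvar)
        assert got_occ == pytest.approx(occ)
        assert got_ref == ref

    def test_sof_encode_decode_inverse(self):
        site = dk.AtomSite(label="X1", element="C", frac=np.zeros(3),
                           occupancy=0.7, free_variable_ref=2,
                           occupancy_multiplier=1.0)
        assert encode_sof(site) == pytest.approx(21.0)
        site.free_variable_ref = -2
        assert encode_sof(site) == pytest.approx(-21.0)


class TestRoundTrips:
    def test_shelx_round_trip_is_lossless(self, propionamide):
        text = dk.write_shelx(propionamide)
        back = dk.parse_shelx(text)
        assert len(back.sites) == len(propionamide.sites)
        for a, b in zip(propionamide.sites, back.sites):
            assert a.label == b.label
            assert a.element == b.element
            assert a.part == b.part
            assert a.residue == b.residue
            assert a.free_variable_ref == b.free_variable_ref
            assert np.allclose(a.frac, b.frac, atol=5e-7)
            assert a.occupancy == pytest.approx(b.occupancy, abs=1e-6)
        assert len(back.operations) == len(propionamide.operations)

    def test_cif_parse_equals_shelx_parse(self, propionamide):
        via_shelx = dk.parse_shelx(dk.write_shelx(propionamide))
        via_cif = dk.parse_cif(write_cif(propionamide))
        assert len(via_cif.sites) == len(via_shelx.sites)
        for a, b in zip(via_shelx.sites, via_cif.sites):
            assert a.label == b.label
            assert a.element == b.element
            assert a.part == b.part
            assert np.allclose(a.frac, b.frac, atol=5e-7)

    def test_cif_disorder_group_dot_maps_to_part_zero(self, propionamide):
        parsed = dk.parse_cif(write_cif(propionamide))
        parts = [s.part for s in parsed.sites]
        assert set(parts) == {0, 1, 2}

    def test_cif_without_symmetry_raises(self):
        text = ("data_x\n_cell_length_a 10\n_cell_length_b 10\n"
                "_cell_length_c 10\n_cell_angle_alpha 90\n"
                "_cell_angle_beta 90\n_cell_angle_gamma 90\n")
        with pytest.raises(FormatError, match="operator"):
            dk.parse_cif(text)


class TestCoordinates:
    def test_cubic_midpoint(self):
        cell = dk.UnitCell(10, 10, 10, 90, 90, 90)
        assert np.allclose(dk.frac_to_cart(cell, [0.5, 0.5, 0.5]),
                           [5, 5, 5])

    def test_orthorhombic_corner(self):
        cell = dk.UnitCell(2, 3, 4, 90, 90, 90)
        assert np.allclose(dk.frac_to_cart(cell, [1, 1, 1]), [2, 3, 4])

    def test_monoclinic_beta90_limit(self):
        mono = dk.UnitCell(2, 3, 4, 90, 90.0, 90)
        orth = dk.UnitCell(2, 3, 4, 90, 90, 90)
        f = np.array([0.3, -0.2, 0.7])
        assert np.allclose(dk.frac_to_cart(mono, f),
                           dk.frac_to_cart(orth, f))

    def test_round_trip_random_cells(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            cell = dk.UnitCell(*rng.uniform(3, 30, 3),
                               *rng.uniform(60, 120, 3))
            frac = rng.uniform(-2, 2, (20, 3))
            back = dk.cart_to_frac(cell, dk.frac_to_cart(cell, frac))
            err = np.abs(dk.frac_to_cart(cell, back - frac)).max()
            assert err <= 1e-10

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            dk.UnitCell(-1, 2, 3, 90, 90, 90)
        with pytest.raises(ValueError):
            dk.UnitCell(1, 2, 3, 90, 185, 90)


class TestTurbomoleOutput:
    def test_bohr_conversion_single_atom(self):
        from disorderkit.cluster_builder import Cluster
        from disorderkit.constants import BOHR_RADIUS_ANGSTROM
        cl = Cluster(asu_elements=["H"],
                     asu_positions=np.array(
                         [[BOHR_RADIUS_ANGSTROM, 0.0, 0.0]]))
        text = dk.write_turbomole_coord(cl)
        lines = text.splitlines()
        assert lines[0] == "$coord"
        assert lines[-1] == "$end"
        vals = lines[1].split()
        assert float(vals[0]) == pytest.approx(1.0, abs=1e-12)
        assert vals[3] == "h"
        assert len(lines) == 3

    def test_environment_atoms_carry_fixed_flag(self, propionamide):
        cl = dk.build_cluster(propionamide, cutoff=3.75)
        text = dk.write_turbomole_coord(cl)
        body = text.splitlines()[1:-1]
        fixed = [l for l in body if l.endswith(" f")]
        assert len(fixed) == cl.n_environment_atoms
        assert len(body) - len(fixed) == cl.n_asu
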