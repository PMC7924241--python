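"""Restraint generation, proximity constraints, instruction files, and
parameter bookkeeping."""

import numpy as np
import pytest

import disorderkit as dk
from disorderkit import restraints_constraints as rc
from disorderkit.archetypes import OccupancyPlan


@pytest.fixture(scope="module")
def arch_pair(propionamide_archetypes):
    return propionamide_archetypes


@pytest.fixture(scope="module")
def restraints_a(arch_pair):
    return rc.generate_restraints(arch_pair[0], residue=1)


class TestGenerateRestraints:
    def test_counts_per_archetype_and_total(self, arch_pair):
        per = [rc.generate_restraints(a, residue=k + 1)
               for k, a in enumerate(arch_pair)]
        for rs in per:
            assert sum(r.kind == "DFIX" for r in rs) == 11
            assert sum(r.kind == "DANG" for r in rs) == 18
        assert sum(len(rs) for rs in per) == 58

    def test_default_sigma(self, restraints_a):
        assert all(r.sigma == 0.005 for r in restraints_a)

    def test_ch_bond_target_is_shrunk(self, arch_pair):
        a = arch_pair[0].structure
        g = dk.perceive_bonds(a.elements, a.cart_coords)
        rs = rc.generate_restraints(arch_pair[0], graph=g, residue=1)
        labels = [s.label for s in a.sites]
        for r in rs:
            if r.kind != "DFIX":
                continue
            i = labels.index(r.atoms[0][0])
            j = labels.index(r.atoms[1][0])
            raw = g.distance(i, j)
            has_h = "H" in (a.sites[i].element, a.sites[j].element)
            expect = raw * 0.865 if has_h else raw
            assert r.target == pytest.approx(expect, abs=1e-9)

    def test_explicit_ch_example(self):
        """A 1.090 A C-H bond restrains to 0.943 A."""
        assert 1.090 * 0.865 == pytest.approx(0.943, abs=5e-4)

    def test_h_shrink_preserves_angles(self, arch_pair):
        """1-3 targets are recomputed from the repositioned H, so the
        X-H angle implied by (d12, d13, d23) is unchanged."""
        a = arch_pair[0].structure
        g = dk.perceive_bonds(a.elements, a.cart_coords)
        labels = [s.label for s in a.sites]
        rs = rc.generate_restraints(arch_pair[0], graph=g, residue=1)
        targets = {frozenset((r.atoms[0][0], r.atoms[1][0])): r.target
                   for r in rs}

        def angle(d_ij, d_jk, d_ik):
            cos = (d_ij ** 2 + d_jk ** 2 - d_ik ** 2) / (2 * d_ij * d_jk)
            return np.degrees(np.arccos(np.clip(cos, -1, 1)))

        # check every H-C-H / H-C-X angle at the methyl carbon
        c1 = labels.index("C1")
        hs = [j for j in g.neighbors(c1) if a.sites[j].element == "H"]
        for i in hs:
            for j in g.neighbors(c1):
                if j <= i or j == c1:
                    continue
                li, lj, lc = labels[i], labels[j], labels[c1]
                restrained = angle(targets[frozenset((li, lc))],
                                   targets[frozenset((lj, lc))],
                                   targets[frozenset((li, lj))])
                raw = angle(g.distance(i, c1), g.distance(j, c1),
                            g.distance(i, j))
                assert restrained == pytest.approx(raw, abs=1e-6)

    def test_restraint_total_matches_pair_enumerator(self, arch_pair):
        """Total = 2 x (bonds + 1-3 pairs) for the two-archetype model."""
        a = arch_pair[0].structure
        g = dk.perceive_bonds(a.elements, a.cart_coords)
        expect = 2 * (len(dk.one_two_pairs(g)) +
                      len(dk.one_three_pairs(g)))
        total = sum(len(rc.generate_restraints(x, residue=k + 1))
                    for k, x in enumerate(arch_pair))
        assert total == expect

    def test_exclude_list_drops_selected(self, arch_pair, restraints_a):
        drop = (restraints_a[0].atoms[0][0], restraints_a[0].atoms[1][0])
        rs = rc.generate_restraints(arch_pair[0], residue=1,
                                    exclude=[drop])
        assert len(rs) == len(restraints_a) - 1


class TestAssignConstraints:
    def test_threshold_rule(self, arch_pair):
        mapping = dk.map_atoms(*arch_pair)
        cons = rc.assign_constraints(mapping, threshold=0.5)
        close = sum(1 for *_, d in mapping.pairs if d < 0.5)
        assert len(cons) == close
        assert all(c.kind == "EADP" for c in cons)

    def test_pair_above_threshold_excluded(self, arch_pair):
        mapping = dk.map_atoms(*arch_pair)
        d = mapping.distances()
        assert (d > 0.5).any()  # flipped H atoms sit well apart
        labels_far = {mapping.pairs[i][0].label
                      for i in np.flatnonzero(d >= 0.5)}
        cons = rc.assign_constraints(mapping, threshold=0.5)
        constrained = {c.atoms[0][0] for c in cons}
        assert labels_far.isdisjoint(constrained)

    def test_simu_mode_carries_sigma(self, arch_pair):
        mapping = dk.map_atoms(*arch_pair)
        cons = rc.assign_constraints(mapping, mode="SIMU",
                                     simu_sigma=0.005)
        assert cons and all(c.kind == "SIMU" and c.sigma == 0.005
                            for c in cons)

    def test_exyz_mode_adds_positional_constraints(self, arch_pair):
        mapping = dk.map_atoms(*arch_pair)
        eadp_only = rc.assign_constraints(mapping, mode="EADP")
        both = rc.assign_constraints(mapping, mode="EADP+EXYZ")
        assert len(both) == 2 * len(eadp_only)
        assert sum(c.kind == "EXYZ" for c in both) == len(eadp_only)

    def test_monotone_in_threshold(self, arch_pair):
        mapping = dk.map_atoms(*arch_pair)
        counts = [len(rc.assign_constraints(mapping, threshold=t))
                  for t in (0.1, 0.3, 0.5, 1.0, 2.0)]
        assert counts == sorted(counts)

    def test_bad_threshold_rejected(self, arch_pair):
        with pytest.raises(ValueError):
            rc.assign_constraints(dk.map_atoms(*arch_pair), threshold=0.0)


class TestInstructionFile:
    def make_plan(self, arch_pair):
        restraints = []
        for k, a in enumerate(arch_pair):
            restraints += rc.generate_restraints(a, residue=k + 1)
        cons = rc.assign_constraints(dk.map_atoms(*arch_pair))
        return rc.RefinementPlan(restraints=restraints, constraints=cons)

    def test_line_format(self):
        plan = rc.RefinementPlan(restraints=[
            rc.Restraint(kind="DFIX", target=1.523, sigma=0.005,
                         atoms=(("C1", 1), ("C2", 1)))])
        text = rc.write_instruction_file(plan)
        assert "DFIX 1.5230 0.0050 C1_1 C2_1" in text

    def test_resi_cards_one_per_residue(self, arch_pair):
        text = rc.write_instruction_file(self.make_plan(arch_pair))
        resi = [l for l in text.splitlines() if l.startswith("RESI")]
        assert resi == ["RESI 1", "RESI 2"]

    def test_round_trip_multiset_equality(self, arch_pair):
        plan = self.make_plan(arch_pair)
        back = rc.parse_instruction_file(rc.write_instruction_file(plan))
        def key_r(r):
            return (r.kind, round(r.target, 4), round(r.sigma, 4), r.atoms)
        assert sorted(map(key_r, plan.restraints)) == \
            sorted(map(key_r, back.restraints))
        def key_c(c):
            return (c.kind, c.atoms,
                    None if c.sigma is None else round(c.sigma, 4))
        assert sorted(map(key_c, plan.constraints)) == \
            sorted(map(key_c, back.constraints))

    def test_deterministic_output(self, arch_pair):
        plan = self.make_plan(arch_pair)
        assert rc.write_instruction_file(plan) == \
            rc.write_instruction_file(plan)

    def test_main_stub_include(self):
        assert rc.main_file_stub("restraints.dfx") == "+restraints.dfx\n"


class TestCountParameters:
    def test_single_ordered_anisotropic_atom(self):
        cell = dk.UnitCell(10, 10, 10, 90, 90, 90)
        s = dk.CrystalStructure(cell=cell, sites=[
            dk.AtomSite(label="C1", element="C", frac=np.zeros(3),
                        adp=np.array([0.03, 0.03, 0.03, 0, 0, 0]))])
        assert rc.count_parameters(s) == 10  # 9 + scale

    def test_propionamide_free_refinement_is_148(self, arch_pair):
        model, plan = dk.recombine(arch_pair)
        free = rc.RefinementPlan(occupancy_plan=plan, strategy="free")
        assert rc.count_parameters(model, free) == 148

    def test_five_aniso_five_iso_eadp_pairs_give_113(self, arch_pair):
        model, occ_plan = dk.recombine(arch_pair)
        heavy = [s.label for s in arch_pair[0].sites
                 if not s.is_hydrogen]
        hydro = [s.label for s in arch_pair[0].sites if s.is_hydrogen][:5]
        cons = [rc.Constraint(kind="EADP", atoms=((l, 1), (l2, 2)))
                for l, l2 in zip(heavy, [s.label for s in
                                         arch_pair[1].sites
                                         if not s.is_hydrogen])]
        cons += [rc.Constraint(kind="EADP", atoms=((l, 1), (l + "'", 2)))
                 for l in hydro]
        plan = rc.RefinementPlan(constraints=cons, occupancy_plan=occ_plan)
        assert rc.count_parameters(model, plan) == 148 - 5 * 6 - 5 * 1

    def test_exyz_reduction(self, arch_pair):
        model, occ_plan = dk.recombine(arch_pair)
        cons = [rc.Constraint(kind="EXYZ", atoms=(("C1", 1), ("C1", 2)))]
        plan = rc.RefinementPlan(constraints=cons, occupancy_plan=occ_plan)
        assert rc.count_parameters(model, plan) == 148 - 3

    def test_free_at_least_constrained(self, arch_pair):
        model, occ_plan = dk.recombine(arch_pair)
        cons = rc.assign_constraints(dk.map_atoms(*arch_pair))
        free = rc.RefinementPlan(occupancy_plan=occ_plan)
        tied = rc.RefinementPlan(constraints=cons, occupancy_plan=occ_plan)
        n_free = rc.count_parameters(model, free)
        n_tied = rc.count_parameters(model, tied)
        assert n_free >= n_tied
        assert (n_free == n_tied) == (len(cons) == 0)
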