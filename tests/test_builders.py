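"""Builder tests: lattice enumeration oracle, charge bookkeeping, grafting
counts, lipid topology, residue mapping, solvation density and neutrality."""

import math

import numpy as np
import pytest

from dpdcoat.builders import (
    CLASS, RESIDUE_MAP, AntibodySpec, NanoparticleSpec, PolymerSpec,
    ProteinSpec, build_antibody, build_bilayer, build_nanoparticle,
    coarse_grain_protein, decorate_antibodies, fcc_sites, graft_polymers,
    make_fixture, nanoparticle_surface_indices, solvate_and_neutralize,
    synthetic_protein_sequence,
)
from dpdcoat.topology import (
    KIND_LIPID, KIND_LIPID_ANIONIC, KIND_PROTEIN, MEMBRANE_KINDS, merge,
)


def primitive_fcc_count(radius: float, a: float) -> int:
    """Independent enumeration of fcc sites |r| <= radius using the primitive
    lattice vectors a/2 (110), a/2 (101), a/2 (011)."""
    v = 0.5 * a * np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], float)
    m = int(math.ceil(2 * radius / a)) + 2
    count = 0
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                p = i * v[0] + j * v[1] + k * v[2]
                if p @ p <= radius * radius + 1e-12:
                    count += 1
    return count


class TestNanoparticle:
    def test_bead_count_matches_primitive_lattice_oracle(self):
        spec = NanoparticleSpec(diameter=6.0, surface="hydrophobic")
        topo = build_nanoparticle(spec)
        assert topo.n_beads == primitive_fcc_count(3.0, 0.40)
        # sanity: the fcc density is 4 / a^3 = 62.5 beads/nm^3
        vol = 4.0 / 3.0 * math.pi * 3.0 ** 3
        assert topo.n_beads == pytest.approx(62.5 * vol, rel=0.05)

    def test_charged_surface_bead_count(self):
        spec = NanoparticleSpec(diameter=10.0, surface="positive",
                                surface_charge_density=0.2)
        topo = build_nanoparticle(spec)
        n_charged = int((topo.charge > 0).sum())
        assert n_charged == round(0.2 * math.pi * 10.0 ** 2) == 63
        # charges sit on the outer shell
        rad = np.linalg.norm(topo.positions[topo.charge > 0], axis=1)
        assert rad.min() >= 5.0 - 0.40

    def test_hydrophobic_np_is_uncharged_and_rigid(self):
        topo = build_nanoparticle(NanoparticleSpec(diameter=6.0))
        assert np.all(topo.charge == 0)
        assert np.all(topo.body_id == 0)

    def test_excessive_charge_density_rejected(self):
        with pytest.raises(ValueError):
            build_nanoparticle(NanoparticleSpec(
                diameter=4.0, surface="positive", surface_charge_density=50.0))

    def test_too_small_diameter_rejected(self):
        with pytest.raises(ValueError):
            NanoparticleSpec(diameter=0.3)


class TestGrafting:
    def test_chain_count(self):
        np_spec = NanoparticleSpec(diameter=10.0)
        core = build_nanoparticle(np_spec)
        out = graft_polymers(core, np_spec, PolymerSpec("HP", 8, 0.8))
        n_chains = sum(1 for k in out.mol_kind.values() if k == "polymer")
        assert n_chains == round(0.8 * math.pi * 100) == 251

    def test_zp_charge_pattern(self):
        np_spec = NanoparticleSpec(diameter=6.0)
        core = build_nanoparticle(np_spec)
        out = graft_polymers(core, np_spec, PolymerSpec("ZP", 8, 0.2))
        for chain in out.molecules_of_kind("polymer"):
            q = out.charge[chain]
            assert list(q[:-2]) == [0.0] * 6
            assert q[-2] == +1.0 and q[-1] == -1.0
            assert q.sum() == 0.0

    def test_zp_ph_ionizes_exact_third(self):
        np_spec = NanoparticleSpec(diameter=10.0)
        core = build_nanoparticle(np_spec)
        sigma = 99 / (math.pi * 100)   # -> exactly 99 chains
        out = graft_polymers(core, np_spec, PolymerSpec("ZP_pH", 8, sigma))
        chains = out.molecules_of_kind("polymer")
        assert len(chains) == 99
        net = [out.charge[c].sum() for c in chains]
        assert sum(1 for q in net if q == 1.0) == 33
        assert sum(1 for q in net if q == 0.0) == 66

    def test_each_chain_anchored_to_surface(self):
        np_spec = NanoparticleSpec(diameter=6.0)
        core = build_nanoparticle(np_spec)
        out = graft_polymers(core, np_spec, PolymerSpec("HP", 4, 0.4))
        n_core = core.n_beads
        anchored = {j for i, j in out.bond_ij if i < n_core <= j} | \
                   {i for i, j in out.bond_ij if j < n_core <= i}
        first_beads = {int(c[0]) for c in out.molecules_of_kind("polymer")}
        assert first_beads <= anchored

    def test_excessive_density_rejected(self):
        np_spec = NanoparticleSpec(diameter=4.0)
        core = build_nanoparticle(np_spec)
        with pytest.raises(ValueError):
            graft_polymers(core, np_spec, PolymerSpec("HP", 4, 20.0))


class TestBilayer:
    def test_composition_counts(self):
        topo = build_bilayer(10, 5, anionic_fraction=0.10)
        kinds = list(topo.mol_kind.values())
        assert len(kinds) == 100
        assert kinds.count(KIND_LIPID_ANIONIC) == 10

    def test_per_lipid_topology(self):
        topo = build_bilayer(3, 3, anionic_fraction=0.0)
        n_lip = 18
        assert topo.n_beads == 10 * n_lip
        assert len(topo.bond_ij) == 10 * n_lip      # 9 bonds + 1 weak bond
        assert len(topo.angle_ijk) == 4 * n_lip
        weak = np.isclose(topo.bond_ks, 10.0)
        assert weak.sum() == n_lip
        assert np.isclose(topo.bond_ks[~weak], 64.0).all()

    def test_neutral_lipid_charges(self):
        topo = build_bilayer(2, 2, anionic_fraction=0.0)
        for mol in topo.molecules_of_kind(*MEMBRANE_KINDS):
            q = topo.charge[mol]
            assert q[0] == 1.0 and q[1] == -1.0 and q[2:].sum() == 0.0

    def test_anionic_lipid_net_charge(self):
        topo = build_bilayer(5, 5, anionic_fraction=1.0)
        assert topo.net_charge() == -50.0

    def test_receptor_heads_flagged(self):
        topo = build_bilayer(4, 4, anionic_fraction=0.0, receptor_fraction=0.25)
        rec_beads = [i for i in range(topo.n_beads)
                     if topo.classes[topo.type_index[i]].is_receptor_head]
        # 4 receptor lipids per leaflet, 2 receptor head beads each
        assert len(rec_beads) == 2 * 2 * 4

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            build_bilayer(4, 4, anionic_fraction=0.8, receptor_fraction=0.5)


class TestProtein:
    def test_mapping_worked_example(self):
        topo = coarse_grain_protein("KDAV")
        labels = [topo.label_of(i) for i in range(4)]
        assert labels == ["AA+", "AA-", "AAH", "AAH"]
        assert list(topo.charge) == [1.0, -1.0, 0.0, 0.0]

    def test_bead_count_and_chain_topology(self):
        seq = synthetic_protein_sequence(30, seed=1)
        topo = coarse_grain_protein(seq)
        assert topo.n_beads == 30
        assert len(topo.bond_ij) == 29
        assert len(topo.angle_ijk) == 28
        assert np.isclose(topo.bond_ks, 64.0).all()
        assert np.isclose(topo.angle_ka, 2.0).all()

    def test_net_charge_counting_oracle(self, rng):
        letters = np.array(list(RESIDUE_MAP))
        for _ in range(5):
            seq = "".join(rng.choice(letters, size=50))
            topo = coarse_grain_protein(seq)
            expected = (seq.count("K") + seq.count("R")
                        - seq.count("D") - seq.count("E"))
            assert topo.net_charge() == expected

    def test_unknown_residue_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            coarse_grain_protein("KDXV")

    def test_synthetic_sequence_composition(self):
        seq = synthetic_protein_sequence(30, hydrophobic_fraction=0.3, seed=4)
        n_h = sum(1 for r in seq if RESIDUE_MAP[r] == "AAH")
        assert n_h == 9

    def test_explicit_coords_rescaled_to_bond_length(self):
        coords = np.cumsum(np.tile([[0.38, 0, 0]], (4, 1)), axis=0)
        topo = coarse_grain_protein("KDAV", coords=coords)
        steps = np.linalg.norm(np.diff(topo.positions, axis=0), axis=1)
        assert np.allclose(steps, 0.5)


class TestAntibody:
    def test_axial_extent(self):
        topo = build_antibody(AntibodySpec())
        extent = topo.positions[:, 2].max() - topo.positions[:, 2].min()
        assert abs(extent - 2.5) <= 0.20 + 1e-9   # within half a lattice spacing

    def test_all_beads_neutral_hydrophilic(self):
        topo = build_antibody(AntibodySpec())
        assert np.all(topo.charge == 0)
        for c in topo.classes:
            assert c.philicity == "hydrophilic" and c.is_antibody

    def test_six_antibodies_merged_into_np_body(self):
        np_spec = NanoparticleSpec(diameter=6.0)
        core = build_nanoparticle(np_spec)
        out = decorate_antibodies(core, np_spec, AntibodySpec(count=6))
        assert out.n_bodies == 1
        ab_mols = out.molecules_of_kind("antibody")
        assert len(ab_mols) == 6
        # maximally separated: octahedral directions are mutually orthogonal
        coms = np.array([out.positions[m].mean(axis=0) for m in ab_mols])
        units = coms / np.linalg.norm(coms, axis=1, keepdims=True)
        dots = np.abs(units @ units.T - np.eye(6))
        # every direction has an antipode and four orthogonal neighbors
        assert dots.max() <= 1.0 + 1e-9


class TestSolvation:
    def test_empty_box_density(self):
        topo = solvate_and_neutralize((10.0, 10.0, 10.0), None, molarity=0.0)
        assert topo.n_beads == 3000

    def test_full_box_ion_pairs(self):
        """0.10 M in the 75 x 75 x 40 nm production box -> ~13,550 pairs."""
        topo = solvate_and_neutralize((75.0, 75.0, 40.0), None, molarity=0.10)
        n_plus = int((topo.charge > 0).sum())
        n_minus = int((topo.charge < 0).sum())
        assert n_plus == n_minus == 13550
        assert topo.n_beads == round(3 * 75 * 75 * 40)

    def test_charged_solute_neutralized(self):
        np_spec = NanoparticleSpec(diameter=4.0, surface="positive",
                                   surface_charge_density=0.2)
        core = build_nanoparticle(np_spec)
        core.positions += 5.0
        full = solvate_and_neutralize((10.0, 10.0, 10.0), core, molarity=0.05)
        assert full.net_charge() == 0.0
        assert abs(full.n_beads - 3000) <= 1

    def test_same_seed_bit_identical(self):
        a = solvate_and_neutralize((8.0, 8.0, 8.0), None, molarity=0.1, seed=5)
        b = solvate_and_neutralize((8.0, 8.0, 8.0), None, molarity=0.1, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.charge, b.charge)

    def test_oversized_solute_rejected(self):
        big = build_nanoparticle(NanoparticleSpec(diameter=7.0))
        big.positions += 4.0
        with pytest.raises(ValueError):
            solvate_and_neutralize((4.0, 4.0, 4.0), big)


class TestFixtures:
    def test_pure_fluid(self):
        sc = make_fixture("pure_fluid", seed=0)
        from dpdcoat.pipeline import build_system
        topo = build_system(sc)
        assert topo.n_beads == 3000
        assert np.all(topo.charge == 0)

    def test_unknown_fixture_lists_available(self):
        with pytest.raises(ValueError, match="pure_fluid"):
            make_fixture("nope")

    def test_toy_protein_composition(self):
        sc = make_fixture("toy_protein", seed=2, n_residues=40,
                          hydrophobic_fraction=0.25)
        from dpdcoat.pipeline import build_system
        topo = build_system(sc)
        prot = topo.beads_of_kind(KIND_PROTEIN)
        assert len(prot) == 40
        n_h = sum(1 for b in prot if topo.label_of(b) == "AAH")
        assert n_h == 10
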