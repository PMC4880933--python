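"""Unit tests for the interaction terms: worked values, symmetries,
energy-force consistency, and the smeared-electrostatics oracle."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from dpdcoat.forcefield import (
    AngleTerm, BeadClass, BondTerm, ElectrostaticParams, ForceField,
    PairRepulsionTable, SoftLJTerm, ThermostatParams, angle_energy_force,
    bond_energy_force, build_pair_table, chi_to_a, conservative_pair_force,
    default_forcefield, dpd_thermostat_pair, smeared_coulomb_pair,
    soft_lj_energy_force,
)


# ---------------------------------------------------------------------------
# bead classes and pair table
# ---------------------------------------------------------------------------

class TestBeadClass:
    def test_charged_bead_must_be_hydrophilic(self):
        with pytest.raises(ValueError):
            BeadClass("X", "hydrophobic", charge=1)

    @pytest.mark.parametrize("q", [-2, 2, 5])
    def test_charge_restricted_to_unit_values(self, q):
        with pytest.raises(ValueError):
            BeadClass("X", "hydrophilic", charge=q)


class TestPairTable:
    def test_philicity_rule(self):
        classes = [BeadClass("W"), BeadClass("T", "hydrophobic"),
                   BeadClass("C", charge=1)]
        tab = build_pair_table(classes)
        assert tab.lookup("W", "W") == 25.0
        assert tab.lookup("T", "T") == 25.0
        assert tab.lookup("W", "T") == 100.0
        # charged beads are hydrophilic, hence 25 against hydrophilic
        assert tab.lookup("C", "W") == 25.0
        assert tab.lookup("C", "T") == 100.0
        assert np.allclose(tab.a, tab.a.T)

    def test_chi_override(self):
        classes = [BeadClass("A"), BeadClass("B")]
        tab = build_pair_table(classes, chi_overrides={("A", "B"): 1.0})
        assert tab.lookup("A", "B") == pytest.approx(28.497)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            PairRepulsionTable(labels=["A", "B"],
                               a=np.array([[25.0, 30.0], [40.0, 25.0]]))


@pytest.mark.parametrize("chi, expected", [
    (0.0, 25.0),
    (21.447, 100.0),
    (1.0, 28.497),
])
def test_chi_to_a(chi, expected):
    assert chi_to_a(25.0, chi) == pytest.approx(expected, abs=5e-4)


# ---------------------------------------------------------------------------
# conservative force
# ---------------------------------------------------------------------------

class TestConservativeForce:
    def test_zero_at_cutoff(self):
        assert np.allclose(conservative_pair_force([1.0, 0, 0], 100.0), 0.0)

    def test_overlap_limit_magnitude(self):
        f = conservative_pair_force([1e-12, 0, 0], 25.0)
        assert np.linalg.norm(f) == pytest.approx(25.0)

    def test_half_cutoff_value(self):
        f = conservative_pair_force([0.5, 0, 0], 100.0)
        assert np.allclose(f, [50.0, 0, 0])

    def test_antisymmetry(self, rng):
        r = rng.normal(size=3) * 0.3
        f1 = conservative_pair_force(r, 37.0)
        f2 = conservative_pair_force(-r, 37.0)
        assert np.allclose(f1, -f2)

    def test_exact_overlap_returns_zero(self):
        assert np.allclose(conservative_pair_force([0.0, 0, 0], 25.0), 0.0)


class TestThermostatPair:
    def test_quiescent_pair_zero(self):
        p = ThermostatParams()
        f = dpd_thermostat_pair([0.5, 0, 0], [0, 0, 0], p, 0.015, 0.0)
        assert np.allclose(f, 0.0)

    def test_fluctuation_dissipation_amplitude(self):
        assert ThermostatParams(gamma=4.5, kBT=1.0).sigma_noise == pytest.approx(3.0)

    def test_zero_beyond_cutoff(self):
        p = ThermostatParams()
        f = dpd_thermostat_pair([1.2, 0, 0], [1, 1, 1], p, 0.015, 0.7)
        assert np.allclose(f, 0.0)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            dpd_thermostat_pair([0.5, 0, 0], [0, 0, 0], ThermostatParams(), 0.0, 0.1)

    def test_dissipative_opposes_approach(self):
        p = ThermostatParams()
        # beads approaching along x: relative velocity of i is negative x
        f = dpd_thermostat_pair([0.5, 0, 0], [-1.0, 0, 0], p, 0.015, 0.0)
        assert f[0] > 0  # pushes i away from j (resists approach)


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

class TestBond:
    @pytest.mark.parametrize("r, ks, expected_u", [
        (0.5, 64.0, 0.0),
        (0.75, 64.0, 16.0),
        (0.75, 10.0, 2.5),
    ])
    def test_worked_energies(self, r, ks, expected_u):
        u, _ = bond_energy_force(r, BondTerm(k_s=ks, l0=0.5))
        assert u == pytest.approx(expected_u)

    def test_force_is_minus_du_dr(self):
        term = BondTerm(k_s=64.0, l0=0.5)
        r, h = 0.63, 1e-7
        _, f = bond_energy_force(r, term)
        u1, _ = bond_energy_force(r + h, term)
        u0, _ = bond_energy_force(r - h, term)
        assert f == pytest.approx(-(u1 - u0) / (2 * h), rel=1e-6)

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            bond_energy_force(0.0, BondTerm())


class TestAngle:
    @pytest.mark.parametrize("phi, ka, expected_u", [
        (180.0, 10.0, 0.0),
        (90.0, 10.0, 10.0),
        (90.0, 2.0, 2.0),
    ])
    def test_worked_energies(self, phi, ka, expected_u):
        rad = math.radians(phi)
        r1 = np.array([1.0, 0.0, 0.0])
        r2 = np.zeros(3)
        r3 = np.array([math.cos(rad), math.sin(rad), 0.0])
        u, *_ = angle_energy_force(r1, r2, r3, AngleTerm(k_a=ka, phi0=180.0))
        assert u == pytest.approx(expected_u)

    def test_forces_sum_to_zero_and_no_net_torque(self, rng):
        r1, r2, r3 = rng.normal(size=(3, 3))
        u, f1, f2, f3 = angle_energy_force(r1, r2, r3, AngleTerm(k_a=7.0))
        assert np.allclose(f1 + f2 + f3, 0.0, atol=1e-12)
        torque = np.cross(r1, f1) + np.cross(r2, f2) + np.cross(r3, f3)
        assert np.allclose(torque, 0.0, atol=1e-10)

    def test_force_matches_numeric_gradient(self, rng):
        term = AngleTerm(k_a=10.0, phi0=180.0)
        r1, r2, r3 = rng.normal(size=(3, 3)) * 0.6 + np.array([1.0, 0, 0])
        h = 1e-7
        _, f1, f2, f3 = angle_energy_force(r1, r2, r3, term)
        for vec, f in ((r1, f1), (r3, f3)):
            for k in range(3):
                e = np.zeros(3)
                e[k] = h
                up, *_ = angle_energy_force(r1 + (e if vec is r1 else 0),
                                            r2, r3 + (e if vec is r3 else 0), term)
                dn, *_ = angle_energy_force(r1 - (e if vec is r1 else 0),
                                            r2, r3 - (e if vec is r3 else 0), term)
                assert f[k] == pytest.approx(-(up - dn) / (2 * h), abs=1e-5)


# ---------------------------------------------------------------------------
# soft LJ
# ---------------------------------------------------------------------------

class TestSoftLJ:
    def test_minimum_location_and_depth(self):
        r_min = 2.0 ** (1 / 6) * 0.624
        u, f = soft_lj_energy_force(r_min, SoftLJTerm())
        assert u == pytest.approx(-5.0)
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_repulsive_cap(self):
        _, f = soft_lj_energy_force(0.3, SoftLJTerm())
        assert f == pytest.approx(25.0)

    def test_truncated_beyond_cutoff(self):
        assert soft_lj_energy_force(1.0, SoftLJTerm()) == (0.0, 0.0)

    @pytest.mark.parametrize("r", [0.25, 0.66, 0.80, 0.95])
    def test_energy_force_consistency(self, r):
        term = SoftLJTerm()
        h = 1e-7
        _, f = soft_lj_energy_force(r, term)
        up, _ = soft_lj_energy_force(r + h, term)
        dn, _ = soft_lj_energy_force(r - h, term)
        assert f == pytest.approx(-(up - dn) / (2 * h), rel=1e-6, abs=1e-6)


# ---------------------------------------------------------------------------
# smeared electrostatics
# ---------------------------------------------------------------------------

def _fourier_oracle(d: float, r_e: float) -> float:
    """Reduced cloud-cloud energy via the k-space convolution integral.

    Independent of the real-space quadrature used by the implementation:
    U(d) = (1/2 pi^2) int dk  rho_hat(k)^2 sinc(k d), with rho_hat the
    radial Fourier transform of the normalized linear-decay cloud.
    """
    def rho_hat(k):
        val, _ = quad(lambda r: 4 * math.pi * r * r
                      * (3 / (math.pi * r_e ** 3)) * (1 - r / r_e)
                      * (math.sin(k * r) / (k * r) if k * r > 1e-12 else 1.0),
                      0, r_e, limit=100)
        return val

    def integrand(k):
        s = math.sin(k * d) / (k * d) if k * d > 1e-12 else 1.0
        return rho_hat(k) ** 2 * s

    val, _ = quad(integrand, 0, 60.0 / r_e, limit=400)
    return val / (2 * math.pi ** 2)


class TestSmearedCoulomb:
    params = ElectrostaticParams()

    def test_point_coulomb_beyond_cloud_overlap(self):
        u, f = smeared_coulomb_pair(4.0, 1, 1, self.params)
        point = self.params.coupling / (4 * math.pi * 4.0)
        assert u == pytest.approx(point, rel=1e-12)
        assert f == pytest.approx(point / 4.0, rel=1e-12)

    @pytest.mark.parametrize("r", [0.0, 0.5, 1.3, 2.4, 3.1])
    def test_matches_fourier_space_oracle(self, r):
        u, _ = smeared_coulomb_pair(r, 1, 1, self.params)
        expected = self.params.coupling * _fourier_oracle(max(r, 1e-9), self.params.r_e)
        assert u == pytest.approx(expected, rel=2e-3)

    def test_finite_at_contact(self):
        u, f = smeared_coulomb_pair(0.0, 1, 1, self.params)
        assert np.isfinite(u) and u > 0
        assert f == pytest.approx(0.0, abs=1e-6)   # symmetry at overlap

    def test_opposite_charges_attract_everywhere(self):
        for r in (0.2, 1.0, 2.5, 5.0):
            u, f = smeared_coulomb_pair(r, 1, -1, self.params)
            assert u < 0
            assert f < 0  # negative scalar force = attraction

    def test_energy_force_consistency(self):
        h = 1e-6
        for r in (0.7, 1.8, 2.9):
            _, f = smeared_coulomb_pair(r, 1, 1, self.params)
            up, _ = smeared_coulomb_pair(r + h, 1, 1, self.params)
            dn, _ = smeared_coulomb_pair(r - h, 1, 1, self.params)
            assert f == pytest.approx(-(up - dn) / (2 * h), rel=1e-4)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_forcefield_yaml_round_trip(tmp_path):
    classes = [BeadClass("W"), BeadClass("T", "hydrophobic"),
               BeadClass("C", charge=-1, is_receptor_head=True)]
    ff = default_forcefield(classes)
    path = tmp_path / "ff.yaml"
    ff.to_yaml(path)
    back = ForceField.from_yaml(path)
    assert back.pair_table.labels == ff.pair_table.labels
    assert np.allclose(back.pair_table.a, ff.pair_table.a)
    assert back.thermostat == ff.thermostat
    assert back.electrostatics == ff.electrostatics
    assert back.classes == ff.classes
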