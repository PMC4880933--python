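"""Interaction terms for coarse-grained DPD simulations of decorated nanoparticles.

All quantities are expressed in reduced DPD units: the pair cutoff ``r_c`` is
the length unit, the bead mass ``m`` the mass unit, and the thermal energy
``kBT`` the energy unit.  The physical mapping used throughout the package is
``r_c = 1 nm`` and ``tau = 2.4 ns``.

The module defines the bead-class vocabulary, the pairwise maximum-repulsion
table, the thermostat (dissipative + random) pair forces, smeared-charge
Coulomb interactions, the soft Lennard-Jones term used for antibody--receptor
recognition, and the bonded (harmonic bond, cosine angle) terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import yaml
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

log = logging.getLogger("dpdcoat")

# ---------------------------------------------------------------------------
# Canonical parameter values (reduced units)
# ---------------------------------------------------------------------------

#: Like-like maximum repulsion, kBT/r_c.
A_LIKE = 25.0
#: Hydrophilic--hydrophobic maximum repulsion, kBT/r_c.
A_UNLIKE = 100.0
#: Conversion slope from Flory-Huggins chi to repulsion at bead density 3.
CHI_SLOPE = 3.497
#: Dissipative friction gamma, kBT*tau/r_c^2 (standard DPD thermostat value).
GAMMA_DEFAULT = 4.5
#: Reduced Coulomb coupling for water at room temperature with r_c ~ 1 nm.
COULOMB_GAMMA = 13.87
#: Charge-smearing radius, r_c.
SMEAR_RADIUS = 1.6
#: Real-space electrostatic cutoff, r_c.
ELEC_CUTOFF = 3.0
#: Soft LJ parameters for the antibody--receptor specific interaction.
LJ_EPSILON = 5.0
LJ_SIGMA = 0.624
LJ_FORCE_CAP = 25.0
#: Harmonic bond defaults (backbone / weak lipid inter-tail bond).
BOND_KS = 64.0
BOND_KS_WEAK = 10.0
BOND_L0 = 0.5
#: Angle stiffness defaults (lipid tails / protein backbone), phi0 = 180 deg.
ANGLE_KA_LIPID = 10.0
ANGLE_KA_PROTEIN = 2.0

HYDROPHILIC = "hydrophilic"
HYDROPHOBIC = "hydrophobic"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadClass:
    """One coarse-grained bead species.

    Charged beads are always hydrophilic: in this model charge implies a polar,
    water-liking site, so a charged hydrophobic bead is rejected outright.
    """

    label: str
    philicity: str = HYDROPHILIC
    charge: int = 0
    is_receptor_head: bool = False
    is_antibody: bool = False

    def __post_init__(self):
        if self.philicity not in (HYDROPHILIC, HYDROPHOBIC):
            raise ValueError(f"unknown philicity {self.philicity!r}")
        if self.charge not in (-1, 0, 1):
            raise ValueError(f"bead charge must be -1, 0 or +1, got {self.charge}")
        if self.charge != 0 and self.philicity != HYDROPHILIC:
            raise ValueError("charged beads must be hydrophilic")


@dataclass
class PairRepulsionTable:
    """Symmetric table of maximum conservative repulsions a_ij (kBT/r_c)."""

    labels: list[str]
    a: np.ndarray
    r_c: float = 1.0

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.labels)
        if self.a.shape != (n, n):
            raise ValueError("a matrix shape does not match label count")
        if not np.allclose(self.a, self.a.T):
            raise ValueError("a matrix must be symmetric")

    def lookup(self, label_i: str, label_j: str) -> float:
        i = self.labels.index(label_i)
        j = self.labels.index(label_j)
        return float(self.a[i, j])


def build_pair_table(
    classes: list[BeadClass],
    chi_overrides: dict[tuple[str, str], float] | None = None,
    r_c: float = 1.0,
) -> PairRepulsionTable:
    """Build the a_ij table from the philicity rule.

    Like-philicity pairs repel with ``A_LIKE`` = 25, hydrophilic--hydrophobic
    pairs with ``A_UNLIKE`` = 100.  Specific pairs may be overridden through a
    Flory-Huggins chi value, mapped as a_ij = 25 + 3.497 chi.
    """
    labels = [c.label for c in classes]
    n = len(classes)
    a = np.empty((n, n))
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            a[i, j] = A_LIKE if ci.philicity == cj.philicity else A_UNLIKE
    if chi_overrides:
        for (li, lj), chi in chi_overrides.items():
            i, j = labels.index(li), labels.index(lj)
            a[i, j] = a[j, i] = chi_to_a(A_LIKE, chi)
    return PairRepulsionTable(labels=labels, a=a, r_c=r_c)


@dataclass(frozen=True)
class ThermostatParams:
    """Dissipative/random pair-force parameters.

    ``sigma_noise`` is tied to ``gamma`` by the fluctuation--dissipation
    relation sigma^2 = 2 gamma kBT, and the weight functions obey
    w^D(r) = [w^R(r)]^2 with the standard linear w^R(r) = 1 - r/r_c.
    """

    gamma: float = GAMMA_DEFAULT
    kBT: float = 1.0

    @property
    def sigma_noise(self) -> float:
        return math.sqrt(2.0 * self.gamma * self.kBT)


@dataclass(frozen=True)
class ElectrostaticParams:
    """Smeared-charge Coulomb parameters.

    Each unit charge is spread over a spherically symmetric cloud with a
    linearly decaying density ``rho(r) ~ (1 - r/r_e)`` for r < r_e, which keeps
    the pair energy finite at zero separation (the soft DPD repulsion permits
    bead overlap).  For separations beyond ``2 r_e`` the clouds do not overlap
    and the interaction is exactly the point Coulomb form Gamma q_i q_j/(4 pi r).
    """

    r_e: float = SMEAR_RADIUS
    coupling: float = COULOMB_GAMMA
    cutoff: float = ELEC_CUTOFF
    method: str = "direct_smeared"

    def __post_init__(self):
        if self.r_e <= 0:
            raise ValueError("smearing radius must be positive")
        if self.method not in ("direct_smeared", "ewald_smeared"):
            raise ValueError(f"unknown electrostatics method {self.method!r}")


@dataclass(frozen=True)
class SoftLJTerm:
    """Truncated 12-6 LJ between antibody beads and receptor head beads.

    The repulsive branch of the force is clamped at ``force_cap`` so that the
    soft DPD dynamics stays stable; the energy inside the cap radius is
    integrated consistently from the capped force.  Truncated (not shifted)
    at the cutoff.
    """

    epsilon: float = LJ_EPSILON
    sigma_lj: float = LJ_SIGMA
    cutoff: float = 1.0
    force_cap: float = LJ_FORCE_CAP


@dataclass(frozen=True)
class BondTerm:
    """Harmonic (fractional-extension) bond U = k_s (1 - r/l0)^2."""

    k_s: float = BOND_KS
    l0: float = BOND_L0

    def __post_init__(self):
        if self.k_s < 0 or self.l0 <= 0:
            raise ValueError("bond requires k_s >= 0 and l0 > 0")


@dataclass(frozen=True)
class AngleTerm:
    """Cosine angle potential U = k_a (1 - cos(phi - phi0)), phi0 in degrees."""

    k_a: float = ANGLE_KA_LIPID
    phi0: float = 180.0

    def __post_init__(self):
        if self.k_a < 0:
            raise ValueError("angle stiffness must be non-negative")


# ---------------------------------------------------------------------------
# Pair interactions
# ---------------------------------------------------------------------------

def chi_to_a(a_ii: float, chi: float) -> float:
    """Map a Flory-Huggins chi parameter to a DPD repulsion a_ij = a_ii + 3.497 chi."""
    return a_ii + CHI_SLOPE * chi


def conservative_pair_force(r_vec: np.ndarray, a_ij: float, r_c: float = 1.0) -> np.ndarray:
    """Soft linear repulsion F = a_ij (1 - r/r_c) r_hat for r < r_c, zero beyond.

    ``r_vec`` is the minimum-image displacement r_i - r_j; the returned force
    acts on bead i (bead j receives the exact negative).  Exact overlap (r = 0)
    has no defined direction; the soft potential permits it, so the force is
    zero there and a warning is logged.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        log.warning("conservative_pair_force: exact bead overlap, returning zero force")
        return np.zeros_like(r_vec)
    if r >= r_c:
        return np.zeros_like(r_vec)
    return a_ij * (1.0 - r / r_c) * (r_vec / r)


def dpd_thermostat_pair(
    r_vec: np.ndarray,
    v_rel: np.ndarray,
    params: ThermostatParams,
    dt: float,
    noise: float,
    r_c: float = 1.0,
) -> np.ndarray:
    """Dissipative plus random pair force of the DPD thermostat.

    F^D = -gamma w^D(r) (r_hat . v_rel) r_hat with w^D = (1 - r/r_c)^2, and
    F^R = sigma w^R(r) theta dt^(-1/2) r_hat with w^R = 1 - r/r_c, where
    ``noise`` is the single unit-normal draw shared (with identical sign
    convention on r_vec) by the (i,j) and (j,i) contributions so the pair
    force is exactly antisymmetric.  Both vanish at and beyond r_c.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r_vec = np.asarray(r_vec, dtype=float)
    v_rel = np.asarray(v_rel, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0 or r >= r_c:
        return np.zeros_like(r_vec)
    e = r_vec / r
    w_r = 1.0 - r / r_c
    w_d = w_r * w_r
    f_d = -params.gamma * w_d * float(np.dot(e, v_rel))
    f_r = params.sigma_noise * w_r * noise / math.sqrt(dt)
    return (f_d + f_r) * e


def bond_energy_force(r: float, term: BondTerm) -> tuple[float, float]:
    """Energy and scalar force of the harmonic bond U = k_s (1 - r/l0)^2.

    Returns ``(energy, f)`` where ``f`` is the force magnitude along the bond
    axis acting on bead i, positive = repulsive (pushing the pair apart):
    f = -dU/dr = 2 k_s (1 - r/l0) / l0.
    """
    if r <= 0:
        raise ValueError("bond separation must be positive (direction undefined at r = 0)")
    x = 1.0 - r / term.l0
    energy = term.k_s * x * x
    f = 2.0 * term.k_s * x / term.l0
    return energy, f


def angle_energy(phi_deg: float, term: AngleTerm) -> float:
    """Energy of the cosine angle potential at angle ``phi_deg`` (degrees)."""
    return term.k_a * (1.0 - math.cos(math.radians(phi_deg - term.phi0)))


def angle_energy_force(
    r1: np.ndarray, r2: np.ndarray, r3: np.ndarray, term: AngleTerm
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Energy and per-bead forces for the angle formed at bead 2 by beads 1-2-3.

    Forces sum to zero and exert zero net torque about any point (the
    potential depends only on the internal angle).  Collinear geometries with
    ``phi0 = 180`` are the potential minimum and return zero force; collinear
    geometries with other ``phi0`` have an undefined bending plane -- the
    force is returned as zero and a warning logged.
    """
    r1, r2, r3 = (np.asarray(v, dtype=float) for v in (r1, r2, r3))
    a = r1 - r2
    b = r3 - r2
    la = float(np.linalg.norm(a))
    lb = float(np.linalg.norm(b))
    if la == 0.0 or lb == 0.0:
        raise ValueError("degenerate angle: coincident beads")
    cos_phi = float(np.dot(a, b)) / (la * lb)
    cos_phi = max(-1.0, min(1.0, cos_phi))
    phi = math.acos(cos_phi)
    phi0 = math.radians(term.phi0)
    energy = term.k_a * (1.0 - math.cos(phi - phi0))
    sin_phi = math.sqrt(max(0.0, 1.0 - cos_phi * cos_phi))
    # dU/d(cos phi) = -k_a sin(phi - phi0) / sin(phi); for phi0 = 180 deg this
    # is exactly +k_a with no singularity (U = k_a (1 + cos phi)).
    if abs(phi0 - math.pi) < 1e-12:
        du_dcos = term.k_a
    elif sin_phi < 1e-8:
        log.warning("angle_energy_force: collinear geometry with phi0 != 180, zero force")
        z = np.zeros(3)
        return energy, z, z, z
    else:
        du_dcos = -term.k_a * math.sin(phi - phi0) / sin_phi
    # d(cos phi)/dr1 and /dr3 by direct differentiation.
    dcos_da = b / (la * lb) - cos_phi * a / (la * la)
    dcos_db = a / (la * lb) - cos_phi * b / (lb * lb)
    f1 = -du_dcos * dcos_da
    f3 = -du_dcos * dcos_db
    f2 = -(f1 + f3)
    return energy, f1, f2, f3


# --- soft Lennard-Jones ----------------------------------------------------

def _lj_force_scalar(r: float, eps: float, sig: float) -> float:
    sr6 = (sig / r) ** 6
    return 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r


@lru_cache(maxsize=16)
def _lj_cap_radius(eps: float, sig: float, cap: float) -> float:
    """Separation below which the repulsive LJ force would exceed the cap."""
    r_min = 2.0 ** (1.0 / 6.0) * sig
    if _lj_force_scalar(r_min * (1.0 - 1e-12), eps, sig) >= cap:
        return r_min
    return brentq(lambda r: _lj_force_scalar(r, eps, sig) - cap, 1e-3 * sig, r_min)


def soft_lj_energy_force(r: float, term: SoftLJTerm) -> tuple[float, float]:
    """Truncated 12-6 LJ with the repulsive force clamped at ``force_cap``.

    Returns ``(energy, f)`` with ``f`` the scalar force on bead i along the
    separation axis (positive = repulsive).  Inside the cap radius the force is
    constant at ``force_cap`` and the energy continues linearly, so energy and
    force stay consistent everywhere.  Beyond the cutoff both are zero
    (truncated, not shifted).
    """
    if r >= term.cutoff:
        return 0.0, 0.0
    eps, sig = term.epsilon, term.sigma_lj
    r_cap = _lj_cap_radius(eps, sig, term.force_cap)
    if r <= r_cap:
        sr6 = (sig / r_cap) ** 6
        u_cap = 4.0 * eps * (sr6 * sr6 - sr6)
        return u_cap + term.force_cap * (r_cap - r), term.force_cap
    sr6 = (sig / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6), _lj_force_scalar(r, eps, sig)


# --- smeared-charge electrostatics ----------------------------------------

def _cloud_potential(s: float, r_e: float) -> float:
    """Electrostatic potential (units of 1/(4 pi)) of one unit linear-decay cloud."""
    if s >= r_e:
        return 1.0 / (4.0 * math.pi * s)
    x = s / r_e
    q_enc = 4.0 * x**3 - 3.0 * x**4
    # shell contribution integral_s^re 4 pi r n(r) dr with n = 3/(pi re^3)(1 - r/re)
    outer = (12.0 / r_e) * ((1.0 - x * x) / 2.0 - (1.0 - x**3) / 3.0)
    return (q_enc / s + outer) / (4.0 * math.pi)


def _smeared_energy_exact(d: float, r_e: float) -> float:
    """Reduced cloud-cloud interaction energy (multiply by Gamma q_i q_j).

    Computed by radial quadrature: the density of cloud 1 weighted with the
    spherical average of the analytic potential of cloud 2.
    """
    if d >= 2.0 * r_e:
        return 1.0 / (4.0 * math.pi * d)

    def shell(r: float) -> float:
        n = 3.0 / (math.pi * r_e**3) * (1.0 - r / r_e)
        if d < 1e-9:
            return 4.0 * math.pi * r * r * n * _cloud_potential(max(r, 1e-12), r_e)
        lo, hi = abs(d - r), d + r
        avg, _ = quad(lambda s: s * _cloud_potential(max(s, 1e-12), r_e), lo, hi)
        return 4.0 * math.pi * r * r * n * avg / (2.0 * r * d)

    val, _ = quad(shell, 0.0, r_e, limit=200)
    return val


@lru_cache(maxsize=8)
def _smeared_table(r_e: float) -> CubicSpline:
    """Cubic spline of the reduced cloud-cloud energy on [0, 2 r_e]."""
    grid = np.linspace(0.0, 2.0 * r_e, 121)
    vals = np.array([_smeared_energy_exact(d, r_e) for d in grid])
    # clamp the boundary slope to the point-Coulomb derivative for smoothness
    return CubicSpline(grid, vals, bc_type=((1, 0.0), (1, -1.0 / (4.0 * math.pi * (2 * r_e) ** 2))))


def smeared_coulomb_pair(
    r: float, q_i: float, q_j: float, params: ElectrostaticParams
) -> tuple[float, float]:
    """Energy and scalar force between two smeared charges at separation ``r``.

    Energy is Gamma q_i q_j times the reduced cloud-cloud interaction; it is
    finite at r = 0 and identical to the point Coulomb Gamma q q'/(4 pi r) for
    r >= 2 r_e.  Positive returned force means repulsion (like charges).
    The production cell-list evaluator applies the real-space cutoff; this
    reference form is the uncut pair law.
    """
    pref = params.coupling * q_i * q_j
    if r >= 2.0 * params.r_e:
        u = pref / (4.0 * math.pi * r)
        return u, u / r
    spl = _smeared_table(params.r_e)
    u = pref * float(spl(r))
    f = -pref * float(spl(r, 1))
    return u, f


# ---------------------------------------------------------------------------
# Aggregate force field + YAML serialization
# ---------------------------------------------------------------------------

FORCEFIELD_SCHEMA_VERSION = 1


@dataclass
class ForceField:
    """Everything needed to evaluate forces on a topology."""

    classes: list[BeadClass]
    pair_table: PairRepulsionTable
    thermostat: ThermostatParams = field(default_factory=ThermostatParams)
    electrostatics: ElectrostaticParams = field(default_factory=ElectrostaticParams)
    soft_lj: SoftLJTerm = field(default_factory=SoftLJTerm)
    r_c: float = 1.0

    def class_index(self, label: str) -> int:
        return self.pair_table.labels.index(label)

    def to_yaml(self, path) -> None:
        doc = {
            "schema_version": FORCEFIELD_SCHEMA_VERSION,
            "r_c": self.r_c,
            "classes": [asdict(c) for c in self.classes],
            "pair_table": {
                "labels": list(self.pair_table.labels),
                "a": self.pair_table.a.tolist(),
            },
            "thermostat": {"gamma": self.thermostat.gamma, "kBT": self.thermostat.kBT},
            "electrostatics": asdict(self.electrostatics),
            "soft_lj": asdict(self.soft_lj),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ForceField":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("schema_version") != FORCEFIELD_SCHEMA_VERSION:
            raise ValueError(f"unsupported force-field schema {doc.get('schema_version')!r}")
        return cls(
            classes=[BeadClass(**c) for c in doc["classes"]],
            pair_table=PairRepulsionTable(
                labels=doc["pair_table"]["labels"],
                a=np.array(doc["pair_table"]["a"]),
                r_c=doc["r_c"],
            ),
            thermostat=ThermostatParams(**doc["thermostat"]),
            electrostatics=ElectrostaticParams(**doc["electrostatics"]),
            soft_lj=SoftLJTerm(**doc["soft_lj"]),
            r_c=doc["r_c"],
        )


def default_forcefield(classes: list[BeadClass], **kwargs) -> ForceField:
    """Force field with the philicity-rule pair table and canonical parameters."""
    return ForceField(classes=classes, pair_table=build_pair_table(classes), **kwargs)
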