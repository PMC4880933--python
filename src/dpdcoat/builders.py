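"""Constructors for every component of the simulated systems.

Nanoparticle cores are fcc-lattice rigid bodies; stealth polymers (HP =
hydrophilic neutral, ZP = zwitterionic with a terminal -/+ dipole, ZP_pH =
partially ionized ZP) are grafted at quasi-uniform spherical anchor points;
membranes are pre-assembled two-leaflet bilayers of 10-bead lipids; serum
proteins are one-bead-per-residue chains (from a PDB file or a synthetic
sequence); antibodies are short rigid hydrophilic cylinders.  All lengths are
in r_c units with the mapping r_c = 1 nm.

This module is also the synthetic-data generator: :func:`make_fixture`
returns small named scenarios (a pure fluid, a mini bilayer, toy proteins, a
nanoparticle over a membrane patch, an electrostatics pair) so every
downstream stage is testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import (
    ANGLE_KA_LIPID, ANGLE_KA_PROTEIN, BOND_KS, BOND_KS_WEAK, BOND_L0,
    BeadClass, HYDROPHILIC, HYDROPHOBIC,
)
from .topology import (
    KIND_ANTIBODY, KIND_ION, KIND_LIPID, KIND_LIPID_ANIONIC,
    KIND_LIPID_RECEPTOR, KIND_NP_CORE, KIND_POLYMER, KIND_PROTEIN, KIND_WATER,
    Topology, merge,
)

FCC_LATTICE_CONSTANT = 0.40   # r_c (= nm)
WATER_DENSITY = 3.0           # beads / r_c^3
AVOGADRO_PER_NM3 = 0.60221408  # formula units per nm^3 at 1 mol/L

# ---------------------------------------------------------------------------
# Bead-class vocabulary
# ---------------------------------------------------------------------------

CLASS = {
    "W": BeadClass("W", HYDROPHILIC, 0),
    "ION+": BeadClass("ION+", HYDROPHILIC, +1),
    "ION-": BeadClass("ION-", HYDROPHILIC, -1),
    "NPH": BeadClass("NPH", HYDROPHOBIC, 0),
    "NPP": BeadClass("NPP", HYDROPHILIC, 0),
    "NP+": BeadClass("NP+", HYDROPHILIC, +1),
    "NP-": BeadClass("NP-", HYDROPHILIC, -1),
    "P": BeadClass("P", HYDROPHILIC, 0),
    "P+": BeadClass("P+", HYDROPHILIC, +1),
    "P-": BeadClass("P-", HYDROPHILIC, -1),
    "LH": BeadClass("LH", HYDROPHILIC, 0),
    "LH+": BeadClass("LH+", HYDROPHILIC, +1),
    "LH-": BeadClass("LH-", HYDROPHILIC, -1),
    "LT": BeadClass("LT", HYDROPHOBIC, 0),
    "RH": BeadClass("RH", HYDROPHILIC, 0, is_receptor_head=True),
    "AA0": BeadClass("AA0", HYDROPHILIC, 0),
    "AA+": BeadClass("AA+", HYDROPHILIC, +1),
    "AA-": BeadClass("AA-", HYDROPHILIC, -1),
    "AAH": BeadClass("AAH", HYDROPHOBIC, 0),
    "AB": BeadClass("AB", HYDROPHILIC, 0, is_antibody=True),
}

#: One-letter residue -> bead class.  Acidic residues carry -e, basic +e,
#: other polar/small residues are neutral hydrophilic, aliphatic/aromatic
#: residues hydrophobic (a Kyte-Doolittle-style split; config-overridable).
RESIDUE_MAP: dict[str, str] = {
    **{r: "AA-" for r in "DE"},
    **{r: "AA+" for r in "KR"},
    **{r: "AA0" for r in "HSTNQCYGP"},
    **{r: "AAH" for r in "AVLIMFW"},
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _fragment(labels, positions, charges=None, body=None, mol_id=None,
              mol_kind=None, bonds=(), angles=()) -> Topology:
    """Assemble a Topology fragment from parallel per-bead lists."""
    uniq: list[str] = []
    for lb in labels:
        if lb not in uniq:
            uniq.append(lb)
    classes = [CLASS[lb] for lb in uniq]
    tindex = np.array([uniq.index(lb) for lb in labels], np.int64)
    n = len(labels)
    if charges is None:
        charges = [CLASS[lb].charge for lb in labels]
    bonds = list(bonds)
    angles = list(angles)
    return Topology(
        classes=classes,
        type_index=tindex,
        positions=np.asarray(positions, float).reshape(n, 3),
        charge=np.asarray(charges, float),
        body_id=np.full(n, -1, np.int64) if body is None else np.asarray(body, np.int64),
        mol_id=np.zeros(n, np.int64) if mol_id is None else np.asarray(mol_id, np.int64),
        mol_kind=mol_kind or {0: KIND_WATER},
        bond_ij=np.array([b[:2] for b in bonds], np.int64).reshape(len(bonds), 2),
        bond_ks=np.array([b[2] for b in bonds], float),
        bond_l0=np.array([b[3] for b in bonds], float),
        angle_ijk=np.array([a[:3] for a in angles], np.int64).reshape(len(angles), 3),
        angle_ka=np.array([a[3] for a in angles], float),
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


# ---------------------------------------------------------------------------
# Component specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NanoparticleSpec:
    diameter: float = 6.0                       # nm
    surface: str = "hydrophobic"                # hydrophobic | positive | negative
    surface_charge_density: float = 0.2         # e / nm^2 (charged surfaces)
    lattice_constant: float = FCC_LATTICE_CONSTANT

    def __post_init__(self):
        if self.surface not in ("hydrophobic", "positive", "negative"):
            raise ValueError(f"unknown surface chemistry {self.surface!r}")
        if self.diameter <= self.lattice_constant:
            raise ValueError("diameter must exceed the lattice constant")


@dataclass(frozen=True)
class PolymerSpec:
    type: str = "HP"            # HP | ZP | ZP_pH
    length: int = 8             # beads per chain
    density: float = 0.8        # chains / nm^2
    ionized_fraction: float = 1.0 / 3.0   # ZP_pH only

    def __post_init__(self):
        if self.type not in ("HP", "ZP", "ZP_pH"):
            raise ValueError(f"unknown polymer type {self.type!r}")
        if self.type in ("ZP", "ZP_pH") and self.length < 2:
            raise ValueError("zwitterionic chains need at least two beads")


@dataclass(frozen=True)
class ProteinSpec:
    sequence: str
    bond_ks: float = BOND_KS
    angle_ka: float = ANGLE_KA_PROTEIN


@dataclass(frozen=True)
class AntibodySpec:
    length: float = 2.5         # nm
    radius: float = 0.5         # nm (unstated in the model; declared default)
    count: int = 6
    lattice_constant: float = FCC_LATTICE_CONSTANT


# ---------------------------------------------------------------------------
# Nanoparticle
# ---------------------------------------------------------------------------

def fcc_sites(extent: float, a: float) -> np.ndarray:
    """All fcc lattice sites with |site| <= extent (conventional cell constant a)."""
    basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]) * a
    m = int(math.ceil(extent / a)) + 1
    cells = np.arange(-m, m + 1) * a
    gx, gy, gz = np.meshgrid(cells, cells, cells, indexing="ij")
    corners = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    sites = (corners[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    keep = np.einsum("ij,ij->i", sites, sites) <= extent * extent + 1e-12
    return sites[keep]


def build_nanoparticle(spec: NanoparticleSpec, seed: int = 0) -> Topology:
    """Rigid fcc-lattice sphere, optionally homogeneously surface-charged.

    Charged variants are hydrophilic; the number of charged surface beads is
    round(density * pi * diameter^2), distributed by snapping a Fibonacci
    point set onto the outermost lattice shell.
    """
    R = spec.diameter / 2.0
    sites = fcc_sites(R, spec.lattice_constant)
    sites = sites[np.argsort(np.einsum("ij,ij->i", sites, sites), kind="stable")]
    n = len(sites)
    if spec.surface == "hydrophobic":
        labels = ["NPH"] * n
    else:
        labels = ["NPP"] * n
        n_charged = int(round(spec.surface_charge_density * math.pi * spec.diameter ** 2))
        rad = np.linalg.norm(sites, axis=1)
        surface = np.nonzero(rad >= R - spec.lattice_constant)[0]
        if n_charged > len(surface):
            raise ValueError(
                f"requested {n_charged} charged beads but only {len(surface)} "
                "surface sites are available")
        dirs = fibonacci_sphere(n_charged)
        unit = sites[surface] / rad[surface, None]
        taken = np.zeros(len(surface), bool)
        charged_label = "NP+" if spec.surface == "positive" else "NP-"
        for d in dirs:
            order = np.argsort(-(unit @ d), kind="stable")
            for k in order:
                if not taken[k]:
                    taken[k] = True
                    labels[surface[k]] = charged_label
                    break
    return _fragment(
        labels, sites,
        body=np.zeros(n, np.int64),
        mol_id=np.zeros(n, np.int64),
        mol_kind={0: KIND_NP_CORE},
    )


def nanoparticle_surface_indices(np_topo: Topology, spec: NanoparticleSpec) -> np.ndarray:
    rad = np.linalg.norm(np_topo.positions, axis=1)
    return np.nonzero(rad >= spec.diameter / 2.0 - spec.lattice_constant)[0]


# ---------------------------------------------------------------------------
# Grafted polymers
# ---------------------------------------------------------------------------

def graft_polymers(np_topo: Topology, np_spec: NanoparticleSpec,
                   spec: PolymerSpec, seed: int = 0) -> Topology:
    """Graft round(density * pi d^2) chains at quasi-uniform anchor points.

    Each chain extends radially outward at the bond rest length and its first
    bead is bonded to the nearest nanoparticle surface bead.  Charge pattern:
    HP all neutral; ZP last bead -e, penultimate +e; ZP_pH additionally
    ionizes exactly round(fraction * n_chains) chains to net +1 (the terminal
    anion is protonated to neutral, chosen by a seeded draw).
    """
    d = np_spec.diameter
    n_chains = int(round(spec.density * math.pi * d * d))
    if n_chains == 0:
        return merge([np_topo])
    surf = nanoparticle_surface_indices(np_topo, np_spec)
    if n_chains > len(surf):
        raise ValueError("grafting density too high: anchor sites would collide")
    dirs = fibonacci_sphere(n_chains)
    surf_pos = np_topo.positions[surf]
    unit = surf_pos / np.linalg.norm(surf_pos, axis=1, keepdims=True)
    taken = np.zeros(len(surf), bool)
    anchors = np.empty(n_chains, np.int64)
    for c, dvec in enumerate(dirs):
        order = np.argsort(-(unit @ dvec), kind="stable")
        for k in order:
            if not taken[k]:
                taken[k] = True
                anchors[c] = surf[k]
                break
    # minimal anchor spacing guard (~0.3 r_c)
    apos = np_topo.positions[anchors]
    if n_chains > 1:
        from scipy.spatial import cKDTree
        dmin, _ = cKDTree(apos).query(apos, k=2)
        if float(dmin[:, 1].min()) < 0.3:
            raise ValueError("grafting density too high: anchors closer than 0.3 r_c")

    rng = np.random.default_rng(seed)
    ionized = np.zeros(n_chains, bool)
    if spec.type == "ZP_pH":
        n_ion = int(round(spec.ionized_fraction * n_chains))
        ionized[rng.choice(n_chains, size=n_ion, replace=False)] = True

    labels, positions, bonds = [], [], []
    mol_id, mol_kind = [], {}
    off = np_topo.n_beads
    for c in range(n_chains):
        base = np_topo.positions[anchors[c]]
        nvec = base / np.linalg.norm(base)
        chain_labels = ["P"] * spec.length
        if spec.type in ("ZP", "ZP_pH"):
            chain_labels[-2] = "P+"
            chain_labels[-1] = "P" if ionized[c] else "P-"
        start = off + len(labels)
        for k in range(spec.length):
            labels.append(chain_labels[k])
            positions.append(base + (k + 1) * BOND_L0 * nvec)
            if k == 0:
                bonds.append((anchors[c], start, BOND_KS, BOND_L0))
            else:
                bonds.append((start + k - 1, start + k, BOND_KS, BOND_L0))
            mol_id.append(c + 1)
        mol_kind[c + 1] = KIND_POLYMER

    poly = _fragment(labels, positions, mol_id=np.asarray(mol_id) - 1,
                     mol_kind={m - 1: k for m, k in mol_kind.items()})
    out = merge([np_topo, poly])
    # grafting + chain bonds were indexed globally; append on the merged topology
    chain_bonds = np.array([[b[0], b[1]] for b in bonds], np.int64)
    out.bond_ij = np.vstack([out.bond_ij, chain_bonds])
    out.bond_ks = np.concatenate([out.bond_ks, np.full(len(bonds), BOND_KS)])
    out.bond_l0 = np.concatenate([out.bond_l0, np.full(len(bonds), BOND_L0)])
    return out


# ---------------------------------------------------------------------------
# Bilayer
# ---------------------------------------------------------------------------

LIPID_N_BEADS = 10


def _lipid_labels(variant: str) -> list[str]:
    if variant == KIND_LIPID:
        head = ["LH+", "LH-", "LH", "LH"]
    elif variant == KIND_LIPID_ANIONIC:
        head = ["LH", "LH-", "LH", "LH"]       # +e head bead replaced: net -e
    elif variant == KIND_LIPID_RECEPTOR:
        head = ["RH", "RH", "LH", "LH"]        # uncharged receptor heads
    else:
        raise ValueError(variant)
    return head + ["LT"] * 6


def build_bilayer(nx: int, ny: int, anionic_fraction: float = 0.10,
                  receptor_fraction: float = 0.0,
                  area_per_lipid: float = 1.28,
                  z_center: float = 0.0, seed: int = 0,
                  origin: tuple[float, float] = (0.0, 0.0)) -> Topology:
    """Pre-assembled two-leaflet bilayer of nx x ny lipids per leaflet.

    Lipids sit on a square grid at the requested projected area per lipid,
    heads outward and tails inward; each leaflet receives
    round(fraction * nx * ny) anionic and receptor lipids, assigned by a
    seeded shuffle, so the composition is within one molecule of the target.
    """
    if not (0 <= anionic_fraction <= 1 and 0 <= receptor_fraction <= 1
            and anionic_fraction + receptor_fraction <= 1):
        raise ValueError("composition fractions must lie in [0, 1] and sum <= 1")
    n_leaf = nx * ny
    s = math.sqrt(area_per_lipid)
    rng = np.random.default_rng(seed)

    labels, positions, bonds, angles = [], [], [], []
    mol_id, mol_kind, body = [], {}, []
    mol = 0

    def add_lipid(x, y, leaflet, variant):
        nonlocal mol
        base = len(labels)
        lls = _lipid_labels(variant)
        sgn = 1.0 if leaflet == 0 else -1.0
        # h1..h4 outward->inward, then two tails inward
        zs_head = [3.2, 2.7, 2.2, 1.7]
        zs_tail = [1.2, 0.7, 0.2]
        pos = [(x, y, z_center + sgn * z) for z in zs_head]
        pos += [(x - 0.15, y, z_center + sgn * z) for z in zs_tail]
        pos += [(x + 0.15, y, z_center + sgn * z) for z in zs_tail]
        labels.extend(lls)
        positions.extend(pos)
        b = base
        # heads h1-h2-h3-h4 in a chain; one three-bead tail from h3, the
        # other from h4, with the weak aligning bond across the first tail
        # beads
        chain = [(b, b + 1), (b + 1, b + 2), (b + 2, b + 3),
                 (b + 2, b + 4), (b + 4, b + 5), (b + 5, b + 6),
                 (b + 3, b + 7), (b + 7, b + 8), (b + 8, b + 9)]
        bonds.extend([(i, j, BOND_KS, BOND_L0) for i, j in chain])
        bonds.append((b + 4, b + 7, BOND_KS_WEAK, BOND_L0))
        angles.extend([
            (b + 2, b + 4, b + 5, ANGLE_KA_LIPID),
            (b + 4, b + 5, b + 6, ANGLE_KA_LIPID),
            (b + 3, b + 7, b + 8, ANGLE_KA_LIPID),
            (b + 7, b + 8, b + 9, ANGLE_KA_LIPID),
        ])
        mol_id.extend([mol] * LIPID_N_BEADS)
        mol_kind[mol] = variant
        body.extend([-1] * LIPID_N_BEADS)
        mol += 1

    for leaflet in range(2):
        n_anion = int(round(anionic_fraction * n_leaf))
        n_rec = int(round(receptor_fraction * n_leaf))
        variants = ([KIND_LIPID_ANIONIC] * n_anion + [KIND_LIPID_RECEPTOR] * n_rec
                    + [KIND_LIPID] * (n_leaf - n_anion - n_rec))
        rng.shuffle(variants)
        k = 0
        for ix in range(nx):
            for iy in range(ny):
                jx, jy = rng.normal(0.0, 0.05, 2)
                add_lipid(origin[0] + (ix + 0.5) * s + jx,
                          origin[1] + (iy + 0.5) * s + jy,
                          leaflet, variants[k])
                k += 1

    return _fragment(labels, positions, body=body, mol_id=mol_id,
                     mol_kind=mol_kind, bonds=bonds, angles=angles)


# ---------------------------------------------------------------------------
# Protein
# ---------------------------------------------------------------------------

def _saw_coords(n: int, l0: float, rng: np.random.Generator,
                start: np.ndarray) -> np.ndarray:
    """Self-avoiding-ish random walk with step l0 (retry on close contacts)."""
    pos = np.empty((n, 3))
    pos[0] = start
    for i in range(1, n):
        for _ in range(50):
            step = rng.normal(size=3)
            step *= l0 / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) > 0.7 * l0:
                pos[i] = cand
                break
        else:
            pos[i] = cand
    return pos


def sequence_from_pdb(path, chain_id: str | None = None) -> tuple[str, np.ndarray]:
    """One-letter sequence and C-alpha coordinates (nm) of one chain of a PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    if chain_id is None:
        chain_id = str(arr.chain_id[0])
    ca = arr[(arr.chain_id == chain_id) & (arr.atom_name == "CA")]
    seq = []
    for res3 in ca.res_name:
        if res3 not in THREE_TO_ONE:
            raise ValueError(f"unknown residue code {res3!r} in chain {chain_id}")
        seq.append(THREE_TO_ONE[res3])
    return "".join(seq), ca.coord / 10.0   # A -> nm


def coarse_grain_protein(spec: ProteinSpec | str, coords: np.ndarray | None = None,
                         seed: int = 0, start=(0.0, 0.0, 0.0),
                         residue_map: dict[str, str] | None = None) -> Topology:
    """One bead per residue with the declared philicity/charge mapping.

    Accepts a :class:`ProteinSpec` (or a plain sequence string); explicit
    C-alpha coordinates are rescaled so consecutive beads sit at the bond rest
    length, otherwise a seeded self-avoiding random walk supplies the initial
    conformation.  The chain uses stiff backbone bonds and a weak straightening
    angle at every interior bead.
    """
    if isinstance(spec, str):
        spec = ProteinSpec(sequence=spec)
    rmap = residue_map or RESIDUE_MAP
    labels = []
    for pos_i, r in enumerate(spec.sequence):
        if r not in rmap:
            raise ValueError(f"unknown residue code {r!r} at position {pos_i}")
        labels.append(rmap[r])
    n = len(labels)
    if n == 0:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(seed)
    if coords is not None:
        coords = np.asarray(coords, float)
        if len(coords) != n:
            raise ValueError("coordinate count does not match sequence length")
        if n > 1:
            mean_step = float(np.mean(np.linalg.norm(np.diff(coords, axis=0), axis=1)))
            coords = coords * (BOND_L0 / mean_step)
        coords = coords - coords.mean(axis=0) + np.asarray(start, float)
    else:
        coords = _saw_coords(n, BOND_L0, rng, np.asarray(start, float))
    bonds = [(i, i + 1, spec.bond_ks, BOND_L0) for i in range(n - 1)]
    angles = [(i, i + 1, i + 2, spec.angle_ka) for i in range(n - 2)]
    return _fragment(labels, coords, mol_id=np.zeros(n, np.int64),
                     mol_kind={0: KIND_PROTEIN}, bonds=bonds, angles=angles)


def synthetic_protein_sequence(n_residues: int, hydrophobic_fraction: float = 0.3,
                               charged_fraction: float = 0.2, net_charge: int = -2,
                               seed: int = 0) -> str:
    """Synthetic residue string with a controlled hydrophobic/charged pattern.

    Stand-in for a real serum-protein sequence in offline tests: the exact
    counts are n_h = round(f_h n) hydrophobic (A), and the charged residues
    split so that (#K) - (#D) equals ``net_charge`` within the charged budget.
    """
    n_h = int(round(hydrophobic_fraction * n_residues))
    n_c = int(round(charged_fraction * n_residues))
    n_pos = max(0, (n_c + net_charge) // 2)
    n_neg = n_c - n_pos
    n_0 = n_residues - n_h - n_c
    if n_0 < 0:
        raise ValueError("fractions exceed 1")
    seq = list("A" * n_h + "K" * n_pos + "D" * n_neg + "S" * n_0)
    rng = np.random.default_rng(seed)
    rng.shuffle(seq)
    return "".join(seq)


# ---------------------------------------------------------------------------
# Antibody
# ---------------------------------------------------------------------------

def build_antibody(spec: AntibodySpec) -> Topology:
    """Rigid hydrophilic cylinder (axis +z, base at the origin) on the fcc spacing."""
    a = spec.lattice_constant
    sites = fcc_sites(max(spec.length, 2 * spec.radius) + a, a)
    keep = (sites[:, 2] >= -1e-9) & (sites[:, 2] <= spec.length + 1e-9) & \
           (sites[:, 0] ** 2 + sites[:, 1] ** 2 <= spec.radius ** 2 + 1e-9)
    pts = sites[keep]
    order = np.lexsort((pts[:, 0], pts[:, 1], pts[:, 2]))
    pts = pts[order]
    n = len(pts)
    return _fragment(["AB"] * n, pts, body=np.zeros(n, np.int64),
                     mol_id=np.zeros(n, np.int64), mol_kind={0: KIND_ANTIBODY})


def decorate_antibodies(np_topo: Topology, np_spec: NanoparticleSpec,
                        spec: AntibodySpec) -> Topology:
    """Attach rigid antibody cylinders at maximally separated surface points.

    The antibodies are merged into the nanoparticle's rigid body (the
    decorations are fixed on the surface), oriented along the outward normal.
    Six antibodies use the octahedral +-x, +-y, +-z directions; other counts
    fall back to a Fibonacci point set.
    """
    if spec.count == 6:
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                         [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
    else:
        dirs = fibonacci_sphere(spec.count)
    R = np_spec.diameter / 2.0
    ab = build_antibody(spec)
    frags = [np_topo]
    for dvec in dirs:
        # rotate +z onto dvec
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, dvec)
        c = float(np.dot(z, dvec))
        if np.linalg.norm(v) < 1e-12:
            rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
        pts = ab.positions @ rot.T + dvec * R
        frag = Topology(
            classes=ab.classes, type_index=ab.type_index.copy(),
            positions=pts, charge=ab.charge.copy(),
            body_id=ab.body_id.copy(), mol_id=ab.mol_id.copy(),
            mol_kind=dict(ab.mol_kind),
            bond_ij=ab.bond_ij.copy(), bond_ks=ab.bond_ks.copy(),
            bond_l0=ab.bond_l0.copy(), angle_ijk=ab.angle_ijk.copy(),
            angle_ka=ab.angle_ka.copy())
        frags.append(frag)
    out = merge(frags)
    # fuse all rigid pieces into the nanoparticle's body
    out.body_id[out.body_id >= 0] = 0
    return out


# ---------------------------------------------------------------------------
# Solvation
# ---------------------------------------------------------------------------

def solvate_and_neutralize(box, topology: Topology | None = None,
                           density: float = WATER_DENSITY,
                           molarity: float = 0.10, seed: int = 0,
                           clearance: float = 0.4) -> Topology:
    """Fill the box with water to total bead density 3/r_c^3, add salt, neutralize.

    Monovalent ion pairs are added at the requested molarity (r_c = 1 nm
    mapping), plus counterions matching the solute's net charge, by
    relabeling randomly chosen water beads; the final system charge is
    exactly zero.  Solvent positions avoid existing beads by ``clearance``
    (soft potentials tolerate mild overlap; dense rigid cores do not).
    """
    box = np.asarray(box, float)
    volume = float(np.prod(box))
    n_total = int(round(density * volume))
    n_existing = topology.n_beads if topology is not None else 0
    n_water = n_total - n_existing
    if n_water < 0.1 * n_total:
        raise ValueError("solute occupies more than 90% of the box bead budget")
    rng = np.random.default_rng(seed)

    if topology is not None and topology.n_beads:
        from scipy.spatial import cKDTree
        wrapped = topology.positions - box * np.floor(topology.positions / box)
        tree = cKDTree(wrapped, boxsize=box)
        placed = np.empty((n_water, 3))
        m = 0
        while m < n_water:
            cand = rng.uniform(0.0, 1.0, size=(2 * (n_water - m) + 16, 3)) * box
            d, _ = tree.query(cand, k=1)
            good = cand[d > clearance]
            take = min(len(good), n_water - m)
            placed[m:m + take] = good[:take]
            m += take
        water_pos = placed
    else:
        water_pos = rng.uniform(0.0, 1.0, size=(n_water, 3)) * box

    n_pairs = int(round(molarity * AVOGADRO_PER_NM3 * volume))
    solute_q = int(round(topology.net_charge())) if topology is not None else 0
    n_plus = n_pairs + max(0, -solute_q)
    n_minus = n_pairs + max(0, solute_q)
    if n_plus + n_minus > n_water:
        raise ValueError("not enough solvent beads to carry the requested ions")

    labels = ["ION+"] * n_plus + ["ION-"] * n_minus + ["W"] * (n_water - n_plus - n_minus)
    order = rng.permutation(n_water)
    labels = [labels[i] for i in np.argsort(order, kind="stable")]
    mol_ids = np.arange(n_water, dtype=np.int64)
    mol_kind = {int(i): (KIND_ION if labels[i] != "W" else KIND_WATER)
                for i in range(n_water)}
    solvent = _fragment(labels, water_pos, mol_id=mol_ids, mol_kind=mol_kind)
    full = merge([topology, solvent]) if topology is not None else solvent
    assert abs(full.net_charge()) < 1e-9
    return full


# ---------------------------------------------------------------------------
# Fixture registry (synthetic-data generator)
# ---------------------------------------------------------------------------

FIXTURES = ("pure_fluid", "mini_bilayer", "toy_protein", "mini_np_membrane",
            "two_charges")


def make_fixture(name: str, seed: int = 0, **overrides):
    """Small, fast named scenarios for offline testing of every stage.

    pure_fluid        3000 water beads in a 10x10x10 box (thermostat checks)
    mini_bilayer      nx*ny*2 lipids (default 200) in solvent, tension control
    toy_protein       synthetic-sequence chain in solvent
    mini_np_membrane  4-nm nanoparticle over a 20x20 r_c membrane patch
    two_charges       a +e/-e pair in a small box (electrostatics oracle)
    """
    from .pipeline import Scenario

    if name == "pure_fluid":
        return Scenario(name=name, box=(10.0, 10.0, 10.0), seed=seed,
                        components={"solvent": {"molarity": 0.0}},
                        n_steps=overrides.pop("n_steps", 10_000),
                        tension_control=False,
                        measure_every=overrides.pop("measure_every", 100),
                        scale="desk", **overrides)
    if name == "mini_bilayer":
        nx = overrides.pop("nx", 10)
        ny = overrides.pop("ny", 10)
        apl = overrides.pop("area_per_lipid", 1.28)
        lz = overrides.pop("lz", 12.0)
        side = math.sqrt(apl)
        return Scenario(
            name=name, box=(nx * side, ny * side, lz), seed=seed,
            components={
                "membrane": {"nx": nx, "ny": ny, "anionic_fraction": 0.0,
                             "receptor_fraction": 0.0, "area_per_lipid": apl},
                "solvent": {"molarity": 0.0},
            },
            n_steps=overrides.pop("n_steps", 20_000), tension_control=True,
            measure_every=overrides.pop("measure_every", 200),
            scale="desk", **overrides)
    if name == "toy_protein":
        n_res = overrides.pop("n_residues", 30)
        fh = overrides.pop("hydrophobic_fraction", 0.3)
        return Scenario(
            name=name, box=(8.0, 8.0, 8.0), seed=seed,
            components={
                "proteins": {"count": 1, "n_residues": n_res,
                             "hydrophobic_fraction": fh},
                "solvent": {"molarity": 0.1},
            },
            n_steps=overrides.pop("n_steps", 2_000), tension_control=False,
            measure_every=overrides.pop("measure_every", 100),
            scale="desk", **overrides)
    if name == "mini_np_membrane":
        return Scenario(
            name=name, box=(20.0, 20.0, 24.0), seed=seed,
            components={
                "nanoparticle": {"diameter": 4.0, "surface": "hydrophobic",
                                 "z_offset": 6.0},
                "membrane": {"nx": 17, "ny": 17, "anionic_fraction": 0.1,
                             "receptor_fraction": 0.0, "area_per_lipid": 1.38},
                "solvent": {"molarity": 0.0},
            },
            n_steps=overrides.pop("n_steps", 20_000), tension_control=False,
            measure_every=overrides.pop("measure_every", 200),
            scale="desk", **overrides)
    if name == "two_charges":
        return Scenario(
            name=name, box=(6.0, 6.0, 6.0), seed=seed,
            components={"charges": {"separation": overrides.pop("separation", 1.0)}},
            n_steps=overrides.pop("n_steps", 0), tension_control=False,
            measure_every=1, scale="desk", **overrides)
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
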