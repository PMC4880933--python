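"""Scenario configuration, system assembly, run drivers and trajectory I/O.

A :class:`Scenario` declaratively describes one in-silico experiment
(components, geometry, protocol, seed); :func:`build_system` assembles the
topology, :func:`run_scenario` chains builders -> engine -> observables and
writes measurements, trajectory, log and checkpoint;
:func:`scan_phase_diagram` drives the resist/target decoration scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import builders, observables
from .builders import (
    AntibodySpec, NanoparticleSpec, PolymerSpec, ProteinSpec,
    build_bilayer, build_nanoparticle, coarse_grain_protein,
    decorate_antibodies, graft_polymers, sequence_from_pdb,
    solvate_and_neutralize, synthetic_protein_sequence,
)
from .engine import DPDEngine, SystemState, TensionController
from .forcefield import ForceField, default_forcefield
from .topology import (
    KIND_ION, KIND_LIPID, KIND_NP_CORE, KIND_PROTEIN, KIND_WATER,
    MEMBRANE_KINDS, NP_COMPLEX_KINDS, Topology, merge, remove_molecules,
)

log = logging.getLogger("dpdcoat")

SCENARIO_SCHEMA_VERSION = 1
FULL_BOX = (75.0, 75.0, 40.0)   # production box, r_c


@dataclass(frozen=True)
class UnitMap:
    """Reduced-to-SI mapping; all nm/ns in reports derive from it."""

    r_c_nm: float = 1.0
    tau_ns: float = 2.4
    kBT: float = 1.0


@dataclass
class Scenario:
    """Declarative description of one experiment."""

    name: str
    box: tuple[float, float, float]
    components: dict
    n_steps: int = 10_000
    tension_control: bool = False
    measure_every: int = 100
    seed: int = 0
    scale: str = "desk"            # full | desk
    outputs: tuple[str, ...] = ("measurements", "trajectory", "checkpoint")
    area_per_lipid: float = 1.28
    dt: float = 0.015

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("full", "desk"):
            raise ValueError(f"scenario.scale must be full|desk, got {self.scale!r}")
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValueError("scenario.box must be three positive lengths")
        if self.n_steps < 0 or self.measure_every <= 0 or self.dt <= 0:
            raise ValueError("invalid protocol numbers")
        known = {"nanoparticle", "polymers", "antibodies", "membrane",
                 "proteins", "solvent", "charges"}
        for key in self.components:
            if key not in known:
                raise ValueError(f"unknown component {key!r} (known: {sorted(known)})")
        if "polymers" in self.components and "nanoparticle" not in self.components:
            raise ValueError("polymers require a nanoparticle")

    def to_yaml(self, path) -> None:
        doc = {"schema_version": SCENARIO_SCHEMA_VERSION, **asdict(self)}
        doc["box"] = list(self.box)
        doc["outputs"] = list(self.outputs)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        ver = doc.pop("schema_version", None)
        if ver != SCENARIO_SCHEMA_VERSION:
            raise ValueError(f"unsupported scenario schema {ver!r}")
        doc["box"] = tuple(doc["box"])
        doc["outputs"] = tuple(doc.get("outputs", ("measurements",)))
        return cls(**doc)


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

def _translated(topo: Topology, offset) -> Topology:
    topo.positions = topo.positions + np.asarray(offset, float)
    return topo


def build_system(scenario: Scenario, seed: int | None = None) -> Topology:
    """Assemble the full topology described by a scenario's component block."""
    seed = scenario.seed if seed is None else seed
    box = np.asarray(scenario.box, float)
    comp = scenario.components
    frags: list[Topology] = []
    center = box / 2.0

    membrane_z = None
    if "membrane" in comp:
        m = dict(comp["membrane"])
        membrane_z = m.pop("z_center", box[2] / 2.0)
        apl = m.pop("area_per_lipid", scenario.area_per_lipid)
        mem = build_bilayer(area_per_lipid=apl, z_center=membrane_z,
                            seed=seed + 11, **m)
        frags.append(mem)

    if "nanoparticle" in comp:
        npd = dict(comp["nanoparticle"])
        z_off = npd.pop("z_offset", 0.0)
        np_spec = NanoparticleSpec(
            diameter=npd.get("diameter", 6.0),
            surface=npd.get("surface", "hydrophobic"),
            surface_charge_density=npd.get("charge_density", 0.2))
        np_topo = build_nanoparticle(np_spec, seed=seed + 1)
        if "polymers" in comp:
            p = comp["polymers"]
            pspec = PolymerSpec(type=p.get("type", "HP"),
                                length=p.get("length", 8),
                                density=p.get("density", 0.8),
                                ionized_fraction=p.get("ionized_fraction", 1 / 3))
            np_topo = graft_polymers(np_topo, np_spec, pspec, seed=seed + 2)
        if "antibodies" in comp:
            ab = comp["antibodies"]
            np_topo = decorate_antibodies(np_topo, np_spec,
                                          AntibodySpec(count=ab.get("count", 6)))
        z_np = (membrane_z if membrane_z is not None else center[2]) + z_off
        np_topo = _translated(np_topo, (center[0], center[1], z_np))
        if frags and membrane_z is not None:
            # carve out lipids overlapping the decorated particle: a lipid
            # bead inside the dense rigid core would blow the patch apart
            from scipy.spatial import cKDTree
            mem = frags[0]
            wrapped_np = np_topo.positions - box * np.floor(np_topo.positions / box)
            wrapped_mem = mem.positions - box * np.floor(mem.positions / box)
            tree = cKDTree(wrapped_np, boxsize=box)
            dmin, _ = tree.query(wrapped_mem, k=1)
            clash_mols = sorted(set(mem.mol_id[dmin < 0.45]))
            if clash_mols:
                frags[0] = remove_molecules(mem, clash_mols)
        frags.append(np_topo)

    if "proteins" in comp:
        p = dict(comp["proteins"])
        count = p.get("count", 1)
        rng = np.random.default_rng(seed + 3)
        for k in range(count):
            if "pdb" in p:
                seq, coords = sequence_from_pdb(p["pdb"], p.get("chain"))
            else:
                seq = p.get("sequence") or synthetic_protein_sequence(
                    p.get("n_residues", 30),
                    p.get("hydrophobic_fraction", 0.3),
                    p.get("charged_fraction", 0.2),
                    p.get("net_charge", -2), seed=seed + 4 + k)
                coords = None
            if "distance_from_np" in p and "nanoparticle" in comp:
                # controlled placement at a set distance from the particle
                # center (seeded random direction) for contact/residence runs
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                np_center = np.array([center[0], center[1],
                                      (membrane_z if membrane_z is not None
                                       else center[2])
                                      + comp["nanoparticle"].get("z_offset", 0.0)])
                start = np_center + p["distance_from_np"] * u
            else:
                start = rng.uniform(0.25, 0.75, 3) * box
                if "nanoparticle" in comp:
                    # keep random placements off the nanoparticle
                    while np.linalg.norm(start - center) < comp["nanoparticle"].get(
                            "diameter", 6.0) / 2.0 + 2.0:
                        start = rng.uniform(0.2, 0.8, 3) * box
            frags.append(coarse_grain_protein(ProteinSpec(sequence=seq),
                                              coords=coords, seed=seed + 40 + k,
                                              start=start))

    if "charges" in comp:
        sep = comp["charges"].get("separation", 1.0)
        pair = builders._fragment(
            ["ION+", "ION-"],
            [center - [sep / 2, 0, 0], center + [sep / 2, 0, 0]],
            mol_id=[0, 1], mol_kind={0: KIND_ION, 1: KIND_ION})
        frags.append(pair)

    solute = merge(frags) if frags else None
    if "solvent" in comp:
        s = comp["solvent"]
        return solvate_and_neutralize(box, solute,
                                      molarity=s.get("molarity", 0.10),
                                      seed=seed + 7)
    if solute is None:
        raise ValueError("scenario has no components")
    return solute


def make_engine(scenario: Scenario, topology: Topology | None = None,
                ff: ForceField | None = None, seed: int | None = None) -> DPDEngine:
    """Build the engine (topology + force field + tension controller) for a scenario."""
    seed = scenario.seed if seed is None else seed
    topo = topology if topology is not None else build_system(scenario, seed)
    ff = ff or default_forcefield(topo.classes)
    tension = TensionController(A0=scenario.area_per_lipid) \
        if scenario.tension_control else None
    return DPDEngine(topo, ff, seed=seed, dt=scenario.dt, tension=tension,
                     box=np.asarray(scenario.box, float))


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    positions: np.ndarray
    box: np.ndarray
    time: float
    species: list[str]


def write_trajectory(frames: list[Frame], path, fmt: str = "xyz") -> None:
    """Write frames as extended XYZ (text) or an HDF5 container (lossless)."""
    if fmt == "xyz":
        with open(path, "w") as fh:
            for fr in frames:
                fh.write(f"{len(fr.positions)}\n")
                b = fr.box
                fh.write(
                    f'Lattice="{b[0]:.6f} 0.0 0.0 0.0 {b[1]:.6f} 0.0 0.0 0.0 '
                    f'{b[2]:.6f}" Properties=species:S:1:pos:R:3 '
                    f"Time={fr.time:.6f}\n")
                for sp, p in zip(fr.species, fr.positions):
                    fh.write(f"{sp:<5s} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}\n")
    elif fmt == "h5":
        with h5py.File(path, "w") as h5:
            for i, fr in enumerate(frames):
                g = h5.create_group(f"frame/{i:06d}")
                g.create_dataset("positions", data=fr.positions)
                g.create_dataset("box", data=fr.box)
                g.attrs["time"] = fr.time
                g.create_dataset("species",
                                 data=np.array(fr.species, dtype="S8"))
    else:
        raise ValueError(f"unknown trajectory format {fmt!r} (xyz|h5)")


def read_trajectory(path, fmt: str = "xyz") -> list[Frame]:
    """Read frames back; a truncated text file yields the complete frames plus
    a warning rather than an error."""
    frames: list[Frame] = []
    if fmt == "xyz":
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            try:
                n = int(lines[i].strip())
                comment = lines[i + 1]
                rows = lines[i + 2:i + 2 + n]
                if len(rows) < n:
                    raise IndexError
            except (ValueError, IndexError):
                log.warning("read_trajectory: truncated file after %d frames",
                            len(frames))
                break
            lat = comment.split('Lattice="')[1].split('"')[0].split()
            box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
            t = float(comment.split("Time=")[1].split()[0]) \
                if "Time=" in comment else 0.0
            species, pos = [], []
            for row in rows:
                parts = row.split()
                species.append(parts[0])
                pos.append([float(x) for x in parts[1:4]])
            frames.append(Frame(np.array(pos), box, t, species))
            i += 2 + n
    elif fmt == "h5":
        with h5py.File(path, "r") as h5:
            for key in sorted(h5["frame"]):
                g = h5[f"frame/{key}"]
                frames.append(Frame(g["positions"][...], g["box"][...],
                                    float(g.attrs["time"]),
                                    [s.decode() for s in g["species"][...]]))
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    return frames


# ---------------------------------------------------------------------------
# Run driver
# ---------------------------------------------------------------------------

def run_scenario(scenario: Scenario | str | Path, outdir,
                 seed: int | None = None) -> dict:
    """Build and run one scenario, writing measurements, trajectory, log, checkpoint.

    Measurement channels recorded every ``measure_every`` steps: temperature,
    potential energy; plus membrane tension, nanoparticle-membrane distance d
    and the protein adsorption count whenever the relevant components are
    present.  Returns a dict with the engine, the measurement series and the
    initial frame (for Delta-E bookkeeping).
    """
    if not isinstance(scenario, Scenario):
        scenario = Scenario.from_yaml(scenario)
    seed = scenario.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    topo = build_system(scenario, seed)
    engine = make_engine(scenario, topology=topo, seed=seed)
    unit = UnitMap()

    logpath = outdir / "run.log"
    with open(logpath, "w") as fh:
        fh.write(f"scenario={scenario.name} schema={SCENARIO_SCHEMA_VERSION} "
                 f"seed={seed} n_beads={topo.n_beads} "
                 f"r_c_nm={unit.r_c_nm} tau_ns={unit.tau_ns}\n")

    np_core = topo.beads_of_kind(KIND_NP_CORE)
    tails = np.array([b for b in topo.beads_of_kind(*MEMBRANE_KINDS)
                      if topo.label_of(b) == "LT"], np.int64)
    protein_groups = topo.molecules_of_kind(KIND_PROTEIN)
    np_complex = topo.beads_of_kind(*NP_COMPLEX_KINDS)
    initial_frame = (engine.state.positions.copy(), engine.state.box.copy())

    times, temps, pots, tensions, dists, ads = [], [], [], [], [], []
    frames: list[Frame] = []
    species = [topo.label_of(i) for i in range(topo.n_beads)]
    flag_history = []

    def observer(eng: DPDEngine):
        st = eng.state
        times.append(st.time)
        temps.append(eng.kinetic_temperature())
        pots.append(eng.energies["potential"])
        if len(tails):
            g, _ = observables.surface_tension(eng.pressure_tensor()[None],
                                               st.box[2])
            tensions.append(g)
        if len(tails) and len(np_core):
            try:
                dists.append(observables.membrane_distance(
                    st.positions, st.box, np_core, tails))
            except observables.MembraneFragmented:
                dists.append(float("nan"))
        if protein_groups and len(np_complex):
            pconf = scenario.components.get("proteins", {})
            ref = np_core if pconf.get("contact_reference") == "core" \
                else np_complex
            flags = observables.adsorption_flags(
                st.positions, st.box, protein_groups, ref,
                cutoff=pconf.get("contact_cutoff", observables.CONTACT_CUTOFF),
                min_contacts=pconf.get("min_contacts", observables.MIN_CONTACTS))
            flag_history.append(flags)
            ads.append(int(flags.sum()))
        if "trajectory" in scenario.outputs and len(frames) < 500:
            frames.append(Frame(st.positions.copy(), st.box.copy(),
                                st.time, species))

    engine.run(scenario.n_steps, observer=observer,
               observe_every=scenario.measure_every)

    channels = {"temperature": np.array(temps), "potential": np.array(pots)}
    units = {"temperature": "kBT", "potential": "kBT"}
    if tensions:
        channels["tension"] = np.array(tensions)
        units["tension"] = "kBT/r_c^2"
    if dists:
        channels["d"] = np.array(dists) * unit.r_c_nm
        units["d"] = "nm"
    if ads:
        channels["adsorption"] = np.array(ads, float)
        units["adsorption"] = "count"
    series = observables.MeasurementSeries(
        time=np.array(times), channels=channels, units=units, seed=seed)

    if "measurements" in scenario.outputs:
        series.to_csv(outdir / "measurements.csv")
    if "trajectory" in scenario.outputs and frames:
        write_trajectory(frames, outdir / "trajectory.xyz", "xyz")
    if "checkpoint" in scenario.outputs:
        engine.save_checkpoint(outdir / "checkpoint.h5")
    with open(logpath, "a") as fh:
        fh.write(f"completed steps={engine.state.step} "
                 f"time_tau={engine.state.time:.2f}\n")

    return {"engine": engine, "series": series, "topology": topo,
            "initial_frame": initial_frame,
            "flag_history": np.array(flag_history) if flag_history else None}


# ---------------------------------------------------------------------------
# Tension-area scan (zero-tension area per lipid)
# ---------------------------------------------------------------------------

def tension_area_scan(areas=(1.10, 1.28, 1.45), nx: int = 10, ny: int = 10,
                      lz: float = 10.0, seed: int = 0,
                      n_equil: int = 4000, n_sample: int = 12_000,
                      sample_every: int = 20) -> dict:
    """Lateral tension of a fixed-area bilayer at each projected area per lipid.

    For each area the nx x ny (x2 leaflets) charge-neutral bilayer is built in
    density-3 solvent at the corresponding box, equilibrated, and the tension
    gamma = Lz [P_zz - (P_xx + P_yy)/2] is window-averaged from the pair
    virial.  Returns the per-area means/standard errors and the area at which
    a linear interpolation of gamma(A) crosses zero.
    """
    areas = sorted(areas)
    means, errs = [], []
    for a_idx, apl in enumerate(areas):
        side = math.sqrt(apl)
        sc = Scenario(
            name=f"tension_scan_A{apl:.3f}",
            box=(nx * side, ny * side, lz),
            components={
                "membrane": {"nx": nx, "ny": ny, "anionic_fraction": 0.0,
                             "receptor_fraction": 0.0, "area_per_lipid": apl},
                "solvent": {"molarity": 0.0},
            },
            n_steps=0, tension_control=False, measure_every=sample_every,
            seed=seed + 1000 * a_idx, outputs=())
        topo = build_system(sc)
        eng = make_engine(sc, topology=topo)
        eng.run(n_equil)
        samples = []

        def grab(e):
            samples.append(e.pressure_tensor())

        eng.run(n_sample, observer=grab, observe_every=sample_every)
        g, se = observables.surface_tension(np.array(samples), lz)
        means.append(g)
        errs.append(se)
        log.info("tension A=%.3f: gamma=%.3f +- %.3f", apl, g, se)
    means = np.array(means)
    a0 = zero_crossing(np.array(areas), means)
    return {"areas": np.array(areas), "tension": means,
            "stderr": np.array(errs), "A0": a0}


def zero_crossing(x: np.ndarray, y: np.ndarray) -> float:
    """Linear-interpolated zero of y(x); falls back to a least-squares line."""
    for k in range(len(x) - 1):
        if y[k] == 0.0:
            return float(x[k])
        if y[k] * y[k + 1] < 0:
            return float(x[k] - y[k] * (x[k + 1] - x[k]) / (y[k + 1] - y[k]))
    slope, icpt = np.polyfit(x, y, 1)
    return float(-icpt / slope)


# ---------------------------------------------------------------------------
# Phase scan
# ---------------------------------------------------------------------------

def resist_scenario(N: int, sigma: float, polymer_type: str = "ZP",
                    surface: str = "hydrophobic", n_steps: int = 4000,
                    n_proteins: int = 3, seed: int = 0,
                    box=(14.0, 14.0, 14.0), diameter: float = 4.0) -> Scenario:
    """Desk-scale protein-adsorption run: coated NP plus proteins in solvent."""
    comp = {
        "nanoparticle": {"diameter": diameter, "surface": surface},
        "proteins": {"count": n_proteins, "n_residues": 24,
                     "hydrophobic_fraction": 0.4},
        "solvent": {"molarity": 0.0 if surface == "hydrophobic" else 0.1},
    }
    if sigma > 0:
        comp["polymers"] = {"type": polymer_type, "length": N, "density": sigma}
    return Scenario(name=f"resist_N{N}_s{sigma}", box=box, components=comp,
                    n_steps=n_steps, measure_every=100, seed=seed,
                    outputs=("measurements",))


def target_scenario(N: int, sigma: float, polymer_type: str = "ZP_pH",
                    surface: str = "positive", n_steps: int = 4000,
                    seed: int = 0, box=(16.0, 16.0, 20.0),
                    diameter: float = 4.0) -> Scenario:
    """Desk-scale targeting run: decorated NP over a receptor-bearing membrane."""
    comp = {
        "nanoparticle": {"diameter": diameter, "surface": surface,
                         "z_offset": diameter / 2.0 + 0.6 * N + 2.0},
        "antibodies": {"count": 6},
        "membrane": {"nx": 13, "ny": 13, "anionic_fraction": 0.1,
                     "receptor_fraction": 0.2,
                     "area_per_lipid": 16.0 * 16.0 / 169.0},
        "solvent": {"molarity": 0.05},
    }
    if sigma > 0:
        comp["polymers"] = {"type": polymer_type, "length": N, "density": sigma}
    return Scenario(name=f"target_N{N}_s{sigma}", box=box, components=comp,
                    n_steps=n_steps, measure_every=100, seed=seed,
                    outputs=("measurements",))


def antibody_receptor_contact(topo: Topology, positions: np.ndarray,
                              box: np.ndarray, cutoff: float = 1.0) -> bool:
    """True when any antibody bead is within the soft-LJ range of a receptor head."""
    from scipy.spatial import cKDTree
    ab = np.array([i for i in range(topo.n_beads)
                   if topo.classes[topo.type_index[i]].is_antibody], np.int64)
    rec = np.array([i for i in range(topo.n_beads)
                    if topo.classes[topo.type_index[i]].is_receptor_head], np.int64)
    if not len(ab) or not len(rec):
        return False
    wrapped = positions - box * np.floor(positions / box)
    tree = cKDTree(wrapped[rec], boxsize=box)
    d, _ = tree.query(wrapped[ab], k=1)
    return bool(np.min(d) < cutoff)


def scan_phase_diagram(N_list, sigma_list, polymer_type: str = "ZP",
                       seed: int = 0, n_steps: int = 4000,
                       workdir=None, replicates: int = 1,
                       resist_threshold: float = 0.5,
                       target_delta_e: float = -20.0) -> list:
    """Run one resist and one target scenario per (N, sigma) grid cell.

    Returns the classified :class:`~dpdcoat.observables.PhaseCell` list.
    Cells whose runs fail are marked undetermined rather than interpolated.
    """
    import tempfile
    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="scan_"))
    results: dict[tuple[int, float], dict] = {}
    for N in N_list:
        for sigma in sigma_list:
            cell: dict = {}
            counts = []
            for rep in range(replicates):
                try:
                    sc = resist_scenario(N, sigma, polymer_type,
                                         n_steps=n_steps, seed=seed + 101 * rep)
                    out = run_scenario(sc, workdir / f"r_N{N}_s{sigma}_{rep}")
                    counts.append(observables.persistent_adsorption_count(
                        out["series"].time, out["flag_history"]))
                except Exception as exc:   # failed cell -> undetermined
                    log.warning("resist cell (N=%s, sigma=%s) failed: %s",
                                N, sigma, exc)
            if counts:
                cell["adsorption"] = float(np.mean(counts))
            try:
                sc = target_scenario(N, sigma, n_steps=n_steps, seed=seed)
                out = run_scenario(sc, workdir / f"t_N{N}_s{sigma}")
                topo = out["topology"]
                eng = out["engine"]
                cell["contact"] = antibody_receptor_contact(
                    topo, eng.state.positions, eng.state.box)
                cell["delta_e"] = observables.interaction_energy_delta(
                    topo, eng.ff, out["initial_frame"],
                    (eng.state.positions, eng.state.box))
            except Exception as exc:
                log.warning("target cell (N=%s, sigma=%s) failed: %s",
                            N, sigma, exc)
            results[(N, sigma)] = cell
    return observables.classify_phase(results, resist_threshold, target_delta_e)


# ---------------------------------------------------------------------------
# Named production scenarios (full scale, cluster budget) and desk twins
# ---------------------------------------------------------------------------

def named_scenarios() -> dict[str, Scenario]:
    """Every published-figure experiment as a full-scale config plus a desk twin.

    Full-scale entries mirror the production geometry (75x75x40 r_c box,
    6/10 nm particles, 0.10 M salt, 10 proteins); desk twins use a 20x20 r_c
    membrane patch, a 4-6 nm particle and 1-3 proteins, sized for property
    tests and non-quantitative where the geometry differs.
    """
    out: dict[str, Scenario] = {}

    def full(name, comp, tension=True, n_steps=2_000_000):
        out[name] = Scenario(name=name, box=FULL_BOX, components=comp,
                             n_steps=n_steps, tension_control=tension,
                             measure_every=1000, scale="full")

    def desk(name, comp, box=(20.0, 20.0, 24.0), tension=False, n_steps=20_000):
        out[name] = Scenario(name=name, box=box, components=comp,
                             n_steps=n_steps, tension_control=tension,
                             measure_every=200, scale="desk")

    membrane_full = {"nx": 66, "ny": 66, "anionic_fraction": 0.10,
                     "receptor_fraction": 0.0, "area_per_lipid": 1.28}
    membrane_desk = {"nx": 17, "ny": 17, "anionic_fraction": 0.10,
                     "receptor_fraction": 0.0, "area_per_lipid": 1.38}

    # protein-adsorption studies (Fig. 2/3 conditions)
    for surface, dia, tag in (("hydrophobic", 6.0, "phob6"),
                              ("hydrophobic", 10.0, "phob10"),
                              ("positive", 10.0, "pos10")):
        for ptype in ("HP", "ZP"):
            for N in (4, 8, 16, 32):
                for sigma in (0.2, 0.4, 0.8, 1.6):
                    comp = {
                        "nanoparticle": {"diameter": dia, "surface": surface},
                        "polymers": {"type": ptype, "length": N, "density": sigma},
                        "proteins": {"count": 10, "pdb": "1ao6.pdb"},
                        "solvent": {"molarity": 0.10},
                    }
                    full(f"adsorption_{tag}_{ptype}_N{N}_s{sigma}", comp,
                         tension=False)

    # membrane-interaction studies (Fig. 4-6 / Table 1 conditions)
    table1 = [
        ("hydrophobic", 6.0, None, None, False),
        ("hydrophobic", 6.0, "HP", 8, False),
        ("hydrophobic", 6.0, "HP", 8, True),
        ("hydrophobic", 6.0, "ZP", 8, False),
        ("hydrophobic", 6.0, "ZP", 8, True),
        ("negative", 10.0, None, None, False),
        ("negative", 10.0, "HP", 16, False),
        ("negative", 10.0, "ZP", 16, False),
        ("positive", 10.0, None, None, False),
        ("positive", 10.0, "HP", 16, False),
        ("positive", 10.0, "HP", 16, True),
        ("positive", 10.0, "ZP", 16, False),
        ("positive", 10.0, "ZP", 16, True),
        ("positive", 10.0, "ZP_pH", 16, False),
        ("positive", 10.0, "ZP_pH", 16, True),
    ]
    for surface, dia, ptype, N, antibody in table1:
        comp = {
            "nanoparticle": {"diameter": dia, "surface": surface,
                             "z_offset": dia / 2.0 + (0.5 * (N or 0)) + 4.0},
            "membrane": dict(membrane_full),
            "solvent": {"molarity": 0.10},
        }
        if ptype:
            comp["polymers"] = {"type": ptype, "length": N, "density": 0.8}
        if antibody:
            comp["antibodies"] = {"count": 6}
            comp["membrane"]["receptor_fraction"] = 0.1
        tag = f"{surface}{int(dia)}_{ptype or 'bare'}" + ("_ab" if antibody else "")
        full(f"membrane_{tag}", comp)
        desk_comp = {
            "nanoparticle": {"diameter": min(dia, 6.0), "surface": surface,
                             "z_offset": min(dia, 6.0) / 2.0 + 3.0},
            "membrane": dict(membrane_desk),
            "solvent": {"molarity": 0.05},
        }
        if ptype:
            desk_comp["polymers"] = {"type": ptype, "length": min(N, 8),
                                     "density": 0.8}
        if antibody:
            desk_comp["antibodies"] = {"count": 6}
            desk_comp["membrane"]["receptor_fraction"] = 0.2
        desk(f"membrane_{tag}_desk", desk_comp)

    # zero-tension membrane reference (Methods conditions)
    full("bilayer_zero_tension",
         {"membrane": dict(membrane_full), "solvent": {"molarity": 0.0}},
         n_steps=500_000)
    desk("bilayer_zero_tension_desk",
         {"membrane": {"nx": 10, "ny": 10, "anionic_fraction": 0.0,
                       "receptor_fraction": 0.0, "area_per_lipid": 1.28},
          "solvent": {"molarity": 0.0}},
         box=(11.3137085, 11.3137085, 12.0), tension=True)
    return out


def export_scenarios(outdir) -> list[Path]:
    """Write every named scenario to YAML under ``outdir`` (configs only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, sc in named_scenarios().items():
        p = outdir / f"{name}.yaml"
        sc.to_yaml(p)
        paths.append(p)
    return paths
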