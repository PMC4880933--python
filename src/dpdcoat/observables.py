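"""Measured quantities: protein adsorption number, nanoparticle-membrane
distance d, interaction energy change Delta E, membrane surface tension, and
the resist/target phase classification.

Distances are reported in nm via the r_c = 1 nm mapping; energies in kBT;
tension in kBT/r_c^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .engine import selected_potential_energy
from .forcefield import ForceField
from .topology import MEMBRANE_KINDS, NP_COMPLEX_KINDS, Topology

log = logging.getLogger("dpdcoat")

# adsorption definition (configurable): a protein is adsorbed when at least
# MIN_CONTACTS of its beads lie within CONTACT_CUTOFF of any bead of the
# nanoparticle complex, persisting for PERSISTENCE_TAU of simulated time.
CONTACT_CUTOFF = 1.0      # r_c
MIN_CONTACTS = 5
PERSISTENCE_TAU = 100.0   # tau


class MembraneFragmented(RuntimeError):
    """The bilayer no longer forms a single slab; d is undefined."""


@dataclass
class MeasurementSeries:
    """Time series of named measurement channels from one replicate."""

    time: np.ndarray
    channels: dict[str, np.ndarray]
    units: dict[str, str]
    replicate: int = 0
    seed: int = 0

    def __post_init__(self):
        n = len(self.time)
        for name, ch in self.channels.items():
            if len(ch) != n:
                raise ValueError(f"channel {name!r} does not share the time grid")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (time, channel, replicate)."""
        rows = []
        for name, ch in self.channels.items():
            rows.append(pd.DataFrame({
                "time_tau": self.time, "channel": name, "value": ch,
                "unit": self.units.get(name, ""), "replicate": self.replicate,
                "seed": self.seed,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PhaseCell:
    """One cell of the resist/target phase diagram."""

    N: int
    sigma: float
    resist: bool | None
    target: bool | None

    @property
    def undetermined(self) -> bool:
        return self.resist is None or self.target is None


# ---------------------------------------------------------------------------
# Adsorption
# ---------------------------------------------------------------------------

def adsorption_flags(positions: np.ndarray, box: np.ndarray,
                     protein_groups: list[np.ndarray], np_beads: np.ndarray,
                     cutoff: float = CONTACT_CUTOFF,
                     min_contacts: int = MIN_CONTACTS) -> np.ndarray:
    """Per-protein boolean contact flags for one frame (minimum-image)."""
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    flags = np.zeros(len(protein_groups), bool)
    if len(np_beads) == 0 or not protein_groups:
        return flags
    wrapped = positions - box * np.floor(positions / box)
    tree = cKDTree(wrapped[np_beads], boxsize=box)
    for p, grp in enumerate(protein_groups):
        counts = tree.query_ball_point(wrapped[grp], cutoff, return_length=True)
        flags[p] = int(np.count_nonzero(counts)) >= min_contacts
    return flags


def adsorption_count(positions: np.ndarray, box: np.ndarray,
                     protein_groups: list[np.ndarray], np_beads: np.ndarray,
                     cutoff: float = CONTACT_CUTOFF,
                     min_contacts: int = MIN_CONTACTS) -> int:
    """Number of proteins with >= min_contacts beads within cutoff of the NP complex."""
    return int(adsorption_flags(positions, box, protein_groups, np_beads,
                                cutoff, min_contacts).sum())


def persistent_adsorption_count(times: np.ndarray, flag_history: np.ndarray,
                                min_duration: float = PERSISTENCE_TAU,
                                occupancy: float = 1.0) -> int:
    """Proteins adsorbed persistently over the trailing ``min_duration`` of time.

    ``flag_history`` is (n_frames, n_proteins) boolean; a protein counts if it
    is in contact in at least the ``occupancy`` fraction of the frames in the
    final window (1.0 = every frame; desk-scale runs use a slightly lower
    occupancy to tolerate flicker of the bead-count threshold).
    """
    times = np.asarray(times, float)
    window = times >= times[-1] - min_duration
    frac = flag_history[window].mean(axis=0)
    return int((frac >= occupancy).sum())


# ---------------------------------------------------------------------------
# Nanoparticle-membrane distance
# ---------------------------------------------------------------------------

def _circular_mean_z(z: np.ndarray, lz: float) -> float:
    theta = 2.0 * math.pi * z / lz
    return float(math.atan2(np.sin(theta).mean(), np.cos(theta).mean())
                 / (2.0 * math.pi) * lz) % lz


def membrane_distance(positions: np.ndarray, box: np.ndarray,
                      np_core: np.ndarray, tail_beads: np.ndarray,
                      max_slab_halfwidth: float = 4.0,
                      min_slab_fraction: float = 0.8) -> float:
    """|z_COM(NP core) - z_midplane| in nm, periodic-aware along z.

    The midplane is the circular-mean z of the lipid tail beads, refined by
    discarding strays beyond ``max_slab_halfwidth`` (a few lipids extracted
    onto the particle must not shift the plane).  If fewer than
    ``min_slab_fraction`` of the tail beads lie within the slab the membrane
    no longer forms one sheet and :class:`MembraneFragmented` is raised.
    """
    lz = float(box[2])
    z_tails = positions[tail_beads, 2]
    z_mid = _circular_mean_z(z_tails, lz)
    for _ in range(3):   # trim strays, re-center on the slab population
        dz = z_tails - z_mid
        dz -= lz * np.round(dz / lz)
        slab = np.abs(dz) <= max_slab_halfwidth
        if not slab.any():
            raise MembraneFragmented("no coherent tail slab found")
        z_mid = _circular_mean_z(z_tails[slab], lz)
    frac = float(slab.mean())
    if frac < min_slab_fraction:
        raise MembraneFragmented(
            f"only {frac:.0%} of tail beads lie within {max_slab_halfwidth} "
            "r_c of the midplane")
    z_np = _circular_mean_z(positions[np_core, 2], lz)
    d = z_np - z_mid
    d -= lz * round(d / lz)
    return abs(float(d))


# ---------------------------------------------------------------------------
# Interaction energy change
# ---------------------------------------------------------------------------

def subsystem_selection(topology: Topology) -> np.ndarray:
    """Mask of beads in the NP complex (core + polymers + antibody) or membrane."""
    sel = np.zeros(topology.n_beads, bool)
    sel[topology.beads_of_kind(*NP_COMPLEX_KINDS)] = True
    sel[topology.beads_of_kind(*MEMBRANE_KINDS)] = True
    return sel


def interaction_energy_delta(topology: Topology, ff: ForceField,
                             initial: tuple[np.ndarray, np.ndarray],
                             final: tuple[np.ndarray, np.ndarray]) -> float:
    """Delta E = E(final) - E(initial) of the NP-complex + membrane subsystem (kBT).

    E sums every pair, bond and angle term with at least one member in the
    nanoparticle complex or the membrane; pure-solvent (water-water, ion-ion)
    terms never enter.  The initial frame is the configuration recorded at
    placement, before any approach.
    """
    sel = subsystem_selection(topology)
    pos0, box0 = initial
    pos1, box1 = final
    e0 = selected_potential_energy(topology, ff, pos0, box0, sel)
    e1 = selected_potential_energy(topology, ff, pos1, box1, sel)
    return e1 - e0


# ---------------------------------------------------------------------------
# Surface tension
# ---------------------------------------------------------------------------

def surface_tension(pressure_tensors: np.ndarray, lz: float | np.ndarray) -> tuple[float, float]:
    """Lateral tension gamma = Lz [P_zz - (P_xx + P_yy)/2], window-averaged.

    ``pressure_tensors`` is (n_samples, 3, 3); returns (mean, standard error).
    A warning is logged when fewer than 100 samples are provided.
    """
    p = np.asarray(pressure_tensors, float)
    if p.ndim == 2:
        p = p[None]
    if 1 < len(p) < 100:
        log.warning("surface_tension: only %d samples (<100); noisy estimate", len(p))
    lz = np.broadcast_to(np.asarray(lz, float), (len(p),))
    g = lz * (p[:, 2, 2] - 0.5 * (p[:, 0, 0] + p[:, 1, 1]))
    se = float(g.std(ddof=1) / math.sqrt(len(g))) if len(g) > 1 else float("nan")
    return float(g.mean()), se


# ---------------------------------------------------------------------------
# Phase classification
# ---------------------------------------------------------------------------

def classify_phase(scan_results: dict[tuple[int, float], dict],
                   resist_threshold: float = 0.5,
                   target_delta_e: float = -20.0) -> list[PhaseCell]:
    """Classify each (N, sigma) cell of a decoration scan.

    resist: mean persistent adsorption count <= ``resist_threshold``
    (sigma = 0 bare surfaces are never resist).  target: an antibody-receptor
    soft-LJ contact formed, or Delta E at/below ``target_delta_e``.  Cells
    missing a channel are marked undetermined, never interpolated.
    """
    cells = []
    for (N, sigma), res in sorted(scan_results.items()):
        resist: bool | None
        target: bool | None
        if "adsorption" not in res:
            resist = None
        elif sigma == 0:
            resist = False
        else:
            resist = bool(res["adsorption"] <= resist_threshold)
        if "contact" not in res and "delta_e" not in res:
            target = None
        else:
            target = bool(res.get("contact", False)
                          or res.get("delta_e", 0.0) <= target_delta_e)
        cells.append(PhaseCell(N=N, sigma=sigma, resist=resist, target=target))
    return cells


def phase_grid_frame(cells: list[PhaseCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"N": c.N, "sigma": c.sigma, "resist": c.resist, "target": c.target}
         for c in cells])


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and standard error over replicate seeds (n = len(values))."""
    v = np.asarray(list(values), float)
    se = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else float("nan")
    return float(v.mean()), se
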