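"""Bead-level system topology shared by the builders and the engine.

A :class:`Topology` is a flat, array-oriented description of one simulation
system: per-bead class indices and charges, bonded terms, rigid-body
membership and molecule labels, plus the initial coordinates produced by the
builders.  Fragments can be concatenated, which is how composite systems
(nanoparticle + polymers + membrane + solvent) are assembled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .forcefield import BeadClass

# molecule kind labels used across the package
KIND_WATER = "water"
KIND_ION = "ion"
KIND_LIPID = "lipid"
KIND_LIPID_ANIONIC = "lipid_anionic"
KIND_LIPID_RECEPTOR = "lipid_receptor"
KIND_NP_CORE = "np_core"
KIND_POLYMER = "polymer"
KIND_PROTEIN = "protein"
KIND_ANTIBODY = "antibody"

MEMBRANE_KINDS = (KIND_LIPID, KIND_LIPID_ANIONIC, KIND_LIPID_RECEPTOR)
NP_COMPLEX_KINDS = (KIND_NP_CORE, KIND_POLYMER, KIND_ANTIBODY)


@dataclass
class Topology:
    """Array-of-structs description of every bead and bonded term in a system."""

    classes: list[BeadClass]
    type_index: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    charge: np.ndarray = field(default_factory=lambda: np.empty(0))
    body_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mol_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mol_kind: dict[int, str] = field(default_factory=dict)
    bond_ij: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    bond_ks: np.ndarray = field(default_factory=lambda: np.empty(0))
    bond_l0: np.ndarray = field(default_factory=lambda: np.empty(0))
    angle_ijk: np.ndarray = field(default_factory=lambda: np.empty((0, 3), np.int64))
    angle_ka: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_beads(self) -> int:
        return len(self.type_index)

    @property
    def n_bodies(self) -> int:
        return int(self.body_id.max()) + 1 if len(self.body_id) and self.body_id.max() >= 0 else 0

    def class_labels(self) -> list[str]:
        return [c.label for c in self.classes]

    def label_of(self, bead: int) -> str:
        return self.classes[self.type_index[bead]].label

    def beads_of_kind(self, *kinds: str) -> np.ndarray:
        """Indices of all beads whose molecule kind is one of ``kinds``."""
        wanted = {m for m, k in self.mol_kind.items() if k in kinds}
        if not wanted:
            return np.empty(0, np.int64)
        mask = np.isin(self.mol_id, np.fromiter(wanted, np.int64))
        return np.nonzero(mask)[0]

    def molecules_of_kind(self, *kinds: str) -> list[np.ndarray]:
        """Per-molecule bead index arrays for every molecule of the given kinds."""
        out = []
        for m in sorted(m for m, k in self.mol_kind.items() if k in kinds):
            out.append(np.nonzero(self.mol_id == m)[0])
        return out

    def net_charge(self) -> float:
        return float(self.charge.sum())

    def count_lipids(self) -> int:
        return sum(1 for k in self.mol_kind.values() if k in MEMBRANE_KINDS)

    def validate(self) -> None:
        n = self.n_beads
        if self.positions.shape != (n, 3):
            raise ValueError("positions shape mismatch")
        for arr in (self.charge, self.body_id, self.mol_id):
            if len(arr) != n:
                raise ValueError("per-bead array length mismatch")
        if len(self.bond_ij) and self.bond_ij.max() >= n:
            raise ValueError("bond index out of range")
        if len(self.angle_ijk) and self.angle_ijk.max() >= n:
            raise ValueError("angle index out of range")
        for b, cls in zip(self.type_index, [self.classes[t] for t in self.type_index]):
            pass  # class table consistency is enforced at construction

    def content_hash(self) -> str:
        """Stable hash of the topology arrays, used to tag checkpoints."""
        h = hashlib.sha256()
        for arr in (
            self.type_index,
            self.charge,
            self.body_id,
            self.mol_id,
            self.bond_ij,
            self.bond_ks,
            self.bond_l0,
            self.angle_ijk,
            self.angle_ka,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(",".join(self.class_labels()).encode())
        return h.hexdigest()[:16]


def remove_molecules(topo: Topology, mol_ids) -> Topology:
    """Return a copy of ``topo`` without the given molecules (indices remapped)."""
    drop = set(int(m) for m in mol_ids)
    keep_mask = ~np.isin(topo.mol_id, np.fromiter(drop, np.int64, len(drop))) \
        if drop else np.ones(topo.n_beads, bool)
    new_index = np.full(topo.n_beads, -1, np.int64)
    new_index[keep_mask] = np.arange(int(keep_mask.sum()))
    kept_mols = sorted(m for m in topo.mol_kind if m not in drop)
    mol_remap = {m: k for k, m in enumerate(kept_mols)}
    bond_keep = keep_mask[topo.bond_ij].all(axis=1) if len(topo.bond_ij) else \
        np.zeros(0, bool)
    ang_keep = keep_mask[topo.angle_ijk].all(axis=1) if len(topo.angle_ijk) else \
        np.zeros(0, bool)
    return Topology(
        classes=list(topo.classes),
        type_index=topo.type_index[keep_mask],
        positions=topo.positions[keep_mask],
        charge=topo.charge[keep_mask],
        body_id=topo.body_id[keep_mask],
        mol_id=np.array([mol_remap[m] for m in topo.mol_id[keep_mask]], np.int64),
        mol_kind={mol_remap[m]: k for m, k in topo.mol_kind.items()
                  if m not in drop},
        bond_ij=new_index[topo.bond_ij[bond_keep]],
        bond_ks=topo.bond_ks[bond_keep],
        bond_l0=topo.bond_l0[bond_keep],
        angle_ijk=new_index[topo.angle_ijk[ang_keep]],
        angle_ka=topo.angle_ka[ang_keep],
    )


def merge(fragments: list[Topology]) -> Topology:
    """Concatenate topology fragments, remapping class, molecule and body ids.

    Bead classes with identical field values are shared; molecule and rigid
    body ids are offset so they stay unique in the merged system.
    """
    classes: list[BeadClass] = []
    class_map: dict[BeadClass, int] = {}
    parts: dict[str, list] = {k: [] for k in (
        "type_index", "positions", "charge", "body_id", "mol_id",
        "bond_ij", "bond_ks", "bond_l0", "angle_ijk", "angle_ka")}
    mol_kind: dict[int, str] = {}
    bead_off = mol_off = body_off = 0
    for frag in fragments:
        remap = np.empty(len(frag.classes), np.int64)
        for i, c in enumerate(frag.classes):
            if c not in class_map:
                class_map[c] = len(classes)
                classes.append(c)
            remap[i] = class_map[c]
        parts["type_index"].append(remap[frag.type_index])
        parts["positions"].append(frag.positions)
        parts["charge"].append(frag.charge)
        bid = frag.body_id.copy()
        bid[bid >= 0] += body_off
        parts["body_id"].append(bid)
        parts["mol_id"].append(frag.mol_id + mol_off)
        for m, k in frag.mol_kind.items():
            mol_kind[m + mol_off] = k
        parts["bond_ij"].append(frag.bond_ij + bead_off)
        parts["bond_ks"].append(frag.bond_ks)
        parts["bond_l0"].append(frag.bond_l0)
        parts["angle_ijk"].append(frag.angle_ijk + bead_off)
        parts["angle_ka"].append(frag.angle_ka)
        bead_off += frag.n_beads
        mol_off += int(frag.mol_id.max()) + 1 if frag.n_beads else 0
        body_off += frag.n_bodies
    return Topology(
        classes=classes,
        type_index=np.concatenate(parts["type_index"]) if parts["type_index"] else np.empty(0, np.int64),
        positions=np.vstack(parts["positions"]) if parts["positions"] else np.empty((0, 3)),
        charge=np.concatenate(parts["charge"]),
        body_id=np.concatenate(parts["body_id"]),
        mol_id=np.concatenate(parts["mol_id"]),
        mol_kind=mol_kind,
        bond_ij=np.vstack(parts["bond_ij"]).astype(np.int64) if parts["bond_ij"] else np.empty((0, 2), np.int64),
        bond_ks=np.concatenate(parts["bond_ks"]),
        bond_l0=np.concatenate(parts["bond_l0"]),
        angle_ijk=np.vstack(parts["angle_ijk"]).astype(np.int64) if parts["angle_ijk"] else np.empty((0, 3), np.int64),
        angle_ka=np.concatenate(parts["angle_ka"]),
    )
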