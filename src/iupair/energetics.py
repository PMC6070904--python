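"""Vacuum nonbonded interaction energies between rigid bases.

The interaction energy between two atom groups is the sum over all
cross pairs of a Coulomb term (dielectric constant 1, no cutoff, no
solvent screening) and a 12-6 Lennard-Jones term with arithmetic-mean
Rmin and geometric-mean well depths.  Only base atoms enter the pair
and step dissections: E_H-bond is the energy between the two bases of
one pair, E_stack the energy between the four bases of two stacked
pairs grouped pair-against-pair, and the total step energy is their
sum.  The duplex formation energy is the cross-strand nonbonded energy
(intra-strand terms cancel in the difference for rigid strands).

Energies are in kcal/mol; these are gas-phase molecular-mechanics
numbers and deliberately exclude any solvation term.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .basegeom import BaseTemplate, ReferenceFrame, rebuild_atoms

__all__ = [
    "COULOMB_CONSTANT", "CLASH_DISTANCE",
    "AtomGroup", "EnergyRecord", "FormationEnergy",
    "interaction_energy", "step_energies", "formation_energy",
    "energy_by_substate",
]

#: Coulomb conversion factor, kcal mol^-1 A e^-2 (AMBER convention).
COULOMB_CONSTANT = 332.0637
#: Below this interatomic distance the configuration is flagged a clash.
CLASH_DISTANCE = 0.3


@dataclass(frozen=True)
class AtomGroup:
    """Atoms with charges and LJ parameters, ready for energy evaluation."""

    coords: np.ndarray       # (n, 3) Angstrom
    charges: np.ndarray      # elementary charges
    rmin_half: np.ndarray    # Angstrom
    epsilon: np.ndarray      # kcal/mol

    @classmethod
    def from_template(cls, template: BaseTemplate,
                      frame: ReferenceFrame | None = None) -> "AtomGroup":
        frame = frame or ReferenceFrame.identity()
        rm, eps = template.lj_params()
        return cls(frame.apply(template.coords()), template.charges(), rm, eps)

    @classmethod
    def from_atoms(cls, atoms: Mapping[str, np.ndarray],
                   template: BaseTemplate) -> "AtomGroup":
        names = [a.name for a in template.atoms if a.name in atoms]
        coords = np.array([atoms[n] for n in names])
        q = np.array([template.atom(n).charge for n in names])
        rm = np.array([template.atom(n).rmin_half for n in names])
        eps = np.array([template.atom(n).epsilon for n in names])
        return cls(coords, q, rm, eps)

    @classmethod
    def merge(cls, groups: Iterable["AtomGroup"]) -> "AtomGroup":
        gs = list(groups)
        return cls(np.vstack([g.coords for g in gs]),
                   np.concatenate([g.charges for g in gs]),
                   np.concatenate([g.rmin_half for g in gs]),
                   np.concatenate([g.epsilon for g in gs]))

    def __len__(self) -> int:
        return len(self.charges)


@dataclass(frozen=True)
class EnergyRecord:
    """Per-frame energy dissection of one base-pair step, kcal/mol."""

    frame_index: int
    e_hbond_pair1: float
    e_hbond_pair2: float
    e_stack: float
    substate_label: Optional[str] = None
    clash: bool = False

    @property
    def e_total_step(self) -> float:
        return self.e_stack + self.e_hbond_pair1 + self.e_hbond_pair2


@dataclass(frozen=True)
class FormationEnergy:
    """Cross-strand vacuum energy of a duplex, kcal/mol."""

    delta_e_formation: float
    clash: bool = False


def _pairwise(group1: AtomGroup, group2: AtomGroup) -> Tuple[float, bool]:
    d = group1.coords[:, None, :] - group2.coords[None, :, :]
    r = np.sqrt((d * d).sum(axis=-1))
    clash = bool((r < CLASH_DISTANCE).any())
    e_coul = COULOMB_CONSTANT * (group1.charges[:, None]
                                 * group2.charges[None, :] / r).sum()
    rmin = group1.rmin_half[:, None] + group2.rmin_half[None, :]
    eps = np.sqrt(group1.epsilon[:, None] * group2.epsilon[None, :])
    s6 = (rmin / r) ** 6
    e_lj = (eps * (s6 * s6 - 2.0 * s6)).sum()
    return float(e_coul + e_lj), clash


def interaction_energy(group1: AtomGroup, group2: AtomGroup) -> float:
    """Vacuum electrostatic + van-der-Waals energy between two groups.

    The groups must be disjoint atom sets; atoms closer than
    ``CLASH_DISTANCE`` are tolerated but indicate an unphysical
    overlap (use :func:`step_energies` to carry the clash flag).
    """
    e, _ = _pairwise(group1, group2)
    return e


def step_energies(pair1: Tuple[AtomGroup, AtomGroup],
                  pair2: Tuple[AtomGroup, AtomGroup],
                  frame_index: int = 0,
                  substate_label: Optional[str] = None) -> EnergyRecord:
    """Dissect one base-pair step into H-bond and stacking terms.

    ``pair1`` and ``pair2`` are the (base1, base2) groups of the two
    stacked pairs; pair1 is the 5' pair on strand 1.
    """
    e1, c1 = _pairwise(*pair1)
    e2, c2 = _pairwise(*pair2)
    es, c3 = _pairwise(AtomGroup.merge(pair1), AtomGroup.merge(pair2))
    return EnergyRecord(frame_index, e1, e2, es,
                        substate_label=substate_label,
                        clash=c1 or c2 or c3)


def formation_energy(strand1: Sequence[AtomGroup],
                     strand2: Sequence[AtomGroup]) -> FormationEnergy:
    """Duplex formation energy: E(duplex) - E(strand1) - E(strand2).

    For rigid strands every intra-strand term cancels in the
    difference, leaving the cross-strand nonbonded energy.
    """
    if len(strand1) != len(strand2):
        raise ValueError(
            f"strands are not complementary in length: "
            f"{len(strand1)} vs {len(strand2)}")
    e, clash = _pairwise(AtomGroup.merge(strand1), AtomGroup.merge(strand2))
    return FormationEnergy(e, clash)


def energy_by_substate(records: Sequence[EnergyRecord],
                       labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Summary statistics of the step energy terms conditioned on substate.

    ``labels`` may override the labels stored on the records; its frame
    indices must then match one-to-one.
    """
    if labels is not None:
        if len(labels) != len(records):
            raise ValueError("label series does not match record count")
        recs = [(r.frame_index, labels[i], r.e_hbond_pair1, r.e_stack,
                 r.e_total_step) for i, r in enumerate(records)]
    else:
        recs = [(r.frame_index, r.substate_label, r.e_hbond_pair1, r.e_stack,
                 r.e_total_step) for r in records]
    df = pd.DataFrame(recs, columns=["frame", "substate", "e_hbond",
                                     "e_stack", "e_total_step"])
    return (df.groupby("substate")[["e_hbond", "e_stack", "e_total_step"]]
              .agg(["count", "mean", "std"]))
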