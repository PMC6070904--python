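"""Hydrogen-bond detection and I-U wobble substate classification.

A hydrogen bond is a donor-H...acceptor triple with donor-acceptor
distance at most 3.4 Angstrom and donor-H-acceptor angle at least 135
degrees (the distance cutoff is generous on purpose, so that minor
thermal fluctuations of a formed bond still count).  C-H donors are
excluded except for the C2-H2 group of inosine, which is needed to
recognise the weakly bonded D and F wobble substates.

The monitored inosine-uracil pair is classified per frame into one of
six geometries by its H-bond pattern, checked in priority order:

=====  =====================================================
label  pattern (I atom - U atom)
=====  =====================================================
A      N1-O2 and O6-N3 (the basic two-bond wobble)
B      O6-N3 only; pair opened toward the minor groove
C      N1-O2 only; pair opened toward the major groove
D      C2-O2, with none of the above
E      N1-O4 (alone or bifurcated with C2-O4)
F      C2-O4 alone
other  anything else, including no bond at all
=====  =====================================================
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .basegeom import (ACCEPTORS, DONORS, WEAK_DONORS, BaseTemplate,
                       ReferenceFrame, load_templates, rebuild_atoms)
from .energetics import AtomGroup, interaction_energy
from .helical import flip_frame

__all__ = [
    "DISTANCE_CUTOFF", "ANGLE_CUTOFF", "SUBSTATE_LABELS",
    "HBond", "SubstateRecord", "SubstatePopulations", "WobblePair",
    "detect_hbonds", "classify_substate", "build_wobble_pair",
    "population_table",
]

DISTANCE_CUTOFF = 3.4     # donor-acceptor, Angstrom
ANGLE_CUTOFF = 135.0      # donor-H-acceptor, degrees
SUBSTATE_LABELS = ("A", "B", "C", "D", "E", "F", "other")

#: H-bond target length used for the wobble-pair distance restraints, A.
RESTRAINT_TARGET = 2.90
#: Stiff tether on the glycosidic nitrogens during in-duplex relaxation,
#: kcal/mol/A^2 -- stands in for the covalent attachment to the fixed
#: backbone, so it is much stiffer than the H-bond distance restraints.
GLYCOSIDIC_ANCHOR_K = 200.0


@dataclass(frozen=True)
class HBond:
    donor: Tuple[int, str]        # (residue slot, atom name)
    hydrogen: Tuple[int, str]
    acceptor: Tuple[int, str]
    distance: float               # donor-acceptor, Angstrom
    angle: float                  # donor-H-acceptor, degrees


@dataclass(frozen=True)
class SubstateRecord:
    frame_index: int
    label: str
    hbonds: Tuple[HBond, ...]
    pair_id: Tuple[int, int]      # (inosine residue, uracil residue)


@dataclass(frozen=True)
class SubstatePopulations:
    pair_id: Tuple[int, int]
    counts: Dict[str, int]
    percentages: Dict[str, float]

    @property
    def n_frames(self) -> int:
        return sum(self.counts.values())


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    u, v = a - b, c - b
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _donor_map(code: str, include_weak: bool) -> Dict[str, Tuple[str, ...]]:
    donors = dict(DONORS.get(code, {}))
    if include_weak:
        donors.update(WEAK_DONORS.get(code, {}))
    return donors


def detect_hbonds(res1_atoms: Mapping[str, np.ndarray], res1_code: str,
                  res2_atoms: Mapping[str, np.ndarray], res2_code: str,
                  include_weak_donors: bool = False,
                  distance_cutoff: float = DISTANCE_CUTOFF,
                  angle_cutoff: float = ANGLE_CUTOFF) -> List[HBond]:
    """All hydrogen bonds between two residues.

    Both donor->acceptor directions are scanned.  When a donor carries
    two hydrogens the one giving the larger donor-H-acceptor angle is
    used.  ``include_weak_donors`` admits the inosine C2-H2 donor,
    which should be enabled only for the monitored I-U pair.
    """
    out: List[HBond] = []
    sides = [(1, res1_atoms, res1_code, 2, res2_atoms, res2_code),
             (2, res2_atoms, res2_code, 1, res1_atoms, res1_code)]
    for dslot, datoms, dcode, aslot, aatoms, acode in sides:
        donors = _donor_map(dcode, include_weak_donors)
        for heavy, hyds in donors.items():
            if heavy not in datoms:
                continue
            missing = [h for h in hyds if h not in datoms]
            if missing:
                raise ValueError(
                    f"declared donor {heavy} of residue {dcode} is missing "
                    f"hydrogen(s) {missing}")
            for acc in ACCEPTORS.get(acode, ()):
                if acc not in aatoms:
                    continue
                d = float(np.linalg.norm(
                    np.asarray(datoms[heavy]) - np.asarray(aatoms[acc])))
                if d > distance_cutoff:
                    continue
                best_h, best_ang = None, -1.0
                for h in hyds:
                    ang = _angle_deg(np.asarray(datoms[heavy]),
                                     np.asarray(datoms[h]),
                                     np.asarray(aatoms[acc]))
                    if ang > best_ang:
                        best_h, best_ang = h, ang
                if best_ang >= angle_cutoff:
                    out.append(HBond((dslot, heavy), (dslot, best_h),
                                     (aslot, acc), d, best_ang))
    return out


def _iu_bond_set(hbonds: Sequence[HBond],
                 inosine_slot: int = 1) -> set:
    """Reduce I-U H-bonds to (I atom, U atom) pairs, direction-free."""
    pairs = set()
    for hb in hbonds:
        if hb.donor[0] == inosine_slot:
            pairs.add((hb.donor[1], hb.acceptor[1]))
        else:
            pairs.add((hb.acceptor[1], hb.donor[1]))
    return pairs


def classify_substate(hbonds: Sequence[HBond],
                      inosine_slot: int = 1) -> str:
    """Label the monitored I-U pair from its H-bond inventory.

    Patterns are evaluated in priority order A, B, C, D, E, F; frames
    matching none get ``"other"``.
    """
    bonds = _iu_bond_set(hbonds, inosine_slot)
    n1_o2 = ("N1", "O2") in bonds
    o6_n3 = ("O6", "N3") in bonds
    if n1_o2 and o6_n3:
        return "A"
    if o6_n3:
        return "B"
    if n1_o2:
        return "C"
    if ("C2", "O2") in bonds:
        return "D"
    if ("N1", "O4") in bonds:
        return "E"
    if ("C2", "O4") in bonds:
        return "F"
    return "other"


@dataclass(frozen=True)
class WobblePair:
    """Result of the restrained rigid-body relaxation of a base pair."""

    frame_b1: ReferenceFrame         # strand-1 base frame (I or A)
    frame_b2: ReferenceFrame         # the uracil base's own frame
    atoms_b1: Dict[str, np.ndarray]
    atoms_b2: Dict[str, np.ndarray]
    energy: float                    # unrestrained pair vacuum energy, kcal/mol
    restraint_distances: Tuple[float, float]
    gradient_norm: float


#: restrained H-bond distances per pair type: (b1 atom, b2 atom)
_RESTRAINED_BONDS = {
    "IU": (("N1", "O2"), ("O6", "N3")),
    "AU": (("N1", "N3"), ("N6", "O4")),
}


def _rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K


def _duplex_context(templates: Dict[str, BaseTemplate]) -> AtomGroup:
    """Two canonical A-U pairs one ideal A-form step above and below the
    relaxing pair, held fixed during the minimization."""
    from .helical import (A_RNA_STEP, PairParams, StepParams, compose_pair,
                          compose_step)
    step = StepParams(0, *A_RNA_STEP)
    zero = PairParams(0, 0, 0, 0, 0, 0, 0)
    mid0 = ReferenceFrame.identity()
    mid_prev = _invert_step(mid0, step)
    mid_next = compose_step(mid0, step)
    groups = []
    for mid in (mid_prev, mid_next):
        f1, f2 = compose_pair(mid, zero)
        groups.append(AtomGroup.from_template(templates["A"], f1))
        groups.append(AtomGroup.from_template(templates["U"], f2))
    return AtomGroup.merge(groups)


def _invert_step(mid, step):
    """The frame whose forward step by ``step`` lands on ``mid``.

    The step map is frame-linear: F(R, o) = (R C, o + R d) with C, d
    read off from F applied to the identity frame.
    """
    from .helical import compose_step
    probe = compose_step(ReferenceFrame.identity(), step)
    C, d = probe.axes, probe.origin
    R = mid.axes @ C.T
    return ReferenceFrame(mid.origin - R @ d, R)


def build_wobble_pair(templates: Optional[Dict[str, BaseTemplate]] = None,
                      restraint_k: float = 20.0,
                      n_steps: int = 2000,
                      restraint_target: float = RESTRAINT_TARGET,
                      pair_type: str = "IU",
                      duplex_context: bool = True,
                      gtol: float = 1e-6) -> WobblePair:
    """Relax a base pair into its H-bonded geometry by restrained
    rigid-body minimization, emulating an in-vacuo minimization in
    which everything but the pair is held fixed.

    The strand-1 base (inosine for ``pair_type="IU"``, adenine for
    ``"AU"``) starts on the purine position of an ideal Watson-Crick
    pair; for inosine this places O6(I) in steric and electrostatic
    conflict with O4(U).  Both bases then move as rigid bodies (6
    degrees of freedom each) minimizing the vacuum nonbonded energy --
    against each other and, when ``duplex_context`` is set, against two
    fixed canonical neighbour pairs stacked one ideal A-form step above
    and below -- plus harmonic restraints of ``restraint_k``
    kcal/mol/A^2 pulling the pair's hydrogen bonds to
    ``restraint_target``.  In duplex context each glycosidic nitrogen
    is additionally tethered to its start by a stiff harmonic of
    ``GLYCOSIDIC_ANCHOR_K`` kcal/mol/A^2, standing in for the covalent
    attachment to the fixed backbone.

    Raises
    ------
    RuntimeError
        If the minimizer has not reached ``gtol`` after ``n_steps``.
    """
    if pair_type not in _RESTRAINED_BONDS:
        raise ValueError(f"unknown pair type {pair_type!r}")
    templates = templates or load_templates()
    t1 = templates[pair_type[0]]
    t2 = templates[pair_type[1]]
    frame1 = ReferenceFrame.identity()
    frame2 = flip_frame(ReferenceFrame.identity())
    xyz1 = frame1.apply(t1.coords())
    xyz2 = frame2.apply(t2.coords())
    names1, names2 = t1.atom_names, t2.atom_names
    (b1a, b2a), (b1b, b2b) = _RESTRAINED_BONDS[pair_type]
    i1a, i1b = names1.index(b1a), names1.index(b1b)
    i2a, i2b = names2.index(b2a), names2.index(b2b)
    g1 = t1.glycosidic_atom
    g2 = t2.glycosidic_atom
    ig1, ig2 = names1.index(g1), names2.index(g2)
    anchor1, anchor2 = xyz1[ig1].copy(), xyz2[ig2].copy()
    q1, q2 = t1.charges(), t2.charges()
    rm1, eps1 = t1.lj_params()
    rm2, eps2 = t2.lj_params()
    ctx = _duplex_context(templates) if duplex_context else None

    def place(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        c1 = t1.coords() @ (_rotvec_to_matrix(x[:3]) @ frame1.axes).T \
            + frame1.origin + x[3:6]
        c2 = t2.coords() @ (_rotvec_to_matrix(x[6:9]) @ frame2.axes).T \
            + frame2.origin + x[9:12]
        return c1, c2

    def objective(x: np.ndarray) -> float:
        c1, c2 = place(x)
        grp1 = AtomGroup(c1, q1, rm1, eps1)
        grp2 = AtomGroup(c2, q2, rm2, eps2)
        e = interaction_energy(grp1, grp2)
        if ctx is not None:
            e += interaction_energy(grp1, ctx) + interaction_energy(grp2, ctx)
        d1 = np.linalg.norm(c1[i1a] - c2[i2a])
        d2 = np.linalg.norm(c1[i1b] - c2[i2b])
        e += restraint_k * ((d1 - restraint_target) ** 2
                            + (d2 - restraint_target) ** 2)
        if ctx is not None:
            e += GLYCOSIDIC_ANCHOR_K * (((c1[ig1] - anchor1) ** 2).sum()
                                        + ((c2[ig2] - anchor2) ** 2).sum())
        return e

    res = minimize(objective, np.zeros(12), method="L-BFGS-B",
                   options={"maxiter": n_steps, "gtol": gtol, "ftol": 1e-14})
    grad_norm = (float(np.max(np.abs(res.jac)))
                 if res.jac is not None else np.inf)
    if not res.success and grad_norm > 1e-3:
        raise RuntimeError(
            f"pair relaxation did not converge in {n_steps} steps; "
            f"final projected gradient norm {grad_norm:.3e}")
    c1, c2 = place(res.x)
    atoms1 = {n: c1[i] for i, n in enumerate(names1)}
    atoms2 = {n: c2[i] for i, n in enumerate(names2)}
    from .basegeom import fit_frame
    grp1 = AtomGroup(c1, q1, rm1, eps1)
    grp2 = AtomGroup(c2, q2, rm2, eps2)
    return WobblePair(
        frame_b1=fit_frame(atoms1, t1),
        frame_b2=fit_frame(atoms2, t2),
        atoms_b1=atoms1,
        atoms_b2=atoms2,
        energy=interaction_energy(grp1, grp2),
        restraint_distances=(float(np.linalg.norm(c1[i1a] - c2[i2a])),
                             float(np.linalg.norm(c1[i1b] - c2[i2b]))),
        gradient_norm=grad_norm,
    )


def population_table(records: Sequence[SubstateRecord]) -> SubstatePopulations:
    """Substate counts and percentage populations over a trajectory."""
    if not records:
        raise ValueError("population table needs at least one record")
    pair_id = records[0].pair_id
    counts = {lab: 0 for lab in SUBSTATE_LABELS}
    for r in records:
        if r.pair_id != pair_id:
            raise ValueError("records mix different monitored pairs")
        counts[r.label] += 1
    total = len(records)
    pct = {lab: 100.0 * c / total for lab, c in counts.items()}
    return SubstatePopulations(pair_id, counts, pct)
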