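"""Rigid nucleobase templates and base reference frames.

Each of the five RNA bases (A, G, C, U and inosine I, i.e. hypoxanthine)
is represented as a rigid, planar template expressed in its standard
reference frame: the Tsukuba convention in which the x-axis points into
the major groove, the y-axis runs along the long axis of a Watson-Crick
pair toward the strand-1 backbone, and the z-axis completes a
right-handed set along the helix advance.  Two bases placed at the same
standard frame (with the second flipped 180 degrees about x) form an
ideal Watson-Crick pair.

Templates carry partial charges (elementary charges) and 12-6
Lennard-Jones parameters (Rmin/2 in Angstrom, well depth in kcal/mol)
in the style of the AMBER nucleic-acid force fields; the inosine entry
is assembled from the guanine Watson-Crick edge with an adenine-like
C2-H group and is documented as an approximation, since published
modified-residue charge sets are not reproduced verbatim here.

Frames are fitted to observed coordinates by least-squares rigid
superposition (Kabsch) of the ring atoms only, which is the convention
underlying the base-pair parameter definitions used downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

__all__ = [
    "Atom",
    "BaseTemplate",
    "ReferenceFrame",
    "load_templates",
    "fit_frame",
    "rebuild_atoms",
    "RESIDUE_SYNONYMS",
]

#: PDB residue-name synonyms accepted for each template code.
RESIDUE_SYNONYMS: Dict[str, str] = {
    "A": "A", "RA": "A", "ADE": "A",
    "G": "G", "RG": "G", "GUA": "G",
    "C": "C", "RC": "C", "CYT": "C",
    "U": "U", "RU": "U", "URA": "U",
    "I": "I", "INO": "I", "HPA": "I", "8AZ": "I",
}

_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

_RING_ATOMS = {
    "A": _PURINE_RING, "G": _PURINE_RING, "I": _PURINE_RING,
    "C": _PYRIMIDINE_RING, "U": _PYRIMIDINE_RING,
}
_GLYCOSIDIC = {"A": "N9", "G": "N9", "I": "N9", "C": "N1", "U": "N1"}

#: donor heavy atom -> attached hydrogens, per residue.  C2(I)-H2 is a
#: weak C-H donor admitted only where the caller asks for it.
DONORS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    "A": {"N6": ("H61", "H62")},
    "G": {"N1": ("H1",), "N2": ("H21", "H22")},
    "C": {"N4": ("H41", "H42")},
    "U": {"N3": ("H3",)},
    "I": {"N1": ("H1",)},
}
WEAK_DONORS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    "I": {"C2": ("H2",)},
}
ACCEPTORS: Dict[str, Tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
    "I": ("O6", "N3", "N7"),
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: np.ndarray          # standard-frame coordinates, Angstrom
    charge: float            # elementary charges
    rmin_half: float         # LJ Rmin/2, Angstrom
    epsilon: float           # LJ well depth, kcal/mol


@dataclass(frozen=True)
class BaseTemplate:
    """A rigid base in its standard reference frame."""

    residue_code: str
    atoms: Tuple[Atom, ...]
    ring_atoms: Tuple[str, ...]
    glycosidic_atom: str
    net_charge: float

    def coords(self, names: Iterable[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.xyz for a in self.atoms])
        lookup = {a.name: a.xyz for a in self.atoms}
        return np.array([lookup[n] for n in names])

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.residue_code} has no atom {name!r}")

    @property
    def atom_names(self) -> Tuple[str, ...]:
        return tuple(a.name for a in self.atoms)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def lj_params(self) -> Tuple[np.ndarray, np.ndarray]:
        return (np.array([a.rmin_half for a in self.atoms]),
                np.array([a.epsilon for a in self.atoms]))


@dataclass(frozen=True)
class ReferenceFrame:
    """Right-handed orthonormal base frame: ``lab = axes @ std + origin``.

    ``axes`` columns are the frame x/y/z unit vectors in lab coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "axes", np.asarray(self.axes, float))
        R = self.axes
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("frame axes are not a proper rotation")

    @classmethod
    def identity(cls) -> "ReferenceFrame":
        return cls(np.zeros(3), np.eye(3))

    def apply(self, std_xyz: np.ndarray) -> np.ndarray:
        return np.asarray(std_xyz) @ self.axes.T + self.origin

    def compose(self, other: "ReferenceFrame") -> "ReferenceFrame":
        """Frame obtained by applying ``self`` after ``other``."""
        return ReferenceFrame(self.axes @ other.origin + self.origin,
                              self.axes @ other.axes)


_TEMPLATE_CACHE: Dict[str, BaseTemplate] | None = None


def load_templates(parameter_table: str | None = None) -> Dict[str, BaseTemplate]:
    """Load the five base templates from the embedded parameter table.

    Parameters
    ----------
    parameter_table
        Optional override text in the embedded TSV format (one row per
        atom: residue, atom, element, x, y, z, charge, Rmin/2, epsilon).
        By default the packaged table is used and the result is cached.

    Raises
    ------
    ValueError
        If a residue or a required atom entry is missing.
    """
    global _TEMPLATE_CACHE
    if parameter_table is None and _TEMPLATE_CACHE is not None:
        return _TEMPLATE_CACHE
    if parameter_table is None:
        parameter_table = (
            resources.files("iupair.data") / "base_templates.tsv"
        ).read_text()

    by_res: Dict[str, List[Atom]] = {}
    for line in parameter_table.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 9:
            raise ValueError(f"malformed template row: {line!r}")
        res, name, el = parts[0], parts[1], parts[2]
        x, y, z, q, rm, eps = map(float, parts[3:])
        by_res.setdefault(res, []).append(
            Atom(name, el, np.array([x, y, z]), q, rm, eps))

    templates: Dict[str, BaseTemplate] = {}
    for code in ("A", "G", "C", "U", "I"):
        if code not in by_res:
            raise ValueError(f"parameter table is missing residue {code!r}")
        atoms = tuple(by_res[code])
        names = {a.name for a in atoms}
        missing = set(_RING_ATOMS[code]) - names
        if missing:
            raise ValueError(
                f"residue {code!r} is missing ring atoms {sorted(missing)}")
        for donor_map in (DONORS[code], WEAK_DONORS.get(code, {})):
            for heavy, hyds in donor_map.items():
                lost = ({heavy} | set(hyds)) - names
                if lost:
                    raise ValueError(
                        f"residue {code!r} donor group missing {sorted(lost)}")
        templates[code] = BaseTemplate(
            residue_code=code,
            atoms=atoms,
            ring_atoms=_RING_ATOMS[code],
            glycosidic_atom=_GLYCOSIDIC[code],
            net_charge=round(sum(a.charge for a in atoms), 6),
        )
    if parameter_table is None or _TEMPLATE_CACHE is None:
        _TEMPLATE_CACHE = templates
    return templates


def fit_frame(observed_atoms: Mapping[str, np.ndarray],
              template: BaseTemplate) -> ReferenceFrame:
    """Fit the base reference frame to observed ring-atom coordinates.

    Performs the least-squares rigid superposition (Kabsch) of the
    template ring atoms onto the observation, matched by atom name, and
    returns the transform carrying the standard frame into the lab
    frame.  A reflection-optimal solution is corrected to a proper
    rotation by flipping the smallest singular direction.
    """
    names = [n for n in template.ring_atoms if n in observed_atoms]
    if len(names) < 3:
        raise ValueError(
            f"need >=3 matched ring atoms to fit a frame, got {len(names)}")
    obs = np.array([np.asarray(observed_atoms[n], float) for n in names])
    ref = template.coords(names)
    ref_c = ref - ref.mean(axis=0)
    obs_c = obs - obs.mean(axis=0)
    # collinearity guard: rank of the reference spread
    if np.linalg.matrix_rank(ref_c, tol=1e-6) < 2:
        raise ValueError("matched ring atoms are collinear")
    H = ref_c.T @ obs_c
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    origin = obs.mean(axis=0) - R @ ref.mean(axis=0)
    return ReferenceFrame(origin, R)


def rebuild_atoms(frame: ReferenceFrame,
                  template: BaseTemplate) -> Dict[str, np.ndarray]:
    """Place all template atoms according to ``frame``."""
    placed = frame.apply(template.coords())
    return {a.name: placed[i] for i, a in enumerate(template.atoms)}
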