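"""Multi-model PDB input/output for duplex ensembles.

Ensembles are exchanged as standard multi-model PDB files
(MODEL/ENDMDL records) with one residue per base carrying the base
atoms plus the phosphorus backbone proxy.  Strand 1 is chain A
(residues 1..n), strand 2 chain B (residues n+1..2n); inosine is
written under residue name ``I`` and read back under the accepted
synonyms (I, INO, HPA, 8AZ).
"""
from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .basegeom import RESIDUE_SYNONYMS, load_templates
from .ensemble import Ensemble, P_LOCAL

__all__ = ["write_ensemble_pdb", "read_multimodel_pdb"]


def _atom_array_template(ensemble: Ensemble) -> struc.AtomArray:
    spec = ensemble.spec
    n = spec.n_pairs
    entries = []   # (chain, res_id, res_name, atom_name, element)
    for pos in range(1, n + 1):
        code = spec.strand1[pos - 1]
        tmpl = ensemble.templates[code]
        entries.append(("A", pos, code, "P", "P"))
        for a in tmpl.atoms:
            entries.append(("A", pos, code, a.name, a.element))
    for pos in range(n, 0, -1):          # strand 2 in residue order n+1..2n
        res_id = spec.partner_residue(pos)
        code = spec.pair_codes(pos)[1]
        tmpl = ensemble.templates[code]
        entries.append(("B", res_id, code, "P", "P"))
        for a in tmpl.atoms:
            entries.append(("B", res_id, code, a.name, a.element))
    arr = struc.AtomArray(len(entries))
    arr.chain_id = np.array([e[0] for e in entries])
    arr.res_id = np.array([e[1] for e in entries])
    arr.res_name = np.array([e[2] for e in entries])
    arr.atom_name = np.array([e[3] for e in entries])
    arr.element = np.array([e[4] for e in entries])
    arr.hetero = np.full(len(entries), False)
    return arr


def write_ensemble_pdb(ensemble: Ensemble, path, stride: int = 1) -> None:
    """Write an ensemble as a multi-model PDB file."""
    template = _atom_array_template(ensemble)
    frames = range(0, ensemble.n_frames, stride)
    stack = struc.AtomArrayStack(len(list(frames)), template.array_length())
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element",
                "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    spec = ensemble.spec
    n = spec.n_pairs
    for k, f in enumerate(range(0, ensemble.n_frames, stride)):
        base_frames = ensemble.base_frames(f)
        coords = []
        for pos in range(1, n + 1):
            fr = base_frames[pos - 1][0]
            tmpl = ensemble.templates[spec.strand1[pos - 1]]
            coords.append(fr.apply(P_LOCAL)[None, :])
            coords.append(fr.apply(tmpl.coords()))
        for pos in range(n, 0, -1):
            fr = base_frames[pos - 1][1]
            tmpl = ensemble.templates[spec.pair_codes(pos)[1]]
            coords.append(fr.apply(P_LOCAL)[None, :])
            coords.append(fr.apply(tmpl.coords()))
        stack.coord[k] = np.vstack(coords)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


FrameDict = Dict[int, Tuple[str, Dict[str, np.ndarray]]]


def read_multimodel_pdb(path) -> List[FrameDict]:
    """Read a multi-model PDB into per-frame residue dictionaries.

    Returns one dict per model mapping residue id ->
    ``(residue_code, {atom_name: xyz})``; residue names are normalised
    through the accepted synonyms.

    Raises
    ------
    ValueError
        On residue names that are not RNA bases or known inosine
        synonyms.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    frames: List[FrameDict] = []
    res_names = stack.res_name
    res_ids = stack.res_id
    atom_names = stack.atom_name
    for f in range(stack.stack_depth()):
        coord = stack.coord[f]
        fd: FrameDict = {}
        for i in range(stack.array_length()):
            rid = int(res_ids[i])
            rname = res_names[i].strip()
            if rname not in RESIDUE_SYNONYMS:
                raise ValueError(f"unrecognised residue name {rname!r}")
            code = RESIDUE_SYNONYMS[rname]
            if rid not in fd:
                fd[rid] = (code, {})
            fd[rid][1][atom_names[i].strip()] = coord[i].copy()
        frames.append(fd)
    return frames
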