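"""End-to-end analysis drivers over generated or loaded ensembles.

Each function runs one stage of the pipeline the way the command-line
interface and the analysis scripts consume it: ensembles in, tidy
pandas tables (or small result objects) out.  All heavy lifting lives
in the per-topic modules; this module only wires them together.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import energetics, entropy, helical, landscapes, pairing
from .basegeom import fit_frame
from .ensemble import Ensemble

__all__ = [
    "substate_records", "population_summary",
    "helical_tables", "bend_summary",
    "step_energy_records", "formation_energy_of_frame",
    "free_energy_profile", "entropy_extrapolation",
]

P_MASS = 30.973762   # amu


def substate_records(ensemble: Ensemble,
                     position: int) -> List[pairing.SubstateRecord]:
    """Classify the monitored I-U pair at ``position`` for every frame."""
    spec = ensemble.spec
    c1, c2 = spec.pair_codes(position)
    if (c1, c2) != ("I", "U"):
        raise ValueError(f"pair at position {position} is {c1}-{c2}, "
                         f"not I-U")
    pair_id = (position, spec.partner_residue(position))
    records = []
    for f in range(ensemble.n_frames):
        a1, a2 = ensemble.pair_atoms(f, position)
        hb = pairing.detect_hbonds(a1, "I", a2, "U",
                                   include_weak_donors=True)
        records.append(pairing.SubstateRecord(
            f, pairing.classify_substate(hb), tuple(hb), pair_id))
    return records


def population_summary(ensemble: Ensemble) -> Dict[int, dict]:
    """Substate percentage populations for every monitored pair."""
    out = {}
    for pos in ensemble.spec.monitored_pairs:
        recs = substate_records(ensemble, pos)
        pops = pairing.population_table(recs)
        out[pos] = {
            "pair_id": list(pops.pair_id),
            "n_frames": pops.n_frames,
            "percentages": {k: round(v, 3)
                            for k, v in pops.percentages.items()},
        }
    return out


def helical_tables(ensemble: Ensemble
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position trajectory means/SDs of pair and step parameters.

    Parameters are recomputed from rebuilt coordinates through frame
    fitting (the full pipeline), not read from the generator truth.
    """
    spec = ensemble.spec
    n = spec.n_pairs
    pair_names = ["shear", "stretch", "stagger",
                  "buckle", "propeller", "opening"]
    step_names = ["shift", "slide", "rise", "tilt", "roll", "twist"]
    pair_vals = np.empty((ensemble.n_frames, n, 6))
    step_vals = np.empty((ensemble.n_frames, n - 1, 6))
    for f in range(ensemble.n_frames):
        mids = []
        atoms = ensemble.frame_atoms(f)
        for pos in range(1, n + 1):
            a1, a2 = atoms[pos - 1]
            t1 = ensemble.templates[spec.strand1[pos - 1]]
            t2 = ensemble.templates[spec.pair_codes(pos)[1]]
            f1 = fit_frame(a1, t1)
            f2 = fit_frame(a2, t2)
            pair_vals[f, pos - 1] = helical.pair_params(
                f1, f2, pos - 1).as_array()
            mids.append(helical.pair_mid_frame(f1, f2))
        for i in range(n - 1):
            step_vals[f, i] = helical.step_params(
                mids[i], mids[i + 1], i).as_array()
    rows = []
    for j, name in enumerate(pair_names):
        mean, sd = helical.trajectory_profile(pair_vals[:, :, j])
        for pos in range(n):
            rows.append(("pair", pos + 1, name, mean[pos], sd[pos]))
    for j, name in enumerate(step_names):
        mean, sd = helical.trajectory_profile(step_vals[:, :, j])
        for pos in range(n - 1):
            rows.append(("step", pos + 1, name, mean[pos], sd[pos]))
    summary = pd.DataFrame(
        rows, columns=["kind", "position", "parameter", "mean", "sd"])
    long_rows = pd.DataFrame({
        "frame": np.repeat(np.arange(ensemble.n_frames), (n - 1)),
        "step": np.tile(np.arange(1, n), ensemble.n_frames),
        "twist": step_vals[:, :, 5].ravel(),
        "local_bend": np.hypot(step_vals[:, :, 4],
                               step_vals[:, :, 3]).ravel(),
    })
    return summary, long_rows


def bend_summary(ensemble: Ensemble,
                 max_frames: int = 200) -> helical.BendSummary:
    """Global duplex bend averaged over (a subsample of) frames."""
    stride = max(1, ensemble.n_frames // max_frames)
    frames = []
    for f in range(0, ensemble.n_frames, stride):
        frames.append([helical.pair_mid_frame(f1, f2)
                       for f1, f2 in ensemble.base_frames(f)])
    return helical.total_bend(frames)


def step_energy_records(ensemble: Ensemble, step_position: int,
                        labels: Optional[Sequence[str]] = None
                        ) -> List[energetics.EnergyRecord]:
    """Energy dissection of the step between pairs ``step_position``
    and ``step_position + 1`` for every frame."""
    spec = ensemble.spec
    recs = []
    for f in range(ensemble.n_frames):
        groups = []
        for pos in (step_position, step_position + 1):
            a1, a2 = ensemble.pair_atoms(f, pos)
            t1 = ensemble.templates[spec.strand1[pos - 1]]
            t2 = ensemble.templates[spec.pair_codes(pos)[1]]
            groups.append((energetics.AtomGroup.from_atoms(a1, t1),
                           energetics.AtomGroup.from_atoms(a2, t2)))
        lab = labels[f] if labels is not None else None
        recs.append(energetics.step_energies(groups[0], groups[1],
                                             frame_index=f,
                                             substate_label=lab))
    return recs


def formation_energy_of_frame(ensemble: Ensemble,
                              frame: int = 0) -> energetics.FormationEnergy:
    """Cross-strand formation energy of one snapshot."""
    spec = ensemble.spec
    s1, s2 = [], []
    for pos in range(1, spec.n_pairs + 1):
        a1, a2 = ensemble.pair_atoms(frame, pos)
        t1 = ensemble.templates[spec.strand1[pos - 1]]
        t2 = ensemble.templates[spec.pair_codes(pos)[1]]
        s1.append(energetics.AtomGroup.from_atoms(a1, t1))
        s2.append(energetics.AtomGroup.from_atoms(a2, t2))
    return energetics.formation_energy(s1, s2)


def free_energy_profile(ensemble: Ensemble, position: int,
                        coordinate_name: str = "shear",
                        smoothing_window: int = 3
                        ) -> landscapes.FreeEnergyProfile:
    """Boltzmann-inverted profile of a monitored pair coordinate."""
    series = landscapes.coordinate_series(ensemble, position,
                                          coordinate_name)
    prof = landscapes.boltzmann_invert(series,
                                       ensemble.config.temperature,
                                       coordinate_name)
    return landscapes.find_minima(prof, smoothing_window)


def entropy_extrapolation(ensemble: Ensemble,
                          window_ends: Optional[Sequence[int]] = None,
                          window_start: Optional[int] = None
                          ) -> entropy.EntropyExtrapolation:
    """Phosphorus-trace quasi-harmonic entropy with the window scheme
    scaled onto the ensemble length (by default windows end at 40, 60,
    80 and 100% of the trajectory after a 20% equilibration offset)."""
    F = ensemble.n_frames
    if window_start is None:
        window_start = F // 5
    if window_ends is None:
        window_ends = [2 * F // 5, 3 * F // 5, 4 * F // 5, F]
    coords = ensemble.phosphorus_coords()
    masses = np.full(coords.shape[1], P_MASS)
    return entropy.windowed_extrapolation(
        coords, masses, window_ends, window_start,
        temperature=ensemble.config.temperature)
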