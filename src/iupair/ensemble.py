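"""Synthetic rigid-base duplex ensembles.

The generator emulates the statistical structure that the analysis
pipeline assumes a solvated MD trajectory of an RNA duplex would have,
without simulating any physics:

* every base pair fluctuates as a rigid body around idealized A-form
  means (Gaussian noise on the six pair and six step parameters);
* steps flanking an I-U wobble pair under-/over-twist symmetrically,
  so the global twist is conserved;
* each *monitored* I-U pair (the 5' pair of a tandem I-U/I-U step)
  switches between six substate geometries A-F following a stationary
  Markov chain whose stationary distribution encodes the sequence
  context, while all other I-U pairs stay in the basic wobble
  geometry;
* the backbone is represented only by one phosphorus atom per residue,
  placed rigidly from the base frame -- enough for the phosphorus-only
  entropy analysis and nothing more.

The 20-mer duplex systems follow the standard naming: ``wt`` is the
unmodified duplex ``GCAAUUAACCAAGGAAAAGC`` (strand 1, residues 1-20;
strand 2 residues 21-40, pair i <-> 41-i), and the modified systems
replace adenosines at positions 7, 8, 11, 12, 15, 16, 17 by inosines
in single (UI, CI, GI, AI_1..AI_4), tandem (UII, CII, GII, AII) and
combined (UII_CII, UII_CII_AII) arrangements, named after the 5'
neighbour(s) of the substituted position(s).

Substate geometries are frozen six-parameter vectors (shear, stretch,
stagger, buckle, propeller, opening) solved so that the rebuilt rigid
pair satisfies exactly the H-bond pattern of its label; each template
classifies back to its own label by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .basegeom import BaseTemplate, ReferenceFrame, load_templates
from .helical import (A_RNA_STEP, PairParams, StepParams, compose_pair,
                      compose_step)

__all__ = [
    "WT_STRAND1", "SYSTEMS", "TABLE1_STATIONARY", "SUBSTATE_PAIR_PARAMS",
    "SequenceSpec", "EnsembleConfig", "Ensemble",
    "sequence_spec", "build_ideal_duplex", "sample_ensemble", "write_truth",
    "transition_matrix",
]

#: Strand-1 sequence of the unmodified duplex, 5'->3'.
WT_STRAND1 = "GCAAUUAACCAAGGAAAAGC"

#: Inosine substitution positions (1-based, strand 1) per system.
SYSTEMS: Dict[str, Tuple[int, ...]] = {
    "wt": (),
    "UI": (7,), "AI_1": (8,), "CI": (11,), "AI_2": (12,),
    "GI": (15,), "AI_3": (16,), "AI_4": (17,),
    "UII": (7, 8), "CII": (11, 12), "GII": (15, 16), "AII": (16, 17),
    "UII_CII": (7, 8, 11, 12),
    "UII_CII_AII": (7, 8, 11, 12, 16, 17),
}

#: Observed substate populations (%, labels A..F) of the first tandem
#: I-U pair, by the 5'-neighbour base of the tandem.  These stationary
#: distributions drive the Markov switching of monitored pairs.
TABLE1_STATIONARY: Dict[str, Tuple[float, ...]] = {
    "U": (90.0, 6.0, 3.0, 1.0, 0.0, 0.0),
    "C": (56.0, 21.0, 4.0, 7.0, 6.0, 6.0),
    "G": (84.0, 2.0, 4.0, 4.0, 5.0, 1.0),
    "A": (76.0, 4.0, 12.0, 7.0, 1.0, 0.0),
}

#: Frozen substate geometries: mean (shear, stretch, stagger, buckle,
#: propeller, opening) in A / degrees, solved for H-bond pattern
#: satisfaction under the rigid templates.  A is the relaxed two-bond
#: wobble (shear ~ -2.6); B opens to the minor groove (opening ~ -35);
#: C to the major groove; D sits at near-zero shear, strongly
#: non-planar, held by the weak C2-H2...O2 bond; E carries the
#: N1-H1...O4 bond at large positive shear; F only C2-H2...O4.
SUBSTATE_PAIR_PARAMS: Dict[str, Tuple[float, ...]] = {
    "A": (-2.586, -0.515, 0.000, 0.000, 0.000, -1.318),
    "B": (-2.688, -0.266, 0.000, -0.001, 0.001, -34.970),
    "C": (-3.045, 0.297, 0.000, 0.002, 0.002, 24.705),
    "D": (0.404, -0.015, 1.233, 28.937, -28.139, 17.874),
    "E": (3.588, 0.198, 0.000, -0.005, 0.002, -15.433),
    "F": (5.329, -0.377, 0.000, 0.002, 0.000, 9.990),
}

_LABELS = ("A", "B", "C", "D", "E", "F")

#: Twist redistribution around an I-U pair: the step 5' of the wobble
#: under-twists and the step 3' of it over-twists by the same amount,
#: so the sum over the two steps is conserved.  Degrees.
TWIST_COMPENSATION = 8.0

#: Phosphorus position in the base's standard frame (a coarse A-form
#: backbone proxy; only its rigid attachment matters).
P_LOCAL = np.array([-4.2, 7.5, 1.0])

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "I": "U"}


@dataclass(frozen=True)
class SequenceSpec:
    """A duplex system: strand-1 sequence with inosine substitutions."""

    system_name: str
    strand1: str
    inosine_positions: Tuple[int, ...]

    def __post_init__(self):
        bad = set(self.strand1) - set("ACGUI")
        if bad:
            raise ValueError(f"invalid residue code(s) {sorted(bad)}")
        for p in self.inosine_positions:
            if self.strand1[p - 1] != "I":
                raise ValueError(f"position {p} is not an inosine")

    @property
    def n_pairs(self) -> int:
        return len(self.strand1)

    @property
    def strand2(self) -> str:
        """Strand-2 sequence 5'->3' (antiparallel complement)."""
        return "".join(_COMPLEMENT[c] for c in reversed(self.strand1))

    def pair_codes(self, position: int) -> Tuple[str, str]:
        """Residue codes (strand1, strand2) of pair ``position`` (1-based)."""
        return self.strand1[position - 1], self.strand2[::-1][position - 1]

    def partner_residue(self, position: int) -> int:
        """Residue number (strand-2 numbering) pairing with ``position``."""
        return 2 * self.n_pairs + 1 - position

    @property
    def monitored_pairs(self) -> Tuple[int, ...]:
        """First pairs of tandem I-U/I-U steps (the dynamic ones)."""
        pos = self.inosine_positions
        return tuple(p for p in pos if p + 1 in pos and p - 1 not in pos)

    def five_prime_neighbour(self, position: int) -> str:
        return self.strand1[position - 2] if position >= 2 else ""


def sequence_spec(system: str) -> SequenceSpec:
    """Build the :class:`SequenceSpec` for a named duplex system."""
    if system not in SYSTEMS:
        raise ValueError(
            f"unknown system {system!r}; choose from {sorted(SYSTEMS)}")
    pos = SYSTEMS[system]
    strand1 = "".join("I" if i + 1 in pos else c
                      for i, c in enumerate(WT_STRAND1))
    return SequenceSpec(system, strand1, pos)


@dataclass(frozen=True)
class EnsembleConfig:
    """Knobs of the synthetic generator.

    Fluctuation SDs are per parameter (x/y/z translations in Angstrom,
    the three rotations in degrees).  Canonical pairs breathe with
    MD-like amplitudes; monitored pairs fluctuate tightly around their
    active substate template so that the H-bond pattern, not the
    noise, defines the state.
    """

    n_frames: int = 1000
    seed: int = 0
    temperature: float = 300.0
    pair_sd: Tuple[float, ...] = (0.25, 0.12, 0.3, 6.0, 6.0, 4.0)
    monitored_pair_sd: Tuple[float, ...] = (0.08, 0.08, 0.08, 2.5, 2.5, 2.5)
    step_sd: Tuple[float, ...] = (0.4, 0.3, 0.25, 3.0, 4.0, 4.0)
    switch_rate: float = 0.05
    stationary: Optional[Mapping[int, Sequence[float]]] = None
    use_md_twist: bool = False    # canonical twist 29.5 instead of 32.7

    def step_means(self) -> np.ndarray:
        base = np.array(A_RNA_STEP)
        if self.use_md_twist:
            base[5] = 29.5
        return base


def transition_matrix(stationary: Sequence[float],
                      switch_rate: float) -> np.ndarray:
    """Reversible chain ``P = (1-r) I + r 1 pi^T`` with the requested
    stationary distribution ``pi`` and per-frame switching rate ``r``."""
    pi = np.asarray(stationary, float)
    if pi.min() < 0 or not np.isclose(pi.sum(), 1.0):
        raise ValueError("stationary distribution must be a probability "
                         "vector summing to 1")
    P = (1.0 - switch_rate) * np.eye(len(pi)) \
        + switch_rate * np.ones((len(pi), 1)) * pi[None, :]
    return P


class Ensemble:
    """A generated duplex ensemble plus its generator truth.

    Coordinates are realized lazily from the stored pair/step
    parameters; the stored parameters and labels *are* the ground
    truth for recovery tests.
    """

    def __init__(self, spec: SequenceSpec, config: EnsembleConfig,
                 pair_parameters: np.ndarray, step_parameters: np.ndarray,
                 labels: Dict[int, np.ndarray],
                 templates: Dict[str, BaseTemplate]):
        self.spec = spec
        self.config = config
        self.pair_parameters = pair_parameters    # (F, n_pairs, 6)
        self.step_parameters = step_parameters    # (F, n_pairs-1, 6)
        self.labels = labels                      # pos -> (F,) label strings
        self.templates = templates

    @property
    def n_frames(self) -> int:
        return self.pair_parameters.shape[0]

    def mid_frames(self, frame: int) -> List[ReferenceFrame]:
        mids = [ReferenceFrame.identity()]
        for i in range(self.spec.n_pairs - 1):
            mids.append(compose_step(
                mids[-1], StepParams(i, *self.step_parameters[frame, i])))
        return mids

    def base_frames(self, frame: int) -> List[Tuple[ReferenceFrame,
                                                    ReferenceFrame]]:
        out = []
        for i, mid in enumerate(self.mid_frames(frame)):
            out.append(compose_pair(
                mid, PairParams(i, *self.pair_parameters[frame, i])))
        return out

    def pair_frames(self, frame: int, position: int
                    ) -> Tuple[ReferenceFrame, ReferenceFrame]:
        """Base frames of a single pair (walks the step chain only up
        to ``position``)."""
        mid = ReferenceFrame.identity()
        for i in range(position - 1):
            mid = compose_step(mid,
                               StepParams(i, *self.step_parameters[frame, i]))
        return compose_pair(
            mid, PairParams(position - 1,
                            *self.pair_parameters[frame, position - 1]))

    def pair_atoms(self, frame: int, position: int
                   ) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
        """Rebuilt atom coordinates of one pair (strand-1, strand-2 base)."""
        c1, c2 = self.spec.pair_codes(position)
        f1, f2 = self.pair_frames(frame, position)
        t1, t2 = self.templates[c1], self.templates[c2]
        from .basegeom import rebuild_atoms
        return rebuild_atoms(f1, t1), rebuild_atoms(f2, t2)

    def frame_atoms(self, frame: int
                    ) -> List[Tuple[Dict[str, np.ndarray],
                                    Dict[str, np.ndarray]]]:
        """Rebuilt atom coordinates of every pair in one frame."""
        from .basegeom import rebuild_atoms
        out = []
        for pos, (f1, f2) in enumerate(self.base_frames(frame), start=1):
            c1, c2 = self.spec.pair_codes(pos)
            out.append((rebuild_atoms(f1, self.templates[c1]),
                        rebuild_atoms(f2, self.templates[c2])))
        return out

    def phosphorus_coords(self) -> np.ndarray:
        """P-atom coordinates, shape (n_frames, 2*n_pairs, 3); strand-1
        residues first (5'->3'), then strand-2 in residue order."""
        n = self.spec.n_pairs
        out = np.empty((self.n_frames, 2 * n, 3))
        for f in range(self.n_frames):
            frames = self.base_frames(f)
            for i, (f1, f2) in enumerate(frames):
                out[f, i] = f1.apply(P_LOCAL)
                # strand-2 residue number 2n+1-(i+1) -> index n + (n-i-1)
                out[f, 2 * n - 1 - i] = f2.apply(P_LOCAL)
        return out

    def truth_dataframe(self) -> pd.DataFrame:
        """Per-frame generator truth for the monitored pairs."""
        rows = []
        for pos, labs in sorted(self.labels.items()):
            partner = self.spec.partner_residue(pos)
            shear = self.pair_parameters[:, pos - 1, 0]
            opening = self.pair_parameters[:, pos - 1, 5]
            for f in range(self.n_frames):
                rows.append((f, pos, partner, labs[f],
                             shear[f], opening[f]))
        return pd.DataFrame(
            rows, columns=["frame", "residue_i", "residue_u", "label",
                           "shear", "opening"])


def _stationary_for(spec: SequenceSpec, position: int) -> np.ndarray:
    nb = spec.five_prime_neighbour(position)
    row = TABLE1_STATIONARY.get(nb, TABLE1_STATIONARY["A"])
    pi = np.asarray(row, float)
    return pi / pi.sum()


def sample_ensemble(spec: SequenceSpec,
                    config: EnsembleConfig) -> Ensemble:
    """Draw a synthetic ensemble; identical config => identical output."""
    templates = load_templates()
    rng = np.random.default_rng(config.seed)
    n_pairs = spec.n_pairs
    F = config.n_frames
    if F < 1:
        raise ValueError("n_frames must be >= 1")

    iu = set(spec.inosine_positions)
    monitored = spec.monitored_pairs
    wobble = np.array(SUBSTATE_PAIR_PARAMS["A"])

    # --- per-pair canonical means
    pair_means = np.zeros((n_pairs, 6))
    for p in iu:
        pair_means[p - 1] = wobble

    # --- per-step means with twist redistribution around I-U pairs
    step_means = np.tile(config.step_means(), (n_pairs - 1, 1))
    for p in iu:
        if p >= 2 and (p - 1) not in iu:
            step_means[p - 2, 5] -= TWIST_COMPENSATION   # step 5' of wobble
        if p < n_pairs and (p + 1) not in iu:
            step_means[p - 1, 5] += TWIST_COMPENSATION   # step 3' of wobble

    # --- Markov switching of monitored pairs
    labels: Dict[int, np.ndarray] = {}
    label_idx: Dict[int, np.ndarray] = {}
    for pos in monitored:
        if config.stationary and pos in config.stationary:
            pi = np.asarray(config.stationary[pos], float)
            pi = pi / pi.sum()
        else:
            pi = _stationary_for(spec, pos)
        P = transition_matrix(pi, config.switch_rate)
        states = np.empty(F, dtype=np.int64)
        states[0] = rng.choice(6, p=pi)
        for f in range(1, F):
            states[f] = rng.choice(6, p=P[states[f - 1]])
        label_idx[pos] = states
        labels[pos] = np.array([_LABELS[s] for s in states])

    # --- parameter noise
    pair_sd = np.asarray(config.pair_sd, float)
    mon_sd = np.asarray(config.monitored_pair_sd, float)
    step_sd = np.asarray(config.step_sd, float)
    pair_parameters = (pair_means[None, :, :]
                       + rng.normal(size=(F, n_pairs, 6)) * pair_sd)
    step_parameters = (step_means[None, :, :]
                       + rng.normal(size=(F, n_pairs - 1, 6)) * step_sd)
    sub_means = np.array([SUBSTATE_PAIR_PARAMS[l] for l in _LABELS])
    for pos in monitored:
        noise = rng.normal(size=(F, 6)) * mon_sd
        pair_parameters[:, pos - 1, :] = sub_means[label_idx[pos]] + noise
    # the 3' pair of a tandem stays in the basic wobble but tightly so,
    # like the monitored pair -- it is an I-U pair, not a breather
    for pos in iu:
        if pos not in monitored:
            continue
        nxt = pos + 1
        if nxt in iu:
            noise = rng.normal(size=(F, 6)) * mon_sd
            pair_parameters[:, nxt - 1, :] = wobble + noise

    return Ensemble(spec, config, pair_parameters, step_parameters,
                    labels, templates)


def build_ideal_duplex(spec: SequenceSpec) -> Ensemble:
    """Single noise-free snapshot: canonical pairs at the A-form means,
    every I-U pair in the basic wobble geometry."""
    cfg = EnsembleConfig(n_frames=1, seed=0,
                         pair_sd=(0.0,) * 6,
                         monitored_pair_sd=(0.0,) * 6,
                         step_sd=(0.0,) * 6,
                         switch_rate=0.0,
                         stationary={p: (1, 0, 0, 0, 0, 0)
                                     for p in SYSTEMS.get(spec.system_name,
                                                          ())})
    ens = sample_ensemble(spec, cfg)
    # pin every monitored pair to the A template (no sampling ambiguity)
    for pos, labs in ens.labels.items():
        labs[:] = "A"
        ens.pair_parameters[:, pos - 1, :] = SUBSTATE_PAIR_PARAMS["A"]
    return ens


def write_truth(ensemble: Ensemble, path) -> None:
    """Write the generator truth (per-frame labels and monitored-pair
    parameters) as CSV."""
    ensemble.truth_dataframe().to_csv(path, index=False)
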