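"""Quasi-harmonic vibrational entropy and its infinite-sampling limit.

The vibrational entropy of a fluctuating selection of atoms (by
default the phosphorus backbone trace) is estimated from the
mass-weighted coordinate covariance matrix: each eigenvalue lambda
(amu A^2) defines a quasi-harmonic mode of angular frequency
omega = sqrt(kB T / lambda), and every mode contributes the quantum
harmonic-oscillator entropy

    S_mode / R = x / (exp(x) - 1) - ln(1 - exp(-x)),   x = hbar omega / kB T.

Frames are rigid-body superposed onto the first frame before the
covariance is accumulated (our synthetic ensembles have no global
drift, so this is nearly a no-op, but external ensembles need it).
Near-zero modes below an eigenvalue floor are excluded.

Because sampled covariances grow with observation time, S is computed
over nested windows and extrapolated against the reciprocal window
length; the intercept estimates the infinite-sampling entropy S_inf.
Entropies are in cal/mol/K.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import constants
from scipy.stats import linregress

__all__ = [
    "GAS_CONSTANT_CAL", "EIGENVALUE_FLOOR",
    "EntropyEstimate", "EntropyExtrapolation",
    "quasiharmonic_entropy", "windowed_extrapolation",
    "extrapolate_series",
]

#: Gas constant, cal/mol/K.
GAS_CONSTANT_CAL = constants.R / constants.calorie
#: Modes with mass-weighted covariance eigenvalue below this (amu A^2)
#: are treated as rigid-body/numerical-null modes and skipped.
EIGENVALUE_FLOOR = 1e-8


@dataclass(frozen=True)
class EntropyEstimate:
    window: Tuple[int, int]        # (start_frame, end_frame), end exclusive
    s_vib: float                   # cal/mol/K
    n_modes: int
    atom_selection: str = "P"


@dataclass(frozen=True)
class EntropyExtrapolation:
    estimates: Tuple[EntropyEstimate, ...]
    s_infinity: float              # cal/mol/K
    se_intercept: float
    slope: float


def _superpose(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted rigid-body superposition of every frame onto frame 0."""
    ref = coords[0]
    w = weights[:, None]
    ref_c = ref - (w * ref).sum(0) / weights.sum()
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        x = coords[f]
        x_c = x - (w * x).sum(0) / weights.sum()
        H = (x_c * w).T @ ref_c
        U, s, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        out[f] = x_c @ R.T
    return out


def _mode_entropy(lam_amu_a2: np.ndarray, temperature: float) -> float:
    """Sum of quantum HO entropies over modes, cal/mol/K."""
    lam_si = lam_amu_a2 * constants.atomic_mass * 1e-20   # kg m^2
    kt = constants.k * temperature
    omega = np.sqrt(kt / lam_si)
    x = constants.hbar * omega / kt
    s_per_r = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(GAS_CONSTANT_CAL * s_per_r.sum())


def quasiharmonic_entropy(coordinates: np.ndarray,
                          masses: Sequence[float],
                          temperature: float = 300.0,
                          superpose: bool = True,
                          eigenvalue_floor: float = EIGENVALUE_FLOOR,
                          ) -> float:
    """Quasi-harmonic vibrational entropy of an atom selection.

    Parameters
    ----------
    coordinates
        Array (n_frames, n_atoms, 3) in Angstrom.
    masses
        Atomic masses (amu), one per atom.
    superpose
        Remove global rotation/translation by superposing every frame
        onto the first before accumulating the covariance.

    Returns
    -------
    float
        S_vib in cal/mol/K (non-negative).

    Raises
    ------
    ValueError
        If fewer than 2 frames, or the covariance is fully rank
        deficient (all modes below the floor).
    """
    coords = np.asarray(coordinates, float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coordinates must have shape (frames, atoms, 3)")
    n_frames, n_atoms = coords.shape[:2]
    masses = np.asarray(masses, float)
    if n_frames < 2:
        raise ValueError(
            f"need at least 2 frames for a covariance, got {n_frames}; "
            f"{3 * n_atoms + 1} or more are required for full rank")
    if superpose:
        coords = _superpose(coords, masses)
    flat = coords.reshape(n_frames, 3 * n_atoms)
    mean = flat.mean(axis=0)
    dev = flat - mean
    w = np.sqrt(np.repeat(masses, 3))
    cov = (dev * w).T @ (dev * w) / n_frames          # amu A^2
    lam = np.linalg.eigvalsh(cov)
    lam = lam[lam > eigenvalue_floor]
    if lam.size == 0:
        return 0.0
    return _mode_entropy(lam, temperature)


def windowed_extrapolation(coordinates: np.ndarray,
                           masses: Sequence[float],
                           window_ends: Sequence[int],
                           window_start: int = 0,
                           temperature: float = 300.0,
                           superpose: bool = True,
                           ) -> EntropyExtrapolation:
    """Entropy over growing windows, extrapolated to infinite sampling.

    S_vib is computed over [window_start, end) for each end in
    ``window_ends`` and regressed linearly against the reciprocal
    window length; the intercept is S_inf, with the standard error of
    the intercept from the regression.

    Raises
    ------
    ValueError
        If fewer than 3 windows, or windows are not increasing.
    """
    ends = list(window_ends)
    if len(ends) < 3:
        raise ValueError("extrapolation needs at least 3 windows")
    if any(b <= a for a, b in zip(ends, ends[1:])):
        raise ValueError("window ends must be strictly increasing")
    estimates = []
    for end in ends:
        s = quasiharmonic_entropy(coordinates[window_start:end], masses,
                                  temperature, superpose=superpose)
        estimates.append(EntropyEstimate((window_start, end), s,
                                         n_modes=3 * coordinates.shape[1]))
    lengths = [e.window[1] - e.window[0] for e in estimates]
    s_infinity, se, slope = extrapolate_series(
        lengths, [e.s_vib for e in estimates])
    return EntropyExtrapolation(tuple(estimates), s_infinity, se, slope)


def extrapolate_series(window_lengths: Sequence[float],
                       s_values: Sequence[float]
                       ) -> Tuple[float, float, float]:
    """Regress entropy values against reciprocal window length.

    Returns ``(s_infinity, se_intercept, slope)``; for a series
    following S(t) = S_inf - c/t exactly the intercept recovers S_inf
    to machine precision.
    """
    lengths = np.asarray(window_lengths, float)
    s_vals = np.asarray(s_values, float)
    if lengths.size < 3:
        raise ValueError("extrapolation needs at least 3 windows")
    fit = linregress(1.0 / lengths, s_vals)
    se = float(fit.intercept_stderr)
    if not np.isfinite(se):       # perfect (e.g. constant) fit
        resid = s_vals - (fit.intercept + fit.slope / lengths)
        se = 0.0 if np.abs(resid).max() < 1e-9 else se
    return float(fit.intercept), se, float(fit.slope)
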