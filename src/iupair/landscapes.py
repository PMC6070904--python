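"""One-dimensional free-energy profiles by Boltzmann inversion.

Given unbiased samples of a base-pair coordinate (shear in Angstrom or
opening in degrees), the free-energy profile over a fixed grid is
G(bin) = -kT ln p(bin), anchored so the global minimum is zero.  The
default grids follow the convention used for the biased sampling the
profiles emulate: 100 bins over [-5, +5] A for shear and [-80, +80]
degrees for opening.  Bins with no samples are marked unsampled (NaN),
never zero.

Because the samples come from unbiased ensembles, barrier tops between
well-separated minima are sampled poorly and the profile is only
qualitative there; the positions of the minima are the robust output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BOLTZMANN_KCAL", "COORDINATE_RANGES",
    "FreeEnergyProfile", "boltzmann_invert", "find_minima",
    "coordinate_series",
]

#: Boltzmann constant, kcal/mol/K.
BOLTZMANN_KCAL = 0.0019872041

#: Default (lo, hi, n_bins) per coordinate.
COORDINATE_RANGES: Dict[str, Tuple[float, float, int]] = {
    "shear": (-5.0, 5.0, 100),
    "opening": (-80.0, 80.0, 100),
}


@dataclass(frozen=True)
class FreeEnergyProfile:
    coordinate_name: str
    bin_edges: np.ndarray          # (n_bins+1,)
    delta_g: np.ndarray            # kcal/mol, NaN where unsampled
    counts: np.ndarray             # samples per bin
    temperature: float             # K
    minima: Tuple[Tuple[float, float], ...] = ()   # (coordinate, dG)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def unsampled(self) -> np.ndarray:
        return self.counts == 0


def boltzmann_invert(samples: Sequence[float],
                     temperature: float = 300.0,
                     coordinate_name: str = "shear",
                     bin_range: Optional[Tuple[float, float, int]] = None,
                     ) -> FreeEnergyProfile:
    """Invert a sampled coordinate distribution into a free-energy
    profile, ``dG(bin) = -kT ln(p(bin)/p_max)``.

    Raises
    ------
    ValueError
        If no sample falls inside the coordinate range.
    """
    lo, hi, nb = bin_range or COORDINATE_RANGES[coordinate_name]
    samples = np.asarray(samples, float)
    counts, edges = np.histogram(samples, bins=nb, range=(lo, hi))
    if counts.sum() == 0:
        raise ValueError(
            f"no samples inside the {coordinate_name} range [{lo}, {hi}]")
    kt = BOLTZMANN_KCAL * temperature
    with np.errstate(divide="ignore"):
        dg = -kt * np.log(counts / counts.max())
    dg[counts == 0] = np.nan
    return FreeEnergyProfile(coordinate_name, edges, dg, counts, temperature)


def find_minima(profile: FreeEnergyProfile,
                smoothing_window: int = 3,
                min_prominence: float = 0.3,
                min_count: int = 5) -> FreeEnergyProfile:
    """Locate local minima of the profile.

    The profile is smoothed by a moving average over
    ``smoothing_window`` sampled bins; minima are wells of the
    smoothed profile with a prominence (barrier to the nearest deeper
    region) of at least ``min_prominence`` kcal/mol, which suppresses
    single-bin statistical dimples; a well bottom must also hold at
    least ``min_count`` samples, since a free energy cannot be
    estimated from a near-empty bin.  Unsampled stretches act as high
    barriers.  Minima carry the raw profile value at the detected bin
    and are sorted by depth, global minimum first, attached to a copy
    of the profile.
    """
    from scipy.signal import find_peaks

    sampled = ~profile.unsampled
    if sampled.sum() < 3:
        raise ValueError("need at least 3 sampled bins to locate minima")
    centers = profile.bin_centers
    half = smoothing_window // 2
    dg = profile.delta_g
    # moving average over sampled bins only
    smooth = np.full_like(dg, np.nan)
    idx = np.where(sampled)[0]
    for j, i in enumerate(idx):
        nb = idx[max(0, j - half):j + half + 1]
        smooth[i] = np.nanmean(dg[nb])
    ceiling = np.nanmax(smooth) + 10.0 * max(min_prominence, 1.0)
    filled = np.where(np.isnan(smooth), ceiling, smooth)
    padded = np.concatenate([[ceiling], filled, [ceiling]])
    peaks, _ = find_peaks(-padded, prominence=min_prominence)
    minima: List[Tuple[float, float]] = []
    for p in peaks - 1:
        if sampled[p] and profile.counts[p] >= min_count:
            minima.append((float(centers[p]), float(dg[p])))
    minima.sort(key=lambda m: m[1])
    from dataclasses import replace
    return replace(profile, minima=tuple(minima))


def coordinate_series(ensemble, position: int,
                      coordinate_name: str = "shear") -> np.ndarray:
    """Per-frame value of a pair coordinate for a monitored pair.

    Runs the full analysis path: rebuild the pair's atoms, fit base
    reference frames to them, and decompose into pair parameters.
    """
    from .basegeom import fit_frame
    from .helical import pair_params
    if coordinate_name not in ("shear", "opening"):
        raise ValueError("coordinate must be 'shear' or 'opening'")
    c1, c2 = ensemble.spec.pair_codes(position)
    t1 = ensemble.templates[c1]
    t2 = ensemble.templates[c2]
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        a1, a2 = ensemble.pair_atoms(f, position)
        pp = pair_params(fit_frame(a1, t1), fit_frame(a2, t2))
        out[f] = pp.shear if coordinate_name == "shear" else pp.opening
    return out
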