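"""Isomer-sensitive elution profiling with Man5-normalized retention.

PGC chromatography separates isobaric glycan structure isomers; a single
precursor mass bin therefore contains several retention-time modes, one
per isomer.  To compare runs, all retention times are expressed relative
to the apex retention time of the ubiquitously detected Man5
(Hex5HexNAc2) glycan in the same run: relative retention = rt / rt(Man5).
Profiles are built from deconvoluted MS1 features and resampled onto a
fixed relative-retention grid so profiles are directly comparable across
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .glycochem import Composition, precursor_mass
from .spectra_io import PrecursorFeature

MAN5 = Composition(hex=5, hexnac=2)
MAN5_MPLUSH = precursor_mass(MAN5, reduced=True, z=1)

DEFAULT_GRID_STEP = 0.005
DEFAULT_GRID_RANGE = (0.1, 3.0)


class Man5NotFoundError(ValueError):
    """No Man5 signal in the run; supply the reference time manually."""


def man5_rt(features: list[PrecursorFeature], tol: float = 0.05) -> float:
    """Apex retention time (s) of the Man5 mass trace."""
    hits = [f for f in features if abs(f.mass - MAN5_MPLUSH) <= tol]
    if not hits:
        raise Man5NotFoundError(
            "no Man5 (Hex5HexNAc2) feature within tolerance; pass the "
            "reference retention time explicitly"
        )
    return max(hits, key=lambda f: f.intensity).rt


def normalize_rt(rt: float, man5: float) -> float:
    """Relative retention: rt divided by the Man5 reference time."""
    if man5 <= 0:
        raise ValueError("Man5 reference time must be positive")
    return rt / man5


@dataclass
class ElutionProfile:
    """Intensity versus relative retention for one mass in one sample."""

    sample: str
    target_mass: float
    grid: np.ndarray        # relative-retention grid points
    intensity: np.ndarray   # summed intensity per grid point
    man5_rt: float

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def modes(self, min_fraction: float = 0.05) -> list[float]:
        """Relative retentions of local maxima above ``min_fraction`` of
        the profile maximum (the positions of isomer peaks)."""
        y = self.intensity
        if y.max() <= 0:
            return []
        thresh = min_fraction * y.max()
        out = []
        for i in range(len(y)):
            left = y[i - 1] if i > 0 else -np.inf
            right = y[i + 1] if i < len(y) - 1 else -np.inf
            if y[i] >= thresh and y[i] > left and y[i] >= right:
                out.append(float(self.grid[i]))
        return out


def _make_grid(step: float, grid_range: tuple[float, float]) -> np.ndarray:
    lo, hi = grid_range
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def elution_profile(target_mass: float, features: list[PrecursorFeature],
                    man5: float, tol: float = 0.05,
                    step: float = DEFAULT_GRID_STEP,
                    grid_range: tuple[float, float] = DEFAULT_GRID_RANGE,
                    smooth: bool = False,
                    sample: str = "") -> ElutionProfile:
    """Build the relative-retention intensity profile of one mass trace.

    Features within +/- ``tol`` of ``target_mass`` are placed at the
    nearest grid point (local summation, conserving total intensity).
    Optional moving-average smoothing (window 3) is off by default.
    """
    grid = _make_grid(step, grid_range)
    y = np.zeros_like(grid)
    hits = [f for f in features if abs(f.mass - target_mass) <= tol]
    if not hits:
        warnings.warn(f"no features within {tol} of {target_mass}",
                      stacklevel=2)
        return ElutionProfile(sample, target_mass, grid, y, man5)
    if not sample:
        samples = {f.sample for f in hits}
        sample = samples.pop() if len(samples) == 1 else ""
    lo = grid[0]
    for f in hits:
        rel = normalize_rt(f.rt, man5)
        i = int(round((rel - lo) / step))
        i = min(max(i, 0), len(grid) - 1)
        y[i] += f.intensity
    if smooth:
        kernel = np.ones(3) / 3.0
        y = np.convolve(y, kernel, mode="same")
    return ElutionProfile(sample, target_mass, grid, y, man5)


def profile_for_composition(comp: Composition,
                            features: list[PrecursorFeature],
                            man5: float, **kwargs) -> ElutionProfile:
    return elution_profile(precursor_mass(comp, reduced=True, z=1),
                           features, man5, **kwargs)


def profile_similarity(p: ElutionProfile, q: ElutionProfile) -> float:
    """Cosine similarity of two gridded profiles; 0 if either is empty."""
    if len(p.grid) != len(q.grid) or not np.allclose(p.grid, q.grid):
        raise ValueError("profiles are on different grids")
    np_, nq = np.linalg.norm(p.intensity), np.linalg.norm(q.intensity)
    if np_ == 0 or nq == 0:
        return 0.0
    return float(np.dot(p.intensity, q.intensity) / (np_ * nq))
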