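"""Precursor mass-bin aggregation: MS1 features -> quantitative histograms.

Deconvoluted MS1 features ([M+H]+ scale) are summed over the whole
chromatographic run onto a fixed mass grid (default 1000-5000 amu, bin
half-width 0.05, centers anchored at 1000.0 so that one-decimal printed
masses coincide with centers).  MS/MS spectra are charge-deconvoluted
onto the same scale and attached to their nearest bin, after which bins
are filtered by cumulative intensity and by the aggregated SNOG score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .msms_profiling import SpectrumScore
from .spectra_io import PrecursorFeature, RunConfig, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class MassBin:
    """One entry of the precursor mass histogram."""

    center: float
    intensity: float
    snog: float | None = None
    spectra: list[str] = field(default_factory=list)
    labels: set[str] = field(default_factory=set)
    annotations: list = field(default_factory=list)  # Composition candidates
    unknown: bool = False


@dataclass
class Histogram:
    """Ordered mass bins of one sample plus a config snapshot."""

    sample: str
    bins: list[MassBin]
    config: RunConfig
    normalized: bool = False

    @property
    def tic(self) -> float:
        return float(sum(b.intensity for b in self.bins))

    def __len__(self) -> int:
        return len(self.bins)

    def bin_at(self, center: float, tol: float = 1e-6) -> MassBin:
        for b in self.bins:
            if abs(b.center - center) <= tol:
                return b
        raise KeyError(f"no bin at {center}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "center_mass": [b.center for b in self.bins],
            "intensity": [b.intensity for b in self.bins],
            "snog": [b.snog if b.snog is not None else np.nan for b in self.bins],
            "n_spectra": [len(b.spectra) for b in self.bins],
            "labels": [";".join(sorted(b.labels)) for b in self.bins],
            "annotations": [
                ";".join(c.render() for c in b.annotations) for b in self.bins
            ],
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_histogram_tsv(path, sample: str, config: RunConfig | None = None) -> Histogram:
    """Load a histogram TSV written by :meth:`Histogram.write_tsv`."""
    from .glycochem import parse_composition

    df = pd.read_csv(path, sep="\t")
    cfg = config or RunConfig()
    bins = []
    for row in df.itertuples(index=False):
        labels = set()
        if "labels" in df.columns and isinstance(row.labels, str) and row.labels:
            labels = set(row.labels.split(";"))
        annotations = []
        if ("annotations" in df.columns and isinstance(row.annotations, str)
                and row.annotations):
            annotations = [parse_composition(t) for t in row.annotations.split(";")]
        bins.append(MassBin(
            center=float(row.center_mass),
            intensity=float(row.intensity),
            snog=None if pd.isna(row.snog) else float(row.snog),
            labels=labels,
            annotations=annotations,
        ))
    bins.sort(key=lambda b: b.center)
    return Histogram(sample=sample, bins=bins, config=cfg)


def grid_center(mass: float, cfg: RunConfig) -> float:
    """Nearest grid center (``bin_low + k * bin_width``) to ``mass``."""
    k = round((mass - cfg.bin_low) / cfg.bin_width)
    return cfg.bin_low + k * cfg.bin_width


def bin_features(features: list[PrecursorFeature], cfg: RunConfig,
                 sample: str | None = None) -> Histogram:
    """Sum feature intensities onto the fixed mass grid.

    Each feature goes to its nearest grid center; features whose nearest
    center falls outside [bin_low, bin_high] are dropped (counted in the
    log).  Summation runs over the entire chromatographic time range.
    """
    if sample is None:
        samples = {f.sample for f in features}
        sample = samples.pop() if len(samples) == 1 else ""
    sums: dict[int, float] = {}
    dropped = 0
    for f in features:
        k = round((f.mass - cfg.bin_low) / cfg.bin_width)
        center = cfg.bin_low + k * cfg.bin_width
        if center < cfg.bin_low - 1e-9 or center > cfg.bin_high + 1e-9:
            dropped += 1
            continue
        sums[k] = sums.get(k, 0.0) + f.intensity
    if dropped:
        logger.info("%s: dropped %d out-of-range features", sample, dropped)
    bins = [
        MassBin(center=cfg.bin_low + k * cfg.bin_width, intensity=v)
        for k, v in sorted(sums.items())
    ]
    return Histogram(sample=sample, bins=bins, config=cfg)


def threshold(hist: Histogram, min_intensity: float | None = None) -> Histogram:
    """Remove bins whose cumulative intensity is strictly below threshold."""
    if min_intensity is None:
        min_intensity = hist.config.intensity_threshold
    kept = [b for b in hist.bins if b.intensity >= min_intensity]
    if not kept and hist.bins:
        warnings.warn(
            f"{hist.sample}: all bins below intensity threshold", stacklevel=2
        )
    return replace(hist, bins=kept)


def attach_spectra(hist: Histogram, spectra: list[Spectrum],
                   scores: dict[str, SpectrumScore],
                   tol: float | None = None) -> Histogram:
    """Assign each MS/MS spectrum to its nearest bin center within ``tol``.

    The spectrum precursor is charge-deconvoluted onto the [M+H]+ scale
    first.  Unknown-charge spectra are skipped and logged; unassigned
    spectra are counted.
    """
    if tol is None:
        tol = hist.config.match_tolerance
    if not hist.bins:
        return hist
    centers = np.array([b.center for b in hist.bins])
    new_bins = [replace(b, spectra=list(b.spectra)) for b in hist.bins]
    skipped = unassigned = 0
    for s in spectra:
        if s.charge is None:
            skipped += 1
            continue
        mass = s.precursor_mass()
        i = int(np.searchsorted(centers, mass))
        best, dist = None, np.inf
        for j in (i - 1, i):
            if 0 <= j < len(centers) and abs(centers[j] - mass) < dist:
                best, dist = j, abs(centers[j] - mass)
        if best is None or dist > tol:
            unassigned += 1
            continue
        new_bins[best].spectra.append(s.id)
    if skipped:
        logger.info("%s: skipped %d unknown-charge spectra", hist.sample, skipped)
    if unassigned:
        logger.info("%s: %d spectra matched no bin", hist.sample, unassigned)
    return replace(hist, bins=new_bins)


def bin_snog(massbin: MassBin, scores: dict[str, SpectrumScore],
             weights: dict[str, float] | None = None,
             aggregate: str = "mean") -> float | None:
    """Aggregate per-spectrum SNOG values of a bin.

    Intensity-weighted mean using triggering-precursor intensities when
    available (uniform otherwise); ``aggregate='max'`` takes the maximum.
    """
    vals, ws = [], []
    for sid in massbin.spectra:
        if sid in scores:
            vals.append(scores[sid].snog)
            ws.append(weights.get(sid, 1.0) if weights else 1.0)
    if not vals:
        return None
    if aggregate == "max":
        return max(vals)
    total_w = sum(ws)
    if total_w <= 0:
        ws = [1.0] * len(vals)
        total_w = float(len(vals))
    return sum(v * w for v, w in zip(vals, ws)) / total_w


def snog_filter(hist: Histogram, scores: dict[str, SpectrumScore],
                cutoff: float | None = None,
                spectra: list[Spectrum] | None = None,
                aggregate: str = "mean") -> Histogram:
    """Reject bins with no attached spectra or aggregated SNOG below cutoff.

    ``spectra`` (optional) supplies triggering-scan precursor intensities
    for the weighted mean; without them weights are uniform.
    """
    if cutoff is None:
        cutoff = hist.config.snog_cutoff
    weights = None
    if spectra is not None:
        weights = {
            s.id: s.precursor_intensity
            for s in spectra if s.precursor_intensity is not None
        }
    kept = []
    for b in hist.bins:
        val = bin_snog(b, scores, weights, aggregate)
        if val is None or val < cutoff:
            continue
        kept.append(replace(b, snog=val))
    return replace(hist, bins=kept)


def tic_normalize(hist: Histogram) -> Histogram:
    """Divide every bin intensity by the histogram TIC (sums to 1)."""
    tic = hist.tic
    if tic <= 0:
        raise ValueError(f"{hist.sample}: zero TIC, cannot normalize")
    bins = [replace(b, intensity=b.intensity / tic) for b in hist.bins]
    return replace(hist, bins=bins, normalized=True)
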