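"""End-to-end convenience: features + spectra -> filtered, scored histogram.

The canonical processing order: bin MS1 features over the whole run,
apply the cumulative intensity threshold, attach charge-deconvoluted
MS/MS spectra, then reject bins whose aggregated SNOG score falls below
the cut-off.
"""

from __future__ import annotations

from .glycochem import Registry, default_registry
from .msms_profiling import SpectrumScore, score_spectra
from .precursor_aggregation import (
    Histogram, attach_spectra, bin_features, snog_filter, threshold,
)
from .spectra_io import PrecursorFeature, RunConfig, Spectrum


def process_sample(features: list[PrecursorFeature],
                   spectra: list[Spectrum],
                   cfg: RunConfig | None = None,
                   registry: Registry | None = None,
                   ) -> tuple[Histogram, dict[str, SpectrumScore]]:
    """Run binning, intensity thresholding, spectrum attachment and SNOG
    filtering for one sample; returns the filtered histogram and the
    per-spectrum scores (needed downstream by stratification)."""
    cfg = cfg or RunConfig()
    registry = registry or default_registry()
    scores = score_spectra(spectra, registry, cfg.match_tolerance)
    hist = bin_features(features, cfg)
    hist = threshold(hist)
    hist = attach_spectra(hist, spectra, scores)
    hist = snog_filter(hist, scores, spectra=spectra)
    return hist, scores
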