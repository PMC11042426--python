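"""Precursor-independent MS/MS profiling.

The SNOG score of a spectrum is the intensity of the reduced-GlcNAc
oxonium ion (224.1118 amu, the tell-tale fragment of a chemically
reduced N-glycan) relative to the spectrum's total ion current; spectra
scoring below 0.03 are treated as non-glycan.  eSNOG scores are the same
ratio computed for any other sub-structure-specific diagnostic ion, each
with its own empirical cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .glycochem import DiagnosticIon, Registry
from .spectra_io import Spectrum

DEFAULT_TOLERANCE = 0.05  # amu, fragment matching window


class UndefinedScoreError(ValueError):
    """Raised when a score denominator is zero (all-zero spectrum)."""


def ion_intensity(spectrum: Spectrum, mz: float, tol: float = DEFAULT_TOLERANCE) -> float:
    """Summed intensity of all peaks within ``[mz - tol, mz + tol]``."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    lo = np.searchsorted(spectrum.mz, mz - tol, side="left")
    hi = np.searchsorted(spectrum.mz, mz + tol, side="right")
    return float(spectrum.intensity[lo:hi].sum())


def esnog(spectrum: Spectrum, ion: DiagnosticIon,
          tol: float = DEFAULT_TOLERANCE) -> float:
    """Relative intensity of a diagnostic ion: ion TIC / spectrum TIC."""
    total = spectrum.total_intensity
    if total <= 0:
        raise UndefinedScoreError(f"{spectrum.id}: spectrum has zero TIC")
    return ion_intensity(spectrum, ion.mz, tol) / total


def snog(spectrum: Spectrum, registry: Registry,
         tol: float = DEFAULT_TOLERANCE) -> float:
    """SNOG score: eSNOG of the reduced-GlcNAc (224.1118) ion."""
    return esnog(spectrum, registry.n_glycan_ion, tol)


@dataclass
class SpectrumScore:
    """All diagnostic-ion scores of one spectrum."""

    spectrum_id: str
    snog: float
    esnog: dict[str, float]
    ions_present: frozenset[str]

    def passes(self, ion: DiagnosticIon) -> bool:
        return self.esnog.get(ion.name, 0.0) >= ion.esnog_cutoff


def score_spectrum(spectrum: Spectrum, registry: Registry,
                   tol: float = DEFAULT_TOLERANCE) -> SpectrumScore:
    scores = {ion.name: esnog(spectrum, ion, tol) for ion in registry}
    present = frozenset(n for n, v in scores.items() if v > 0)
    return SpectrumScore(
        spectrum_id=spectrum.id,
        snog=scores[registry.n_glycan_ion.name],
        esnog=scores,
        ions_present=present,
    )


def score_spectra(spectra: list[Spectrum], registry: Registry,
                  tol: float = DEFAULT_TOLERANCE) -> dict[str, SpectrumScore]:
    """Score every spectrum; keyed by spectrum id."""
    return {s.id: score_spectrum(s, registry, tol) for s in spectra}


@dataclass
class ProfileReport:
    """Per-sample diagnostic-ion spectral-count profile.

    ``fractions`` are normalized to the number of N-glycan-derived
    spectra (those containing the 224.1118 ion), the convention used for
    relative spectral counts; ``fractions_total`` uses all spectra.
    ``rt_counts`` maps ion name -> {bin start (s) -> spectrum count}.
    """

    sample: str
    total_spectra: int
    n_glycan_spectra: int
    ion_counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    fractions_total: dict[str, float] = field(default_factory=dict)
    rt_counts: dict[str, dict[float, int]] = field(default_factory=dict)
    normalizer_defined: bool = True


def profile(spectra: list[Spectrum], registry: Registry,
            rt_bin: float = 10.0, tol: float = DEFAULT_TOLERANCE) -> ProfileReport:
    """Count spectra containing each diagnostic ion, overall and per RT bin."""
    samples = {s.sample for s in spectra}
    if len(samples) > 1:
        raise ValueError(f"profile expects one sample, got {sorted(samples)}")
    sample = samples.pop() if samples else ""
    report = ProfileReport(sample=sample, total_spectra=len(spectra),
                           n_glycan_spectra=0)
    if not spectra:
        report.normalizer_defined = False
        return report

    n_glycan_name = registry.n_glycan_ion.name
    counts = {ion.name: 0 for ion in registry}
    rt_counts: dict[str, dict[float, int]] = {ion.name: {} for ion in registry}
    for s in spectra:
        bin_start = math.floor(s.rt / rt_bin) * rt_bin
        for ion in registry:
            if ion_intensity(s, ion.mz, tol) > 0:
                counts[ion.name] += 1
                bins = rt_counts[ion.name]
                bins[bin_start] = bins.get(bin_start, 0) + 1
    report.ion_counts = counts
    report.rt_counts = rt_counts
    report.n_glycan_spectra = counts[n_glycan_name]
    report.fractions_total = {
        n: c / len(spectra) for n, c in counts.items()
    }
    if report.n_glycan_spectra > 0:
        report.fractions = {
            n: c / report.n_glycan_spectra for n, c in counts.items()
        }
    else:
        report.normalizer_defined = False
        report.fractions = {n: float("nan") for n in counts}
    return report
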