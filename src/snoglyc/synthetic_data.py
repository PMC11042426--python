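"""Synthetic LC-MS/MS fixture generator with exact ground truth.

Emulates the data shape the analysis workflow consumes: deconvoluted
MS1 feature tables ([M+H]+ scale) and DDA MS/MS spectra whose fragment
content reflects each glycan's sub-structural features.  Every N-glycan
spectrum contains the reduced-end GlcNAc oxonium (224.1118) plus the
diagnostic ions implied by its feature tags; contaminant spectra mimic
glycogen-degradation hexose oligomers (a Hex ion ladder, no 224.1118).

Ground truth records, per sample: expected mass-bin centers, feature
tags and category labels per bin, realized TIC fractions per tag and
label, isomer mode positions (Man5-relative), and contaminant bins.
Mass jitter is drawn from a truncated normal so that no feature can
cross a mass-bin boundary; retention-time structure places each isomer
mode at a fixed Man5-relative position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .glycochem import PROTON, Composition, Registry, default_registry, precursor_mass
from .precursor_aggregation import grid_center
from .spectra_io import PrecursorFeature, RunConfig, Spectrum

#: feature tag -> positive stratification category it implies
TAG_TO_CATEGORY = {
    "fucose_antenna": "distal_fucose",
    "neu5ac": "neu5ac",
    "neu5gc": "neu5gc",
    "alpha_gal": "alpha_gal",
}

#: relative intensity of each tag's diagnostic ion within a spectrum
_TAG_ION_HEIGHT = 0.08
_BASE_PEAKS = (  # (m/z, relative intensity): generic glycan fragments
    (204.0867, 0.15),   # HexNAc oxonium
    (224.1118, 0.25),   # reduced-end GlcNAc (SNOG numerator)
    (366.1395, 0.12),   # LacNAc
)
_FILLER_PEAKS = (  # uninformative peaks away from every diagnostic window
    (150.0, 0.10), (300.0, 0.10), (400.0, 0.06), (450.0, 0.04),
)
_HEX_LADDER = (163.0601, 325.1129, 487.1657, 649.2186, 811.2714)

_HEX = 162.05282
_REDUCED_END = 18.01056 + 2.01565 + PROTON  # water + 2H + proton


def hexose_oligomer_mass(n: int) -> float:
    """[M+H]+ of a reduced hexose n-mer (glycogen-like contaminant)."""
    return n * _HEX + _REDUCED_END


@dataclass(frozen=True)
class GlycanSpec:
    """One glycan in a sample: abundance, features, isomer modes."""

    composition: Composition
    intensity: float
    tags: tuple[str, ...] = ()
    modes: tuple[tuple[float, float], ...] = ((1.0, 1.0),)  # (rel rt, weight)

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("glycan intensity must be positive")
        w = sum(m[1] for m in self.modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mode weights must sum to 1, got {w}")


@dataclass(frozen=True)
class SampleSpec:
    """Recipe for one synthetic sample."""

    label: str
    glycans: tuple[GlycanSpec, ...]
    man5_rt: float = 900.0
    contaminant_intensity: float = 0.0
    contaminant_lengths: tuple[int, ...] = (7, 8, 9, 10, 11, 12)
    features_per_mode: int = 3
    spectra_per_mode: int = 2
    intensity_cv: float = 0.10
    mz_jitter_sd: float = 0.005
    mz_jitter_max: float = 0.008  # truncation bound, keeps bins sharp
    rt_jitter_sd: float = 1.0     # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.man5_rt <= 0:
            raise ValueError("man5_rt must be positive")
        if self.mz_jitter_sd > 0.01:
            raise ValueError("mz jitter SD capped at 0.01 amu")


@dataclass
class BinTruth:
    center: float
    composition: Composition
    tags: tuple[str, ...]
    intensity: float            # realized summed MS1 intensity
    expected_labels: set[str]
    mode_positions: tuple[float, ...]


@dataclass
class GroundTruth:
    sample: str
    man5_rt: float
    glycan_bins: dict[float, BinTruth] = field(default_factory=dict)
    contaminant_bins: dict[float, float] = field(default_factory=dict)
    tag_fractions: dict[str, float] = field(default_factory=dict)
    label_fractions: dict[str, float] = field(default_factory=dict)
    total_glycan_intensity: float = 0.0
    total_contaminant_intensity: float = 0.0


@dataclass
class SimulationResult:
    features: list[PrecursorFeature]
    spectra: list[Spectrum]
    truth: GroundTruth


def _expected_labels(g: GlycanSpec) -> set[str]:
    labels = {TAG_TO_CATEGORY[t] for t in g.tags if t in TAG_TO_CATEGORY}
    c = g.composition
    if (c.hexnac == 2 and 4 <= c.hex <= 9 and c.dhex == 0
            and c.neu5ac == 0 and c.neu5gc == 0):
        labels.add("oligomannose")
    if not labels:
        labels.add("undecorated")
    return labels


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float) -> float:
    if sd <= 0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= bound:
            return float(x)


def _glycan_peaks(g: GlycanSpec, registry: Registry,
                  rng: np.random.Generator, cv: float,
                  jitter_sd: float, jitter_max: float,
                  scale: float) -> tuple[np.ndarray, np.ndarray]:
    peaks = list(_BASE_PEAKS) + list(_FILLER_PEAKS)
    for tag in g.tags:
        for ion in registry.by_feature(tag):
            peaks.append((ion.mz, _TAG_ION_HEIGHT))
    mzs, ints = [], []
    for mz, h in peaks:
        mzs.append(mz + _truncated_normal(rng, jitter_sd, jitter_max))
        ints.append(max(h * scale * (1.0 + cv * rng.normal()), 1e-3 * scale))
    return np.array(mzs), np.array(ints)


def simulate(spec: SampleSpec,
             registry: Registry | None = None,
             cfg: RunConfig | None = None) -> SimulationResult:
    """Generate MS1 features, MS/MS spectra and ground truth for a sample.

    Deterministic for a fixed ``spec`` (the seed fixes all randomness).
    Raises if any glycan or contaminant mass lies too close to a mass-bin
    edge for the configured jitter, or if a contaminant bin collides with
    a glycan bin.
    """
    registry = registry or default_registry()
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(spec.seed)
    features: list[PrecursorFeature] = []
    spectra: list[Spectrum] = []
    truth = GroundTruth(sample=spec.label, man5_rt=spec.man5_rt)

    def home_bin(mass: float, what: str) -> tuple[float, float]:
        """Grid center and per-mass jitter bound keeping features in-bin."""
        center = grid_center(mass, cfg)
        margin = cfg.bin_half_width - abs(mass - center)
        if margin <= 1e-4:
            raise ValueError(
                f"{what}: mass {mass:.4f} sits on a bin edge; adjust the "
                "composition or the grid"
            )
        return round(center, 6), min(spec.mz_jitter_max, 0.9 * margin)

    for g in spec.glycans:
        mass = precursor_mass(g.composition, reduced=True, z=1)
        center, jitter_bound = home_bin(mass, g.composition.render())
        realized = 0.0
        z = 3 if mass > 2500 else 2
        prec_mz = (mass - PROTON) / z + PROTON
        for m_idx, (rel, weight) in enumerate(g.modes):
            rt_center = rel * spec.man5_rt
            per_feature = g.intensity * weight / spec.features_per_mode
            for i in range(spec.features_per_mode):
                inten = max(per_feature * (1.0 + spec.intensity_cv * rng.normal()),
                            0.01 * per_feature)
                realized += inten
                features.append(PrecursorFeature(
                    mass=mass + _truncated_normal(rng, spec.mz_jitter_sd,
                                                  jitter_bound),
                    rt=max(rt_center + rng.normal(0.0, spec.rt_jitter_sd), 0.0),
                    intensity=inten,
                    sample=spec.label,
                ))
            for i in range(spec.spectra_per_mode):
                mzs, ints = _glycan_peaks(
                    g, registry, rng, spec.intensity_cv,
                    spec.mz_jitter_sd, spec.mz_jitter_max, scale=1e4)
                spectra.append(Spectrum(
                    id=f"{spec.label}.{g.composition.render()}.m{m_idx}.s{i}",
                    precursor_mz=prec_mz,
                    charge=z,
                    rt=max(rt_center + rng.normal(0.0, spec.rt_jitter_sd), 0.0),
                    mz=mzs,
                    intensity=ints,
                    sample=spec.label,
                    precursor_intensity=per_feature,
                ))
        truth.glycan_bins[center] = BinTruth(
            center=center,
            composition=g.composition,
            tags=g.tags,
            intensity=realized,
            expected_labels=_expected_labels(g),
            mode_positions=tuple(m[0] for m in g.modes),
        )
        truth.total_glycan_intensity += realized

    if spec.contaminant_intensity > 0:
        per_bin = spec.contaminant_intensity / len(spec.contaminant_lengths)
        for n in spec.contaminant_lengths:
            mass = hexose_oligomer_mass(n)
            center, jitter_bound = home_bin(mass, f"hexose oligomer n={n}")
            if center in truth.glycan_bins:
                raise ValueError(
                    f"contaminant bin {center} collides with a glycan bin"
                )
            realized = 0.0
            z = 2
            prec_mz = (mass - PROTON) / z + PROTON
            rt_center = rng.uniform(0.3, 0.9) * spec.man5_rt
            for i in range(spec.features_per_mode):
                inten = max(per_bin / spec.features_per_mode
                            * (1.0 + spec.intensity_cv * rng.normal()), 1.0)
                realized += inten
                features.append(PrecursorFeature(
                    mass=mass + _truncated_normal(rng, spec.mz_jitter_sd,
                                                  jitter_bound),
                    rt=max(rt_center + rng.normal(0.0, spec.rt_jitter_sd), 0.0),
                    intensity=inten,
                    sample=spec.label,
                ))
            for i in range(spec.spectra_per_mode):
                mzs, ints = [], []
                for mz in _HEX_LADDER:
                    mzs.append(mz + _truncated_normal(
                        rng, spec.mz_jitter_sd, spec.mz_jitter_max))
                    ints.append(max(1e3 * (1.0 + spec.intensity_cv * rng.normal()),
                                    1.0))
                spectra.append(Spectrum(
                    id=f"{spec.label}.hexose{n}.s{i}",
                    precursor_mz=prec_mz,
                    charge=z,
                    rt=max(rt_center + rng.normal(0.0, spec.rt_jitter_sd), 0.0),
                    mz=np.array(mzs),
                    intensity=np.array(ints),
                    sample=spec.label,
                    precursor_intensity=per_bin,
                ))
            truth.contaminant_bins[center] = realized
            truth.total_contaminant_intensity += realized

    total = truth.total_glycan_intensity
    tags = sorted({t for b in truth.glycan_bins.values() for t in b.tags})
    truth.tag_fractions = {
        t: sum(b.intensity for b in truth.glycan_bins.values() if t in b.tags) / total
        for t in tags
    }
    labels = sorted({l for b in truth.glycan_bins.values()
                     for l in b.expected_labels})
    truth.label_fractions = {
        l: sum(b.intensity for b in truth.glycan_bins.values()
               if l in b.expected_labels) / total
        for l in labels
    }
    features.sort(key=lambda f: (f.rt, f.mass))
    return SimulationResult(features=features, spectra=spectra, truth=truth)


def _comp(text: str) -> Composition:
    from .glycochem import parse_composition
    return parse_composition(text)


def mouse_panel(seed: int = 0) -> list[SampleSpec]:
    """A six-sample toy panel echoing headline tissue contrasts.

    Serum-like (Neu5Gc-dominated), brain-like (Neu5Ac + bisecting +
    di-sialyl Lewis C + sulfated HNK-1), kidney-like (distal fucose,
    HNK-1, fucosylated LacdiNAc), pancreas-like (alpha-Gal + sulfated
    HexNAc), seminal-vesicle-like (Lewis Y, low sialylation), and
    liver-like (heavy hexose-oligomer contamination: most raw bins are
    contaminant-only and must be SNOG-rejected).
    """
    man5 = GlycanSpec(_comp("Man5"), 1.5e7)
    specs = [
        SampleSpec(
            label="serum_like",
            glycans=(
                man5,
                GlycanSpec(_comp("Hex5HexNAc4Neu5Gc1"), 5e7, ("neu5gc",)),
                GlycanSpec(_comp("Hex5HexNAc4Neu5Gc2"), 4e7, ("neu5gc",),
                           modes=((1.4, 1.0),)),
                GlycanSpec(_comp("Hex5HexNAc4Fuc1Neu5Ac2"), 1e7, ("neu5ac",),
                           modes=((1.25, 0.6), (1.45, 0.4))),
            ),
            seed=(seed * 101 + 1) % 2**31,
        ),
        SampleSpec(
            label="brain_like",
            glycans=(
                man5,
                GlycanSpec(_comp("Hex5HexNAc5Fuc1Neu5Ac2"), 3e7,
                           ("neu5ac", "bisecting")),
                GlycanSpec(_comp("Hex4HexNAc3Fuc1Neu5Ac1"), 2e7, ("neu5ac",)),
                GlycanSpec(_comp("Hex5HexNAc4Fuc3"), 2e7, ("fucose_antenna",),
                           modes=((0.9, 0.5), (1.3, 0.5))),
                GlycanSpec(_comp("Hex5HexNAc4Fuc1Neu5Ac4"), 1e7,
                           ("neu5ac", "disialyl_lewis_c_ac")),
                GlycanSpec(_comp("Hex5HexNAc4HexA1SO41"), 0.8e7,
                           ("hnk1", "hnk1_sulfo")),
            ),
            seed=(seed * 101 + 2) % 2**31,
        ),
        SampleSpec(
            label="kidney_like",
            glycans=(
                man5,
                GlycanSpec(_comp("Hex5HexNAc4Fuc3"), 3.5e7, ("fucose_antenna",),
                           modes=((0.9, 0.6), (1.3, 0.4))),
                GlycanSpec(_comp("Hex6HexNAc6Fuc3HexA1"), 1e7,
                           ("hnk1", "fucose_antenna")),
                GlycanSpec(_comp("Hex5HexNAc4Fuc1Neu5Ac2"), 2e7, ("neu5ac",),
                           modes=((1.25, 0.6), (1.45, 0.4))),
                GlycanSpec(_comp("Hex5HexNAc4Fuc1Neu5Gc2"), 2e7, ("neu5gc",),
                           modes=((1.4, 1.0),)),
                GlycanSpec(_comp("Hex4HexNAc5Fuc2"), 0.8e7, ("lacdinac_fuc",)),
            ),
            seed=(seed * 101 + 3) % 2**31,
        ),
        SampleSpec(
            label="pancreas_like",
            glycans=(
                man5,
                GlycanSpec(_comp("Hex7HexNAc4Fuc1"), 3e7, ("alpha_gal",)),
                GlycanSpec(_comp("Hex6HexNAc4Fuc1"), 2e7, ("alpha_gal",)),
                GlycanSpec(_comp("Hex5HexNAc4Fuc1SO41"), 0.8e7,
                           ("sulfo_hexnac",)),
                GlycanSpec(_comp("Hex5HexNAc4Fuc1Neu5Gc1"), 1.5e7, ("neu5gc",)),
            ),
            seed=(seed * 101 + 4) % 2**31,
        ),
        SampleSpec(
            label="seminal_like",
            glycans=(
                man5,
                GlycanSpec(_comp("Hex5HexNAc4Fuc4"), 3e7,
                           ("fucose_antenna", "lewis_y")),
                GlycanSpec(_comp("Hex6HexNAc5Fuc5"), 1.5e7,
                           ("fucose_antenna", "lewis_y")),
                GlycanSpec(_comp("Hex7HexNAc5Fuc3"), 2.5e7,
                           ("fucose_antenna", "alpha_gal")),
                GlycanSpec(_comp("Hex5HexNAc4Fuc1Neu5Ac2"), 0.8e7, ("neu5ac",)),
            ),
            seed=(seed * 101 + 5) % 2**31,
        ),
        SampleSpec(
            label="liver_like",
            glycans=(
                man5,
                GlycanSpec(_comp("Hex5HexNAc4Fuc1Neu5Gc2"), 2e7, ("neu5gc",),
                           modes=((1.4, 1.0),)),
                GlycanSpec(_comp("Hex5HexNAc4Fuc1Neu5Gc1Ac1"), 0.9e7,
                           ("neu5gc", "oac_neu5gc")),
            ),
            contaminant_intensity=6e7,
            seed=(seed * 101 + 6) % 2**31,
        ),
    ]
    return specs


def replicate(spec: SampleSpec, index: int) -> SampleSpec:
    """A replicate of a sample: same recipe, different noise seed."""
    return replace(spec, label=f"{spec.label}_{index}",
                   seed=(spec.seed * 7919 + index) % 2**31)
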