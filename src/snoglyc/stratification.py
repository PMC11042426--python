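"""eSNOG-based stratification of mass bins and rare-epitope screening.

A bin acquires a category label when at least one of its attached MS/MS
spectra carries the category's diagnostic ion above the per-ion eSNOG
cut-off (multi-label: categories may overlap, so TIC fractions can sum
past 100%).  Oligomannose is assigned from the composition annotation
(HexNAc = 2, Hex 4-9) rather than from a fragment ion; "undecorated" is
the complement of the five positive categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import pandas as pd

from .glycochem import Composition, Registry
from .msms_profiling import SpectrumScore
from .precursor_aggregation import Histogram, MassBin

POSITIVE_CATEGORIES = (
    "distal_fucose", "neu5gc", "neu5ac", "alpha_gal", "oligomannose",
)

#: rare/non-canonical epitope tag -> qualifying registry features
RARE_FEATURES: dict[str, tuple[str, ...]] = {
    "hnk1": ("hnk1",),
    "hnk1_sulfo": ("hnk1_sulfo",),
    "sulfo_hexnac": ("sulfo_hexnac",),
    "lacdinac_fuc": ("lacdinac_fuc",),
    "lewis_y": ("lewis_y",),
    "disialyl_lewis_c_ac": ("disialyl_lewis_c_ac",),
    "disialyl_lewis_c_gc": ("disialyl_lewis_c_gc",),
    "oac_neu5ac": ("oac_neu5ac",),
    "oac_neu5gc": ("oac_neu5gc",),
    "sda": ("sda",),
    "sia_hexnac": ("sia_hexnac_ac", "sia_hexnac_gc"),
}


def _is_oligomannose(c: Composition) -> bool:
    return (c.hexnac == 2 and 4 <= c.hex <= 9 and c.dhex == 0
            and c.neu5ac == 0 and c.neu5gc == 0)


@dataclass(frozen=True)
class CategoryRule:
    """One stratification category: qualifying ions and/or a predicate."""

    label: str
    features: tuple[str, ...] = ()
    predicate: Callable[[Composition], bool] | None = None

    def __post_init__(self) -> None:
        if not self.features and self.predicate is None:
            raise ValueError(f"rule {self.label}: needs ions or a predicate")


def default_rules() -> list[CategoryRule]:
    """The six-category scheme: five positive categories + complement.

    Either the intact sialic-acid oxonium or its water-loss ion
    qualifies for the two sialylation categories.
    """
    return [
        CategoryRule("distal_fucose", features=("fucose_antenna",)),
        CategoryRule("neu5gc", features=("neu5gc",)),
        CategoryRule("neu5ac", features=("neu5ac",)),
        CategoryRule("alpha_gal", features=("alpha_gal",)),
        CategoryRule("oligomannose", predicate=_is_oligomannose),
    ]


def classify(hist: Histogram, scores: dict[str, SpectrumScore],
             registry: Registry, rules: list[CategoryRule] | None = None,
             min_spectra: int = 1) -> Histogram:
    """Label each bin with every category it qualifies for.

    Ion categories need >= ``min_spectra`` attached spectra passing the
    per-ion cut-off; predicate categories consult the bin's composition
    annotations.  Bins carrying none of the positive labels are labeled
    "undecorated".
    """
    if rules is None:
        rules = default_rules()
    if not scores and any(r.features for r in rules):
        raise ValueError("classification requires spectrum scores")
    ions_by_feature = {
        feat: registry.by_feature(feat)
        for rule in rules for feat in rule.features
    }
    new_bins = []
    for b in hist.bins:
        labels: set[str] = set()
        bin_scores = [scores[sid] for sid in b.spectra if sid in scores]
        for rule in rules:
            hit = False
            if rule.features:
                n_pass = sum(
                    1 for sc in bin_scores
                    if any(sc.passes(ion)
                           for feat in rule.features
                           for ion in ions_by_feature[feat])
                )
                hit = n_pass >= min_spectra
            if not hit and rule.predicate is not None:
                hit = any(rule.predicate(c) for c in b.annotations)
            if hit:
                labels.add(rule.label)
        if not labels & set(POSITIVE_CATEGORIES):
            labels.add("undecorated")
        new_bins.append(replace(b, labels=labels))
    return replace(hist, bins=new_bins)


@dataclass
class StratificationReport:
    sample: str
    tic_fractions: dict[str, float]
    bin_centers: dict[str, list[float]]
    top_compositions: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": list(self.tic_fractions),
            "tic_fraction": list(self.tic_fractions.values()),
            "n_bins": [len(self.bin_centers[k]) for k in self.tic_fractions],
        })


def tic_fractions(hist: Histogram, top_n: int = 5) -> StratificationReport:
    """TIC share of each label: sum of labeled-bin intensities over TIC."""
    tic = hist.tic
    if tic <= 0:
        raise ValueError(f"{hist.sample}: zero TIC")
    labels = sorted({lab for b in hist.bins for lab in b.labels})
    fractions, centers, tops = {}, {}, {}
    for lab in labels:
        hit_bins = [b for b in hist.bins if lab in b.labels]
        fractions[lab] = sum(b.intensity for b in hit_bins) / tic
        centers[lab] = [b.center for b in hit_bins]
        ranked = sorted(hit_bins, key=lambda b: -b.intensity)[:top_n]
        tops[lab] = [
            b.annotations[0].render() if b.annotations else f"{b.center:.1f}"
            for b in ranked
        ]
    return StratificationReport(sample=hist.sample, tic_fractions=fractions,
                                bin_centers=centers, top_compositions=tops)


def rare_screen(hist: Histogram, scores: dict[str, SpectrumScore],
                registry: Registry,
                min_spectra: int = 1) -> StratificationReport:
    """Screen bins for rare epitopes via their diagnostic-ion eSNOGs.

    For each rare feature, reports the TIC fraction of bins with at
    least ``min_spectra`` qualifying spectra plus the contributing
    precursor compositions.
    """
    tic = hist.tic
    fractions, centers, tops = {}, {}, {}
    for tag, feats in RARE_FEATURES.items():
        ions = [ion for feat in feats for ion in registry.by_feature(feat)]
        hit_bins = []
        for b in hist.bins:
            n_pass = sum(
                1 for sid in b.spectra if sid in scores
                and any(scores[sid].passes(ion) for ion in ions)
            )
            if n_pass >= min_spectra:
                hit_bins.append(b)
        fractions[tag] = (
            sum(b.intensity for b in hit_bins) / tic if tic > 0 else 0.0
        )
        centers[tag] = [b.center for b in hit_bins]
        tops[tag] = [
            b.annotations[0].render() if b.annotations else f"{b.center:.1f}"
            for b in sorted(hit_bins, key=lambda b: -b.intensity)[:5]
        ]
    return StratificationReport(sample=hist.sample, tic_fractions=fractions,
                                bin_centers=centers, top_compositions=tops)
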