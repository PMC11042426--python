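"""In-silico N-glycan composition database and histogram annotation.

Canonical N-glycan compositions are enumerated exhaustively under
biosynthetic plausibility rules (chitobiose core of two HexNAc, antenna
bound, sialic acids limited by antenna count, fucoses limited by antenna
plus core).  The enumeration is composition-level only: no topology or
linkage is modelled.  The database maps each composition's reduced
[M+H]+ mass onto the same grid used for precursor histograms, and
histogram bins without any candidate within the matching tolerance are
flagged "unknown".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import pandas as pd

from .glycochem import Composition, parse_composition, precursor_mass
from .precursor_aggregation import Histogram, grid_center
from .spectra_io import RunConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnumerationConstraints:
    """Bounds and structural rules for canonical N-glycan enumeration.

    ``max_antennae`` bounds the non-core HexNAc count (plus one for a
    bisecting GlcNAc when ``allow_bisecting``); sialic acid totals are
    capped by the antenna count (+1 under ``allow_disialyl`` for doubly
    sialylated antennae); fucoses by antennae + 1 (core).  Compositions
    with HexNAc = 2 follow the pauci/oligomannose rule instead (Hex
    between ``oligo_hex_min`` and ``oligo_hex_max``, no sialic acid, at
    most one core fucose).
    """

    hex_min: int = 3
    hex_max: int = 12
    hexnac_min: int = 2
    hexnac_max: int = 8
    dhex_max: int = 6
    neu5ac_max: int = 4
    neu5gc_max: int = 4
    hexa_max: int = 0
    sulfate_max: int = 0
    acetyl_max: int = 0
    max_antennae: int = 4
    allow_bisecting: bool = True
    allow_disialyl: bool = False
    oligo_hex_min: int = 3
    oligo_hex_max: int = 9
    mass_low: float = 1000.0
    mass_high: float = 5000.0

    def __post_init__(self) -> None:
        if self.hex_min > self.hex_max or self.hexnac_min > self.hexnac_max:
            raise ValueError("min bound exceeds max bound")
        if self.mass_low >= self.mass_high:
            raise ValueError("mass range must be positive")

    def admits(self, c: Composition) -> bool:
        """Structural plausibility of one composition (mass not checked)."""
        if not (self.hexnac_min <= c.hexnac <= self.hexnac_max):
            return False
        if not (self.hex_min <= c.hex <= self.hex_max):
            return False
        if (c.dhex > self.dhex_max or c.neu5ac > self.neu5ac_max
                or c.neu5gc > self.neu5gc_max or c.hexa > self.hexa_max
                or c.sulfate > self.sulfate_max or c.acetyl > self.acetyl_max):
            return False
        if c.hexnac < 2:
            return False
        if c.hexnac == 2:
            # pauci-/oligomannosidic: mannose series on the chitobiose core
            return (self.oligo_hex_min <= c.hex <= self.oligo_hex_max
                    and c.neu5ac == 0 and c.neu5gc == 0 and c.dhex <= 1
                    and c.hexa == 0)
        extra_hexnac = c.hexnac - 2
        antenna_cap = self.max_antennae + (1 if self.allow_bisecting else 0)
        if extra_hexnac > antenna_cap:
            return False
        antennae = min(extra_hexnac, self.max_antennae)
        sia_cap = antennae + (1 if self.allow_disialyl else 0)
        if c.neu5ac + c.neu5gc > sia_cap:
            return False
        if c.dhex > antennae + 1:
            return False
        # core 3 Hex + per antenna one Gal and optionally one alpha-Gal,
        # with a hybrid allowance of up to 9 Hex
        if c.hex > max(self.oligo_hex_max, 3 + 2 * antennae):
            return False
        if c.hexa > antennae or c.sulfate > c.hexnac:
            return False
        return True


@dataclass
class GlycoDB:
    """Enumerated compositions plus a mass-bin index."""

    compositions: list[Composition]
    constraints: EnumerationConstraints
    mass_index: dict[float, list[Composition]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.compositions)

    @property
    def n_mass_bins(self) -> int:
        return len(self.mass_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "composition": [c.render() for c in self.compositions],
            "monoisotopic_mass": [
                precursor_mass(c, reduced=True, z=1) - 1.00728
                for c in self.compositions
            ],
            "mplush": [
                precursor_mass(c, reduced=True, z=1) for c in self.compositions
            ],
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_db_tsv(path, constraints: EnumerationConstraints | None = None) -> GlycoDB:
    df = pd.read_csv(path, sep="\t")
    comps = [parse_composition(t) for t in df["composition"]]
    return GlycoDB(compositions=comps,
                   constraints=constraints or EnumerationConstraints())


def enumerate_compositions(constraints: EnumerationConstraints) -> GlycoDB:
    """Exhaustively enumerate all admissible compositions in the mass window.

    The resulting composition count and mass-bin count are logged as a
    diagnostic against the reference database sizes (1429 compositions /
    960 precursor mass bins) whose exact rule set is not recoverable.
    """
    c = constraints
    found: list[Composition] = []
    for h, n, f, sa, sg, ua, su, ac in product(
        range(c.hex_min, c.hex_max + 1),
        range(c.hexnac_min, c.hexnac_max + 1),
        range(0, c.dhex_max + 1),
        range(0, c.neu5ac_max + 1),
        range(0, c.neu5gc_max + 1),
        range(0, c.hexa_max + 1),
        range(0, c.sulfate_max + 1),
        range(0, c.acetyl_max + 1),
    ):
        try:
            comp = Composition(hex=h, hexnac=n, dhex=f, neu5ac=sa, neu5gc=sg,
                               hexa=ua, sulfate=su, acetyl=ac)
        except ValueError:
            continue
        if not c.admits(comp):
            continue
        m = precursor_mass(comp, reduced=True, z=1)
        if not (c.mass_low <= m <= c.mass_high):
            continue
        found.append(comp)
    unique = sorted(set(found),
                    key=lambda x: (precursor_mass(x, reduced=True, z=1),
                                   x.render()))
    if not unique:
        logger.warning("enumeration produced no compositions")
    db = GlycoDB(compositions=unique, constraints=c)
    logger.info("glycoDB: %d compositions", len(db))
    return db


def build_mass_index(db: GlycoDB, cfg: RunConfig | None = None) -> dict[float, list[Composition]]:
    """Map each composition's reduced [M+H]+ to its histogram grid bin.

    Isobaric compositions share a bin; the index is stored on the DB and
    returned.
    """
    cfg = cfg or RunConfig()
    index: dict[float, list[Composition]] = {}
    for comp in db.compositions:
        center = round(grid_center(precursor_mass(comp, reduced=True, z=1), cfg), 6)
        index.setdefault(center, []).append(comp)
    db.mass_index = index
    logger.info("glycoDB: %d precursor mass bins", len(index))
    return index


@dataclass
class AnnotationReport:
    sample: str
    n_annotated: int
    n_unknown: int
    unknown_tic_fraction: float
    unknown_centers: list[float] = field(default_factory=list)


def annotate(hist: Histogram, db: GlycoDB,
             tol: float = 0.05) -> tuple[Histogram, AnnotationReport]:
    """Attach candidate compositions to each bin; flag unknowns.

    A candidate qualifies when |bin center - reduced [M+H]+| <= tol.
    The unknown TIC fraction is the intensity share of bins without any
    candidate.
    """
    masses = [(precursor_mass(c, reduced=True, z=1), c) for c in db.compositions]
    masses.sort(key=lambda t: t[0])
    new_bins = []
    unknown_tic = 0.0
    unknown_centers = []
    for b in hist.bins:
        cands = [c for m, c in masses if abs(m - b.center) <= tol]
        cands.sort(key=lambda c: abs(
            precursor_mass(c, reduced=True, z=1) - b.center))
        nb = replace(b, annotations=cands, unknown=not cands)
        if not cands:
            unknown_tic += b.intensity
            unknown_centers.append(b.center)
        new_bins.append(nb)
    tic = hist.tic
    report = AnnotationReport(
        sample=hist.sample,
        n_annotated=sum(1 for b in new_bins if not b.unknown),
        n_unknown=len(unknown_centers),
        unknown_tic_fraction=(unknown_tic / tic) if tic > 0 else 0.0,
        unknown_centers=unknown_centers,
    )
    return replace(hist, bins=new_bins), report
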