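"""Glycan composition arithmetic and the diagnostic-ion registry.

Compositions are monosaccharide count vectors (Hex, HexNAc, dHex/Fuc,
Neu5Ac, Neu5Gc, HexA, sulfate, O-acetyl).  All masses are monoisotopic.
Released N-glycans are chemically reduced at the innermost GlcNAc
(alditol, +2 H), so precursor masses carry the reduction mass in addition
to the water of the free reducing end.

B-type oxonium fragments are sums of dehydrated residue masses plus a
proton; reduced-end Y-type fragments additionally carry water and the
two reduction hydrogens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator

import pandas as pd

# monoisotopic residue (dehydrated) masses, amu
RESIDUE_MASSES: dict[str, float] = {
    "hex": 162.05282,      # C6H10O5
    "hexnac": 203.07937,   # C8H13NO5
    "dhex": 146.05791,     # C6H10O4 (fucose)
    "neu5ac": 291.09542,   # C11H17NO8
    "neu5gc": 307.09033,   # C11H17NO9
    "hexa": 176.03209,     # C6H8O6 (hexuronic acid)
    "sulfate": 79.95682,   # SO3
    "acetyl": 42.01057,    # C2H2O
}

WATER = 18.01056
PROTON = 1.00728
REDUCTION = 2.01565  # two hydrogens of the alditol reduced end

#: ion-feature controlled vocabulary
FEATURES = frozenset({
    "n_glycan", "neu5ac", "neu5gc", "fucose_antenna", "bisecting",
    "alpha_gal", "hnk1", "hnk1_sulfo", "sulfo_hexnac", "lacdinac_fuc",
    "lewis_y", "disialyl_lewis_c_ac", "disialyl_lewis_c_gc",
    "oac_neu5ac", "oac_neu5gc", "sda", "sia_hexnac_ac", "sia_hexnac_gc",
    "hexose_oligomer", "other",
})


class CompositionError(ValueError):
    """Raised for invalid composition strings or count vectors."""


@dataclass(frozen=True)
class Composition:
    """Composition-level identity of a glycan: residue counts."""

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neu5ac: int = 0
    neu5gc: int = 0
    hexa: int = 0
    sulfate: int = 0
    acetyl: int = 0

    def __post_init__(self) -> None:
        for name, count in self.counts().items():
            if count < 0:
                raise CompositionError(f"negative count for {name}: {count}")
        if self.acetyl > self.neu5ac + self.neu5gc:
            raise CompositionError(
                "O-acetyl count exceeds total sialic acid count"
            )

    def counts(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in RESIDUE_MASSES}

    @property
    def is_empty(self) -> bool:
        return all(v == 0 for v in self.counts().values())

    def residue_mass_sum(self) -> float:
        return sum(RESIDUE_MASSES[k] * v for k, v in self.counts().items())

    def render(self) -> str:
        """Canonical text form, e.g. ``Hex5HexNAc4Fuc1Neu5Ac2``."""
        parts = []
        for token, attr in _CANONICAL_ORDER:
            n = getattr(self, attr)
            if n:
                parts.append(f"{token}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_CANONICAL_ORDER = (
    ("Hex", "hex"),
    ("HexNAc", "hexnac"),
    ("Fuc", "dhex"),
    ("Neu5Ac", "neu5ac"),
    ("Neu5Gc", "neu5gc"),
    ("HexA", "hexa"),
    ("SO4", "sulfate"),
    ("Ac", "acetyl"),
)

# longest-match-first token table; aliases map onto the canonical fields
_TOKEN_ALIASES = {
    "hexnac": "hexnac",
    "neu5ac": "neu5ac",
    "neu5gc": "neu5gc",
    "hexa": "hexa",
    "hex": "hex",
    "fuc": "dhex",
    "dhex": "dhex",
    "so4": "sulfate",
    "sulf": "sulfate",
    "ac": "acetyl",
}
_TOKEN_RE = re.compile(
    r"(HexNAc|Neu5Ac|Neu5Gc|HexA|Hex|Fuc|dHex|SO4|Sulf|Ac)[\s_]*(\d*)[\s_]*",
    re.IGNORECASE,
)


def parse_composition(text: str) -> Composition:
    """Parse a composition string such as ``Hex5HexNAc4Fuc1Neu5Ac2``.

    Accepts the tokens Hex, HexNAc, Fuc/dHex, Neu5Ac, Neu5Gc, HexA,
    SO4/Sulf and Ac, optionally separated by underscores (the style
    ``Hex_5_HexNAc_4_`` round-trips), a missing count meaning 1, and the
    alias ``Man5`` for the oligomannosidic Hex5HexNAc2.
    """
    if not text or not text.strip():
        raise CompositionError("empty composition string")
    s = text.strip()
    if s.lower() == "man5":
        return Composition(hex=5, hexnac=2)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise CompositionError(
                f"unknown token at {s[pos:]!r} in composition {text!r}"
            )
        residue = _TOKEN_ALIASES[m.group(1).lower()]
        n = int(m.group(2)) if m.group(2) else 1
        counts[residue] = counts.get(residue, 0) + n
        pos = m.end()
    return Composition(**counts)


def residue_mass(residue: str) -> float:
    """Monoisotopic dehydrated mass of a single residue token."""
    key = _TOKEN_ALIASES.get(residue.lower(), residue.lower())
    try:
        return RESIDUE_MASSES[key]
    except KeyError:
        raise CompositionError(f"unknown residue token {residue!r}") from None


def precursor_mass(comp: Composition, reduced: bool = True, z: int = 1) -> float:
    """m/z of the (reduced) glycan precursor at charge ``z``.

    ``(sum of residue masses + water [+ reduction]) + z protons``, over z.
    """
    if comp.is_empty:
        raise CompositionError("cannot compute mass of an empty composition")
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    neutral = comp.residue_mass_sum() + WATER + (REDUCTION if reduced else 0.0)
    return (neutral + z * PROTON) / z


def fragment_mz(comp: Composition, reduced_end: bool = False) -> float:
    """Singly charged fragment m/z: B-type oxonium, or reduced-end Y-type."""
    if comp.is_empty:
        raise CompositionError("cannot compute mass of an empty composition")
    mz = comp.residue_mass_sum() + PROTON
    if reduced_end:
        mz += WATER + REDUCTION
    return mz


@dataclass(frozen=True)
class DiagnosticIon:
    """A named diagnostic fragment with its feature tag and eSNOG cut-off."""

    name: str
    mz: float
    composition: Composition | None = None
    reduced_end: bool = False
    feature: str = "other"
    esnog_cutoff: float = 0.01

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"ion {self.name}: mz must be positive")
        if not 0.0 <= self.esnog_cutoff <= 1.0:
            raise ValueError(f"ion {self.name}: cutoff outside [0, 1]")
        if self.feature not in FEATURES:
            raise ValueError(f"ion {self.name}: unknown feature {self.feature!r}")


class Registry:
    """Ordered collection of diagnostic ions, unique by name."""

    def __init__(self, ions: list[DiagnosticIon]):
        names = [i.name for i in ions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate ion names in registry: {dupes}")
        self.ions = list(ions)
        self._by_name = {i.name: i for i in ions}

    def __len__(self) -> int:
        return len(self.ions)

    def __iter__(self) -> Iterator[DiagnosticIon]:
        return iter(self.ions)

    def __getitem__(self, name: str) -> DiagnosticIon:
        return self._by_name[name]

    def lookup_mz(self, mz: float, tol: float = 0.005) -> DiagnosticIon:
        """The registry ion closest to ``mz`` within ``tol``."""
        best = min(self.ions, key=lambda i: abs(i.mz - mz))
        if abs(best.mz - mz) > tol:
            raise KeyError(f"no registry ion within {tol} of {mz}")
        return best

    def by_feature(self, feature: str) -> list[DiagnosticIon]:
        return [i for i in self.ions if i.feature == feature]

    @property
    def n_glycan_ion(self) -> DiagnosticIon:
        """The reduced-GlcNAc ion (224.1118) that defines the SNOG score."""
        ions = self.by_feature("n_glycan")
        if not ions:
            raise KeyError("registry has no n_glycan ion")
        return ions[0]

    def with_cutoffs(self, cutoffs: dict[str, float]) -> "Registry":
        """A copy with per-ion eSNOG cut-offs overridden by name."""
        return Registry([
            replace(i, esnog_cutoff=cutoffs.get(i.name, i.esnog_cutoff))
            for i in self.ions
        ])


def load_registry(path) -> Registry:
    """Read a diagnostic-ion registry TSV.

    Columns: name, mz, composition (canonical string or empty),
    reduced_end (true/false), feature, esnog_cutoff.
    """
    df = pd.read_csv(path, sep="\t", dtype={"composition": str})
    required = {"name", "mz", "composition", "reduced_end", "feature",
                "esnog_cutoff"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry file missing columns: {sorted(missing)}")
    ions = []
    for row in df.itertuples(index=False):
        comp_text = "" if pd.isna(row.composition) else str(row.composition)
        comp = parse_composition(comp_text) if comp_text else None
        reduced = str(row.reduced_end).strip().lower() in {"true", "1", "yes"}
        ions.append(DiagnosticIon(
            name=str(row.name), mz=float(row.mz), composition=comp,
            reduced_end=reduced, feature=str(row.feature),
            esnog_cutoff=float(row.esnog_cutoff),
        ))
    return Registry(ions)


def write_registry(registry: Registry, path) -> None:
    rows = [{
        "name": i.name,
        "mz": i.mz,
        "composition": i.composition.render() if i.composition else "",
        "reduced_end": str(i.reduced_end).lower(),
        "feature": i.feature,
        "esnog_cutoff": i.esnog_cutoff,
    } for i in registry]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_registry() -> Registry:
    """The built-in 49-ion diagnostic registry with default cut-offs."""
    with resources.as_file(
        resources.files("snoglyc").joinpath("data/diagnostic_ions.tsv")
    ) as p:
        return load_registry(p)
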