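"""Spectrum / feature-table I/O and run configuration.

MGF blocks are read and written through :mod:`pyteomics.mgf`.  This
artifact's MGF dialect is stricter than permissive MGF: PEPMASS is
mandatory (its first value is the precursor m/z), RTINSECONDS is
mandatory (the downstream workflow is retention-time aware), CHARGE is
optional and recorded as unknown when absent.

Charge-deconvoluted MS1 feature tables arrive as CSV.  Two dialects are
accepted: the generic one (columns rt_seconds, neutral_monoisotopic_mass,
charge, abundance) and a DeCon2 "_isos"-style table carrying a
``monoisotopic_mw`` column plus an explicit retention-time column.
Neutral masses are converted to the singly-protonated [M+H]+ scale on
read; every downstream mass axis uses that scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .glycochem import PROTON

logger = logging.getLogger(__name__)


class SpectrumParseError(ValueError):
    pass


@dataclass
class Spectrum:
    """One MS/MS scan: precursor descriptors plus a centroided peak list."""

    id: str
    precursor_mz: float
    charge: int | None  # None = unknown
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray
    sample: str = ""
    precursor_intensity: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise SpectrumParseError(f"{self.id}: peak arrays differ in length")
        if np.any(~np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise SpectrumParseError(f"{self.id}: invalid peak intensities")
        if self.rt < 0:
            raise SpectrumParseError(f"{self.id}: negative retention time")
        order = np.argsort(self.mz, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def precursor_mass(self) -> float:
        """Singly-protonated precursor mass; requires a known charge."""
        if self.charge is None:
            raise ValueError(f"{self.id}: unknown charge")
        return (self.precursor_mz - PROTON) * self.charge + PROTON


@dataclass(frozen=True)
class PrecursorFeature:
    """One deconvoluted MS1 feature on the [M+H]+ mass scale."""

    mass: float
    rt: float
    intensity: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("feature mass must be positive")
        if self.intensity < 0:
            raise ValueError("feature intensity must be non-negative")


@dataclass
class RunConfig:
    """Workflow constants; defaults follow the published analysis settings."""

    bin_low: float = 1000.0
    bin_high: float = 5000.0
    bin_half_width: float = 0.05
    intensity_threshold: float = 5e6
    snog_cutoff: float = 0.03
    match_tolerance: float = 0.05
    rt_bin: float = 10.0
    registry_path: str | None = None

    def __post_init__(self) -> None:
        if self.bin_low >= self.bin_high:
            raise ValueError("bin_low must be below bin_high")
        if self.bin_half_width <= 0:
            raise ValueError("bin_half_width must be positive")
        if not 0.0 <= self.snog_cutoff <= 1.0:
            raise ValueError("snog_cutoff outside [0, 1]")

    @property
    def bin_width(self) -> float:
        return 2.0 * self.bin_half_width


def load_config(path) -> RunConfig:
    """Read a flat key-value (YAML) run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def read_mgf(path, sample: str | None = None) -> list[Spectrum]:
    """Parse an MGF file into :class:`Spectrum` objects.

    Peaks are sorted ascending; a block without PEPMASS or RTINSECONDS is
    a parse error naming the block index; an empty file yields an empty
    list with a warning.
    """
    path = Path(path)
    label = sample if sample is not None else path.stem
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            if "pepmass" not in params or params["pepmass"] is None:
                raise SpectrumParseError(
                    f"{path.name}: block {idx} has no PEPMASS"
                )
            pepmass = params["pepmass"]
            mz0 = float(pepmass[0])
            prec_int = None
            if len(pepmass) > 1 and pepmass[1] is not None:
                prec_int = float(pepmass[1])
            if "rtinseconds" not in params:
                raise SpectrumParseError(
                    f"{path.name}: block {idx} has no RTINSECONDS"
                )
            charge = None
            if "charge" in params and params["charge"]:
                charge = int(params["charge"][0])
            title = str(params.get("title", f"{path.stem}.{idx}"))
            spectra.append(Spectrum(
                id=title,
                precursor_mz=mz0,
                charge=charge,
                rt=float(params["rtinseconds"]),
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                sample=label,
                precursor_intensity=prec_int,
            ))
    if not spectra:
        warnings.warn(f"{path.name}: no spectra found", stacklevel=2)
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Write spectra as MGF; round-trips through :func:`read_mgf`."""
    entries = []
    for s in spectra:
        params: dict = {"title": s.id, "rtinseconds": s.rt}
        if s.precursor_intensity is not None:
            params["pepmass"] = (s.precursor_mz, s.precursor_intensity)
        else:
            params["pepmass"] = s.precursor_mz
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append({
            "params": params,
            "m/z array": s.mz,
            "intensity array": s.intensity,
        })
    _mgf.write(entries, str(path), file_mode="w")


_GENERIC_COLS = {"rt_seconds", "neutral_monoisotopic_mass", "abundance"}


def read_features(path, sample: str | None = None) -> list[PrecursorFeature]:
    """Read a charge-deconvoluted MS1 feature CSV.

    Accepts the generic dialect (rt_seconds, neutral_monoisotopic_mass,
    charge, abundance) or a DeCon2-style table with ``monoisotopic_mw``
    plus an ``rt_seconds``/``scan_time`` column.  Neutral masses are
    shifted by one proton to the [M+H]+ scale; zero/negative-abundance
    rows are dropped and counted.
    """
    path = Path(path)
    label = sample if sample is not None else path.stem
    df = pd.read_csv(path)
    cols = set(df.columns)
    if _GENERIC_COLS <= cols:
        mass_col, rt_col, ab_col = "neutral_monoisotopic_mass", "rt_seconds", "abundance"
    elif "monoisotopic_mw" in cols:
        mass_col, ab_col = "monoisotopic_mw", "abundance"
        rt_col = "rt_seconds" if "rt_seconds" in cols else "scan_time"
        if rt_col not in cols:
            raise ValueError(
                f"{path.name}: DeCon2-style table needs an rt_seconds or "
                "scan_time column"
            )
        if ab_col not in cols:
            raise ValueError(f"{path.name}: missing required column 'abundance'")
    else:
        missing = sorted(_GENERIC_COLS - cols)
        raise ValueError(f"{path.name}: missing required columns {missing}")
    n_dropped = int((df[ab_col] <= 0).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with non-positive abundance",
                    path.name, n_dropped)
        df = df[df[ab_col] > 0]
    return [
        PrecursorFeature(
            mass=float(m) + PROTON,
            rt=float(rt),
            intensity=float(ab),
            sample=label,
        )
        for m, rt, ab in zip(df[mass_col], df[rt_col], df[ab_col])
    ]


def write_features(features: list[PrecursorFeature], path) -> None:
    """Write features in the generic CSV dialect (neutral-mass column)."""
    pd.DataFrame({
        "rt_seconds": [f.rt for f in features],
        "neutral_monoisotopic_mass": [f.mass - PROTON for f in features],
        "charge": [1] * len(features),
        "abundance": [f.intensity for f in features],
    }).to_csv(path, index=False)
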