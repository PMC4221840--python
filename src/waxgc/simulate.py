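"""Seeded forward model of EI-GC/MS runs of gum-base wax mixtures.

Each species in a reference profile elutes as a Gaussian peak centered at
the retention time the linear RT model predicts for its total carbon
number.  Every scan under the peak carries the species' diagnostic
fragment ions with fixed within-spectrum intensity ratios, scaled by
relative abundance times the Gaussian envelope, so integrated ion current
is exactly proportional to abundance (equal detector response across
species).  Additive Gaussian noise (truncated at zero) is applied per
centroid; a given (profile, config, seed) always yields a bit-identical
run.
"""
from __future__ import annotations

import base64
import struct
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .calibration import LinearModel, default_rt_model
from .chem import (
    ChainSpecies,
    IonType,
    SpeciesClass,
    Triglyceride,
    WaxEster,
    fragment_set,
    nominal_mass,
    triglyceride_fragment_mzs,
)
from .profiles import ReferenceProfile

#: Within-spectrum intensity ratios for wax-ester fragments
#: (molecular : acid+1 : acylium : acid alkyl : alcohol ions).  Invented
#: conventions: only the set of m/z present and area proportionality are
#: load-bearing downstream, never these ratios.
WAX_ESTER_RATIOS: dict[IonType, float] = {
    IonType.MOLECULAR_ION: 10.0,
    IonType.ACID_ACYLIUM_PLUS_H: 100.0,
    IonType.ACYLIUM: 40.0,
    IonType.ACID_ALKYL: 20.0,
    IonType.ALCOHOL_ALKYL: 15.0,
    IonType.ALCOHOL_ESTER: 15.0,
}

#: Alkyl-ladder EI spectrum used for saturated hydrocarbons.
HYDROCARBON_RATIOS: dict[int, float] = {57: 100.0, 71: 85.0, 85: 60.0, 99: 35.0, 113: 15.0}

#: Cholesterol-backbone ions used for sterol-related species (the backbone
#: ions dominate cholesteryl-ester EI spectra regardless of the acyl chain).
STEROL_BACKBONE_RATIOS: dict[int, float] = {368: 100.0, 386: 40.0, 353: 30.0, 255: 15.0}

#: Free fatty alcohols: alkyl ladder plus [M-H2O]+.
FREE_ALCOHOL_LADDER: dict[int, float] = {57: 100.0, 71: 80.0, 85: 55.0, 97: 30.0}

#: Free fatty acids: McLafferty ions plus molecular ion.
FREE_ACID_RATIOS: dict[int, float] = {60: 100.0, 73: 70.0, 129: 25.0}

_TAG_RATIOS = {"molecular": 40.0, "acyloxy_loss": 80.0, "acylium": 60.0}

#: m/z slot used for the constant-baseline centroid when baseline > 0.
BASELINE_MZ = 50


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Instrument/forward-model settings for a synthetic run.

    ``mz_range`` defaults to the 50-920 scan range of a unit-resolution
    quadrupole; ``noise_sd`` is a fraction of the maximum centroid
    intensity in the noiseless run.
    """

    rt_model: LinearModel = field(default_factory=default_rt_model)
    peak_width_sigma: float = 0.05  # min
    scan_interval: float = 0.01  # min
    mz_range: tuple[int, int] = (50, 920)
    noise_sd: float = 0.01
    baseline: float = 0.0  # counts added to every scan at BASELINE_MZ
    seed: int = 0
    rt_window: tuple[float, float] = (1.0, 34.0)
    intensity_scale: float = 1.0e6

    def __post_init__(self) -> None:
        if self.scan_interval <= 0 or self.peak_width_sigma <= 0:
            raise SimulationError("scan_interval and peak_width_sigma must be > 0")
        if not (50 <= self.mz_range[0] < self.mz_range[1] <= 920):
            raise SimulationError(f"mz_range {self.mz_range} outside instrument bounds 50-920")
        if self.rt_window[0] >= self.rt_window[1]:
            raise SimulationError("empty rt_window")


@dataclass
class Scan:
    """One centroided MS1 scan: retention time plus (m/z, intensity) pairs."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class Run:
    """An ordered list of centroided scans plus provenance metadata."""

    scans: list[Scan]
    metadata: dict = field(default_factory=dict)
    _flat: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise SimulationError("scan retention times must be strictly increasing")
        for s in self.scans:
            if np.any(s.intensity < 0):
                raise SimulationError("centroid intensities must be non-negative")

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=float)

    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (scan_index, mz, intensity) arrays, cached for fast EICs."""
        if self._flat is None:
            if self.scans:
                idx = np.concatenate(
                    [np.full(s.mz.size, i) for i, s in enumerate(self.scans)]
                )
                mz = np.concatenate([s.mz for s in self.scans]).astype(float)
                inten = np.concatenate([s.intensity for s in self.scans]).astype(float)
            else:
                idx = np.empty(0, dtype=int)
                mz = np.empty(0)
                inten = np.empty(0)
            self._flat = (idx, mz, inten)
        return self._flat

    @property
    def mz_range(self) -> tuple[int, int]:
        return tuple(self.metadata.get("mz_range", (50, 920)))


def _elution_carbons(species) -> int:
    """Total carbon count that the RT model is applied to."""
    if isinstance(species, (WaxEster, Triglyceride)):
        return species.total_carbons
    return species.carbon_count


def _species_fragments(species) -> list[tuple[int, float]]:
    """(m/z, unnormalized ratio) pairs for any simulatable species."""
    if isinstance(species, WaxEster):
        return [(ion.mz, WAX_ESTER_RATIOS[ion.ion_type]) for ion in fragment_set(species)]
    if isinstance(species, Triglyceride):
        frags = triglyceride_fragment_mzs(species)
        out = [(frags[IonType.MOLECULAR_ION][0], _TAG_RATIOS["molecular"])]
        losses = frags[IonType.ALCOHOL_ESTER]
        acyliums = frags[IonType.ACYLIUM]
        # per-chain contributions folded onto distinct m/z
        chain_counts: dict[int, int] = {}
        for c in species.acyl_chains:
            loss = species.nominal_mass_da - (nominal_mass(c) - 1)
            chain_counts[loss] = chain_counts.get(loss, 0) + 1
        for mz in losses:
            out.append((mz, _TAG_RATIOS["acyloxy_loss"] * chain_counts[mz] / 3.0))
        acylium_counts: dict[int, int] = {}
        for c in species.acyl_chains:
            acylium_counts[nominal_mass(c) - 17] = (
                acylium_counts.get(nominal_mass(c) - 17, 0) + 1
            )
        for mz in acyliums:
            out.append((mz, _TAG_RATIOS["acylium"] * acylium_counts[mz] / 3.0))
        return out
    if isinstance(species, ChainSpecies):
        mw = nominal_mass(species)
        if species.species_class is SpeciesClass.HYDROCARBON:
            return [*HYDROCARBON_RATIOS.items(), (mw, 5.0)]
        if species.species_class is SpeciesClass.STEROL:
            out = list(STEROL_BACKBONE_RATIOS.items())
            if mw not in STEROL_BACKBONE_RATIOS:
                out.append((mw, 10.0))
            return out
        if species.species_class is SpeciesClass.FATTY_ALCOHOL:
            return [*FREE_ALCOHOL_LADDER.items(), (mw - 18, 45.0)]
        if species.species_class is SpeciesClass.FATTY_ACID:
            return [*FREE_ACID_RATIOS.items(), (mw, 10.0)]
    raise SimulationError(f"cannot simulate species {species!r}")


def generate_run(profile: ReferenceProfile, config: SimulationConfig) -> Run:
    """Forward-simulate a centroided EI-GC/MS run of a reference profile."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.rt_window
    rts = np.arange(lo, hi + 1e-9, config.scan_interval)
    spectra: list[dict[int, float]] = [dict() for _ in rts]
    mz_lo, mz_hi = config.mz_range
    sigma = config.peak_width_sigma

    for species, w in profile.all_species():
        if w <= 0:
            continue
        rt0 = config.rt_model.predict(_elution_carbons(species))
        if rt0 < lo or rt0 > hi:
            warnings.warn(
                f"species {species} of profile {profile.name!r} elutes at "
                f"{rt0:.2f} min, outside the scan window {config.rt_window}; skipped",
                stacklevel=2,
            )
            continue
        frags = [(mz, r) for mz, r in _species_fragments(species) if mz_lo <= mz <= mz_hi]
        total_ratio = sum(r for _, r in frags)
        if total_ratio <= 0:
            continue
        idx = np.nonzero(np.abs(rts - rt0) <= 5.0 * sigma)[0]
        env = (
            config.intensity_scale
            * w
            * np.exp(-((rts[idx] - rt0) ** 2) / (2.0 * sigma**2))
        )
        for i, amplitude in zip(idx, env):
            spectrum = spectra[i]
            for mz, r in frags:
                spectrum[mz] = spectrum.get(mz, 0.0) + amplitude * r / total_ratio

    if config.baseline > 0:
        for spectrum in spectra:
            spectrum[BASELINE_MZ] = spectrum.get(BASELINE_MZ, 0.0) + config.baseline

    if config.noise_sd > 0:
        gmax = max((max(s.values()) for s in spectra if s), default=0.0)
        sd = config.noise_sd * gmax
        if sd > 0:
            for spectrum in spectra:
                for mz in sorted(spectrum):
                    spectrum[mz] = max(0.0, spectrum[mz] + rng.normal(0.0, sd))

    scans = []
    for rt, spectrum in zip(rts, spectra):
        if not spectrum:
            continue
        mzs = np.array(sorted(spectrum), dtype=int)
        inten = np.array([spectrum[mz] for mz in mzs], dtype=float)
        scans.append(Scan(rt=float(rt), mz=mzs, intensity=inten))

    return Run(
        scans=scans,
        metadata={
            "profile": profile.name,
            "seed": config.seed,
            "noise_sd": config.noise_sd,
            "mz_range": config.mz_range,
            "scan_interval": config.scan_interval,
            "peak_width_sigma": config.peak_width_sigma,
        },
    )


# ---------------------------------------------------------------------------
# writers


def write_run(run: Run, path, format: str = "csv_scan_table") -> None:
    """Write a run as a CSV scan table or minimal centroided MS1 mzML."""
    if format == "csv_scan_table":
        _write_csv(run, path)
    elif format == "mzml":
        _write_mzml(run, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_csv(run: Run, path) -> None:
    rows = {
        "rt_min": np.concatenate([np.full(s.mz.size, s.rt) for s in run.scans])
        if run.scans
        else np.empty(0),
        "mz": np.concatenate([s.mz for s in run.scans]) if run.scans else np.empty(0, dtype=int),
        "intensity": np.concatenate([s.intensity for s in run.scans])
        if run.scans
        else np.empty(0),
    }
    # %.17g keeps doubles bit-exact through the text round trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def _write_mzml(run: Run, path) -> None:
    """Minimal PSI-MS 1.1.0 mzML: centroided MS1 spectra, uncompressed
    64-bit float arrays."""
    name = str(run.metadata.get("profile", "synthetic"))
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        "<fileDescription><fileContent>",
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
        "</fileContent></fileDescription>",
        f'<run id="{escape(name)}">',
        f'<spectrumList count="{len(run.scans)}">',
    ]
    for i, scan in enumerate(run.scans):
        mz_b64 = _b64_doubles(scan.mz.astype(float))
        it_b64 = _b64_doubles(scan.intensity)
        parts.extend(
            [
                f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.mz.size}">',
                '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>',
                '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>',
                '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
                '<scanList count="1"><scan>',
                f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>',
                "</scan></scanList>",
                '<binaryDataArrayList count="2">',
                f'<binaryDataArray encodedLength="{len(mz_b64)}">',
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
                '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>',
                f"<binary>{mz_b64}</binary>",
                "</binaryDataArray>",
                f'<binaryDataArray encodedLength="{len(it_b64)}">',
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>',
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>',
                '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>',
                f"<binary>{it_b64}</binary>",
                "</binaryDataArray>",
                "</binaryDataArrayList>",
                "</spectrum>",
            ]
        )
    parts.extend(["</spectrumList>", "</run>", "</mzML>"])
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
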