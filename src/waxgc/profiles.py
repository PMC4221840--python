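"""Gum-base reference profiles: the simulator's ground truth and the
classifier's reference catalog.

A :class:`ReferenceProfile` lists a gum base's wax-ester species,
triglycerides and interferents (alkanes, sterol-related material, free
alcohols) with relative abundances.  Ten profiles matching the
characteristic compositions of the food-additive gum bases (lanolin,
beeswax, jojoba, candelilla, shellac, carnauba, rice bran, montan, urushi,
Japan wax) ship with the package; user catalogs use the same JSON schema.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Union

from .chem import (
    ChainSpecies,
    SpeciesClass,
    Triglyceride,
    WaxEster,
    ester_from_parts,
    parse_chain,
)

BUILTIN_NAMES = (
    "lanolin",
    "beeswax",
    "jojoba",
    "candelilla",
    "shellac",
    "carnauba",
    "rice_bran",
    "montan",
    "urushi",
    "japan_wax",
)


class CatalogError(KeyError):
    """Requested profile is not in the catalog."""


AnySpecies = Union[WaxEster, Triglyceride, ChainSpecies]


@dataclass
class ReferenceProfile:
    """A gum base's composition: species with normalized relative abundances."""

    name: str
    ester_species: list[tuple[WaxEster, float]] = field(default_factory=list)
    triglycerides: list[tuple[Triglyceride, float]] = field(default_factory=list)
    interferents: list[tuple[ChainSpecies, float]] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.all_species())
        if total <= 0:
            raise ValueError(f"profile {self.name!r} has no positive abundance")
        self.ester_species = [(s, w / total) for s, w in self.ester_species]
        self.triglycerides = [(s, w / total) for s, w in self.triglycerides]
        self.interferents = [(s, w / total) for s, w in self.interferents]

    def all_species(self) -> Iterator[tuple[AnySpecies, float]]:
        yield from self.ester_species
        yield from self.triglycerides
        yield from self.interferents

    @property
    def ester_carbon_numbers(self) -> list[int]:
        return sorted({e.total_carbons for e, w in self.ester_species if w > 0})


def _profile_from_dict(name: str, raw: dict) -> ReferenceProfile:
    esters = [
        (
            ester_from_parts(
                parse_chain(e["alcohol"], SpeciesClass.FATTY_ALCOHOL),
                parse_chain(e["acid"], SpeciesClass.FATTY_ACID),
            ),
            float(e["w"]),
        )
        for e in raw.get("esters", [])
    ]
    tgs = [
        (Triglyceride.from_label(t["label"]), float(t["w"]))
        for t in raw.get("triglycerides", [])
    ]
    interferents = [
        (
            parse_chain(i["formula_shorthand"], SpeciesClass(i["class"])),
            float(i["w"]),
        )
        for i in raw.get("interferents", [])
    ]
    return ReferenceProfile(
        name=name,
        ester_species=esters,
        triglycerides=tgs,
        interferents=interferents,
        provenance=raw.get("provenance", ""),
    )


def load_catalog(path) -> dict[str, ReferenceProfile]:
    """Load a JSON profile catalog ``{name: {esters, triglycerides, ...}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return {name: _profile_from_dict(name, entry) for name, entry in raw.items()}


def _builtin_catalog() -> dict[str, ReferenceProfile]:
    text = resources.files("waxgc.data").joinpath("profiles.json").read_text()
    raw = json.loads(text)
    return {name: _profile_from_dict(name, entry) for name, entry in raw.items()}


def builtin_profile(name: str) -> ReferenceProfile:
    """Return one of the ten packaged gum-base profiles by name."""
    catalog = _builtin_catalog()
    if name not in catalog:
        raise CatalogError(
            f"unknown profile {name!r}; builtin profiles: {', '.join(BUILTIN_NAMES)}"
        )
    return catalog[name]


def builtin_profiles() -> list[ReferenceProfile]:
    """All ten packaged profiles, in catalog order."""
    catalog = _builtin_catalog()
    return [catalog[name] for name in BUILTIN_NAMES]
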