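"""Chemical data model and nominal-mass / fragment-ion arithmetic for
long-chain wax esters and triglycerides.

Natural ester-type gum bases (beeswax, carnauba, lanolin, ...) are mixtures
of wax esters: condensation products of a long-chain fatty acid and a
long-chain fatty alcohol, conventionally labeled by their total carbon
number (e.g. C54).  Under electron ionization each ester yields a small set
of diagnostic product ions: an acid-side series ([R1COO]+-type at acid
MW + 1, acylium [R1CO]+, alkyl [R1]+), alcohol-side ions ([R2]+ and
[R2OCO]+), and a molecular ion.  The acid-side series depends only on the
acid chain, which is what makes per-ester fatty-acid composition estimation
from extracted-ion chromatograms possible.

All masses are nominal integer masses (C=12, H=1, O=16), matching
unit-resolution quadrupole EI data scanned at integer m/z.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Union


class WaxChemError(ValueError):
    """Base class for chemistry-layer errors."""


class InvalidSpeciesError(WaxChemError):
    """Species definition violates a structural constraint."""


class WrongClassError(WaxChemError):
    """Operation applied to a species of the wrong class."""


class UnsupportedSpeciesError(WaxChemError):
    """Fragmentation is only modeled for unbranched, non-hydroxy chains."""


class SpeciesClass(str, Enum):
    FATTY_ACID = "fatty_acid"
    FATTY_ALCOHOL = "fatty_alcohol"
    HYDROCARBON = "hydrocarbon"
    STEROL = "sterol"


class IonType(str, Enum):
    #: the printed diagnostic acid series ("[RCOO]+" in common usage); its
    #: m/z equals the acid nominal mass + 1, i.e. a protonated-acid value
    ACID_ACYLIUM_PLUS_H = "acid_acylium_plus_H"
    ACYLIUM = "acylium"              # [R1CO]+, acid MW - 17
    ACID_ALKYL = "acid_alkyl"        # [R1]+,   acid MW - 45
    ALCOHOL_ALKYL = "alcohol_alkyl"  # [R2]+,   modeled as CmH2m-1+ (14m - 1)
    ALCOHOL_ESTER = "alcohol_ester"  # [R2OCO]+, 14m + 43
    MOLECULAR_ION = "molecular_ion"


# Nominal mass of a saturated CnH(2n+x)Oy backbone is 14n + base:
#   fatty acid   CnH2nO2  -> 14n + 32
#   fatty alcohol CnH2n+2O -> 14n + 18
#   alkane       CnH2n+2  -> 14n + 2
#   sterol backbone CnH2n-8O -> 14n + 8  (cholesterol, C27H46O -> 386)
_BASE_MASS = {
    SpeciesClass.FATTY_ACID: 32,
    SpeciesClass.FATTY_ALCOHOL: 18,
    SpeciesClass.HYDROCARBON: 2,
    SpeciesClass.STEROL: 8,
}

_CHAIN_RE = re.compile(r"^C(\d+):(\d+)$")


@dataclass(frozen=True)
class ChainSpecies:
    """A single-chain species: fatty acid, fatty alcohol, alkane, or sterol.

    ``carbon_count``/``double_bonds`` follow lipid shorthand ``Cn:d``
    (palmitic acid = C16:0).  ``hydroxyl_count`` and ``branched`` exist so
    that hydroxy and branched calibration standards are representable, but
    fragmentation is only modeled for plain chains.
    """

    species_class: SpeciesClass
    carbon_count: int
    double_bonds: int = 0
    hydroxyl_count: int = 0
    branched: bool = False

    def __post_init__(self) -> None:
        if self.carbon_count < 1:
            raise InvalidSpeciesError(
                f"carbon_count must be >= 1, got {self.carbon_count}"
            )
        if self.double_bonds < 0 or self.hydroxyl_count < 0:
            raise InvalidSpeciesError("double_bonds/hydroxyl_count must be >= 0")
        if self.double_bonds > self.carbon_count / 2:
            raise InvalidSpeciesError(
                f"{self.double_bonds} double bonds impossible on a "
                f"C{self.carbon_count} chain"
            )

    @property
    def shorthand(self) -> str:
        """``Cn:d`` rendering (bijective for unbranched, non-hydroxy chains)."""
        return f"C{self.carbon_count}:{self.double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.shorthand


def parse_chain(
    text: str, species_class: SpeciesClass = SpeciesClass.FATTY_ACID
) -> ChainSpecies:
    """Parse ``Cn:d`` shorthand into a :class:`ChainSpecies`."""
    m = _CHAIN_RE.match(text.strip())
    if m is None:
        raise InvalidSpeciesError(f"cannot parse chain shorthand {text!r}")
    return ChainSpecies(
        species_class=SpeciesClass(species_class),
        carbon_count=int(m.group(1)),
        double_bonds=int(m.group(2)),
    )


@dataclass(frozen=True)
class WaxEster:
    """Ester of a long-chain fatty acid (R1) and fatty alcohol (R2).

    Rendered ``<alcohol>x<acid>`` (alcohol carbon first), e.g. behenyl
    stearate is ``C22:0xC18:0``: C22:0 alcohol, C18:0 acid, total C40.
    """

    acid: ChainSpecies
    alcohol: ChainSpecies

    def __post_init__(self) -> None:
        if self.acid.species_class is not SpeciesClass.FATTY_ACID:
            raise WrongClassError(f"ester acid moiety must be a fatty acid, got {self.acid}")
        if self.alcohol.species_class is not SpeciesClass.FATTY_ALCOHOL:
            raise WrongClassError(
                f"ester alcohol moiety must be a fatty alcohol, got {self.alcohol}"
            )

    @property
    def total_carbons(self) -> int:
        return self.acid.carbon_count + self.alcohol.carbon_count

    @property
    def nominal_mass_da(self) -> int:
        # condensation: acid + alcohol - H2O
        return nominal_mass(self.acid) + nominal_mass(self.alcohol) - 18

    @property
    def shorthand(self) -> str:
        return f"{self.alcohol.shorthand}x{self.acid.shorthand}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.shorthand


def ester_from_parts(alcohol: ChainSpecies, acid: ChainSpecies) -> WaxEster:
    """Condense a fatty alcohol and a fatty acid into a wax ester."""
    return WaxEster(acid=acid, alcohol=alcohol)


def parse_ester(text: str) -> WaxEster:
    """Parse ``Ca:daxCb:db`` (alcohol x acid) ester shorthand.

    Accepts ``x``, ``X`` or the multiplication sign as separator.
    """
    parts = re.split(r"[xX×]", text.strip())
    if len(parts) != 2:
        raise InvalidSpeciesError(f"cannot parse ester shorthand {text!r}")
    alcohol = parse_chain(parts[0], SpeciesClass.FATTY_ALCOHOL)
    acid = parse_chain(parts[1], SpeciesClass.FATTY_ACID)
    return ester_from_parts(alcohol, acid)


#: Three-letter triglyceride codes: one letter per acyl chain.
ACYL_CODES: dict[str, tuple[int, int]] = {
    "P": (16, 0),  # palmitic
    "S": (18, 0),  # stearic
    "O": (18, 1),  # oleic
    "M": (14, 0),  # myristic
    "L": (18, 2),  # linoleic
}


@dataclass(frozen=True)
class Triglyceride:
    """Glycerol triester labeled by a three-letter acyl code (PPP, PPO, ...)."""

    acyl_chains: tuple[ChainSpecies, ChainSpecies, ChainSpecies]
    label: str

    def __post_init__(self) -> None:
        if len(self.acyl_chains) != 3:
            raise InvalidSpeciesError("a triglyceride has exactly three acyl chains")
        for c in self.acyl_chains:
            if c.species_class is not SpeciesClass.FATTY_ACID:
                raise WrongClassError(f"acyl chain must be a fatty acid, got {c}")
        if len(self.label) != 3:
            raise InvalidSpeciesError(f"label must have three letters, got {self.label!r}")
        coded = sorted(ACYL_CODES.get(letter) for letter in self.label)
        if None in coded:
            raise InvalidSpeciesError(f"unknown acyl code letter in {self.label!r}")
        chains = sorted((c.carbon_count, c.double_bonds) for c in self.acyl_chains)
        if coded != chains:
            raise InvalidSpeciesError(
                f"label {self.label!r} does not match acyl chains {chains}"
            )

    @classmethod
    def from_label(cls, label: str) -> "Triglyceride":
        try:
            chains = tuple(
                ChainSpecies(SpeciesClass.FATTY_ACID, *ACYL_CODES[letter])
                for letter in label
            )
        except KeyError as exc:
            raise InvalidSpeciesError(f"unknown acyl code letter {exc}") from exc
        if len(chains) != 3:
            raise InvalidSpeciesError(f"label must have three letters, got {label!r}")
        return cls(acyl_chains=chains, label=label)

    @property
    def total_carbons(self) -> int:
        # glycerol backbone contributes 3 carbons
        return 3 + sum(c.carbon_count for c in self.acyl_chains)

    @property
    def nominal_mass_da(self) -> int:
        # glycerol (92) + three acids - three waters
        return 92 + sum(nominal_mass(c) for c in self.acyl_chains) - 3 * 18


Species = Union[ChainSpecies, WaxEster, Triglyceride]


def nominal_mass(species: Species) -> int:
    """Integer nominal molecular mass of a chain, wax ester or triglyceride.

    Saturated fatty acid CnH2nO2 -> 14n + 32; saturated fatty alcohol
    CmH2m+2O -> 14m + 18; each double bond subtracts 2; each hydroxyl adds
    16.  Esters condense (acid + alcohol - 18); triglycerides condense
    glycerol with three acids (- 3 x 18).
    """
    if isinstance(species, WaxEster):
        return species.nominal_mass_da
    if isinstance(species, Triglyceride):
        return species.nominal_mass_da
    if isinstance(species, ChainSpecies):
        return (
            14 * species.carbon_count
            + _BASE_MASS[species.species_class]
            - 2 * species.double_bonds
            + 16 * species.hydroxyl_count
        )
    raise InvalidSpeciesError(f"not a species: {species!r}")


def acid_fragment_mz(acid: ChainSpecies) -> int:
    """Diagnostic acid-series m/z for a fatty acid: nominal mass + 1.

    For saturated even-carbon acids this is the printed series
    C16:0 -> 257, C18:0 -> 285, ..., C32:0 -> 481 (14n + 33 - 2d).
    """
    if not isinstance(acid, ChainSpecies) or acid.species_class is not SpeciesClass.FATTY_ACID:
        raise WrongClassError(f"acid_fragment_mz requires a fatty acid, got {acid!r}")
    return nominal_mass(acid) + 1


@dataclass(frozen=True)
class FragmentIon:
    """A diagnostic EI product ion of a parent species."""

    ion_type: IonType
    mz: int
    parent: str  # shorthand of the parent species

    def __post_init__(self) -> None:
        if self.mz < 15:
            raise InvalidSpeciesError(f"fragment m/z {self.mz} below CH3+ floor")


def fragment_set(ester: WaxEster) -> list[FragmentIon]:
    """Diagnostic EI ions of a wax ester.

    Acid-side series at acid MW + 1 (protonated-acid value), MW - 17
    (acylium) and MW - 45 (alkyl); alcohol-side [R2]+ at 14m - 1 - 2d
    (alkenyl cation, a model convention) and [R2OCO]+ at 14m + 43 - 2d;
    plus the molecular ion.  Only unbranched, non-hydroxy chains are
    supported.
    """
    for chain in (ester.acid, ester.alcohol):
        if chain.branched or chain.hydroxyl_count > 0:
            raise UnsupportedSpeciesError(
                f"fragmentation not modeled for branched/hydroxy chain {chain}"
            )
    acid_mw = nominal_mass(ester.acid)
    m = ester.alcohol.carbon_count
    d = ester.alcohol.double_bonds
    parent = ester.shorthand
    ions = [
        FragmentIon(IonType.ACID_ACYLIUM_PLUS_H, acid_mw + 1, parent),
        FragmentIon(IonType.ACYLIUM, acid_mw - 17, parent),
        FragmentIon(IonType.ACID_ALKYL, acid_mw - 45, parent),
        FragmentIon(IonType.ALCOHOL_ALKYL, 14 * m - 1 - 2 * d, parent),
        FragmentIon(IonType.ALCOHOL_ESTER, 14 * m + 43 - 2 * d, parent),
        FragmentIon(IonType.MOLECULAR_ION, ester.nominal_mass_da, parent),
    ]
    seen = set()
    for ion in ions:
        key = (ion.ion_type, ion.mz)
        if key in seen:  # pragma: no cover - impossible for valid esters
            raise InvalidSpeciesError(f"duplicate fragment {key}")
        seen.add(key)
    return ions


def triglyceride_fragment_mzs(tg: Triglyceride) -> dict[IonType, list[int]]:
    """Diagnostic TAG ions: molecular ion, acyloxy losses [M-RCOO]+, acyliums.

    These are the ions used to resolve co-eluting triglycerides, e.g.
    tripalmitin (PPP, M 806) vs 1,2-dipalmitoyl-3-oleoylglycerol
    (PPO, M 832).
    """
    mw = tg.nominal_mass_da
    losses = sorted({mw - (nominal_mass(c) - 1) for c in tg.acyl_chains})
    acyliums = sorted({nominal_mass(c) - 17 for c in tg.acyl_chains})
    return {
        IonType.MOLECULAR_ION: [mw],
        IonType.ALCOHOL_ESTER: losses,  # reuse of the ester-loss slot for [M-RCOO]+
        IonType.ACYLIUM: acyliums,
    }


def enumerate_esters(
    total_carbons: int,
    acid_range: tuple[int, int] = (16, 32),
    alcohol_range: tuple[int, int] = (16, 38),
    even_only: bool = True,
) -> list[WaxEster]:
    """All saturated acid x alcohol pairs with the given total carbon number.

    Both chains must fall inside their (inclusive) ranges; ``even_only``
    restricts both chains to even carbon counts.  Returns candidates sorted
    by acid carbon count; an unreachable total yields an empty list.
    """
    a_lo, a_hi = acid_range
    o_lo, o_hi = alcohol_range
    if a_lo > a_hi or o_lo > o_hi:
        raise InvalidSpeciesError("empty acid or alcohol range")
    out: list[WaxEster] = []
    for n in range(a_lo, a_hi + 1):
        if even_only and n % 2:
            continue
        m = total_carbons - n
        if m < o_lo or m > o_hi:
            continue
        if even_only and m % 2:
            continue
        out.append(
            ester_from_parts(
                ChainSpecies(SpeciesClass.FATTY_ALCOHOL, m),
                ChainSpecies(SpeciesClass.FATTY_ACID, n),
            )
        )
    return out
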