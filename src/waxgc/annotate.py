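"""Ester-peak annotation: the central inference of the pipeline.

For each TIC peak the workflow (1) assigns an ester carbon number by
inverting the RT calibration, (2) apportions the peak among a panel of
candidate fatty acids using the areas of their diagnostic acid-series EICs
integrated over the shared peak window (the Gaussian envelope cancels in
the ratios, so under equal detector response the fractions are molar acid
fractions), (3) classifies the peak (wax ester / triglyceride /
hydrocarbon / sterol-related / unknown) from its fragment evidence, and
(4) infers the paired alcohol chain lengths by subtraction.  Per-run
results roll up into a composition table (acids x ester carbon numbers, in
percent) and, for triglyceride-dominated waxes, a PPO/PPP peak-area ratio.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import LinearModel, carbon_from_rt
from .chem import (
    ChainSpecies,
    SpeciesClass,
    Triglyceride,
    acid_fragment_mz,
    enumerate_esters,
    nominal_mass,
)
from .peaks import Chromatogram, Peak, compute_tic, detect_peaks, extract_eic, integrate
from .simulate import Run, STEROL_BACKBONE_RATIOS

#: Diagnostic m/z triplet of the alkane fragment ladder (CnH2n+1+).
ALKYL_LADDER = (57, 71, 85)

#: Sterol-backbone diagnostic ions (cholesterol skeleton).
STEROL_DIAGNOSTIC = tuple(sorted(STEROL_BACKBONE_RATIOS))

#: Triglycerides the annotator knows how to assign.  PPP/PPO molecular ions
#: (806 vs 832) resolve the palmitate-rich TAG region.
DEFAULT_TG_TABLE: tuple[str, ...] = ("PPP", "PPO", "PPS", "POO", "SSS")


class AnnotationError(ValueError):
    pass


class UndefinedRatioError(ZeroDivisionError):
    """PPP area is zero: the PPO/PPP ratio is undefined."""


def default_acid_panel(extended: bool = False) -> list[ChainSpecies]:
    """Candidate constitutive fatty acids.

    Default: saturated even-carbon C16:0-C32:0 (the panel the diagnostic
    series 257-481 covers).  ``extended=True`` adds even-carbon
    monounsaturated acids C16:1-C24:1 for unsaturated waxes such as jojoba.
    """
    panel = [ChainSpecies(SpeciesClass.FATTY_ACID, n) for n in range(16, 33, 2)]
    if extended:
        panel += [ChainSpecies(SpeciesClass.FATTY_ACID, n, 1) for n in range(16, 25, 2)]
    return panel


@dataclass(frozen=True)
class AnnotateParams:
    """Tunables of the annotation stage (all CLI-overridable)."""

    min_fraction: float = 0.005  # acid fractions below this are dropped
    ester_evidence_frac: float = 0.2  # acid-series area / TIC area for wax_ester
    tg_evidence_frac: float = 0.2
    sterol_evidence_frac: float = 0.2
    hydrocarbon_base_frac: float = 0.5  # ladder share of the apex spectrum
    eic_tol: float = 0.5  # Th, unit-resolution quadrupole
    min_height_frac: float = 0.01
    smooth_window: int = 5
    parity: str = "even"
    alcohol_range: tuple[int, int] = (16, 40)


@dataclass
class EsterAnnotation:
    """Everything inferred about one TIC peak."""

    peak: Peak
    ester_carbon_number: int
    peak_class: str  # wax_ester | hydrocarbon | sterol_related | triglyceride | unknown
    acid_fractions: dict[ChainSpecies, float] = field(default_factory=dict)
    inferred_pairs: list[tuple[ChainSpecies, ChainSpecies, float]] = field(
        default_factory=list
    )
    tg_assignment: Optional[str] = None  # TAG label when peak_class == triglyceride


@dataclass
class AnnotationContext:
    """Precomputed chromatograms shared across the peaks of one run."""

    run: Run
    tic: Chromatogram
    acid_panel: list[ChainSpecies]
    acid_eics: dict[ChainSpecies, Chromatogram]
    tg_species: list[Triglyceride]
    tg_mol_eics: dict[str, Chromatogram]
    tg_diag_eics: list[Chromatogram]
    sterol_eics: list[Chromatogram]
    params: AnnotateParams


def _build_context(
    run: Run, acid_panel: list[ChainSpecies], params: AnnotateParams
) -> AnnotationContext:
    tic = compute_tic(run)
    lo, hi = run.mz_range

    def eic(mz: int) -> Optional[Chromatogram]:
        if not (lo <= mz <= hi):
            return None
        return extract_eic(run, mz, tol=params.eic_tol)

    acid_eics = {}
    for acid in acid_panel:
        chrom = eic(acid_fragment_mz(acid))
        if chrom is not None:
            acid_eics[acid] = chrom
    tg_species = [Triglyceride.from_label(label) for label in DEFAULT_TG_TABLE]
    tg_mol_eics = {}
    tg_diag_eics = []
    seen = set()
    for tg in tg_species:
        mol = tg.nominal_mass_da
        chrom = eic(mol)
        if chrom is not None:
            tg_mol_eics[tg.label] = chrom
            if mol not in seen:
                tg_diag_eics.append(chrom)
                seen.add(mol)
    # acyloxy-loss ions of the TAG table are diagnostic too
    for tg in tg_species:
        for chain in tg.acyl_chains:
            loss = tg.nominal_mass_da - (nominal_mass(chain) - 1)
            if loss not in seen:
                chrom = eic(loss)
                if chrom is not None:
                    tg_diag_eics.append(chrom)
                    seen.add(loss)
    sterol_eics = [c for c in (eic(mz) for mz in STEROL_DIAGNOSTIC) if c is not None]
    return AnnotationContext(
        run=run,
        tic=tic,
        acid_panel=acid_panel,
        acid_eics=acid_eics,
        tg_species=tg_species,
        tg_mol_eics=tg_mol_eics,
        tg_diag_eics=tg_diag_eics,
        sterol_eics=sterol_eics,
        params=params,
    )


def _apex_scan(run: Run, apex_rt: float):
    rts = run.rts
    return run.scans[int(np.argmin(np.abs(rts - apex_rt)))]


def classify_peak(
    run: Run, peak: Peak, ctx: AnnotationContext
) -> tuple[str, dict[ChainSpecies, float], Optional[str]]:
    """Classify one peak and return (class, acid EIC areas, TAG label).

    Rules, in order: wax ester if the summed acid-series EIC area reaches
    ``ester_evidence_frac`` of the TIC peak area; triglyceride if the TAG
    diagnostic ions (molecular + acyloxy-loss) dominate, with the label
    assigned by the strongest molecular ion; hydrocarbon if the apex
    spectrum is dominated by the 57/71/85 alkyl ladder without acid
    evidence; sterol-related if the sterol backbone ions dominate; else
    unknown.
    """
    window = (peak.start_rt, peak.end_rt)
    params = ctx.params
    acid_areas = {
        acid: integrate(chrom, window) for acid, chrom in ctx.acid_eics.items()
    }
    total_acid = sum(acid_areas.values())
    tic_area = peak.area
    if tic_area > 0 and total_acid / tic_area >= params.ester_evidence_frac:
        return "wax_ester", acid_areas, None

    tg_diag = sum(integrate(chrom, window) for chrom in ctx.tg_diag_eics)
    if tic_area > 0 and tg_diag / tic_area >= params.tg_evidence_frac:
        mol_areas = {
            label: integrate(chrom, window) for label, chrom in ctx.tg_mol_eics.items()
        }
        label = max(sorted(mol_areas), key=lambda k: mol_areas[k])
        return "triglyceride", acid_areas, label

    scan = _apex_scan(run, peak.apex_rt)
    total_scan = float(scan.intensity.sum())
    if total_scan > 0:
        ladder = sum(
            float(scan.intensity[np.abs(scan.mz - mz) <= params.eic_tol].sum())
            for mz in ALKYL_LADDER
        )
        if ladder / total_scan >= params.hydrocarbon_base_frac:
            return "hydrocarbon", acid_areas, None

    sterol = sum(integrate(chrom, window) for chrom in ctx.sterol_eics)
    if tic_area > 0 and sterol / tic_area >= params.sterol_evidence_frac:
        return "sterol_related", acid_areas, None

    return "unknown", acid_areas, None


def annotate_run(
    run: Run,
    rt_model: LinearModel,
    acid_panel: Optional[list[ChainSpecies]] = None,
    params: Optional[AnnotateParams] = None,
) -> list[EsterAnnotation]:
    """Annotate every TIC peak of a run.

    Requires a calibrated ``rt_model`` (positive slope).  The default acid
    panel is saturated even-carbon C16:0-C32:0.
    """
    if rt_model is None:
        raise AnnotationError("annotate_run needs a calibrated RT model")
    if params is None:
        params = AnnotateParams()
    if acid_panel is None:
        acid_panel = default_acid_panel()
    ctx = _build_context(run, acid_panel, params)
    peaks = detect_peaks(
        ctx.tic, min_height_frac=params.min_height_frac, smooth_window=params.smooth_window
    )
    annotations: list[EsterAnnotation] = []
    for peak in peaks:
        carbon = carbon_from_rt(rt_model, peak.apex_rt, parity=params.parity)
        peak_class, acid_areas, tg_label = classify_peak(run, peak, ctx)
        fractions: dict[ChainSpecies, float] = {}
        pairs: list[tuple[ChainSpecies, ChainSpecies, float]] = []
        if peak_class == "wax_ester":
            total = sum(acid_areas.values())
            if total > 0:
                fractions = {a: v / total for a, v in acid_areas.items() if v > 0}
                # drop trace acids and renormalize so fractions stay a partition
                fractions = {
                    a: v for a, v in fractions.items() if v >= params.min_fraction
                }
                norm = sum(fractions.values())
                fractions = {a: v / norm for a, v in fractions.items()}
                pairs = _infer_pairs(carbon, fractions, params)
            else:
                peak_class = "unknown"
        annotations.append(
            EsterAnnotation(
                peak=peak,
                ester_carbon_number=carbon,
                peak_class=peak_class,
                acid_fractions=fractions,
                inferred_pairs=pairs,
                tg_assignment=tg_label,
            )
        )
    return annotations


def _infer_pairs(
    carbon: int, fractions: dict[ChainSpecies, float], params: AnnotateParams
) -> list[tuple[ChainSpecies, ChainSpecies, float]]:
    """Alcohol chains by subtraction: alcohol carbons = ester - acid carbons."""
    pairs = []
    a_lo, a_hi = params.alcohol_range
    for acid, frac in sorted(fractions.items(), key=lambda kv: kv[0].carbon_count):
        candidates = enumerate_esters(
            carbon,
            acid_range=(acid.carbon_count, acid.carbon_count),
            alcohol_range=(a_lo, a_hi),
            even_only=False,
        )
        for ester in candidates:
            pairs.append((acid, ester.alcohol, frac))
    return pairs


@dataclass
class CompositionTable:
    """Per-ester-carbon-number acid percentages (rows acids, columns esters).

    Cells hold unrounded percentages; rounding to integers happens only at
    presentation (:meth:`to_csv`).  Each column sums to 100 over present
    cells.
    """

    data: pd.DataFrame  # index: acid shorthand; columns: int carbon numbers

    def cell(self, acid: str, carbon: int) -> Optional[float]:
        if carbon not in self.data.columns or acid not in self.data.index:
            return None
        value = self.data.loc[acid, carbon]
        return None if pd.isna(value) else float(value)

    def to_csv(self, path, absent: str = "-") -> None:
        out = self.data.round(0).astype("Int64").astype(object)
        out = out.where(~self.data.isna(), absent)
        out.columns = [f"C{c}" for c in out.columns]
        out.index.name = "constitutive_fatty_acid"
        out.to_csv(path)


def composition_table(
    annotations: list[EsterAnnotation], carbons: Optional[list[int]] = None
) -> CompositionTable:
    """Assemble the acid-composition table from wax-ester annotations.

    For each requested ester carbon number, the wax-ester peak with the
    largest area supplies the column; requested numbers with no such peak
    are omitted with a warning.
    """
    esters = [a for a in annotations if a.peak_class == "wax_ester" and a.acid_fractions]
    if carbons is None:
        carbons = sorted({a.ester_carbon_number for a in esters})
    columns: dict[int, dict[str, float]] = {}
    for carbon in carbons:
        matches = [a for a in esters if a.ester_carbon_number == carbon]
        if not matches:
            warnings.warn(f"no wax-ester peak with carbon number {carbon}; column omitted",
                          stacklevel=2)
            continue
        best = max(matches, key=lambda a: a.peak.area)
        columns[carbon] = {
            acid.shorthand: 100.0 * frac for acid, frac in best.acid_fractions.items()
        }
    acids = sorted(
        {acid for col in columns.values() for acid in col},
        key=lambda s: (int(s[1:].split(":")[0]), int(s.split(":")[1])),
    )
    frame = pd.DataFrame(
        {carbon: [columns[carbon].get(acid, np.nan) for acid in acids]
         for carbon in columns},
        index=acids,
        dtype=float,
    )
    return CompositionTable(data=frame)


def ppo_ppp_ratio(
    run: Run,
    rt_model: LinearModel,
    params: Optional[AnnotateParams] = None,
    annotations: Optional[list[EsterAnnotation]] = None,
) -> float:
    """Peak-area ratio of PPO to PPP (the urushi-vs-Japan-wax discriminant).

    Triglyceride peaks are assigned labels by their dominant molecular ion
    (832 for PPO vs 806 for PPP).  Raises :class:`UndefinedRatioError`
    when no PPP area is found; returns 0 when PPP is present but PPO is
    not.
    """
    if annotations is None:
        annotations = annotate_run(run, rt_model, params=params)
    return ratio_from_annotations(annotations)


def ratio_from_annotations(annotations: list[EsterAnnotation]) -> float:
    areas: dict[str, float] = {}
    for ann in annotations:
        if ann.peak_class == "triglyceride" and ann.tg_assignment:
            areas[ann.tg_assignment] = areas.get(ann.tg_assignment, 0.0) + ann.peak.area
    ppp = areas.get("PPP", 0.0)
    if ppp <= 0:
        raise UndefinedRatioError("no PPP peak area; PPO/PPP ratio undefined")
    return areas.get("PPO", 0.0) / ppp
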