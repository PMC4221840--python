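"""End-to-end orchestration: run file -> composition table, fingerprint,
classification, and a parameter log.

Outputs are fully determined by the input file and the configuration (no
timestamps), so repeated invocations produce byte-identical files.
"""
from __future__ import annotations

import json
import os
import warnings
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .annotate import (
    AnnotateParams,
    annotate_run,
    composition_table,
    default_acid_panel,
    ratio_from_annotations,
    UndefinedRatioError,
)
from .calibration import LinearModel, default_rt_model, fit_line, read_points_csv
from .classify import ClassifyConfig, DEFAULT_WEIGHTS, classify, fingerprint
from .io import read_run
from .profiles import ReferenceProfile, builtin_profiles, load_catalog


class StageError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PeakSettings(_Forbid):
    min_height_frac: float = 0.01
    smooth_window: int = 5
    eic_tol: float = 0.5


class AnnotateSettings(_Forbid):
    min_fraction: float = 0.005
    ester_evidence_frac: float = 0.2
    extended_panel: bool = False
    parity: str = "even"


class ClassifySettings(_Forbid):
    weights: dict[str, float] = dict(DEFAULT_WEIGHTS)
    extended_panel: bool = True
    reference_seed: int = 0


class PipelineConfig(_Forbid):
    """Serializable pipeline configuration; unknown keys are rejected."""

    rt_cal: Optional[str] = None  # path to a (carbon_number, rt_min) CSV
    peak: PeakSettings = PeakSettings()
    annotate: AnnotateSettings = AnnotateSettings()
    classify: ClassifySettings = ClassifySettings()
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))

    def annotate_params(self) -> AnnotateParams:
        return AnnotateParams(
            min_fraction=self.annotate.min_fraction,
            ester_evidence_frac=self.annotate.ester_evidence_frac,
            eic_tol=self.peak.eic_tol,
            min_height_frac=self.peak.min_height_frac,
            smooth_window=self.peak.smooth_window,
            parity=self.annotate.parity,
        )


def _rt_model_from_config(config: PipelineConfig) -> LinearModel:
    if config.rt_cal is None:
        return default_rt_model()
    x, y = read_points_csv(config.rt_cal)
    return fit_line(x, y)


def _fingerprint_json(fp) -> dict:
    return {
        "ester_carbon_distribution": {
            str(k): v for k, v in sorted(fp.ester_carbon_distribution.items())
        },
        "acid_matrix": {
            f"{acid}@C{carbon}": v for (acid, carbon), v in sorted(fp.acid_matrix.items())
        },
        "class_flags": fp.class_flags,
        "ppo_ppp": fp.ppo_ppp,
    }


def run_pipeline(
    run_path,
    config: Optional[PipelineConfig] = None,
    outdir=".",
    references: Optional[Sequence[ReferenceProfile]] = None,
) -> dict[str, str]:
    """Run the full workflow on one run file.

    Writes ``composition.csv``, ``fingerprint.json``,
    ``classification.json`` and ``pipeline.log`` under ``outdir`` and
    returns their paths.  Any stage failure raises :class:`StageError`
    naming the stage.
    """
    if config is None:
        config = PipelineConfig()
    os.makedirs(outdir, exist_ok=True)
    log_lines: list[str] = ["waxgc pipeline", f"run: {run_path}"]
    log_lines.append("config: " + config.model_dump_json())

    try:
        run = read_run(run_path)
    except Exception as exc:
        raise StageError("read_run", exc) from exc

    try:
        rt_model = _rt_model_from_config(config)
        log_lines.append(
            f"rt_model: slope={rt_model.slope} intercept={rt_model.intercept} "
            f"r_squared={rt_model.r_squared} n={rt_model.n_points}"
        )
    except Exception as exc:
        raise StageError("calibrate", exc) from exc

    try:
        extended = config.annotate.extended_panel
        panel = default_acid_panel(extended=extended)
        params = config.annotate_params()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            annotations = annotate_run(run, rt_model, acid_panel=panel, params=params)
            for w in caught:
                log_lines.append(f"warning: {w.message}")
        log_lines.append(f"acid panel: {[a.shorthand for a in panel]} (extended={extended})")
        for ann in annotations:
            fr = {a.shorthand: round(f, 4) for a, f in sorted(
                ann.acid_fractions.items(), key=lambda kv: kv[0].carbon_count)}
            log_lines.append(
                f"peak apex={ann.peak.apex_rt:.3f} area={ann.peak.area:.6g} "
                f"carbon={ann.ester_carbon_number} class={ann.peak_class} "
                f"acids={fr} tg={ann.tg_assignment}"
            )
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    paths = {
        "composition": os.path.join(outdir, "composition.csv"),
        "fingerprint": os.path.join(outdir, "fingerprint.json"),
        "classification": os.path.join(outdir, "classification.json"),
        "log": os.path.join(outdir, "pipeline.log"),
    }

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = composition_table(annotations)
            for w in caught:
                log_lines.append(f"warning: {w.message}")
        table.to_csv(paths["composition"])
    except Exception as exc:
        raise StageError("composition", exc) from exc

    try:
        ppo = None
        if any(a.peak_class == "triglyceride" for a in annotations):
            try:
                ppo = ratio_from_annotations(annotations)
            except UndefinedRatioError:
                ppo = None
        fp = fingerprint(annotations, composition=table, ppo_ppp=ppo)
        with open(paths["fingerprint"], "w") as fh:
            json.dump(_fingerprint_json(fp), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise StageError("fingerprint", exc) from exc

    try:
        refs = list(references) if references is not None else builtin_profiles()
        cconf = ClassifyConfig(
            weights=dict(config.classify.weights),
            extended_panel=config.classify.extended_panel,
            reference_seed=config.classify.reference_seed,
            annotate_params=params,
        )
        result = classify(run, refs, config=cconf, rt_model=rt_model)
        with open(paths["classification"], "w") as fh:
            json.dump(
                {
                    "call": result.call,
                    "margin": result.margin,
                    "ranked": [{"profile": n, "similarity": s} for n, s in result.ranked],
                    "evidence": _fingerprint_json(fp),
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        log_lines.append(f"classification call: {result.call} margin={result.margin:.4f}")
    except Exception as exc:
        raise StageError("classify", exc) from exc

    with open(paths["log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return paths


def load_references(path=None) -> list[ReferenceProfile]:
    """References from a JSON catalog file, or the builtin ten."""
    if path is None:
        return builtin_profiles()
    return list(load_catalog(path).values())
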