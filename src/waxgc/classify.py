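"""Gum-base discrimination by chromatographic fingerprint.

A fingerprint assembles four evidence blocks from an annotated run: the
ester-carbon-number TIC-area distribution, the flattened acid-composition
matrix, the class presence flags (hydrocarbon / sterol-related /
triglyceride area fractions), and the PPO/PPP triglyceride ratio when one
exists.  Similarity is a weighted mean of per-block cosine similarities;
queries are ranked against reference fingerprints generated by passing a
noiseless simulated run of each reference profile through the identical
annotation pipeline, which avoids any feature drift between query and
reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotate import (
    AnnotateParams,
    EsterAnnotation,
    UndefinedRatioError,
    annotate_run,
    composition_table,
    default_acid_panel,
    ratio_from_annotations,
)
from .calibration import LinearModel, default_rt_model
from .profiles import ReferenceProfile
from .simulate import Run, SimulationConfig, generate_run


class EmptyFingerprintError(ValueError):
    """The run produced no peaks at all."""


class UndefinedSimilarityError(ValueError):
    """Both fingerprints are empty in every block."""


CLASS_FLAG_KEYS = ("hydrocarbon", "sterol_related", "triglyceride")

#: Default block weights: distribution 0.4, acid matrix 0.4, class flags
#: 0.15, PPO/PPP agreement 0.05.
DEFAULT_WEIGHTS: dict[str, float] = {
    "distribution": 0.40,
    "acid_matrix": 0.40,
    "class_flags": 0.15,
    "ppo_ppp": 0.05,
}


@dataclass
class Fingerprint:
    """Deterministic feature blocks of one annotated run."""

    ester_carbon_distribution: dict[int, float]
    acid_matrix: dict[tuple[str, int], float]  # (acid shorthand, ester carbons)
    class_flags: dict[str, float]
    ppo_ppp: Optional[float] = None


@dataclass
class ClassificationResult:
    ranked: list[tuple[str, float]]
    call: str
    margin: float


@dataclass(frozen=True)
class ClassifyConfig:
    """Classifier settings.

    References are fingerprinted from noiseless runs generated with a
    fixed seed so that reference and query traverse the same pipeline.
    The extended acid panel (adds monounsaturated acids) is on by default
    so unsaturated waxes such as jojoba produce a usable acid block.
    """

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    extended_panel: bool = True
    reference_seed: int = 0
    annotate_params: AnnotateParams = field(default_factory=AnnotateParams)
    sim_config: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(noise_sd=0.0, seed=0)
    )


def fingerprint(
    annotations: Sequence[EsterAnnotation],
    composition=None,
    ppo_ppp: Optional[float] = None,
) -> Fingerprint:
    """Assemble a fingerprint from a run's annotations.

    ``composition`` defaults to the table derived from the annotations;
    ``ppo_ppp`` defaults to the ratio computed from triglyceride peaks
    (None when no PPP peak exists).
    """
    if not annotations:
        raise EmptyFingerprintError("cannot fingerprint a run with no peaks")
    total_area = sum(a.peak.area for a in annotations)
    esters = [a for a in annotations if a.peak_class == "wax_ester"]
    ester_area = sum(a.peak.area for a in esters)
    distribution: dict[int, float] = {}
    if ester_area > 0:
        for a in esters:
            c = a.ester_carbon_number
            distribution[c] = distribution.get(c, 0.0) + a.peak.area / ester_area
    if composition is None:
        composition = composition_table(annotations)
    matrix: dict[tuple[str, int], float] = {}
    for carbon in composition.data.columns:
        for acid in composition.data.index:
            value = composition.cell(acid, carbon)
            if value is not None and value > 0:
                matrix[(acid, int(carbon))] = value / 100.0
    flags = {key: 0.0 for key in CLASS_FLAG_KEYS}
    if total_area > 0:
        for a in annotations:
            if a.peak_class in flags:
                flags[a.peak_class] += a.peak.area / total_area
    if ppo_ppp is None and any(a.peak_class == "triglyceride" for a in annotations):
        try:
            ppo_ppp = ratio_from_annotations(list(annotations))
        except UndefinedRatioError:
            ppo_ppp = None
    return Fingerprint(
        ester_carbon_distribution=distribution,
        acid_matrix=matrix,
        class_flags=flags,
        ppo_ppp=ppo_ppp,
    )


def _cosine(a: dict, b: dict) -> Optional[float]:
    """Cosine similarity over the key union; None when both sides are empty
    (block absent from both fingerprints)."""
    keys = sorted(set(a) | set(b), key=repr)
    if not keys:
        return None
    va = np.array([a.get(k, 0.0) for k in keys])
    vb = np.array([b.get(k, 0.0) for k in keys])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 and nb == 0:
        return None
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(va @ vb / (na * nb), 0.0, 1.0))


def similarity(
    a: Fingerprint, b: Fingerprint, weights: Optional[dict[str, float]] = None
) -> float:
    """Weighted mean of per-block cosine similarities, in [0, 1].

    Blocks absent from both fingerprints are dropped and the remaining
    weights renormalized, so identical fingerprints always score 1 and a
    block present on only one side scores 0.  The PPO/PPP block scores
    min/max agreement of the two ratios.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    scores: dict[str, Optional[float]] = {
        "distribution": _cosine(a.ester_carbon_distribution, b.ester_carbon_distribution),
        "acid_matrix": _cosine(a.acid_matrix, b.acid_matrix),
        "class_flags": _cosine(a.class_flags, b.class_flags),
    }
    if a.ppo_ppp is None and b.ppo_ppp is None:
        scores["ppo_ppp"] = None
    elif a.ppo_ppp is None or b.ppo_ppp is None:
        scores["ppo_ppp"] = 0.0
    elif a.ppo_ppp == b.ppo_ppp:
        scores["ppo_ppp"] = 1.0  # covers the 0 == 0 case
    else:
        hi = max(a.ppo_ppp, b.ppo_ppp)
        scores["ppo_ppp"] = min(a.ppo_ppp, b.ppo_ppp) / hi if hi > 0 else 0.0
    total_w = 0.0
    acc = 0.0
    for block, score in scores.items():
        w = weights.get(block, 0.0)
        if score is None or w <= 0:
            continue
        total_w += w
        acc += w * score
    if total_w == 0:
        raise UndefinedSimilarityError("both fingerprints are empty in every block")
    return acc / total_w


def fingerprint_run(
    run: Run,
    rt_model: Optional[LinearModel] = None,
    config: Optional[ClassifyConfig] = None,
) -> Fingerprint:
    """Annotate a run and assemble its fingerprint in one step."""
    if config is None:
        config = ClassifyConfig()
    if rt_model is None:
        rt_model = default_rt_model()
    panel = default_acid_panel(extended=config.extended_panel)
    annotations = annotate_run(run, rt_model, acid_panel=panel, params=config.annotate_params)
    if not annotations:
        raise EmptyFingerprintError(f"run {run.metadata.get('profile')} produced no peaks")
    return fingerprint(annotations)


# cache of reference fingerprints keyed by profile content and config
_REF_CACHE: dict[tuple, Fingerprint] = {}


def _profile_key(profile: ReferenceProfile) -> tuple:
    return (
        profile.name,
        tuple((str(s), w) for s, w in profile.ester_species),
        tuple((t.label, w) for t, w in profile.triglycerides),
        tuple((str(s), s.species_class.value, w) for s, w in profile.interferents),
    )


def _config_key(config: ClassifyConfig, rt_model: LinearModel) -> tuple:
    sim = config.sim_config
    return (
        config.extended_panel,
        config.reference_seed,
        config.annotate_params,
        rt_model.slope,
        rt_model.intercept,
        sim.peak_width_sigma,
        sim.scan_interval,
        sim.mz_range,
        sim.rt_window,
        sim.intensity_scale,
    )


def reference_fingerprint(
    profile: ReferenceProfile,
    rt_model: Optional[LinearModel] = None,
    config: Optional[ClassifyConfig] = None,
) -> Fingerprint:
    """Fingerprint of a noiseless, fixed-seed run of a reference profile."""
    if config is None:
        config = ClassifyConfig()
    if rt_model is None:
        rt_model = default_rt_model()
    key = (_profile_key(profile), _config_key(config, rt_model))
    if key not in _REF_CACHE:
        sim = replace(config.sim_config, noise_sd=0.0, seed=config.reference_seed,
                      rt_model=rt_model)
        run = generate_run(profile, sim)
        _REF_CACHE[key] = fingerprint_run(run, rt_model, config)
    return _REF_CACHE[key]


def classify(
    run: Run,
    references: Sequence[ReferenceProfile],
    config: Optional[ClassifyConfig] = None,
    rt_model: Optional[LinearModel] = None,
) -> ClassificationResult:
    """Rank reference profiles by fingerprint similarity to a query run."""
    if not references:
        raise ValueError("classify needs at least one reference profile")
    if config is None:
        config = ClassifyConfig()
    if rt_model is None:
        rt_model = default_rt_model()
    query = fingerprint_run(run, rt_model, config)
    ranked = []
    for profile in references:
        try:
            ref = reference_fingerprint(profile, rt_model, config)
        except Exception as exc:
            raise RuntimeError(
                f"reference generation failed for profile {profile.name!r}"
            ) from exc
        ranked.append((profile.name, similarity(query, ref, config.weights)))
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    margin = ranked[0][1] - ranked[1][1] if len(ranked) > 1 else 0.0
    return ClassificationResult(ranked=ranked, call=ranked[0][0], margin=margin)
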