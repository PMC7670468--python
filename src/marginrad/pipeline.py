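"""Two-stage study pipeline.

Stage 1 (model building, hysterectomy-cohort analogue): VOI construction
-> feature extraction on T2 and ADC -> ICC repeatability filter against
repeated/perturbed delineations -> Boruta all-relevant selection on the
training half -> random-forest models (all repeatable features vs the
Boruta subset) and the positive-margin baseline -> evaluation on the
frozen Youden threshold -> paired DeLong AUC comparisons.

Stage 2 (risk validation, uterine-preservation analogue): score a second
cohort with the stage-1 model, split high/low risk at the frozen
threshold, and compare disease-free survival with Kaplan–Meier /
log-rank.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn``, so stages are reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .boruta import BorutaConfig, BorutaResult, boruta_select
from .features import PrepConfig, extract_case
from .modeling import (
    delong_test,
    evaluate,
    make_split,
    margin_baseline,
    predict_scores,
    train_model,
    youden_threshold,
)
from .reliability import ICCReport, filter_repeatable
from .survival import assign_risk, km_estimate, logrank_test
from .synthetic import PhantomCase, PhantomConfig, generate_cohort, perturb_segmentation
from .voi import build_margin_voi

__all__ = ["StudyConfig", "StudyReport", "extract_cohort", "run_stage1", "run_stage2"]


@dataclass
class StudyConfig:
    """Parameters for the end-to-end phantom study.

    The phantom geometry uses 1 mm in-plane voxels, so the band-cleaning
    erosion is 1 pixel (proportionate to the 3-pixel disk on a finer
    clinical pixel grid; 3 px would consume the whole 5-voxel band here).
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    prep: PrepConfig = field(default_factory=lambda: PrepConfig(erosion_px=1))
    icc_threshold: float = 0.75
    icc_subset: int = 40          # cases re-delineated for repeatability
    icc_jitter_intra_mm: float = 0.4
    icc_jitter_inter_mm: float = 0.75
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    rf_n_estimators: int = 500
    split_ratio: float = 0.5
    #: preservation-cohort size for stage 2
    n_preservation: int = 28
    preservation_residual_fraction: float = 0.18
    seed: int = 0


@dataclass
class StudyReport:
    """Machine-checkable record of one pipeline run."""

    seed: int
    n_cases: int
    n_features_per_sequence: int
    icc: ICCReport | None
    n_repeatable: int
    kept_by_sequence: dict[str, int]
    boruta: BorutaResult | None
    n_confirmed: int
    metrics: pd.DataFrame  # model x cohort panel, Table-2 shaped
    delong: dict
    threshold: float
    survival: dict | None = None

    def metrics_dict(self) -> dict:
        return {
            f"{row.model}_{row.cohort}": row._asdict()
            for row in self.metrics.itertuples(index=False)
        }


def _stage_seeds(seed: int, n: int):
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(n)]


def extract_cohort(cases: list[PhantomCase], prep: PrepConfig, masks_override=None) -> pd.DataFrame:
    """Cases x features table with sequence-prefixed columns.

    ``masks_override`` maps case_id -> MaskSet to extract from perturbed
    delineations (the ICC repeat arms).
    """
    rows = {}
    for case in cases:
        masks = (masks_override or {}).get(case.case_id, case.masks)
        if masks.margin_voi is None:
            masks = build_margin_voi(masks, band_mm=prep.band_mm, erosion_px=prep.erosion_px)
        fv_t2, fv_adc = extract_case(case, masks, prep)
        row = {f"T2WI_{k}": v for k, v in fv_t2.entries.items()}
        row.update({f"ADC_{k}": v for k, v in fv_adc.entries.items()})
        rows[case.case_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def manifest_frame(cases: list[PhantomCase]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [c.label for c in cases],
            "margin_positive": [c.margin_positive for c in cases],
            "followup_time": [c.followup_time for c in cases],
            "event": [c.event for c in cases],
        },
        index=[c.case_id for c in cases],
    )


def _icc_filter(cases, features, cfg: StudyConfig, seed: int) -> ICCReport:
    subset = cases[: min(cfg.icc_subset, len(cases))]
    rng = np.random.default_rng(seed)
    repeat_masks, rater2_masks = {}, {}
    for case in subset:
        repeat_masks[case.case_id] = perturb_segmentation(
            case.masks, cfg.icc_jitter_intra_mm, int(rng.integers(2**31 - 1))
        )
        rater2_masks[case.case_id] = perturb_segmentation(
            case.masks, cfg.icc_jitter_inter_mm, int(rng.integers(2**31 - 1))
        )
    ids = [c.case_id for c in subset]
    fv1 = features.loc[ids]
    fv1r = extract_cohort(subset, cfg.prep, repeat_masks)
    fv2 = extract_cohort(subset, cfg.prep, rater2_masks)
    return filter_repeatable(fv1, fv1r.loc[ids, fv1.columns], fv2.loc[ids, fv1.columns], cfg.icc_threshold)


def run_stage1(config: StudyConfig, cases: list[PhantomCase] | None = None,
               features: pd.DataFrame | None = None, run_icc: bool = True) -> StudyReport:
    """Model building on the hysterectomy-cohort phantom."""
    cfg = config
    seeds = _stage_seeds(cfg.seed, 5)
    if cases is None:
        phantom = PhantomConfig(**{**asdict(cfg.phantom), "seed": seeds[0]})
        cases = generate_cohort(phantom)
    if features is None:
        features = extract_cohort(cases, cfg.prep)
    manifest = manifest_frame(cases)
    y = (manifest["label"] == "residual").astype(int)

    n_per_seq = features.columns.str.startswith("T2WI_").sum()
    if run_icc:
        icc_report = _icc_filter(cases, features, cfg, seeds[1])
        kept = icc_report.kept_ids
    else:
        icc_report, kept = None, list(features.columns)
    kept_by_seq = {
        "T2WI": sum(k.startswith("T2WI_") for k in kept),
        "ADC": sum(k.startswith("ADC_") for k in kept),
    }
    if not kept:
        raise RuntimeError("ICC filter rejected every feature; nothing to model")

    split = make_split(list(features.index), y.to_numpy(), seed=seeds[2], ratio=cfg.split_ratio)
    tr, te = split.training_ids, split.test_ids
    X = features[kept]

    boruta_cfg = BorutaConfig(**{**asdict(cfg.boruta), "seed": seeds[3]})
    boruta_res = boruta_select(X.loc[tr], y.loc[tr], boruta_cfg)
    confirmed = boruta_res.confirmed

    rows = []
    rf_model = train_model(X.loc[tr], y.loc[tr], kept, n_estimators=cfg.rf_n_estimators, seed=seeds[4])
    rf_thr = youden_threshold(predict_scores(rf_model, X.loc[tr]), y.loc[tr])
    scores = {"RF": {c: predict_scores(rf_model, X.loc[ids]) for c, ids in [("training", tr), ("test", te)]}}
    thresholds = {"RF": rf_thr}

    boruta_model = None
    if confirmed:
        boruta_model = train_model(X.loc[tr], y.loc[tr], confirmed, n_estimators=cfg.rf_n_estimators, seed=seeds[4])
        thresholds["Boruta"] = youden_threshold(predict_scores(boruta_model, X.loc[tr]), y.loc[tr])
        scores["Boruta"] = {c: predict_scores(boruta_model, X.loc[ids]) for c, ids in [("training", tr), ("test", te)]}

    for model, per_cohort in scores.items():
        for cohort, ids in [("training", tr), ("test", te)]:
            rep = evaluate(per_cohort[cohort], y.loc[ids], thresholds[model], cohort)
            rows.append({"model": model, **rep.as_dict()})
    for cohort, ids in [("training", tr), ("test", te)]:
        rep = margin_baseline(manifest.loc[ids, "margin_positive"], y.loc[ids], cohort)
        rows.append({"model": "PM", **rep.as_dict()})

    delong = {}
    if boruta_model is not None:
        delong["boruta_vs_rf"] = delong_test(scores["Boruta"]["test"], scores["RF"]["test"], y.loc[te])
        pm_scores = manifest.loc[te, "margin_positive"].astype(float).to_numpy()
        delong["boruta_vs_pm"] = delong_test(scores["Boruta"]["test"], pm_scores, y.loc[te])

    report = StudyReport(
        seed=cfg.seed,
        n_cases=len(cases),
        n_features_per_sequence=int(n_per_seq),
        icc=icc_report,
        n_repeatable=len(kept),
        kept_by_sequence=kept_by_seq,
        boruta=boruta_res,
        n_confirmed=len(confirmed),
        metrics=pd.DataFrame(rows),
        delong=delong,
        threshold=thresholds.get("Boruta", rf_thr),
    )
    report._model = boruta_model if boruta_model is not None else rf_model  # stage-2 artifact
    report._features = X
    return report


def run_stage2(config: StudyConfig, stage1: StudyReport,
               cases: list[PhantomCase] | None = None) -> dict:
    """Risk assignment + KM/log-rank on the preservation-cohort phantom."""
    cfg = config
    if getattr(stage1, "_model", None) is None:
        raise ValueError("stage-1 artifacts missing: run run_stage1 first")
    seeds = _stage_seeds(cfg.seed + 1, 2)
    if cases is None:
        phantom = PhantomConfig(**{
            **asdict(cfg.phantom),
            "n_cases": cfg.n_preservation,
            "residual_fraction": cfg.preservation_residual_fraction,
            "seed": seeds[0],
        })
        cases = generate_cohort(phantom)
    features = extract_cohort(cases, cfg.prep)
    manifest = manifest_frame(cases)
    scores = predict_scores(stage1._model, features)
    groups = assign_risk(scores, stage1.threshold)

    result = {
        "n_high": int(np.sum(groups == "high")),
        "n_low": int(np.sum(groups == "low")),
        "n_events": int(manifest["event"].sum()),
        "groups": pd.Series(groups, index=features.index),
        "km": {
            g: km_estimate(
                manifest.loc[groups == g, "followup_time"],
                manifest.loc[groups == g, "event"],
            )
            for g in np.unique(groups)
        },
        "manifest": manifest,
    }
    if result["n_high"] == 0 or result["n_low"] == 0:
        result["logrank"] = None
        result["note"] = "one risk group is empty; log-rank comparison untestable"
    else:
        result["logrank"] = logrank_test(manifest["followup_time"], manifest["event"], groups)
    return result
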