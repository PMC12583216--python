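"""End-to-end orchestration: phantoms -> segmenter -> ROI -> regressor -> report.

:func:`run_pipeline` executes the full laboratory workflow on synthetic
cohorts: generate train/validation/test phantoms, train the vertebra
segmenter, extract anatomical ROI patches using the *predicted* masks
(cases failing the ROI-coverage check are recorded and dropped, mirroring
how unusable localisations are excluded in practice), train the score
regressor, evaluate every metric on the held-out test set, and render
saliency explanations for a few cases.  Every stage draws its seed from the
global seed via ``numpy`` seed sequences and logs it, so a rerun with the
same configuration reproduces the data manifest byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, explain, io, phantom, regression, roi, segmentation
from .evaluation import PairedScores
from .kauppila import Severity

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "score_image", "load_run_config"]

log = logging.getLogger("aacscore.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "aacscore_run"
    n_train: int = 60
    n_val: int = 20
    n_test: int = 20
    severity_mix: tuple[float, float, float] = phantom.DEFAULT_SEVERITY_MIX
    seg: segmentation.SegConfig = field(default_factory=segmentation.SegConfig)
    reg: regression.RegressorConfig = field(default_factory=regression.RegressorConfig)
    train: regression.TrainConfig = field(default_factory=regression.TrainConfig.desk_preset)
    augment: regression.AugmentConfig = field(default_factory=regression.AugmentConfig)
    roi_masks: str = "predicted"  # "predicted" (two-stage) or "truth" (oracle masks)
    bootstrap_B: int = 200
    bootstrap_mode: str = "resample"
    kappa_scheme: str = "quadratic"
    acceptability_threshold: float = 4.0
    n_explain: int = 4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) < 1:
            raise ValueError("n_train, n_val and n_test must all be >= 1")
        if self.roi_masks not in ("predicted", "truth"):
            raise ValueError(f"roi_masks must be 'predicted' or 'truth', got {self.roi_masks!r}")
        self.seg.validate()
        self.reg.validate()
        self.train.validate()
        self.augment.validate()


class PipelineError(RuntimeError):
    """A stage failure, naming the stage; partial artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    for key, cls in (("seg", segmentation.SegConfig), ("reg", regression.RegressorConfig),
                     ("train", regression.TrainConfig), ("augment", regression.AugmentConfig)):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = {k: tuple(v) if isinstance(v, list) else v for k, v in kwargs[key].items()}
            kwargs[key] = cls(**sub)
    if "severity_mix" in kwargs:
        kwargs["severity_mix"] = tuple(kwargs["severity_mix"])
    return RunConfig(**kwargs)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in np.random.SeedSequence(seed).spawn(n)]


def _patches_for(samples, seg_model, target, use_truth_masks=False):
    """ROI patches via predicted (or ground-truth) masks; returns kept/dropped."""
    kept, dropped = [], []
    for s in samples:
        mask = s.vertebra_mask if use_truth_masks else segmentation.segment_vertebrae(
            seg_model, s.image, anterior_side=s.spec.anterior_side)
        report = segmentation.check_roi_coverage(mask)
        if not report.passed:
            dropped.append({"id": s.case_id, "reasons": list(report.reasons)})
            continue
        box = roi.compute_crop_box(mask)
        patch = roi.extract_patch(s.image, box, target=target, source_id=s.case_id)
        kept.append((s, mask, box, patch))
    return kept, dropped


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the evaluation report (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    (out / "stage_seeds.json").write_text(json.dumps(
        dict(zip(["train_cohort", "val_cohort", "test_cohort", "seg", "reg", "explain"], seeds[:6]))))

    # --- stage 1: simulate -------------------------------------------------
    stage = "simulate"
    try:
        cohorts = {}
        for name, n, s in (("train", config.n_train, seeds[0]),
                           ("val", config.n_val, seeds[1]),
                           ("test", config.n_test, seeds[2])):
            cohorts[name] = phantom.sample_cohort(
                phantom.CohortSpec(n_cases=n, severity_mix=config.severity_mix, seed=s))
            phantom.write_dataset(cohorts[name], out / "data" / name)
            log.info("wrote %d %s phantoms (seed %d)", n, name, s)
    except Exception as e:
        raise PipelineError(stage, e)

    # --- stage 2: segmentation training ------------------------------------
    stage = "train-seg"
    try:
        seg_cfg = dataclasses.replace(config.seg, seed=seeds[3])
        seg_model = segmentation.train_segmenter(cohorts["train"], seg_cfg)
        io.save_segmenter(seg_model, out / "models" / "segmenter")
        log.info("segmenter trained: final val Dice %.3f", seg_model.history[-1]["val_dice"])
    except Exception as e:
        raise PipelineError(stage, e)

    # --- stage 3: ROI extraction -------------------------------------------
    stage = "extract-roi"
    try:
        target = config.reg.input_size
        rois = {}
        drop_log = {}
        for name in ("train", "val", "test"):
            rois[name], drop_log[name] = _patches_for(
                cohorts[name], seg_model, target, use_truth_masks=config.roi_masks == "truth")
            log.info("%s: %d ROIs kept, %d dropped by coverage check",
                     name, len(rois[name]), len(drop_log[name]))
        (out / "roi_dropped.json").write_text(json.dumps(drop_log, indent=2))
    except Exception as e:
        raise PipelineError(stage, e)

    # --- stage 4: regressor training ---------------------------------------
    stage = "train-reg"
    try:
        tc = dataclasses.replace(config.train, seed=seeds[4])
        tr = ([p for *_, p in rois["train"]], [s.truth.total for s, *_ in rois["train"]])
        va = ([p for *_, p in rois["val"]], [s.truth.total for s, *_ in rois["val"]])
        reg_model, history = regression.train_regressor(tr, va, config.reg, tc, config.augment)
        io.save_regressor(reg_model, out / "models" / "regressor")
        import pandas as pd

        pd.DataFrame(history).to_csv(out / "models" / "regressor_history.csv", index=False)
    except Exception as e:
        raise PipelineError(stage, e)

    # --- stage 5: evaluation -----------------------------------------------
    stage = "evaluate"
    try:
        test_kept = rois["test"]
        if len(test_kept) < 2:
            raise ValueError("fewer than 2 usable test cases after coverage filtering")
        refs = [s.truth.total for s, *_ in test_kept]
        preds = [regression.predict_score(reg_model, p) for *_, p in test_kept]
        pairs = PairedScores(np.array(refs), np.array(preds),
                             ids=tuple(s.case_id for s, *_ in test_kept))
        report = evaluate_pairs(pairs, config)
        report["segmentation"] = {
            "final_val_dice": seg_model.history[-1]["val_dice"],
            "roi_coverage_rate": {
                name: 1.0 - len(drop_log[name]) / len(cohorts[name]) for name in cohorts
            },
        }
        (out / "eval_report.json").write_text(json.dumps(report, indent=2))
        (out / "eval_report.md").write_text(_markdown_report(report))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e)

    # --- stage 6: explanation ----------------------------------------------
    stage = "explain"
    try:
        rng = np.random.default_rng(seeds[5])
        chosen = rng.choice(len(test_kept), size=min(config.n_explain, len(test_kept)), replace=False)
        (out / "explain").mkdir(parents=True, exist_ok=True)
        focus = []
        for i in chosen:
            s, mask, box, patch = test_kept[i]
            heat = explain.grad_cam(reg_model, patch)
            calc_in_patch = roi.transform_mask(s.calcification_mask, box, target)
            f = explain.focus_fraction(heat, calc_in_patch, top_q=0.1, dilation=2)
            focus.append({"id": s.case_id, "focus_fraction": None if np.isnan(f) else f})
            explain.save_overlay(patch, heat, out / "explain" / f"{s.case_id}_gradcam.png")
        report["explain"] = focus
        (out / "eval_report.json").write_text(json.dumps(report, indent=2))
    except Exception as e:
        raise PipelineError(stage, e)

    return report


def evaluate_pairs(pairs: PairedScores, config: RunConfig) -> dict:
    """All evaluation statistics for one set of paired scores, as a dict."""
    m = evaluation.regression_metrics(pairs, config.acceptability_threshold)
    ci = evaluation.bootstrap_metrics(pairs, B=config.bootstrap_B, mode="resample",
                                      seed=config.seed + 17,
                                      acceptability_threshold=config.acceptability_threshold)
    rounded = np.clip(np.round(pairs.predicted), 0, 24).astype(int)
    icc = evaluation.icc_2_1(np.column_stack([pairs.reference, pairs.predicted]))
    kappa = evaluation.weighted_kappa(pairs.reference.astype(int), rounded,
                                      scheme=config.kappa_scheme)
    summary = evaluation.severity_report(pairs)
    return {
        "n_test": len(pairs),
        "metrics": {
            "mae": m.mae, "mse": m.mse, "spearman_rho": m.spearman_rho, "r2": m.r2,
            "acceptable_proportion": m.acceptable_proportion,
        },
        "ci95": {k: list(v) for k, v in ci.items()},
        "agreement": {"icc_2_1": icc, "weighted_kappa": kappa, "kappa_scheme": config.kappa_scheme},
        "confusion_matrix": summary.matrix.tolist(),
        "per_category": {
            cat.value: {name: {"percent": val, "ci95": list(ci_)}
                        for name, (val, ci_) in metrics.items()}
            for cat, metrics in summary.per_category.items()
        },
    }


def _markdown_report(report: dict) -> str:
    lines = ["# Evaluation report", "", f"Test cases: {report['n_test']}", "",
             "| Metric | Value | 95% CI |", "|---|---|---|"]
    for k, v in report["metrics"].items():
        ci = report["ci95"].get(k)
        ci_s = f"({ci[0]:.3f}, {ci[1]:.3f})" if ci else "-"
        lines.append(f"| {k} | {v:.3f} | {ci_s} |")
    ag = report["agreement"]
    lines += ["", f"ICC(2,1): {ag['icc_2_1']:.3f}; weighted kappa ({ag['kappa_scheme']}): "
              f"{ag['weighted_kappa']:.3f}", "", "## Severity confusion matrix (rows = reference)", ""]
    cats = [c.value for c in (Severity.no_mild, Severity.moderate, Severity.severe)]
    lines.append("| | " + " | ".join(cats) + " |")
    lines.append("|---|" + "---|" * 3)
    for cat, row in zip(cats, report["confusion_matrix"]):
        lines.append(f"| {cat} | " + " | ".join(str(x) for x in row) + " |")
    lines += ["", "## Per-category metrics (%)", ""]
    header = ["category", "accuracy", "sensitivity", "specificity", "npv", "ppv"]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|---|" + "---|" * 5)
    for cat, metrics in report["per_category"].items():
        cells = [cat]
        for name in header[1:]:
            v = metrics[name]["percent"]
            lo, hi = metrics[name]["ci95"]
            cells.append(f"{v:.1f} ({lo:.1f}-{hi:.1f})" if np.isfinite(v) else "undefined")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def score_image(image_path: str | Path, seg_path: str | Path, reg_path: str | Path,
                anterior_side: str = "left") -> dict:
    """Score a single saved radiograph with saved models; returns a record."""
    image = io.read_image(image_path)
    seg_model = io.load_segmenter(seg_path)
    reg_model = io.load_regressor(reg_path)
    mask = segmentation.segment_vertebrae(seg_model, image, anterior_side=anterior_side)
    report = segmentation.check_roi_coverage(mask)
    record: dict = {"image": str(image_path), "coverage_passed": report.passed,
                    "coverage_reasons": list(report.reasons)}
    if not report.passed:
        return record
    box = roi.compute_crop_box(mask)
    patch = roi.extract_patch(image, box, target=reg_model.config.input_size,
                              source_id=str(image_path))
    raw = regression.predict_score(reg_model, patch)
    record.update({
        "score_raw": raw,
        "score": float(np.clip(raw, 0, 24)),
        "category": regression.predict_category(reg_model, patch).value,
        "crop_box": patch.provenance["box"],
    })
    return record
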