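"""End-to-end orchestration: preprocess → features → CV → performance.

A run is a deterministic function of (input files, configuration, seed).
Every artifact written to disk embeds the package version and a hash of the
resolved configuration, so outputs are traceable and reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (CLASSIFIER_NAMES, ClassifierSpec, CVResult,
                       crossval_probabilities)
from .io import Cohort
from .performance import PerformanceSummary, roc_points, summarize
from .preprocess import (CropWindow, FeatureMatrix, crop, denoise_threshold,
                         realign_baseline, to_feature_matrix)

__all__ = ["RunConfig", "preprocess_cohort", "cohort_features",
           "run_comparison", "run_all"]

log = logging.getLogger("gcimsvoc")

#: The study's three pairwise comparisons; first-named group is positive.
STUDY_COMPARISONS = (("CD", "RCD"), ("CD", "HC"), ("RCD", "HC"))


@dataclass
class RunConfig:
    """Resolved settings for a full analysis run."""

    seed: int
    crop: CropWindow | None = None
    threshold_value: float | None = None
    background_window: CropWindow | None = None
    realign_reference_ms: float | None = None
    selection_k: int = 100
    cv_k: int = 10
    classifiers: tuple = tuple(ClassifierSpec(n) for n in CLASSIFIER_NAMES)
    headline: str = "svm"
    comparisons: tuple = STUDY_COMPARISONS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifiers"] = [dataclasses.asdict(c) for c in self.classifiers]
        d["crop"] = dataclasses.asdict(self.crop) if self.crop else None
        d["background_window"] = (dataclasses.asdict(self.background_window)
                                  if self.background_window else None)
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("crop"):
            d["crop"] = CropWindow(**d["crop"])
        if d.get("background_window"):
            d["background_window"] = CropWindow(**d["background_window"])
        if "classifiers" in d:
            d["classifiers"] = tuple(
                ClassifierSpec(c["name"], c.get("params", {}))
                if isinstance(c, dict) else ClassifierSpec(c)
                for c in d["classifiers"])
        if "comparisons" in d:
            d["comparisons"] = tuple(tuple(c) for c in d["comparisons"])
        if "seed" not in d:
            raise ValueError("config must declare a seed "
                             "(no silent nondeterminism)")
        return cls(**d)


def preprocess_cohort(cohort: Cohort, config: RunConfig) -> Cohort:
    """Crop → threshold → realign, logging each stage."""
    n = len(cohort)
    if config.crop is not None:
        cohort = cohort.map_chromatograms(lambda c: crop(c, config.crop))
        log.info("crop: %d samples, window=%s", n, config.crop)
    if config.threshold_value is not None or \
            config.background_window is not None:
        cohort = cohort.map_chromatograms(
            lambda c: denoise_threshold(
                c, threshold=config.threshold_value,
                background_window=config.background_window))
        log.info("threshold: value=%s auto_window=%s",
                 config.threshold_value, config.background_window)
    cohort = realign_baseline(cohort, config.realign_reference_ms)
    log.info("realign: reference=%s", config.realign_reference_ms
             or "cohort median RIP")
    return cohort


def cohort_features(cohort: Cohort, config: RunConfig) -> FeatureMatrix:
    """Full preprocessing then pixel-feature extraction."""
    fm = to_feature_matrix(preprocess_cohort(cohort, config))
    log.info("features: %d samples x %d pixels", fm.n_samples, fm.n_features)
    return fm


def _probability_frame(cv: CVResult) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": cv.sample_ids,
        "group": cv.labels,
        "fold": cv.fold_ids,
        "probability": cv.probabilities,
    })


def _write_artifacts(out_dir: Path, tag: str, name: str, cv: CVResult,
                     summary: PerformanceSummary, config: RunConfig) -> None:
    comp_dir = out_dir / tag
    comp_dir.mkdir(parents=True, exist_ok=True)
    _probability_frame(cv).to_csv(
        comp_dir / f"{name}_probabilities.csv", index=False,
        float_format="%.9g")
    pts = roc_points(cv.probabilities, cv.y.astype(bool))
    pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
        comp_dir / f"{name}_roc.csv", index=False, float_format="%.9g")
    payload = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "comparison": tag,
        "classifier": name,
        "summary": summary.to_dict(),
    }
    (comp_dir / f"{name}_summary.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True))


def run_comparison(cohort: Cohort, comparison, config: RunConfig,
                   out_dir=None) -> dict:
    """One pairwise comparison, all configured classifiers.

    Returns ``{classifier_name: {"cv": CVResult, "summary":
    PerformanceSummary}}``; writes probability/ROC CSVs and a summary JSON
    per classifier when ``out_dir`` is given.
    """
    pos, neg = comparison
    present = set(cohort.groups)
    for g in (pos, neg):
        if g not in present:
            raise ValueError(f"comparison group {g!r} not in the cohort "
                             f"(has {sorted(present)})")
    sub = cohort.subset([pos, neg])
    log.info("comparison %s vs %s: %d samples", pos, neg, len(sub))
    features = cohort_features(sub, config)
    labels = np.asarray(sub.groups)

    tag = f"{pos}_vs_{neg}"
    results = {}
    for spec in config.classifiers:
        cv = crossval_probabilities(
            features, labels, spec, positive_class=pos,
            k=config.cv_k, n_select=config.selection_k, seed=config.seed)
        summary = summarize(cv.probabilities, labels, positive_class=pos)
        results[spec.name] = {"cv": cv, "summary": summary}
        log.info("  %s: AUC=%.3f p=%.4g", spec.name, summary.auc,
                 summary.p_value)
        if out_dir is not None:
            _write_artifacts(Path(out_dir), tag, spec.name, cv, summary,
                             config)
    return results


def run_all(cohort: Cohort, config: RunConfig, out_dir=None) -> dict:
    """All configured comparisons; returns ``{tag: run_comparison(...)}``.

    When writing to disk, also emits ``headline.csv`` — one row per
    comparison for the headline classifier, mirroring the standard
    AUC (CI) / sensitivity / specificity / PPV / NPV reporting layout.
    """
    results = {}
    rows = []
    names = [c.name for c in config.classifiers]
    headline = config.headline if config.headline in names else names[0]
    for comparison in config.comparisons:
        tag = "{}_vs_{}".format(*comparison)
        results[tag] = run_comparison(cohort, comparison, config, out_dir)
        s = results[tag][headline]["summary"]
        rows.append({
            "comparison": tag,
            "auc": round(s.auc, 3),
            "ci": f"({s.ci_low:.2f}-{s.ci_high:.2f})",
            "sensitivity": round(s.sensitivity, 3),
            "specificity": round(s.specificity, 3),
            "ppv": round(s.ppv, 3) if np.isfinite(s.ppv) else "",
            "npv": round(s.npv, 3) if np.isfinite(s.npv) else "",
            "p_value": s.p_value,
        })
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out_dir / "headline.csv", index=False)
        meta = {"package_version": __version__,
                "config_hash": config.config_hash(),
                "config": config.to_dict()}
        (out_dir / "run_config.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True, default=str))
    return results
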