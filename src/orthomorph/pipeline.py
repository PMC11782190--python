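"""One-command orchestration: prep → features → cluster → NOR → associations.

The pipeline either reads per-participant recording files from a directory or
simulates a cohort, then quality-screens, extracts features, clusters with
k-means++ (k = 3 by default), applies the NOR reassignment rule and estimates
the indicator associations. All randomness flows from one seed; the config
hash and seed are recorded so a run can be reproduced bit-identically.
Outputs are written atomically (write to a temp file, then rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (ClusterModel, ClusterQuality, cluster_quality,
                         fit_kmeans, label_morphologies)
from .features import extract_features, features_to_frame, frame_to_matrix
from .frailty import association_table
from .nor_rule import NOR_THRESHOLDS, ReassignmentSummary, reassign
from .signal_prep import QualityConfig, read_recording, screen_quality
from .synthetic import SimConfig, simulate_cohort

logger = logging.getLogger("orthomorph")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Run configuration; every analysis constant is surfaced here."""

    input_dir: str | None = None        # directory of recording CSVs, or None
    simulate: bool = False
    n_simulated: int = 400
    seed: int = 0
    k: int = 3
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-6
    n_boot: int = 100                   # bootstrap resamples for Jaccard
    nor_thresholds: tuple[float, float, float] = NOR_THRESHOLDS
    quality: QualityConfig = field(default_factory=QualityConfig)
    association_models: tuple[str, ...] = ("unadjusted", "age_sex")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(str(path), encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        quality = QualityConfig(**raw.pop("quality", {}))
        if "nor_thresholds" in raw:
            raw["nor_thresholds"] = tuple(raw["nor_thresholds"])
        if "association_models" in raw:
            raw["association_models"] = tuple(raw["association_models"])
        cfg = cls(quality=quality, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2 (silhouette is undefined below)")
        if not self.simulate and not self.input_dir:
            raise ValueError("either input_dir or simulate must be set")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    features: pd.DataFrame
    model: ClusterModel
    quality: ClusterQuality
    morphology: dict[int, str]
    groups: pd.DataFrame                 # original_cluster, final_group per id
    summary: ReassignmentSummary
    associations: pd.DataFrame | None
    excluded: dict[str, list[str]]       # participant id -> QC flag kinds
    metadata: dict

    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        _atomic_csv(self.features.round(10), os.path.join(outdir, "features.csv"))
        _atomic_csv(self.groups, os.path.join(outdir, "groups.csv"))
        clusters = {
            "k": self.model.k,
            "centroids": self.model.centroids.tolist(),
            "inertia": self.model.inertia,
            "i_conv": self.model.i_conv,
            "labels": {pid: int(lab) for pid, lab
                       in zip(self.features.index, self.model.labels)},
            "morphology": {str(k): v for k, v in self.morphology.items()},
            "quality": {
                "d_c": self.quality.d_c.tolist(),
                "diameter": self.quality.diameter.tolist(),
                "d_cc": self.quality.d_cc.tolist(),
                "d_c_per_feature": self.quality.d_c_per_feature.tolist(),
                "silhouette": self.quality.silhouette,
                "jaccard": self.quality.jaccard,
            },
            "reassignment": dataclasses.asdict(self.summary),
        }
        _atomic_json(clusters, os.path.join(outdir, "clusters.json"))
        if self.associations is not None:
            _atomic_json(self.associations.to_dict(orient="records"),
                         os.path.join(outdir, "assoc.json"))
        _atomic_json(self.metadata, os.path.join(outdir, "report.json"))


def _atomic_write(text: str, path: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _atomic_json(obj, path: str) -> None:
    _atomic_write(json.dumps(obj, indent=2, sort_keys=True) + "\n", path)


def _atomic_csv(df: pd.DataFrame, path: str) -> None:
    _atomic_write(df.to_csv(lineterminator="\n"), path)


def run_pipeline(cfg: PipelineConfig,
                 participants: pd.DataFrame | None = None) -> ReportBundle:
    """Execute the full analysis and return the report bundle.

    ``participants`` (covariates/indicators indexed by participant id) is
    required for the association stage when reading real recordings; it is
    generated internally when simulating.
    """
    cfg.validate()

    if cfg.simulate:
        sim_cfg = SimConfig(n=cfg.n_simulated, seed=cfg.seed)
        recordings, participants = simulate_cohort(sim_cfg)
        logger.info("simulated %d recordings", len(recordings))
    else:
        recordings = {}
        for name in sorted(os.listdir(cfg.input_dir)):
            if name.endswith(".csv") and name != "participants.csv":
                rec = read_recording(os.path.join(cfg.input_dir, name))
                recordings[rec.participant_id] = rec
        logger.info("read %d recordings from %s", len(recordings), cfg.input_dir)
    if not recordings:
        raise ValueError("no recordings to analyse")

    excluded: dict[str, list[str]] = {}
    fvs = []
    for pid, rec in recordings.items():
        try:
            report = screen_quality(rec, cfg.quality)
            if not report.passed:
                excluded[pid] = sorted({f.kind for f in report.flags})
                continue
            fvs.append(extract_features(rec))
        except Exception as exc:
            raise RuntimeError(f"stage signal_prep failed for {pid}: {exc}") from exc
    logger.info("quality screen: %d passed, %d excluded", len(fvs), len(excluded))
    if len(fvs) < cfg.k:
        raise ValueError("fewer analyzable recordings than clusters")

    features = features_to_frame(fvs)
    X = frame_to_matrix(features)
    model = fit_kmeans(X, cfg.k, rng=cfg.seed, n_init=cfg.n_init,
                       max_iter=cfg.max_iter, tol=cfg.tol)
    quality = cluster_quality(X, model, n_boot=cfg.n_boot, rng=cfg.seed)
    morphology = (label_morphologies(model) if cfg.k == 3
                  else {j: f"cluster{j}" for j in range(cfg.k)})

    cluster_names = pd.Series(
        [morphology[int(l)] for l in model.labels], index=features.index
    )
    groups, summary = reassign(cluster_names, features, cfg.nor_thresholds)

    associations = None
    if participants is not None:
        indicator_cols = [c for c in participants.columns
                          if participants[c].dtype == bool and c != "female"]
        kept = participants.index.intersection(groups.index)
        cov = participants.loc[kept, [c for c in ("age", "female")
                                      if c in participants.columns]]
        try:
            associations = association_table(
                groups.loc[kept, "final_group"],
                participants.loc[kept, indicator_cols],
                covariates=cov if len(cov.columns) == 2 else None,
                models=cfg.association_models,
                on_error="skip",
            )
        except RuntimeError as exc:
            raise RuntimeError(f"stage frailty_analysis failed: {exc}") from exc

    metadata = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_input": len(recordings),
        "n_analyzed": int(len(features)),
        "n_excluded": len(excluded),
        "cluster_sizes": {morphology[j]: int(np.sum(model.labels == j))
                          for j in range(cfg.k)},
        "nor_size": summary.nor_size,
    }
    return ReportBundle(
        features=features, model=model, quality=quality, morphology=morphology,
        groups=groups, summary=summary, associations=associations,
        excluded=excluded, metadata=metadata,
    )
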