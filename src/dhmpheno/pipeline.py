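"""Single-config orchestration of the full analysis with a run manifest.

One global seed deterministically derives per-stage seeds via
``numpy.random.SeedSequence(global_seed, spawn_key=(stage_index,))``, so
any stage can be re-run reproducibly in isolation.  The manifest records
versions, all seeds, and cell counts per stage; re-running with the same
config reproduces every numeric output byte-for-byte.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierSpec, balance_classes, cross_validate
from .features import FEATURE_NAMES_V1, compute_features, features_to_frame
from .heterogeneity import compare_heterogeneity, embed_umap, heterogeneity_score
from .phantoms import (EPITHELIAL, MESENCHYMAL, match_to_truth,
                       render_spike_in, write_scene)
from .preprocess import extract_cells

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "preprocess", "features", "classify", "embed")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: SeedSequence(global, spawn_key=(stage index,))."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated, file-round-trippable pipeline configuration."""

    seed: int = 0
    out_dir: str = "dhm_pheno_run"
    # either simulate a scene ...
    simulate: dict = field(default_factory=lambda: {
        "n_cells": 500, "p_mesenchymal": 0.5, "cells_per_frame": 12,
        "noise_sd_rad": 0.05})
    # ... or read an existing stack (multi-page float TIFF + optional truth)
    input_tiff: str | None = None
    truth_csv: str | None = None
    preprocess: dict = field(default_factory=lambda: {
        "background_n": 50, "threshold": 0.8, "min_area": 30, "patch": 96})
    classify: dict = field(default_factory=lambda: {
        "enabled": True, "methods": ["random_forest"], "folds": 5})
    embedding: dict = field(default_factory=lambda: {
        "enabled": False, "n_neighbors": 15, "min_dist": 0.1})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {artifact}: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/ingest -> preprocess -> features -> classify ->
    embed+score; returns the manifest dict (also written to manifest.json).
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "global_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "counts": {},
    }

    # --- simulate or ingest -------------------------------------------------
    truth = None
    if config.input_tiff is not None:
        import tifffile

        frames = tifffile.imread(config.input_tiff)
        if frames.ndim == 2:
            frames = frames[None]
        if config.truth_csv is not None:
            truth_df = pd.read_csv(config.truth_csv)
        else:
            truth_df = None
    else:
        sim = config.simulate
        n_cells = int(sim.get("n_cells", 500))
        frames, truth, _ = render_spike_in(
            float(sim.get("p_mesenchymal", 0.5)), n_cells,
            stage_seed(config.seed, "simulate"),
            cells_per_frame=int(sim.get("cells_per_frame", 12)),
            noise_sd_rad=float(sim.get("noise_sd_rad", 0.05)))
        write_scene(out / "scene", frames, truth)
        truth_df = None
    manifest["counts"]["frames"] = int(frames.shape[0])
    manifest["counts"]["cells_simulated"] = len(truth) if truth is not None else None

    # --- preprocess ---------------------------------------------------------
    pp = config.preprocess
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            extraction = extract_cells(
                frames, background_n=int(pp.get("background_n", 50)),
                threshold=float(pp.get("threshold", 0.8)),
                min_area=int(pp.get("min_area", 30)),
                patch_size=int(pp.get("patch", 96)))
    except Exception as e:  # noqa: BLE001 - abort with stage context
        raise StageError("preprocess", str(out / "scene"), e) from e
    manifest["counts"].update({
        "contours_detected": extraction.contours_detected,
        "survivors": extraction.survivors,
        "area_rejections": extraction.area_rejections,
        "border_rejections": extraction.border_rejections,
    })

    # --- features -----------------------------------------------------------
    vectors = [compute_features(p) for p in extraction.patches]
    fdf = features_to_frame(vectors)
    fdf.to_csv(out / "features.csv", index=False, float_format="%.10g")
    manifest["counts"]["features_qc_pass"] = int(fdf["qc_pass"].sum()) if len(fdf) else 0

    ok = fdf.index[fdf["qc_pass"]].to_numpy() if len(fdf) else np.array([], dtype=int)
    X = fdf.loc[ok, list(FEATURE_NAMES_V1)].to_numpy() if len(ok) else np.empty((0, len(FEATURE_NAMES_V1)))
    labels = None
    if truth is not None and len(ok):
        cents = np.array([extraction.patches[i].centroid for i in ok])
        fids = np.array([extraction.patches[i].frame_id for i in ok])
        matched = match_to_truth(cents, fids, truth)
        labels = np.array([m if m is not None else "unmatched" for m in matched])

    # --- classify -----------------------------------------------------------
    manifest["counts"]["cells_classified"] = 0
    if config.classify.get("enabled", True) and labels is not None:
        keep = labels != "unmatched"
        classes, counts = (np.unique(labels[keep], return_counts=True)
                           if keep.any() else (np.array([]), np.array([])))
        folds = int(config.classify.get("folds", 5))
        if classes.size >= 2 and counts.min() >= max(10, folds):
            seed_c = stage_seed(config.seed, "classify")
            Xb, yb, _ = balance_classes(X[keep], labels[keep], seed=seed_c)
            reports = {}
            for method in config.classify.get("methods", ["random_forest"]):
                rep = cross_validate(Xb, yb, ClassifierSpec(method=method, seed=seed_c),
                                     n_folds=folds)
                reports[method] = rep.to_dict()
            with open(out / "classification.json", "w") as fh:
                json.dump(reports, fh, indent=2, sort_keys=True)
            manifest["counts"]["cells_classified"] = int(yb.size)
        else:
            manifest["classify_skipped"] = "insufficient labelled cells per class"

    # --- embed + heterogeneity ---------------------------------------------
    if config.embedding.get("enabled", False) and labels is not None and len(ok) >= 10:
        emb = embed_umap(X, labels,
                         n_neighbors=int(config.embedding.get("n_neighbors", 15)),
                         min_dist=float(config.embedding.get("min_dist", 0.1)),
                         seed=stage_seed(config.seed, "embed"))
        het = heterogeneity_score(emb)
        pd.DataFrame({"cell_id": ok, "x": emb.coords[:, 0],
                      "y": emb.coords[:, 1], "sample": labels,
                      "d": het.per_cell_d}).to_csv(out / "embedding.csv",
                                                   index=False,
                                                   float_format="%.10g")
        summary = {"per_sample_mean": het.per_sample_mean}
        if len(het.per_sample_mean) >= 2:
            summary["comparison"] = compare_heterogeneity(het)
        with open(out / "heterogeneity.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
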