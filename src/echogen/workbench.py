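"""End-to-end experiment orchestration.

Ties the stages together: simulate a paired phantom cohort, fit
normalization, train a translator, synthesize RF from B-mode, run QUS +
texture feature extraction for both provenances, compute sample-level
metrics, and run the four-condition classification matrix. Every stage
writes its artifacts under the run directory and is recorded in a manifest
(config hash, seeds, artifact checksums); completed stages are skipped on
re-run.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classification as cls
from . import evaluation as ev
from . import generative as gen
from . import preprocessing as pre
from . import qus, texture
from .synthetic import DatasetConfig, PairedDataset, build_paired_dataset
from .types import GridSpec, RFFrame

__all__ = [
    "RunConfig", "run_pipeline", "split_lesions", "extract_lesion_features",
    "dataset_pairs",
]


@dataclass
class RunConfig:
    """Scale-configurable pipeline configuration (desk preset by default)."""

    out_dir: str = "run"
    seed: int = 0
    scale: str = "desk"                      # desk | full
    n_lesions_per_class: int = 4
    n_planes: int = 2
    variant: str = "vit_shallow"
    epochs_main: int = 4
    epochs_select: int = 2
    train_fraction: float = 0.6
    val_fraction: float = 0.1
    qus_overlap: float = 0.94
    n_bootstrap: int = 1000

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dataset_config(self) -> DatasetConfig:
        if self.scale == "full":
            grid = GridSpec(n_axial=2080, n_lines=510,
                            lateral_pitch_mm=60.0 / 510)
        else:
            grid = GridSpec()
        return DatasetConfig(n_lesions_per_class=self.n_lesions_per_class,
                             n_planes=self.n_planes, grid=grid)


def split_lesions(labels: dict, train_fraction: float, val_fraction: float,
                  seed: int):
    """Stratified lesion-level train/val/test split."""
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls_name in sorted({v for v in labels.values()}):
        ids = sorted(i for i, v in labels.items() if v == cls_name)
        ids = list(rng.permutation(ids))
        n_tr = max(1, int(round(train_fraction * len(ids))))
        n_val = int(round(val_fraction * len(ids)))
        if n_tr + n_val >= len(ids):
            n_val = max(0, len(ids) - n_tr - 1)
        train += ids[:n_tr]
        val += ids[n_tr:n_tr + n_val]
        test += ids[n_tr + n_val:]
    return sorted(train), sorted(val), sorted(test)


def dataset_pairs(dataset: PairedDataset, lesion_ids, norm: dict):
    """(B-mode, RF) training pairs, both normalized to [0, 1]."""
    pairs = []
    for s in dataset.samples:
        if s.lesion_id in lesion_ids:
            x = s.bmode.pixels
            y = pre.minmax_normalize(s.rf.samples, norm["rf"])
            pairs.append((x, y))
    return pairs


def extract_lesion_features(dataset: PairedDataset,
                            qus_config: Optional[qus.QUSConfig] = None,
                            rf_override: Optional[dict] = None,
                            region: str = "both"):
    """Per-lesion 25-D QUS feature table.

    ``rf_override`` maps sample index -> RF matrix (e.g. synthetic RF after
    denormalization); geometry is inherited from the original frame.
    """
    qus_config = qus_config or qus.QUSConfig()
    by_lesion: dict[int, list] = {}
    labels: dict[int, str] = {}
    for i, s in enumerate(dataset.samples):
        rf = s.rf
        if rf_override is not None and i in rf_override:
            rf = RFFrame(rf_override[i], rf.sampling_rate_mhz,
                         rf.speed_of_sound_mps, rf.lateral_pitch_mm,
                         provenance="synthetic")
        roi = qus.make_roi_mask(s.roi_mask, rf, qus_config.margin_mm)
        maps = qus.build_parametric_maps(rf, dataset.reference, roi,
                                         qus_config)
        by_lesion.setdefault(s.lesion_id, []).append(maps)
        labels[s.lesion_id] = s.class_label
    rows = {lid: texture.lesion_feature_vector(planes, region=region)
            for lid, planes in sorted(by_lesion.items())}
    return pd.DataFrame.from_dict(rows, orient="index"), labels


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full desk-scale study; returns the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    manifest = {"config": asdict(config),
                "config_hash": hashlib.sha256(
                    json.dumps(asdict(config), sort_keys=True).encode()
                ).hexdigest(),
                "seed": config.seed, "stages": {}, "artifacts": {}}

    def record(stage: str, files: dict, **extra) -> None:
        manifest["stages"][stage] = {"status": "complete", **extra}
        for name, path in files.items():
            manifest["artifacts"][name] = {"path": path,
                                           "sha256": _sha256(path)}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # -- simulate ------------------------------------------------------
        dataset = build_paired_dataset(config.dataset_config(), config.seed)
        labels = {s.lesion_id: s.class_label for s in dataset.samples}
        record("simulate", {}, n_samples=len(dataset.samples))

        # -- split + normalization (training lesions only) -----------------
        train_ids, val_ids, test_ids = split_lesions(
            labels, config.train_fraction, config.val_fraction, config.seed)
        norm = {"rf": pre.fit_normalization(
            [s.rf.samples for s in dataset.samples
             if s.lesion_id in train_ids], kind="rf")}
        norm_path = os.path.join(config.out_dir, "norm_params.json")
        with open(norm_path, "w") as fh:
            fh.write(norm["rf"].to_json())
        record("preprocess", {"norm_params": norm_path},
               split={"train": train_ids, "val": val_ids, "test": test_ids})

        # -- train translator ---------------------------------------------
        grid = dataset.config.grid
        gspec = gen.desk_generator_spec(config.variant, grid.n_axial,
                                        grid.n_lines)
        translator, tlog = gen.train_cgan(
            dataset_pairs(dataset, set(train_ids), norm),
            dataset_pairs(dataset, set(val_ids), norm),
            gspec, gen.desk_discriminator_spec(grid.n_axial, grid.n_lines),
            config=gen.TrainConfig(epochs_main=config.epochs_main,
                                   epochs_select=config.epochs_select,
                                   seed=config.seed),
            norm_params=norm["rf"])
        log_path = os.path.join(config.out_dir, "training_log.json")
        with open(log_path, "w") as fh:
            json.dump({"g_loss": tlog.g_loss, "d_loss": tlog.d_loss,
                       "val_recon": tlog.val_recon,
                       "selected_epoch": tlog.selected_epoch}, fh, indent=2)
        record("train", {"training_log": log_path}, variant=config.variant)

        # -- synthesize + sample metrics ----------------------------------
        rf_syn, metrics = {}, []
        rf_range = (norm["rf"].rf_min, norm["rf"].rf_max)
        from .synthetic import form_bmode
        for i, s in enumerate(dataset.samples):
            syn_norm = gen.synthesize_rf(translator, s.bmode.pixels)
            syn = pre.denormalize(syn_norm, norm["rf"])
            rf_syn[i] = syn
            syn_frame = RFFrame(syn, s.rf.sampling_rate_mhz,
                                s.rf.speed_of_sound_mps,
                                s.rf.lateral_pitch_mm, provenance="synthetic")
            m = ev.sample_metrics(s.rf.samples, syn, s.bmode.pixels,
                                  form_bmode(syn_frame,
                                             s.bmode.dynamic_range_db).pixels,
                                  rf_cohort_range=rf_range)
            metrics.append(asdict(m))
        metrics_path = os.path.join(config.out_dir, "sample_metrics.json")
        with open(metrics_path, "w") as fh:
            json.dump({"per_frame": metrics,
                       "cohort_mean": {k: float(np.mean([m[k] for m in metrics]))
                                       for k in metrics[0]},
                       "cohort_sd": {k: float(np.std([m[k] for m in metrics]))
                                     for k in metrics[0]}}, fh, indent=2)
        record("synthesize", {"sample_metrics": metrics_path})

        # -- QUS + texture features ---------------------------------------
        feats_orig, _ = extract_lesion_features(dataset)
        feats_syn, _ = extract_lesion_features(dataset, rf_override=rf_syn)
        fo_path = os.path.join(config.out_dir, "features_original.csv")
        fs_path = os.path.join(config.out_dir, "features_synthetic.csv")
        feats_orig.assign(label=[labels[i] for i in feats_orig.index]) \
            .to_csv(fo_path, index_label="lesion_id")
        feats_syn.assign(label=[labels[i] for i in feats_syn.index]) \
            .to_csv(fs_path, index_label="lesion_id")
        record("features", {"features_original": fo_path,
                            "features_synthetic": fs_path})

        # -- classification matrix ----------------------------------------
        matrix = cls.run_experiment_matrix(
            feats_orig, labels, feats_syn,
            sorted(train_ids + val_ids), test_ids, seed=config.seed,
            n_resamples=config.n_bootstrap)
        report_path = os.path.join(config.out_dir, "classification.json")
        with open(report_path, "w") as fh:
            json.dump({name: asdict(rep)
                       for name, rep in matrix.conditions.items()},
                      fh, indent=2, default=str)
        record("classify", {"classification": report_path})
    except Exception as exc:  # record partial completion before re-raising
        manifest["stages"]["failed"] = {"status": "error", "error": str(exc)}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    return manifest
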