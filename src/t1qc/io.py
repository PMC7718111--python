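"""On-disk formats and the end-to-end pipeline.

Each simulated case is a directory of NIfTI volumes (the 7-frame IRW stack,
the T1 map, the R² map, six segment masks) with a JSON sidecar carrying the
centroid, seed and motion schedule; dataset-level labels live in one CSV.
Model checkpoints are self-describing ``.npz`` archives embedding the
network configuration.  A pipeline run is reproducible from its manifest:
one master seed is fanned out to the simulation, fold split and both
training arms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .network import MotionClassifier, NetworkConfig, build_classifier
from .phantom import (
    AcquisitionConfig,
    ConfigurationError,
    MotionSchedule,
    N_FRAMES,
    N_SEGMENTS,
    SegmentMaskSet,
    SyntheticCase,
    generate_dataset,
)
from .training import TrainConfig, make_folds, prepare_samples, train

__all__ = [
    "write_case",
    "read_case",
    "write_labels",
    "read_labels",
    "save_checkpoint",
    "load_checkpoint",
    "RunManifest",
    "run_pipeline",
]


def _nifti(arr: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine=np.eye(4))


def write_case(case: SyntheticCase, out_dir: str | Path) -> dict[str, str]:
    """Write one case as NIfTI volumes plus a JSON sidecar; returns paths."""
    d = Path(out_dir) / case.case_id
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    # IRW stack stored frames-last so each volume is one inversion time
    nib.save(_nifti(np.moveaxis(case.irw_stack, 0, -1)), d / "irw.nii.gz")
    nib.save(_nifti(case.t1_map), d / "t1.nii.gz")
    nib.save(_nifti(case.r2_map), d / "r2.nii.gz")
    for s in range(N_SEGMENTS):
        nib.save(_nifti(case.segment_masks.masks[s].astype(np.float32)),
                 d / f"mask_seg{s + 1}.nii.gz")
    sidecar = {
        "case_id": case.case_id,
        "seed": case.seed,
        "lv_centroid": list(map(float, case.lv_centroid)),
        "inversion_times": [float(t) for t in case.inversion_times],
        "rv_insertion_angle": case.segment_masks.rv_insertion_angle,
        "motion": {
            "per_frame_shift": [list(map(float, s)) for s in case.motion.per_frame_shift],
            "reference_frame": case.motion.reference_frame,
        },
        "labels": [int(v) for v in case.labels],
        "metadata": case.metadata,
    }
    (d / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    for p in sorted(d.iterdir()):
        paths[p.name] = str(p)
    return paths


def read_case(case_dir: str | Path) -> SyntheticCase:
    """Round-trip reader for :func:`write_case` output, with validation."""
    d = Path(case_dir)
    sidecar_path = d / "sidecar.json"
    if not sidecar_path.exists():
        raise ConfigurationError(f"missing sidecar.json in {d}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as e:
        raise ConfigurationError(f"malformed sidecar in {d}: {e}") from e

    irw = np.asarray(nib.load(d / "irw.nii.gz").dataobj, dtype=np.float32)
    if irw.ndim != 3 or irw.shape[-1] != N_FRAMES:
        raise ConfigurationError(
            f"expected 7 frames in irw stack, got shape {irw.shape}"
        )
    irw = np.moveaxis(irw, -1, 0)
    t1 = np.asarray(nib.load(d / "t1.nii.gz").dataobj, dtype=np.float32)
    r2 = np.asarray(nib.load(d / "r2.nii.gz").dataobj, dtype=np.float32)
    masks = np.stack(
        [
            np.asarray(nib.load(d / f"mask_seg{s + 1}.nii.gz").dataobj) > 0.5
            for s in range(N_SEGMENTS)
        ]
    )
    if t1.shape != irw.shape[1:] or masks.shape[1:] != irw.shape[1:]:
        raise ConfigurationError("mask/image shape mismatch")
    labels = np.asarray(sidecar["labels"], dtype=int)
    return SyntheticCase(
        irw_stack=irw,
        inversion_times=np.asarray(sidecar["inversion_times"], dtype=float),
        t1_map=t1,
        r2_map=r2,
        lv_centroid=tuple(sidecar["lv_centroid"]),
        segment_masks=SegmentMaskSet(
            masks=masks, rv_insertion_angle=sidecar["rv_insertion_angle"]
        ),
        labels=labels,
        motion=MotionSchedule(
            per_frame_shift=tuple(
                tuple(s) for s in sidecar["motion"]["per_frame_shift"]
            ),
            reference_frame=sidecar["motion"]["reference_frame"],
        ),
        seed=sidecar["seed"],
        case_id=sidecar["case_id"],
        metadata=sidecar.get("metadata", {}),
    )


def write_labels(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    seg_cols = [f"seg{i}" for i in range(1, N_SEGMENTS + 1)]
    missing = [c for c in seg_cols + ["case_id"] if c not in table.columns]
    if missing:
        raise ConfigurationError(f"labels CSV missing columns: {missing}")
    if not np.isin(table[seg_cols].values, (0, 1)).all():
        raise ConfigurationError("labels CSV contains non-binary entries")
    return table


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MotionClassifier, path: str | Path, **meta) -> None:
    """Self-describing checkpoint: weights plus the embedded network config."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    header = {"network": dataclasses.asdict(model.config), "meta": meta}
    np.savez_compressed(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **payload)


def load_checkpoint(path: str | Path) -> MotionClassifier:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        net_kwargs = header["network"]
        for key in ("stem_kernel", "block_counts", "stage_channels"):
            net_kwargs[key] = tuple(net_kwargs[key])
        model = build_classifier(NetworkConfig(**net_kwargs))
        model.load_state_dict(
            {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        )
    return model


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    created: str
    stages: dict
    out_dir: str

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "out_dir": "runs/demo",
    "simulate": {"n_cases": 100, "prevalence": 0.4, "image_size": 64, "noise_sd": 0.02},
    "network": {"crop_size": 64, "stage_channels": [16, 32, 64, 128]},
    "training": {
        "batch_size": 16,
        "initial_lr": 3e-3,
        "max_epochs": 4,
        "plateau_patience_epochs": 3,
        "early_stop_patience_epochs": 4,
        "max_translation_px": 4.0,
        "k_folds": 5,
        "repetitions": 1,
    },
    "evaluation": {"threshold": 0.5},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def run_pipeline(config: dict | str | Path) -> RunManifest:
    """simulate → train both arms (with / without attention supervision) →
    evaluate → attention maps, all funnelled through one master seed.

    Writes ``report.json`` comparing the two arms (agreement, ROC-AUC at
    per-segment and per-case level, DeLong p) plus per-arm score tables,
    histories, checkpoints and example attention overlays, and returns the
    manifest describing every artefact.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_PIPELINE_CONFIG, config)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    # -- simulate ---------------------------------------------------------
    sim = cfg["simulate"]
    acq = AcquisitionConfig(
        image_size=int(sim["image_size"]), noise_sd=float(sim["noise_sd"])
    )
    cases, labels = generate_dataset(
        int(sim["n_cases"]), float(sim["prevalence"]), acq, seed=seed
    )
    cases_dir = out_dir / "cases"
    for case in cases:
        write_case(case, cases_dir)
    write_labels(labels, out_dir / "labels.csv")
    stages["simulate"] = {
        "n_cases": len(cases),
        "labels": str(out_dir / "labels.csv"),
        "cases_dir": str(cases_dir),
    }

    # -- train both arms --------------------------------------------------
    net_kwargs = dict(cfg["network"])
    for key in ("stage_channels", "block_counts", "stem_kernel"):
        if key in net_kwargs:
            net_kwargs[key] = tuple(net_kwargs[key])
    net_config = NetworkConfig(**net_kwargs)
    tr = dict(cfg["training"])
    k = int(tr.pop("k_folds"))
    repetitions = int(tr.pop("repetitions"))
    train_config = TrainConfig(seed=seed + 1, **tr)

    samples = prepare_samples(cases, net_config.crop_size)
    folds = make_folds(
        [s.case_id for s in samples],
        k=k,
        seed=seed + 2,
        stratify_labels=np.array([int(s.labels.any()) for s in samples]),
    )
    arms = {}
    for arm, supervised in (("baseline", False), ("attention", True)):
        result = _train_arm(samples, folds, net_config, train_config,
                            supervised, repetitions)
        table = result["score_table"]
        table.to_csv(out_dir / f"scores_{arm}.csv", index=False)
        for rep, (model, hist) in enumerate(zip(result["models"], result["histories"])):
            hist.to_csv(out_dir / f"history_{arm}_rep{rep}.csv", index=False)
            save_checkpoint(model, out_dir / f"model_{arm}_rep{rep}.npz",
                            arm=arm, repetition=rep, seed=seed)
        arms[arm] = result
        stages[f"train_{arm}"] = {
            "scores": str(out_dir / f"scores_{arm}.csv"),
            "repetitions": repetitions,
        }

    # -- evaluate ---------------------------------------------------------
    thr = float(cfg["evaluation"]["threshold"])
    report = {"arms": {}, "comparison": {}}
    tables = {}
    for arm, result in arms.items():
        table = result["score_table"]
        scores = table[[f"score{i}" for i in range(1, 7)]].values
        labels_arr = table[[f"label{i}" for i in range(1, 7)]].values
        tables[arm] = (scores, labels_arr)
        pred = ev.binarise(scores, thr)
        report["arms"][arm] = {
            "per_segment_agreement_pct": ev.agreement(pred, labels_arr, "per_segment"),
            "whole_image_agreement_pct": ev.agreement(pred, labels_arr, "per_image"),
            "per_segment_auc": ev.roc_auc(scores.ravel(), labels_arr.ravel()).auc,
            "per_case_auc": ev.roc_auc(
                ev.whole_image_score(scores),
                [ev.whole_image_label(l) for l in labels_arr],
            ).auc,
        }
    (sa, la), (sb, lb) = tables["attention"], tables["baseline"]
    if not np.array_equal(la, lb):
        raise RuntimeError("arms scored different cases; cannot compare")
    seg_cmp = ev.delong_compare(sa.ravel(), sb.ravel(), la.ravel())
    case_cmp = ev.delong_compare(
        ev.whole_image_score(sa), ev.whole_image_score(sb),
        [ev.whole_image_label(l) for l in la],
    )
    report["comparison"] = {
        "per_segment": dataclasses.asdict(seg_cmp),
        "per_case": dataclasses.asdict(case_cmp),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=float))
    stages["evaluate"] = {"report": str(report_path)}

    # -- attention overlays -----------------------------------------------
    overlay_dir = out_dir / "attention_maps"
    model = arms["attention"]["models"][0]
    example = next(s for s in samples if s.labels.any())
    written = save_attention_maps(model, example, overlay_dir)
    stages["attend"] = {"outputs": [str(p) for p in written]}

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        seed=seed,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        stages=stages,
        out_dir=str(out_dir),
    )
    manifest.save(out_dir / "manifest.json")
    return manifest


def _train_arm(samples, folds, net_config, train_config, supervised, repetitions):
    if repetitions >= folds.k:
        return train(samples, folds, net_config, train_config, supervised)
    # reduced run: only the first `repetitions` rotations of the 5-fold cycle
    from .training import predict_scores, train_fold

    by_id = {s.case_id: i for i, s in enumerate(samples)}
    rows, models, histories = [], [], []
    for rep in range(repetitions):
        train_f, val_f, test_f = folds.roles(rep)
        train_idx = [by_id[c] for f in train_f for c in folds.fold_ids(f)]
        val_idx = [by_id[c] for c in folds.fold_ids(val_f)]
        test_idx = [by_id[c] for c in folds.fold_ids(test_f)]
        model, hist = train_fold(
            samples, train_idx, val_idx, net_config, train_config,
            supervised_attention=supervised, seed=train_config.seed + 9973 * rep,
        )
        test_samples = [samples[i] for i in test_idx]
        scores = predict_scores(model, test_samples, train_config.batch_size)
        for s, sc in zip(test_samples, scores):
            row = {"case_id": s.case_id, "fold": rep}
            row.update({f"score{k + 1}": float(sc[k]) for k in range(N_SEGMENTS)})
            row.update({f"label{k + 1}": int(s.labels[k]) for k in range(N_SEGMENTS)})
            rows.append(row)
        models.append(model)
        histories.append(hist)
    table = pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)
    return {"models": models, "histories": histories, "score_table": table}


def save_attention_maps(model, sample, out_dir: str | Path) -> list[Path]:
    """Per-segment Grad-CAM overlays (PNG) and raw maps (NIfTI) for one case."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .attention import grad_cam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    fig, axes = plt.subplots(2, 3, figsize=(9, 6))
    for s, ax in zip(range(1, N_SEGMENTS + 1), axes.ravel()):
        cam, _ = grad_cam(model, sample.model_input, s)
        nii_path = out_dir / f"{sample.case_id}_gradcam_seg{s}.nii.gz"
        nib.save(_nifti(cam.map), nii_path)
        written.append(nii_path)
        ax.imshow(sample.model_input.t1_image, cmap="gray")
        ax.imshow(cam.map, cmap="inferno", alpha=0.5)
        ax.contour(sample.masks[s - 1], levels=[0.5], colors="cyan", linewidths=0.6)
        ax.set_title(f"segment {s} (label {sample.labels[s - 1]})", fontsize=8)
        ax.axis("off")
    png_path = out_dir / f"{sample.case_id}_gradcam.png"
    fig.tight_layout()
    fig.savefig(png_path, dpi=110)
    plt.close(fig)
    written.append(png_path)
    return written
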