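"""Stage-by-stage pipeline over a working directory.

Each command reads the artifacts of the previous stage from the working
directory and writes its own, together with a run-manifest entry carrying the
hash of the configuration that produced it.  With a fixed config and seed
every artifact is byte-for-byte reproducible.

Artifacts
    cohort/                 per-record CSVs + manifest.csv   (simulate)
    images.npy, vectors.npy, image_manifest.csv              (preprocess)
    model/                  filter banks + params            (train)
    classifier/             linear-classifier arrays         (train)
    features_train.*        sparse feature arrays            (train)
    features_test.*, predictions.csv, accuracy.json,
    confusion.csv                                            (evaluate)
    sweep.csv                                                (sweep)
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from . import classify, network
from .config import PipelineConfig
from .io import read_cohort
from .preprocessing import build_beat_vector, to_image
from .synthetic import generate_cohort, write_cohort

__all__ = ["run_pipeline"]

log = logging.getLogger("eecgnet")

_COMMANDS = ("simulate", "preprocess", "train", "evaluate", "sweep")


def _stamp(workdir: Path, stage: str, config: PipelineConfig, artifacts: list[str]) -> None:
    manifest_path = workdir / "run_manifest.json"
    entries = json.loads(manifest_path.read_text()) if manifest_path.exists() else []
    entries = [e for e in entries if e["stage"] != stage]
    entries.append({"stage": stage, "config_hash": config.config_hash(),
                    "seed": config.seed, "artifacts": artifacts})
    manifest_path.write_text(json.dumps(entries, indent=2, sort_keys=True))


def _save_sparse(path_prefix: Path, X: sparse.csr_matrix) -> list[str]:
    np.save(f"{path_prefix}_data.npy", X.data)
    np.save(f"{path_prefix}_indices.npy", X.indices)
    np.save(f"{path_prefix}_indptr.npy", X.indptr)
    np.save(f"{path_prefix}_shape.npy", np.array(X.shape))
    return [f"{path_prefix.name}_{s}.npy" for s in ("data", "indices", "indptr", "shape")]


def _load_sparse(path_prefix: Path) -> sparse.csr_matrix:
    return sparse.csr_matrix(
        (
            np.load(f"{path_prefix}_data.npy"),
            np.load(f"{path_prefix}_indices.npy"),
            np.load(f"{path_prefix}_indptr.npy"),
        ),
        shape=tuple(np.load(f"{path_prefix}_shape.npy")),
    )


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing artifact {path.name}: run `{hint}` first")
    return path


def _preprocess_kwargs(config: PipelineConfig) -> dict:
    return dict(
        baseline_width=config.baseline_width,
        smooth_width=config.smooth_width,
        window=config.beat_window,
        refractory=config.refractory,
        rel_threshold=config.rel_threshold,
    )


def _cmd_simulate(config: PipelineConfig, workdir: Path) -> None:
    cohort = generate_cohort(
        n_subjects=config.n_subjects,
        records_per_subject=config.records_per_subject,
        duration=config.duration,
        fs=config.fs,
        noise=config.noise_spec(),
        seed=config.seed,
        n_leads=config.n_leads,
    )
    write_cohort(cohort, workdir / "cohort")
    log.info("simulate: %d records (%d subjects x %d), fs=%g Hz, seed=%d",
             len(cohort.records), config.n_subjects, config.records_per_subject,
             config.fs, config.seed)
    _stamp(workdir, "simulate", config, ["cohort/"])


def _cmd_preprocess(config: PipelineConfig, workdir: Path) -> None:
    cohort = read_cohort(_require(workdir / "cohort", "simulate"))
    kwargs = _preprocess_kwargs(config)
    vectors, rows = [], []
    for rec, split in zip(cohort.records, cohort.split_assignment):
        vec = build_beat_vector(rec, target_len=config.target_len, **kwargs)
        to_image(vec, config.m, config.n)  # validates geometry
        vectors.append(vec)
        rows.append({"record_id": rec.record_id, "subject_id": rec.subject_id,
                     "split": split})
    V = np.stack(vectors)
    np.save(workdir / "vectors.npy", V)
    np.save(workdir / "images.npy", V.reshape(-1, config.m, config.n))
    pd.DataFrame(rows).to_csv(workdir / "image_manifest.csv", index=False)
    log.info("preprocess: %d beat images of %dx%d", len(rows), config.m, config.n)
    _stamp(workdir, "preprocess", config,
           ["vectors.npy", "images.npy", "image_manifest.csv"])


def _split(workdir: Path) -> tuple[np.ndarray, pd.DataFrame]:
    images = np.load(_require(workdir / "images.npy", "preprocess"))
    manifest = pd.read_csv(workdir / "image_manifest.csv")
    return images, manifest


def _cmd_train(config: PipelineConfig, workdir: Path) -> None:
    images, manifest = _split(workdir)
    train_mask = (manifest["split"] == "train").to_numpy()
    train_images = list(images[train_mask])
    train_labels = manifest.loc[train_mask, "subject_id"].to_numpy()
    params = config.network_params()
    model = network.fit(train_images, params)
    model.save(workdir / "model")
    F_train = network.transform(model, train_images)
    artifacts = _save_sparse(workdir / "features_train", F_train)
    clf = classify.train_classifier(F_train, train_labels, C=config.C)
    clf_dir = workdir / "classifier"
    clf_dir.mkdir(exist_ok=True)
    np.save(clf_dir / "coef.npy", clf.coef_)
    np.save(clf_dir / "intercept.npy", clf.intercept_)
    np.save(clf_dir / "classes.npy", clf.classes_.astype(str))
    log.info("train: fitted %s on %d images, feature length %d",
             params, len(train_images), F_train.shape[1])
    _stamp(workdir, "train", config, ["model/", "classifier/"] + artifacts)


def _linear_predict(clf_dir: Path, X: sparse.csr_matrix) -> np.ndarray:
    coef = np.load(clf_dir / "coef.npy")
    intercept = np.load(clf_dir / "intercept.npy")
    classes = np.load(clf_dir / "classes.npy")
    scores = X @ coef.T + intercept
    if coef.shape[0] == 1:  # binary: positive score -> second class
        return classes[(np.asarray(scores).ravel() > 0).astype(int)]
    return classes[np.asarray(scores).argmax(axis=1)]


def _cmd_evaluate(config: PipelineConfig, workdir: Path) -> None:
    images, manifest = _split(workdir)
    model = network.EECGNetModel.load(_require(workdir / "model", "train"))
    clf_dir = _require(workdir / "classifier", "train")
    test_mask = (manifest["split"] == "test").to_numpy()
    test_images = list(images[test_mask])
    test_labels = manifest.loc[test_mask, "subject_id"].to_numpy().astype(str)
    F_test = network.transform(model, test_images)
    artifacts = _save_sparse(workdir / "features_test", F_test)
    preds = _linear_predict(clf_dir, F_test)
    acc = classify.accuracy(preds, test_labels)
    out = pd.DataFrame({
        "record_id": manifest.loc[test_mask, "record_id"].to_numpy(),
        "truth": test_labels, "prediction": preds,
    })
    out.to_csv(workdir / "predictions.csv", index=False)
    classify.confusion_counts(preds, test_labels).to_csv(
        workdir / "confusion.csv", index=False)
    (workdir / "accuracy.json").write_text(
        json.dumps({"accuracy_pct": acc, "n_test": int(test_mask.sum())},
                   indent=2, sort_keys=True))
    log.info("evaluate: accuracy %.2f%% on %d test records", acc, test_mask.sum())
    _stamp(workdir, "evaluate", config,
           ["predictions.csv", "confusion.csv", "accuracy.json"] + artifacts)


def _cmd_sweep(config: PipelineConfig, workdir: Path) -> None:
    cohort = read_cohort(_require(workdir / "cohort", "simulate"))
    result = classify.sweep(
        cohort,
        h_grid=config.sweep_h, k_grid=config.sweep_k,
        L_grid=config.sweep_L, R_grid=config.sweep_R,
        m=config.m, n=config.n, C=config.C,
        pad_before_blocks=config.pad_before_blocks,
        **_preprocess_kwargs(config),
    )
    result.to_csv(workdir / "sweep.csv", index=False)
    for skip in result.attrs.get("skipped", []):
        log.info("sweep: skipped %s", skip)
    log.info("sweep: %d grid points evaluated", len(result))
    _stamp(workdir, "sweep", config, ["sweep.csv"])


def run_pipeline(config: PipelineConfig, command: str, workdir: str | Path) -> Path:
    """Run one pipeline stage in ``workdir``; returns the working directory."""
    if command not in _COMMANDS:
        raise ValueError(f"unknown command {command!r}; expected one of {_COMMANDS}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    {
        "simulate": _cmd_simulate,
        "preprocess": _cmd_preprocess,
        "train": _cmd_train,
        "evaluate": _cmd_evaluate,
        "sweep": _cmd_sweep,
    }[command](config, workdir)
    return workdir
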