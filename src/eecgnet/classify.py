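"""Classifier head, baselines, identification accuracy and the parameter sweep.

The network's block-histogram features go to a multi-class linear max-margin
classifier (one-vs-rest).  Baselines operate on the averaged-beat vectors
themselves: an eigen-PCA projection feeding the same classifier, a single
extreme learning machine (random fixed hidden layer, least-squares readout),
and a majority-vote ensemble of ELMs across activations and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from .network import PCANetParams, fit as fit_network, transform as transform_network
from .preprocessing import build_beat_vector, to_image
from .synthetic import LabeledCohort

__all__ = [
    "train_classifier",
    "accuracy",
    "confusion_counts",
    "pca_features",
    "ELMModel",
    "elm_fit",
    "elm_predict",
    "EnsembleELM",
    "eelm_fit",
    "sweep",
    "cohort_to_images",
]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "relu": lambda z: np.maximum(z, 0.0),
    "sin": np.sin,
}


def train_classifier(features, labels, C: float = 1.0) -> LinearSVC:
    """Multi-class linear max-margin classifier (one-vs-rest).

    Deterministic for fixed input: the coordinate-descent shuffling seed is
    pinned.  Accepts dense or sparse feature matrices.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes")
    clf = LinearSVC(C=C, random_state=0, max_iter=5000)
    clf.fit(features, labels)
    return clf


def accuracy(predictions, truth) -> float:
    """Percentage of correct identifications, 100 * correct / total."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    return 100.0 * float(np.mean(predictions == truth))


def confusion_counts(predictions, truth) -> pd.DataFrame:
    """Per-class one-vs-rest (TP, TN, FP, FN) counts.

    Micro-averaging (TP+TN)/(TP+TN+FP+FN) over these tables reproduces plain
    multi-class accuracy when every sample belongs to exactly one class.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    rows = []
    for c in np.unique(np.concatenate([truth, predictions])):
        tp = int(np.sum((predictions == c) & (truth == c)))
        tn = int(np.sum((predictions != c) & (truth != c)))
        fp = int(np.sum((predictions == c) & (truth != c)))
        fn = int(np.sum((predictions != c) & (truth == c)))
        rows.append({"class": c, "TP": tp, "TN": tn, "FP": fp, "FN": fn})
    return pd.DataFrame(rows)


def pca_features(train: np.ndarray, test: np.ndarray, n_components: int):
    """Eigen-decomposition baseline: project both splits on the top
    ``n_components`` eigenvectors of the training covariance (mean estimated
    on the training split only)."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if not 1 <= n_components <= min(train.shape):
        raise ValueError("n_components out of range")
    pca = PCA(n_components=n_components, svd_solver="full")
    train_proj = pca.fit_transform(train)
    return train_proj, pca.transform(test)


@dataclass(frozen=True)
class ELMModel:
    """Extreme learning machine: random fixed hidden layer, solved readout."""

    input_weights: np.ndarray  # (d, n_hidden)
    biases: np.ndarray         # (n_hidden,)
    activation: str
    output_weights: np.ndarray  # (n_hidden, n_classes)
    classes: np.ndarray
    seed: int


def _hidden(model_or_w, biases, activation, X) -> np.ndarray:
    return _ACTIVATIONS[activation](X @ model_or_w + biases)


def elm_fit(features, labels, n_hidden: int = 1000, activation: str = "sigmoid",
            seed: int = 0) -> ELMModel:
    """Fit an ELM: uniform(-1,1) input weights/biases from ``seed``, one-hot
    targets, minimum-norm least-squares output weights."""
    if activation not in _ACTIVATIONS:
        raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, (X.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, n_hidden)
    H = _hidden(W, b, activation, X)
    beta, *_ = np.linalg.lstsq(H, Y, rcond=None)
    return ELMModel(input_weights=W, biases=b, activation=activation,
                    output_weights=beta, classes=classes, seed=seed)


def elm_predict(model: ELMModel, features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    H = _hidden(model.input_weights, model.biases, model.activation, X)
    scores = H @ model.output_weights
    return model.classes[np.argmax(scores, axis=1)]


@dataclass(frozen=True)
class EnsembleELM:
    """Majority-vote ensemble of ELMs across activations and seeds."""

    members: tuple[ELMModel, ...]

    def predict(self, features) -> np.ndarray:
        votes = np.stack([elm_predict(m, features) for m in self.members])
        classes = self.members[0].classes
        counts = np.stack([(votes == c).sum(axis=0) for c in classes])
        # argmax breaks ties toward the lowest class id
        return classes[np.argmax(counts, axis=0)]


def eelm_fit(features, labels, n_hidden: int = 1000,
             seeds: tuple[int, ...] = (0,)) -> EnsembleELM:
    """One ELM per (seed x activation in {sigmoid, relu, sin}); >= 3 members."""
    members = [
        elm_fit(features, labels, n_hidden=n_hidden, activation=act, seed=s)
        for s in seeds
        for act in ("sigmoid", "relu", "sin")
    ]
    if len(members) < 3:
        raise ValueError("ensemble needs at least 3 members")
    return EnsembleELM(members=tuple(members))


def cohort_to_images(
    cohort: LabeledCohort, m: int, n: int, **preprocess_kwargs
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Preprocess every record of a cohort into beat images.

    Returns (train_images, train_labels, test_images, test_labels,
    train_vectors, test_vectors); the flat vectors feed the baselines.
    """
    tr_im, tr_y, te_im, te_y, tr_v, te_v = [], [], [], [], [], []
    for rec, split in zip(cohort.records, cohort.split_assignment):
        vec = build_beat_vector(rec, target_len=m * n, **preprocess_kwargs)
        img = to_image(vec, m, n)
        if split == "train":
            tr_im.append(img); tr_y.append(rec.subject_id); tr_v.append(vec)
        else:
            te_im.append(img); te_y.append(rec.subject_id); te_v.append(vec)
    return (np.stack(tr_im), np.array(tr_y), np.stack(te_im), np.array(te_y),
            np.stack(tr_v), np.stack(te_v))


def evaluate_eecgnet(train_images, train_labels, test_images, test_labels,
                     params: PCANetParams, C: float = 1.0) -> float:
    """Fit network + classifier on the train split, return test accuracy (%)."""
    model = fit_network(list(train_images), params)
    F_train = transform_network(model, list(train_images))
    F_test = transform_network(model, list(test_images))
    clf = train_classifier(F_train, train_labels, C=C)
    return accuracy(clf.predict(F_test), np.asarray(test_labels))


def sweep(
    cohort: LabeledCohort,
    h_grid, k_grid, L_grid, R_grid,
    m: int = 28, n: int = 28,
    C: float = 1.0,
    pad_before_blocks: bool = True,
    **preprocess_kwargs,
) -> pd.DataFrame:
    """Grid evaluation over (h, k, L, R) with h1=h2, k1=k2, L1=L2.

    Infeasible points (even k, L > k*k, block larger than the image) are
    skipped with the reason recorded in the ``skipped`` attribute of the
    returned table.
    """
    grid = [(h, k, L, R) for h in h_grid for k in k_grid for L in L_grid for R in R_grid]
    if not grid:
        raise ValueError("empty sweep grid")
    tr_im, tr_y, te_im, te_y, _, _ = cohort_to_images(cohort, m, n, **preprocess_kwargs)
    rows, skipped = [], []
    for h, k, L, R in grid:
        try:
            params = PCANetParams(k1=k, k2=k, L1=L, L2=L, h1=h, h2=h, R=R,
                                  pad_before_blocks=pad_before_blocks)
            params.validate_for_image(m, n)
        except ValueError as exc:
            skipped.append({"h": h, "k": k, "L": L, "R": R, "reason": str(exc)})
            continue
        acc = evaluate_eecgnet(tr_im, tr_y, te_im, te_y, params, C=C)
        rows.append({"h": h, "k": k, "L": L, "R": R, "accuracy": acc})
    result = pd.DataFrame(rows, columns=["h", "k", "L", "R", "accuracy"])
    result.attrs["skipped"] = skipped
    return result
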