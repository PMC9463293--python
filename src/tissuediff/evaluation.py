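"""Recording-disjoint cross-validation, metrics, and the experiment grid.

Samples from one recording are strongly correlated, so folds are formed at
the recording level: no recording contributes samples to more than one of
train/validation/test in any fold.  Folds are stratified by stiffness class.
The networks additionally hold out 12.5% of each fold's non-test recordings
(recording-disjoint, stratified) for validation/early stopping; the random
forest trains on all non-test recordings.

Metrics per fold: macro F1, accuracy, macro PPV (precision), macro TPR
(recall) and AUROC from the probability of the designated positive class
(``very_soft``).  The grid crosses {raw, lowpass, bandstop} preprocessing
with {rf, nn, cnn} classifiers, normalizing with statistics fitted on each
fold's training recordings only, and reports per-fold values plus mean and
standard deviation over the five folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .classifiers import (
    AEClassifierConfig,
    CNNConfig,
    RFConfig,
    TrainConfig,
    predict_recording_proba,
    train_ae_nn,
    train_cnn,
    train_rf,
)
from .preprocessing import filter_dataset, fit_normalizer, make_filter
from .synthesis import Dataset, POSITIVE_CLASS, extract_contact_window

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "make_group_folds",
    "compute_metrics",
    "aggregate_metrics",
    "run_experiment_grid",
    "permute_recording_labels",
    "METRIC_NAMES",
]

METRIC_NAMES = ("f1", "acc", "ppv", "tpr", "auroc")


@dataclass(frozen=True)
class FoldSplit:
    """Recording-id partition for one cross-validation fold."""

    fold_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        tr, va, te = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if tr & va or tr & te or va & te:
            raise ValueError("train/val/test recording sets overlap")


def make_group_folds(dataset: Dataset, k: int = 5, val_fraction: float = 0.125,
                     seed: int = 0) -> list[FoldSplit]:
    """K folds over recordings, class-stratified and recording-disjoint.

    Every recording appears in exactly one test set across the k folds.  The
    validation split takes ``val_fraction`` of each fold's non-test
    recordings (rounded, stratified by class); with 40 recordings, k=5 and
    12.5% this is 4 of the 32 non-test recordings per fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = dataset.labels_by_id()
    by_class: dict[str, list[str]] = {}
    for rid in sorted(labels):
        by_class.setdefault(labels[rid], []).append(rid)
    for cls, ids in by_class.items():
        if len(ids) < k:
            raise ValueError(f"class {cls!r} has fewer recordings ({len(ids)}) than k={k}")

    rng = np.random.default_rng(seed)
    chunks: dict[str, list[np.ndarray]] = {}
    for cls, ids in by_class.items():
        ids = np.array(ids)
        rng.shuffle(ids)
        chunks[cls] = np.array_split(ids, k)

    folds = []
    for i in range(k):
        test = sorted(rid for cls in chunks for rid in chunks[cls][i])
        rest_by_class = {
            cls: [rid for j, chunk in enumerate(chunks[cls]) if j != i for rid in chunk]
            for cls in chunks
        }
        n_rest = sum(len(v) for v in rest_by_class.values())
        n_val = round(val_fraction * n_rest)
        val: list[str] = []
        # stratified pick, largest classes first so rounding stays balanced
        order = sorted(rest_by_class, key=lambda c: -len(rest_by_class[c]))
        for j, cls in enumerate(order):
            share = round(n_val * len(rest_by_class[cls]) / n_rest) if j < len(order) - 1 \
                else n_val - len(val)
            pool = np.array(rest_by_class[cls])
            rng_fold = np.random.default_rng(np.random.SeedSequence([seed, i, j]))
            pick = rng_fold.choice(pool, size=min(share, len(pool)), replace=False)
            val.extend(pick.tolist())
        train = sorted(set(labels) - set(test) - set(val))
        folds.append(FoldSplit(fold_index=i, train_ids=tuple(train),
                               val_ids=tuple(sorted(val)), test_ids=tuple(test)))
    return folds


def compute_metrics(y_true, y_prob, classes, positive_class: str = POSITIVE_CLASS) -> dict:
    """Single-fold metric set from labels and class probabilities.

    F1/PPV/TPR are macro-averaged over the two classes; ACC is the argmax
    fraction correct; AUROC uses the probability of ``positive_class``.  With
    a single-class ``y_true`` the AUROC is undefined and reported as NaN.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape[0] != y_prob.shape[0]:
        raise ValueError("labels and probabilities have different lengths")
    classes = np.asarray(classes)
    y_pred = classes[np.argmax(y_prob, axis=1)]
    out = {
        "f1": f1_score(y_true, y_pred, average="macro", zero_division=0),
        "acc": accuracy_score(y_true, y_pred),
        "ppv": precision_score(y_true, y_pred, average="macro", zero_division=0),
        "tpr": recall_score(y_true, y_pred, average="macro", zero_division=0),
    }
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class fold: AUROC undefined", RuntimeWarning)
        out["auroc"] = np.nan
    else:
        pos_col = int(np.where(classes == positive_class)[0][0])
        out["auroc"] = roc_auc_score((y_true == positive_class).astype(int),
                                     y_prob[:, pos_col])
    return out


@dataclass
class MetricsReport:
    """Per-fold metric values plus mean and std over folds."""

    per_fold: pd.DataFrame  # columns: fold + METRIC_NAMES
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)

    @classmethod
    def from_folds(cls, rows: list[dict]) -> "MetricsReport":
        df = pd.DataFrame(rows)
        mean = {m: float(df[m].mean()) for m in METRIC_NAMES if m in df}
        std = {m: float(df[m].std(ddof=1)) for m in METRIC_NAMES if m in df}
        return cls(per_fold=df, mean=mean, std=std)


def aggregate_metrics(per_fold_metrics: list[dict]) -> MetricsReport:
    return MetricsReport.from_folds(per_fold_metrics)


def permute_recording_labels(dataset: Dataset, seed: int) -> Dataset:
    """Shuffle class labels among recordings (label-permutation null).

    Class counts are preserved; samples stay attached to their recording, so
    a leakage-free pipeline must fall to chance-level scores on the result.
    """
    import dataclasses

    from .synthesis import build_per_sample_view

    rng = np.random.default_rng(seed)
    labels = [r.class_label for r in dataset.recordings]
    permuted = rng.permutation(labels)
    recs = [dataclasses.replace(r, class_label=str(l))
            for r, l in zip(dataset.recordings, permuted)]
    window_s = dataset.config.contact_window_s if dataset.config else 1.0
    n_channels = recs[0].n_channels if recs else 9
    view = build_per_sample_view(recs, window_s, n_channels)
    return Dataset(recordings=recs, per_sample_view=view, config=dataset.config)


# ---------------------------------------------------------------------------
# Experiment grid
# ---------------------------------------------------------------------------

def _fold_seed(seed: int, *parts: int) -> int:
    ss = np.random.SeedSequence([seed, *parts])
    return int(ss.generate_state(1)[0] % (2**31))


def _sample_table(recs_windows, labels_by_id, rec_ids):
    """Stack per-sample rows (n, channels) + labels for the given recordings."""
    xs, ys = [], []
    for rid in rec_ids:
        win = recs_windows[rid]
        xs.append(win.T)
        ys.append(np.repeat(labels_by_id[rid], win.shape[1]))
    return np.concatenate(xs), np.concatenate(ys)


def run_experiment_grid(
    dataset: Dataset,
    classifiers=("rf", "nn", "cnn"),
    filters=("raw", "lowpass", "bandstop"),
    seed: int = 0,
    k: int = 5,
    val_fraction: float = 0.125,
    rf_config: RFConfig | None = None,
    nn_config: AEClassifierConfig | None = None,
    cnn_config: CNNConfig | None = None,
    train_config: TrainConfig | None = None,
    contact_window_s: float | None = None,
) -> pd.DataFrame:
    """Cross every filter with every classifier over the same k folds.

    Per fold and cell: recordings are filtered in full, the analysed contact
    window is extracted, a normalizer is fitted on the fold's *training*
    recordings only and applied everywhere, the model is trained and scored
    on the fold's test recordings.  CNN metrics cover only the samples with
    63 predecessors (937 of 1000 per recording at the defaults).

    Returns a long-format table with columns
    ``classifier, filter, fold, metric, value``.
    """
    nn_config = nn_config or AEClassifierConfig(input_dim=dataset.recordings[0].n_channels)
    cnn_config = cnn_config or CNNConfig(in_channels=dataset.recordings[0].n_channels)
    train_config = train_config or TrainConfig()
    if contact_window_s is None:
        contact_window_s = dataset.config.contact_window_s if dataset.config else 1.0

    folds = make_group_folds(dataset, k=k, val_fraction=val_fraction, seed=seed)
    labels_by_id = dataset.labels_by_id()
    fs = dataset.recordings[0].fs

    rows = []
    for fi, fname in enumerate(filters):
        ds_f = filter_dataset(make_filter(fname, fs=fs), dataset)
        windows = {
            r.recording_id: extract_contact_window(r, contact_window_s)
            for r in ds_f.recordings
        }
        for ci, cname in enumerate(classifiers):
            for fold in folds:
                cell_seed = _fold_seed(seed, fi, ci, fold.fold_index)
                metrics = _run_cell(
                    cname, windows, labels_by_id, fold, cell_seed,
                    rf_config, nn_config, cnn_config, train_config,
                )
                for m, v in metrics.items():
                    rows.append({"classifier": cname, "filter": fname,
                                 "fold": fold.fold_index, "metric": m, "value": v})
    return pd.DataFrame(rows)


def _run_cell(cname, windows, labels_by_id, fold, cell_seed,
              rf_config, nn_config, cnn_config, train_config):
    X_train, y_train = _sample_table(windows, labels_by_id, fold.train_ids)
    norm = fit_normalizer(X_train)

    if cname == "rf":
        # RF has no validation split: it trains on all non-test recordings
        X_all, y_all = _sample_table(windows, labels_by_id,
                                     fold.train_ids + fold.val_ids)
        cfg = rf_config or RFConfig(seed=cell_seed)
        model = train_rf(norm.transform(X_all), y_all, cfg)
        X_test, y_test = _sample_table(windows, labels_by_id, fold.test_ids)
        probs = model.predict_proba(norm.transform(X_test))
        return compute_metrics(y_test, probs, model.classes)

    if cname == "nn":
        X_val, y_val = _sample_table(windows, labels_by_id, fold.val_ids)
        tc = _reseed(train_config, cell_seed)
        model = train_ae_nn(norm.transform(X_train), y_train,
                            norm.transform(X_val), y_val, nn_config, tc)
        X_test, y_test = _sample_table(windows, labels_by_id, fold.test_ids)
        probs = model.predict_proba(norm.transform(X_test))
        return compute_metrics(y_test, probs, model.classes)

    if cname == "cnn":
        def recs(ids):
            return [(norm.transform(windows[rid].T).T, labels_by_id[rid], rid)
                    for rid in ids]

        tc = _reseed(train_config, cell_seed)
        model = train_cnn(recs(fold.train_ids), recs(fold.val_ids), cnn_config, tc)
        y_true, probs = [], []
        for samples, label, rid in recs(fold.test_ids):
            p, targets = predict_recording_proba(model, samples)
            probs.append(p)
            y_true.append(np.repeat(label, len(targets)))
        return compute_metrics(np.concatenate(y_true), np.concatenate(probs),
                               model.classes)

    raise ValueError(f"unknown classifier {cname!r}")


def _reseed(tc: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(tc, seed=seed)


def summarize_grid(long_table: pd.DataFrame) -> pd.DataFrame:
    """Mean (std) over folds for each (classifier, filter, metric) cell."""
    g = long_table.groupby(["classifier", "filter", "metric"])["value"]
    out = g.agg(["mean", "std"]).reset_index()
    return out
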