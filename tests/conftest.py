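import numpy as np
import pytest

from tissuediff import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The full study conditions: 40 recordings, 9 channels, 1000 Hz."""
    return generate_dataset(GeneratorConfig())


@pytest.fixture(scope="session")
def separable_config():
    """Well-separated classes, low noise: every classifier should recover them."""
    return GeneratorConfig(
        n_models_per_class=2,
        class_separation=4.0,
        broadband_sigma=0.1,
        periodic_noise_amplitude=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def separable_dataset(separable_config):
    return generate_dataset(separable_config)


def fold_tables(dataset, fold, contact_window_s=1.0):
    """Normalized per-sample tables (train/val/test) for one fold."""
    from tissuediff import extract_contact_window, fit_normalizer
    from tissuediff.evaluation import _sample_table

    windows = {
        r.recording_id: extract_contact_window(r, contact_window_s)
        for r in dataset.recordings
    }
    labels = dataset.labels_by_id()
    out = {}
    X_train, y_train = _sample_table(windows, labels, fold.train_ids)
    norm = fit_normalizer(X_train)
    for name, ids in (("train", fold.train_ids), ("val", fold.val_ids),
                      ("test", fold.test_ids)):
        X, y = _sample_table(windows, labels, ids)
        out[name] = (norm.transform(X), y)
    out["windows"] = windows
    out["labels"] = labels
    out["normalizer"] = norm
    return out
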