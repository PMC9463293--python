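"""Synthetic multichannel ultrasonic-aspirator recordings.

An ultrasonic aspirator's generator exposes nine electrical features (voltage,
current, frequency, ...) whose levels depend on the mechanical load, i.e. on
the stiffness of the tissue being fragmented.  This module generates
phenomenological stand-ins for such recordings: each recording is one lane
traversal over one artificial tissue model and consists of an initial idle
phase, a contact phase during which the instrument ablates tissue, and a
final idle phase.  Two stiffness classes are emulated -- ``very_soft``
(meningioma-like) and ``soft`` (healthy-brain-like) -- which differ by a
per-channel offset of the contact-phase baseline.  A slow linear drift models
the continuous descent of the instrument into the tissue, an optional
sinusoid near 1.2 Hz models periodic irrigation noise, and white noise models
broadband measurement noise.

The channels are anonymous: classifiers downstream consume them as a generic
feature vector, so no attempt is made to model the physics of individual
electrical quantities.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "POSITIVE_CLASS",
    "ConfigError",
    "GeneratorConfig",
    "Recording",
    "Dataset",
    "generate_recording",
    "generate_dataset",
    "extract_contact_window",
    "save_dataset",
    "load_dataset",
    "export_per_sample_csv",
    "dataset_content_hash",
]

#: The two stiffness classes.  ``very_soft`` emulates meningioma-like models
#: and is the designated positive class for AUROC; ``soft`` emulates healthy
#: brain tissue.
CLASSES: tuple[str, str] = ("very_soft", "soft")
POSITIVE_CLASS = "very_soft"

# Fixed direction in channel space along which the two class baselines are
# separated.  Unit norm, so the Euclidean distance between noise-free class
# means equals `class_separation` exactly.
_CHANNEL_PATTERN = np.array([1.0, -0.8, 0.6, -0.4, 0.9, 0.3, -0.7, 0.5, -0.2])


class ConfigError(ValueError):
    """Raised when a generator or filter configuration violates an invariant."""


def _separation_direction(n_channels: int) -> np.ndarray:
    pattern = np.resize(_CHANNEL_PATTERN, n_channels).astype(float)
    return pattern / np.linalg.norm(pattern)


def default_class_offsets(n_channels: int = 9) -> dict[str, np.ndarray]:
    """Per-class, per-channel baseline offsets, +/- half a unit vector.

    Scaled by ``class_separation`` at generation time, so the distance
    between the two class-conditional contact baselines is exactly
    ``class_separation`` signal units.
    """
    u = _separation_direction(n_channels)
    return {"very_soft": 0.5 * u, "soft": -0.5 * u}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic recordings.

    Defaults mirror the laboratory protocol being emulated: 1000 Hz sampling,
    nine electrical channels, 1 s + 4.5 s + 1 s idle/contact/idle phases of
    which the first second of contact is analysed, four tissue models per
    class traversed along five lanes each (40 recordings), and periodic
    irrigation noise near 1.2 Hz on about half the recordings.
    """

    fs: float = 1000.0
    n_channels: int = 9
    n_models_per_class: int = 4
    lanes_per_model: int = 5
    idle_pre_s: float = 1.0
    contact_s: float = 4.5
    idle_post_s: float = 1.0
    contact_window_s: float = 1.0
    class_offsets: Mapping[str, np.ndarray] | None = None
    class_separation: float = 1.0
    idle_level: float = 0.0
    contact_level: float = 2.0
    drift_slope: float = 0.05  # signal units per second during contact
    periodic_noise_hz: float = 1.2
    periodic_noise_amplitude: float = 1.2
    periodic_noise_fraction: float = 0.5
    broadband_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("sampling frequency must be positive")
        if self.n_channels < 1:
            raise ConfigError("need at least one channel")
        for name in ("idle_pre_s", "contact_s", "idle_post_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.contact_window_s <= self.contact_s:
            raise ConfigError("contact_window_s must lie within the contact phase")
        if not 0.0 <= self.periodic_noise_fraction <= 1.0:
            raise ConfigError("periodic_noise_fraction must be in [0, 1]")
        if self.fs <= 2.0 * self.periodic_noise_hz:
            raise ConfigError("fs must exceed twice the periodic noise frequency")
        if self.broadband_sigma < 0:
            raise ConfigError("broadband_sigma must be non-negative")
        if self.n_models_per_class < 0 or self.lanes_per_model < 0:
            raise ConfigError("model/lane counts must be non-negative")

    def offsets(self) -> dict[str, np.ndarray]:
        if self.class_offsets is not None:
            return {k: np.asarray(v, dtype=float) for k, v in self.class_offsets.items()}
        return default_class_offsets(self.n_channels)

    @property
    def samples_per_phase(self) -> tuple[int, int, int]:
        return (
            round(self.idle_pre_s * self.fs),
            round(self.contact_s * self.fs),
            round(self.idle_post_s * self.fs),
        )


@dataclass
class Recording:
    """One lane traversal: multichannel time series with phase bookkeeping.

    ``samples`` has shape (n_channels, total_samples); ``phase_bounds`` is
    the half-open ``[contact_start, contact_end)`` integer sample interval.
    ``has_periodic_noise`` is generation ground truth, kept for testing.
    """

    recording_id: str
    tissue_model_id: str
    lane_index: int
    class_label: str
    samples: np.ndarray
    phase_bounds: tuple[int, int]
    fs: float
    has_periodic_noise: bool = False

    def __post_init__(self) -> None:
        start, end = self.phase_bounds
        total = self.samples.shape[1]
        if not (0 <= start < end <= total):
            raise ValueError("phase bounds outside recording")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def contact_samples(self) -> int:
        return self.phase_bounds[1] - self.phase_bounds[0]


@dataclass
class Dataset:
    """Recordings plus the flattened per-sample view used by RF and the NN.

    ``per_sample_view`` holds only contact-window samples, one row per
    measurement point, columns ``ch0..ch{n-1}``, ``label``, ``recording_id``.
    """

    recordings: list[Recording]
    per_sample_view: pd.DataFrame
    config: GeneratorConfig | None = None

    def __len__(self) -> int:
        return len(self.recordings)

    def recording_ids(self) -> list[str]:
        return [r.recording_id for r in self.recordings]

    def labels_by_id(self) -> dict[str, str]:
        return {r.recording_id: r.class_label for r in self.recordings}


def _recording_rng(seed: int, recording_id: str) -> np.random.Generator:
    # Per-recording substream keyed on (seed, id): adding or removing other
    # recordings never perturbs this one.
    digest = hashlib.sha256(f"{seed}:{recording_id}".encode()).digest()
    return np.random.default_rng(np.random.SeedSequence(int.from_bytes(digest[:8], "little")))


def generate_recording(
    config: GeneratorConfig,
    class_label: str,
    tissue_model_id: str,
    lane_index: int,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Synthesize one recording (idle-contact-idle) for one lane.

    The contact baseline is ``contact_level + class_separation * offset`` per
    channel, with a linear drift from contact start.  A sinusoid at
    ``periodic_noise_hz`` (per-channel random phase) is superimposed on the
    whole recording with probability ``periodic_noise_fraction``; white noise
    with ``broadband_sigma`` is always added.
    """
    offsets = config.offsets()
    if class_label not in offsets:
        raise ConfigError(f"unknown class label {class_label!r}")
    if not 0 <= lane_index < max(config.lanes_per_model, 1):
        raise ConfigError(f"lane_index {lane_index} out of range")

    recording_id = f"{tissue_model_id}-lane{lane_index}"
    if rng is None:
        rng = _recording_rng(config.seed, recording_id)

    n_pre, n_contact, n_post = config.samples_per_phase
    total = n_pre + n_contact + n_post
    t = np.arange(total) / config.fs

    sig = np.full((config.n_channels, total), config.idle_level, dtype=float)
    contact = slice(n_pre, n_pre + n_contact)
    baseline = config.contact_level + config.class_separation * offsets[class_label]
    t_contact = (np.arange(n_contact)) / config.fs
    sig[:, contact] = baseline[:, None] + config.drift_slope * t_contact[None, :]

    has_noise = bool(rng.uniform() < config.periodic_noise_fraction)
    if has_noise and config.periodic_noise_amplitude != 0.0:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
        sig += config.periodic_noise_amplitude * np.sin(
            2.0 * np.pi * config.periodic_noise_hz * t[None, :] + phases[:, None]
        )
    if config.broadband_sigma > 0:
        sig += rng.normal(0.0, config.broadband_sigma, size=sig.shape)

    return Recording(
        recording_id=recording_id,
        tissue_model_id=tissue_model_id,
        lane_index=lane_index,
        class_label=class_label,
        samples=sig,
        phase_bounds=(n_pre, n_pre + n_contact),
        fs=config.fs,
        has_periodic_noise=has_noise,
    )


def extract_contact_window(recording: Recording, window_s: float) -> np.ndarray:
    """First ``window_s`` seconds of the contact phase, as a copy.

    Raises ``ValueError`` if the window exceeds the contact phase.
    """
    n = round(window_s * recording.fs)
    start, end = recording.phase_bounds
    if n < 0 or start + n > end:
        raise ValueError(
            f"window of {n} samples exceeds contact phase of {end - start} samples"
        )
    return recording.samples[:, start : start + n].copy()


def build_per_sample_view(
    recordings: Sequence[Recording], contact_window_s: float, n_channels: int
) -> pd.DataFrame:
    cols = [f"ch{i}" for i in range(n_channels)]
    frames = []
    for rec in recordings:
        win = extract_contact_window(rec, contact_window_s)
        df = pd.DataFrame(win.T, columns=cols)
        df["label"] = rec.class_label
        df["recording_id"] = rec.recording_id
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=cols + ["label", "recording_id"])
    return pd.concat(frames, ignore_index=True)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """All recordings for the configured study: models x lanes per class.

    Fully reproducible given ``config.seed``; per-recording RNG substreams
    make the set of other recordings irrelevant to any one recording.
    """
    recordings: list[Recording] = []
    for class_label in CLASSES:
        if class_label not in config.offsets():
            continue
        for m in range(config.n_models_per_class):
            tissue_model_id = f"{class_label}-model{m}"
            for lane in range(config.lanes_per_model):
                recordings.append(
                    generate_recording(config, class_label, tissue_model_id, lane)
                )
    ids = [r.recording_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise ConfigError("recording ids are not unique")
    view = build_per_sample_view(recordings, config.contact_window_s, config.n_channels)
    return Dataset(recordings=recordings, per_sample_view=view, config=config)


# ---------------------------------------------------------------------------
# Persistence: HDF5 container + flat CSV export
# ---------------------------------------------------------------------------

def save_dataset(dataset: Dataset, path: str) -> None:
    """Write recordings to an HDF5 file (one group per recording)."""
    with h5py.File(path, "w") as f:
        if dataset.config is not None:
            f.attrs["contact_window_s"] = dataset.config.contact_window_s
            f.attrs["n_channels"] = dataset.config.n_channels
        grp = f.create_group("recordings")
        for rec in dataset.recordings:
            g = grp.create_group(rec.recording_id)
            g.create_dataset("samples", data=rec.samples)
            g.attrs["tissue_model_id"] = rec.tissue_model_id
            g.attrs["lane_index"] = rec.lane_index
            g.attrs["label"] = rec.class_label
            g.attrs["phase_bounds"] = rec.phase_bounds
            g.attrs["fs"] = rec.fs
            g.attrs["has_periodic_noise"] = rec.has_periodic_noise


def load_dataset(path: str, contact_window_s: float | None = None) -> Dataset:
    recordings = []
    with h5py.File(path, "r") as f:
        if contact_window_s is None:
            contact_window_s = float(f.attrs.get("contact_window_s", 1.0))
        for rid in f["recordings"]:
            g = f["recordings"][rid]
            recordings.append(
                Recording(
                    recording_id=rid,
                    tissue_model_id=str(g.attrs["tissue_model_id"]),
                    lane_index=int(g.attrs["lane_index"]),
                    class_label=str(g.attrs["label"]),
                    samples=np.asarray(g["samples"]),
                    phase_bounds=tuple(int(x) for x in g.attrs["phase_bounds"]),
                    fs=float(g.attrs["fs"]),
                    has_periodic_noise=bool(g.attrs["has_periodic_noise"]),
                )
            )
    recordings.sort(key=lambda r: r.recording_id)
    n_channels = recordings[0].n_channels if recordings else 9
    view = build_per_sample_view(recordings, contact_window_s, n_channels)
    return Dataset(recordings=recordings, per_sample_view=view)


def export_per_sample_csv(dataset: Dataset, path: str) -> None:
    dataset.per_sample_view.to_csv(path, index=False)


def dataset_content_hash(dataset: Dataset) -> str:
    """Content hash of the per-sample view, for provenance logging."""
    h = hashlib.sha256()
    view = dataset.per_sample_view
    num = view.select_dtypes(include=[np.number]).to_numpy()
    h.update(np.ascontiguousarray(num).tobytes())
    h.update(",".join(view["recording_id"].astype(str)).encode())
    h.update(",".join(view["label"].astype(str)).encode())
    return h.hexdigest()
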