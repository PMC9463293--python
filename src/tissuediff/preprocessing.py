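"""Noise-removal filters, per-feature normalization, training-time input noise.

Two filters target the ~1.2 Hz periodic irrigation noise seen on a portion of
recordings: a third-order Butterworth low-pass (cutoff 0.75 Hz) that keeps
only the slow load-dependent baseline, and a second-order IIR notch at 1.2 Hz
with quality factor 0.4 (a deliberately wide stopband, ~3 Hz) that preserves
high-frequency content.  Filters are applied zero-phase (forward-backward)
over the full recording before the analysed contact window is extracted, so
edge transients fall outside the window and no group delay is introduced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import signal

from .synthesis import Dataset, Recording, build_per_sample_view

__all__ = [
    "FilterSpec",
    "design_lowpass",
    "design_bandstop",
    "make_filter",
    "apply_filter",
    "filter_dataset",
    "Normalizer",
    "fit_normalizer",
    "add_gaussian_noise",
]

_STD_FLOOR = 1e-8


@dataclass(frozen=True)
class FilterSpec:
    """A realized digital filter in second-order sections.

    ``params`` records the design parameters (order/cutoff or center/Q) for
    provenance; ``sos`` is the realized coefficient array.
    """

    kind: str  # "lowpass_butterworth" | "bandstop_notch"
    fs: float
    params: dict
    sos: np.ndarray

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex response H(f) of a single (one-way) pass."""
        _, h = signal.sosfreqz(self.sos, worN=np.atleast_1d(freqs_hz), fs=self.fs)
        return h

    def gain(self, freq_hz: float) -> float:
        return float(np.abs(self.frequency_response(np.array([freq_hz])))[0])

    def poles(self) -> np.ndarray:
        _, p, _ = signal.sos2zpk(self.sos)
        return p

    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.poles()) < 1.0))

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "fs": self.fs, "params": self.params,
             "sos": self.sos.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterSpec":
        d = json.loads(text)
        return cls(kind=d["kind"], fs=d["fs"], params=d["params"],
                   sos=np.asarray(d["sos"]))


def design_lowpass(cutoff_hz: float = 0.75, order: int = 3, fs: float = 1000.0) -> FilterSpec:
    """Digital Butterworth low-pass: unit DC gain, -3 dB at the cutoff."""
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return FilterSpec(
        kind="lowpass_butterworth",
        fs=fs,
        params={"cutoff_hz": cutoff_hz, "order": order},
        sos=sos,
    )


def design_bandstop(center_hz: float = 1.2, quality_factor: float = 0.4, fs: float = 1000.0) -> FilterSpec:
    """Second-order IIR notch: exact null at the center, unit gain at DC/Nyquist.

    The -3 dB stopband width is center/Q, so Q = 0.4 at 1.2 Hz removes a band
    about 3 Hz wide.
    """
    if not 0 < center_hz < fs / 2:
        raise ValueError("center frequency must lie strictly between 0 and Nyquist")
    if quality_factor <= 0:
        raise ValueError("quality factor must be positive")
    b, a = signal.iirnotch(center_hz, quality_factor, fs=fs)
    return FilterSpec(
        kind="bandstop_notch",
        fs=fs,
        params={"center_hz": center_hz, "quality_factor": quality_factor},
        sos=signal.tf2sos(b, a),
    )


def make_filter(name: str, fs: float = 1000.0) -> FilterSpec | None:
    """Filter by experiment-grid name: 'raw'/'none', 'lowpass', 'bandstop'."""
    if name in ("raw", "none"):
        return None
    if name == "lowpass":
        return design_lowpass(fs=fs)
    if name == "bandstop":
        return design_bandstop(fs=fs)
    raise ValueError(f"unknown filter {name!r}")


def apply_filter(spec: FilterSpec, recording: Recording) -> Recording:
    """Zero-phase filter every channel over the full recording.

    Forward-backward application squares the magnitude response and cancels
    the phase, so there is no delay to re-align; phase bounds are unchanged.
    """
    if abs(spec.fs - recording.fs) > 1e-9:
        raise ValueError(
            f"filter designed at fs={spec.fs} applied to recording at fs={recording.fs}"
        )
    filtered = signal.sosfiltfilt(spec.sos, recording.samples, axis=1)
    return dc_replace(recording, samples=np.ascontiguousarray(filtered))


def filter_dataset(spec: FilterSpec | None, dataset: Dataset) -> Dataset:
    """Apply a filter to every recording and rebuild the per-sample view."""
    if spec is None:
        return dataset
    recs = [apply_filter(spec, r) for r in dataset.recordings]
    window_s = dataset.config.contact_window_s if dataset.config else 1.0
    n_channels = recs[0].n_channels if recs else 9
    view = build_per_sample_view(recs, window_s, n_channels)
    return Dataset(recordings=recs, per_sample_view=view, config=dataset.config)


@dataclass
class Normalizer:
    """Zero-mean/unit-variance scaler fitted on training-partition samples only."""

    mean_: np.ndarray
    std_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.std_


def fit_normalizer(training_samples) -> Normalizer:
    """Per-feature mean/std of the training samples; std floored at 1e-8."""
    X = np.asarray(training_samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 training samples")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if np.any(std < _STD_FLOOR):
        warnings.warn("constant feature(s) detected; std floored", RuntimeWarning)
        std = np.maximum(std, _STD_FLOOR)
    return Normalizer(mean_=mean, std_=std)


def add_gaussian_noise(samples: np.ndarray, sigma: float, rng) -> np.ndarray:
    """I.i.d. zero-mean Gaussian perturbation of every entry (train-time only)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    X = np.asarray(samples, dtype=float)
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return X + rng.normal(0.0, sigma, size=X.shape)
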