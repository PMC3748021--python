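"""Continuous-signal conditioning and epoching.

The conditioning chain mirrors a standard P300 pipeline: a zero-phase
fourth-order Butterworth band-pass (1--10 Hz, the delta/theta band carrying
the P300), integer decimation to 32 Hz, common-average re-referencing, an
optional regression-based EOG correction, and extraction of 200--700 ms
post-stimulus epochs.  All operations are linear, so their relative order
(beyond band-passing before decimation) does not affect the result; the
band-pass doubles as the anti-alias filter for the 128 -> 32 Hz step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "EpochSet",
    "EogModel",
    "TTI_GT3",
    "bandpass_filter",
    "resample",
    "car_reference",
    "fit_eog_model",
    "apply_eog_correction",
    "epoch",
    "select_channels",
    "preprocess",
]

#: TTI category code meaning "more than 3 stimuli since the previous target"
#: (also assigned to the first target of a sequence, which has no predecessor).
TTI_GT3 = 4

#: TTI code for trials where the interval is undefined (non-target trials).
TTI_UNDEFINED = -1


@dataclass
class Recording:
    """Continuous multichannel signal with stimulus events.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal in arbitrary consistent units (uV for real EEG).
    sample_rate : float
        Sampling frequency in Hz.
    channel_names : list of str
        One name per channel.
    events : ndarray, shape (n_events, 2), int
        Columns ``(onset_sample, image_id)``.  May be empty.
    """

    data: np.ndarray
    sample_rate: float
    channel_names: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a samples x channels matrix")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if self.events.size:
            onsets = self.events[:, 0]
            if onsets.min() < 0 or onsets.max() >= self.n_samples:
                raise ValueError("event onsets must lie within [0, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class EpochSet:
    """Per-trial signal segments, time-locked to stimulus onsets.

    ``data`` has shape (n_trials, n_channels, n_samples_per_epoch).  The
    window is half-open, ``[start, end)`` in ms relative to onset, so that a
    500 ms window at 32 Hz yields exactly 16 samples.  ``tti`` holds the
    target-to-target interval category per trial (1, 2, 3, or ``TTI_GT3``),
    defined only for target trials; other trials carry ``TTI_UNDEFINED``.
    """

    data: np.ndarray
    window_ms: tuple[float, float]
    sample_rate: float
    image_ids: np.ndarray
    true_label: np.ndarray | None = None
    tti: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        start, end = self.window_ms
        expect = int(round((end - start) / 1000.0 * self.sample_rate))
        if self.data.shape[0] and self.data.shape[2] != expect:
            raise ValueError(
                f"window {self.window_ms} at {self.sample_rate} Hz implies "
                f"{expect} samples, got {self.data.shape[2]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def features(self) -> np.ndarray:
        """Flatten to (n_trials, n_channels * n_samples), channel-major."""
        return self.data.reshape(self.n_trials, -1)


@dataclass
class EogModel:
    """Linear EOG-to-EEG leakage coefficients from OLS regression."""

    coefficients: np.ndarray  # (n_eog_channels, n_eeg_channels)
    eog_channels: list[str]
    eeg_channels: list[str]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("EOG coefficients must be finite")
        if self.coefficients.shape != (len(self.eog_channels), len(self.eeg_channels)):
            raise ValueError("coefficient shape does not match channel lists")


def bandpass_filter(rec: Recording, low: float = 1.0, high: float = 10.0,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward application).

    Zero-phase filtering preserves ERP latencies, which matter downstream
    for both the epoch window and the TTI analysis.
    """
    nyq = rec.sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sample_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=0)
    return replace(rec, data=filtered)


def resample(rec: Recording, new_rate: float) -> Recording:
    """Integer decimation; event onsets are rescaled by the same factor.

    The caller is responsible for prior anti-alias filtering (the 1--10 Hz
    band-pass suffices for decimation down to >= 32 Hz).
    """
    ratio = rec.sample_rate / new_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"new rate {new_rate} Hz must integer-divide {rec.sample_rate} Hz"
        )
    if factor == 1:
        return replace(rec)
    data = rec.data[::factor]
    events = rec.events.copy()
    if events.size:
        events[:, 0] = events[:, 0] // factor
    return Recording(data=data, sample_rate=new_rate,
                     channel_names=list(rec.channel_names), events=events)


def car_reference(rec: Recording) -> Recording:
    """Common-average re-referencing: subtract the cross-channel mean per sample."""
    if rec.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return replace(rec, data=data)


def fit_eog_model(calib_eeg: Recording, calib_eog: Recording) -> EogModel:
    """Estimate EOG leakage by OLS regression of each EEG channel on the EOG.

    Assumes the uncontaminated EEG is uncorrelated with the EOG over the
    calibration segment (voluntary eye movements and blinks), so the
    regression coefficient converges on the true mixing.
    """
    if calib_eeg.n_samples != calib_eog.n_samples:
        raise ValueError("calibration EEG and EOG must have equal length")
    if calib_eeg.sample_rate != calib_eog.sample_rate:
        raise ValueError("calibration EEG and EOG must share a sample rate")
    eog = calib_eog.data
    if np.any(eog.var(axis=0) <= 0):
        raise ValueError("zero-variance EOG channel: calibration has no EOG activity")
    coef, *_ = np.linalg.lstsq(eog, calib_eeg.data, rcond=None)
    return EogModel(coefficients=coef,
                    eog_channels=list(calib_eog.channel_names),
                    eeg_channels=list(calib_eeg.channel_names))


def apply_eog_correction(rec: Recording, eog: Recording, model: EogModel) -> Recording:
    """Subtract the regressed EOG contribution: corrected = EEG - C^T . EOG."""
    if rec.n_samples != eog.n_samples:
        raise ValueError("EEG and EOG recordings must have equal length")
    if list(rec.channel_names) != model.eeg_channels:
        raise ValueError("model was fitted on a different EEG channel set")
    if list(eog.channel_names) != model.eog_channels:
        raise ValueError("model was fitted on a different EOG channel set")
    data = rec.data - eog.data @ model.coefficients
    return replace(rec, data=data)


def epoch(rec: Recording, window_ms: tuple[float, float] = (200.0, 700.0),
          labels: np.ndarray | None = None) -> EpochSet:
    """Cut one epoch per event over a half-open post-onset window.

    Parameters
    ----------
    rec : Recording
    window_ms : (start, end)
        Half-open window ``[start, end)`` relative to stimulus onset, in ms.
        The default 200--700 ms at 32 Hz gives 16 samples per channel.
    labels : array-like of {0, 1}, optional
        Ground-truth target labels aligned with ``rec.events``; when given,
        per-trial TTI categories are computed for target trials as the
        stimulus-count distance to the preceding target (1, 2, 3, or
        ``TTI_GT3``; the first target of the sequence gets ``TTI_GT3``).
    """
    start_ms, end_ms = window_ms
    fs = rec.sample_rate
    offset = int(round(start_ms / 1000.0 * fs))
    n_samp = int(round((end_ms - start_ms) / 1000.0 * fs))
    events = rec.events
    epochs = np.empty((len(events), rec.n_channels, n_samp))
    for k, (onset, _img) in enumerate(events):
        a = onset + offset
        b = a + n_samp
        if a < 0 or b > rec.n_samples:
            raise ValueError(
                f"event {k} (onset sample {onset}, image {events[k, 1]}): "
                f"window [{a}, {b}) exceeds recording of {rec.n_samples} samples"
            )
        epochs[k] = rec.data[a:b].T

    true_label = None
    tti = None
    if labels is not None:
        true_label = np.asarray(labels, dtype=np.int64)
        if true_label.shape != (len(events),):
            raise ValueError("labels must align one-to-one with events")
        tti = compute_tti(true_label)

    return EpochSet(data=epochs, window_ms=(float(start_ms), float(end_ms)),
                    sample_rate=fs, image_ids=events[:, 1].copy(),
                    true_label=true_label, tti=tti)


def compute_tti(labels: np.ndarray) -> np.ndarray:
    """Target-to-target interval categories for a presentation sequence.

    The interval is the distance, in stimuli, from a target to the preceding
    target.  Distances above 3 and the sequence's first target (no
    predecessor) fall in the ``TTI_GT3`` category; non-targets get
    ``TTI_UNDEFINED``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    tti = np.full(labels.shape, TTI_UNDEFINED, dtype=np.int64)
    prev = None
    for k in np.flatnonzero(labels == 1):
        if prev is None:
            tti[k] = TTI_GT3
        else:
            dist = k - prev
            tti[k] = dist if dist <= 3 else TTI_GT3
        prev = int(k)
    return tti


def select_channels(rec: Recording, names: list[str]) -> Recording:
    """Restrict a recording to the named channels, in the given order."""
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise KeyError(f"channels not in recording: {missing}")
    idx = [rec.channel_names.index(n) for n in names]
    return Recording(data=rec.data[:, idx], sample_rate=rec.sample_rate,
                     channel_names=list(names), events=rec.events.copy())


def preprocess(rec: Recording, eog: Recording | None = None,
               eog_model: EogModel | None = None,
               low: float = 1.0, high: float = 10.0, order: int = 4,
               target_rate: float = 32.0) -> Recording:
    """Full conditioning chain: band-pass -> decimate -> (EOG correct) -> CAR.

    The EOG recording, when provided, is put through the same band-pass and
    decimation before the regression correction so the model applies on
    matched signals.
    """
    out = bandpass_filter(rec, low=low, high=high, order=order)
    out = resample(out, target_rate)
    if eog is not None:
        if eog_model is None:
            raise ValueError("eog recording given without a fitted EogModel")
        eog_p = resample(bandpass_filter(eog, low=low, high=high, order=order),
                         target_rate)
        out = apply_eog_correction(out, eog_p, eog_model)
    return car_reference(out)
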