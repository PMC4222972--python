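"""Continuous EEG to clean, average-referenced epochs.

The pipeline order is fixed: zero-phase band-pass + notch filtering of the
continuous record, epoch extraction around response-onset events, per-trial
bad-channel detection (200 µV after an 80 ms moving average) and spherical-
spline replacement, fast-transient artifact rejection, and finally
common-average re-referencing.

The amplitude units are µV throughout; time is ms relative to the response
onset, with t = 0 at the event sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal

from .errors import FormatError, ParameterError, ProcessingError
from .forward import SensorArray

logger = logging.getLogger(__name__)

__all__ = [
    "RawEEG",
    "EpochSet",
    "filter_continuous",
    "extract_epochs",
    "detect_bad_channels",
    "interpolate_bad_channels",
    "reject_artifact_epochs",
    "rereference_common_average",
    "preprocess_pipeline",
    "read_raw",
    "write_raw",
    "save_epochs",
    "load_epochs",
]


@dataclass
class RawEEG:
    """Continuous multichannel EEG (µV) with response-onset event markers."""

    data: np.ndarray                # (n_channels, n_samples) µV
    rate: float                     # Hz
    events: list[tuple[int, str]]   # (sample index, condition label)
    labels: list[str] | None = None
    reference: str = "Cz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ParameterError("sampling rate must be > 0")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise FormatError(f"event sample {s} outside recording of {n} samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class EpochSet:
    """Trials × channels × samples, window in ms relative to response onset."""

    data: np.ndarray                       # (n_trials, n_channels, n_samples) µV
    window: tuple[float, float]            # ms, inclusive endpoints
    rate: float
    condition: list[str] = field(default_factory=list)
    bad_channels: list[set[int]] = field(default_factory=list)
    kept: np.ndarray | None = None          # per-trial bool
    reference: str = "Cz"
    n_events_total: int = 0
    n_edge_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.kept is None:
            self.kept = np.ones(self.data.shape[0], dtype=bool)
        if not self.bad_channels:
            self.bad_channels = [set() for _ in range(self.data.shape[0])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms; both window endpoints are on the grid."""
        n = self.data.shape[2] if self.data.ndim == 3 else 0
        return self.window[0] + np.arange(n) * 1000.0 / self.rate

    def kept_data(self) -> np.ndarray:
        return self.data[np.asarray(self.kept, dtype=bool)]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_continuous(
    raw: RawEEG,
    band: tuple[float, float] = (1.0, 120.0),
    notch: float | None = 60.0,
    notch_q: float = 30.0,
) -> RawEEG:
    """Zero-phase band-pass plus line-noise notch on the continuous record.

    Forward-backward (filtfilt) filtering is used so ERD/ERS latencies are
    not shifted: a 4th-order Butterworth band-pass and a biquad notch.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ParameterError(f"band edges {band} must satisfy 0 < low < high")
    if raw.rate < 2 * hi:
        raise ParameterError(
            f"rate {raw.rate} Hz cannot represent the {hi} Hz band edge"
        )
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=raw.rate, output="sos")
    out = signal.sosfiltfilt(sos, raw.data, axis=1)
    if notch is not None:
        b, a = signal.iirnotch(notch, notch_q, fs=raw.rate)
        out = signal.filtfilt(b, a, out, axis=1)
    return replace(raw, data=out)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def extract_epochs(
    raw: RawEEG,
    window: tuple[float, float] = (-1000.0, 1000.0),
    condition: str | None = None,
) -> EpochSet:
    """One epoch per event; endpoints inclusive on the sample grid.

    Events whose window would run past the recording edge are dropped with a
    logged warning (counted in ``n_edge_dropped``).
    """
    w0, w1 = window
    if w1 <= w0:
        raise ParameterError("window end must exceed window start")
    off0 = int(round(w0 * raw.rate / 1000.0))
    off1 = int(round(w1 * raw.rate / 1000.0))
    n_samp = raw.data.shape[1]
    trials, labels = [], []
    n_matching = 0
    n_dropped = 0
    for s, lab in raw.events:
        if condition is not None and lab != condition:
            continue
        n_matching += 1
        a, b = s + off0, s + off1
        if a < 0 or b >= n_samp:
            n_dropped += 1
            logger.warning("event at sample %d too close to recording edge; dropped", s)
            continue
        trials.append(raw.data[:, a : b + 1])
        labels.append(lab)
    data = (
        np.stack(trials)
        if trials
        else np.empty((0, raw.n_channels, off1 - off0 + 1))
    )
    return EpochSet(
        data=data,
        window=(w0, w1),
        rate=raw.rate,
        condition=labels,
        reference=raw.reference,
        n_events_total=n_matching,
        n_edge_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# bad channels
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, size: int) -> np.ndarray:
    """Centered boxcar along the last axis; the window shrinks at the edges."""
    n = x.shape[-1]
    if size >= n:
        raise ParameterError("smoothing window must be shorter than the epoch")
    half_l = (size - 1) // 2
    half_r = size // 2
    csum = np.cumsum(x, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def detect_bad_channels(
    epoch: np.ndarray,
    rate: float,
    threshold: float = 200.0,
    smooth_ms: float = 80.0,
) -> set[int]:
    """Channels whose boxcar-smoothed signal exceeds ``threshold`` µV in magnitude.

    The signal is smoothed first, then the absolute value is taken, so an
    isolated single-sample spike is diluted by the window (a 500 µV spike
    becomes ~6 µV after an 80-sample boxcar at 1 kHz) while a sustained
    offset survives smoothing unchanged.
    """
    size = max(1, int(round(smooth_ms * rate / 1000.0)))
    smoothed = _moving_average(np.asarray(epoch, dtype=float), size)
    return set(np.flatnonzero(np.any(np.abs(smoothed) > threshold, axis=-1)).tolist())


# ---------------------------------------------------------------------------
# spherical spline interpolation (Perrin-style, order m = 4)
# ---------------------------------------------------------------------------

def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """g(cos γ) kernel of the spherical spline: Legendre series with 1/(l(l+1))^m."""
    cosang = np.clip(cosang, -1.0, 1.0)
    out = np.zeros_like(cosang)
    p_prev = np.ones_like(cosang)
    p_cur = cosang.copy()
    for l in range(1, n_terms + 1):
        out += (2 * l + 1) / (l * (l + 1)) ** m * p_cur
        p_prev, p_cur = p_cur, ((2 * l + 1) * cosang * p_cur - l * p_prev) / (l + 1)
    return out / (4.0 * np.pi)


def spline_interpolation_matrix(
    pos_from: np.ndarray,
    pos_to: np.ndarray,
    m: int = 4,
    reg: float = 1e-5,
) -> np.ndarray:
    """Matrix mapping potentials at ``pos_from`` to estimates at ``pos_to``.

    Positions are projected to the unit sphere.  The spline system with the
    usual zero-sum constraint is solved with Tikhonov-style regularization
    ``reg`` added to the kernel diagonal.
    """
    pf = pos_from / np.linalg.norm(pos_from, axis=1, keepdims=True)
    pt = pos_to / np.linalg.norm(pos_to, axis=1, keepdims=True)
    g_ff = _spline_g(pf @ pf.T, m=m) + reg * np.eye(len(pf))
    g_tf = _spline_g(pt @ pf.T, m=m)
    n = len(pf)
    lhs = np.zeros((n + 1, n + 1))
    lhs[:n, :n] = g_ff
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    # solve for [C; mu] with rhs [V; 0]; interpolation = G_tf C + mu
    inv = np.linalg.solve(lhs, np.eye(n + 1))
    mapping = g_tf @ inv[:n, :n] + inv[n, :n][None, :]
    return mapping


def interpolate_bad_channels(
    epoch: np.ndarray,
    bad: set[int],
    sensors: SensorArray,
    m: int = 4,
    reg: float = 1e-5,
) -> np.ndarray:
    """Replace bad channels by spherical-spline estimates from the good ones."""
    epoch = np.asarray(epoch, dtype=float)
    if not bad:
        return epoch
    n_ch = epoch.shape[0]
    if not bad < set(range(n_ch)):
        raise ParameterError("bad set must be a proper subset of channels")
    good = sorted(set(range(n_ch)) - bad)
    if len(good) < 4:
        raise ProcessingError(
            f"only {len(good)} good channels; spherical spline needs at least 4"
        )
    bad_idx = sorted(bad)
    mapping = spline_interpolation_matrix(
        sensors.positions[good], sensors.positions[bad_idx], m=m, reg=reg
    )
    out = epoch.copy()
    out[bad_idx] = mapping @ epoch[good]
    return out


# ---------------------------------------------------------------------------
# artifact rejection and re-referencing
# ---------------------------------------------------------------------------

def reject_artifact_epochs(
    epochs: EpochSet,
    limit: float = 25.0,
    mode: str = "gradient",
) -> EpochSet:
    """Mark trials with fast transients (or absolute excursions) as not kept.

    ``gradient`` (default): a trial is rejected when any channel's sample-to-
    sample first difference exceeds ``limit`` µV — blinks and muscle bursts
    are step-like at EEG sampling rates, while ongoing oscillations change
    only fractions of a µV per sample.  ``absolute`` applies the same limit
    to the raw amplitude instead.
    """
    if mode not in ("gradient", "absolute"):
        raise ParameterError(f"unknown rejection mode {mode!r}")
    if epochs.n_trials == 0:
        return epochs
    if mode == "gradient":
        excursion = np.abs(np.diff(epochs.data, axis=2)).max(axis=(1, 2))
    else:
        excursion = np.abs(epochs.data).max(axis=(1, 2))
    kept = np.asarray(epochs.kept, dtype=bool) & (excursion <= limit)
    if not np.any(kept):
        raise ProcessingError(
            f"all {epochs.n_trials} trials rejected by the ±{limit} µV {mode} rule"
        )
    logger.info("artifact rejection kept %d of %d trials", int(kept.sum()),
                epochs.n_trials)
    return replace(epochs, kept=kept)


def rereference_common_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous channel mean from every trial and sample."""
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return replace(epochs, data=data, reference="common-average")


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def preprocess_pipeline(
    raw: RawEEG,
    sensors: SensorArray,
    window: tuple[float, float] = (-1000.0, 1000.0),
    condition: str | None = None,
    band: tuple[float, float] = (1.0, 120.0),
    notch: float | None = 60.0,
    bad_threshold: float = 200.0,
    smooth_ms: float = 80.0,
    reject_limit: float = 25.0,
    reject_mode: str = "gradient",
    cleaned_hook=None,
) -> EpochSet:
    """Filter → epoch → interpolate bad channels → reject → re-reference.

    ``cleaned_hook``, if given, receives the epoched data after bad-channel
    interpolation and before artifact rejection and may return replacement
    data — the injection point for externally denoised (e.g. ICA-cleaned)
    epochs.
    """
    filtered = filter_continuous(raw, band=band, notch=notch)
    epochs = extract_epochs(filtered, window=window, condition=condition)
    for t in range(epochs.n_trials):
        bad = detect_bad_channels(epochs.data[t], raw.rate,
                                  threshold=bad_threshold, smooth_ms=smooth_ms)
        epochs.bad_channels[t] = bad
        if bad:
            epochs.data[t] = interpolate_bad_channels(epochs.data[t], bad, sensors)
    if cleaned_hook is not None:
        replacement = cleaned_hook(epochs)
        if replacement is not None:
            epochs = replacement
    epochs = reject_artifact_epochs(epochs, limit=reject_limit, mode=reject_mode)
    return rereference_common_average(epochs)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_raw(path, events_path=None) -> RawEEG:
    """Read continuous EEG.

    ``.edf`` / ``.bdf`` go through mne; anything else is the plain binary
    matrix format with a sidecar JSON header (``<path>.json`` holding rate,
    labels, events, dtype and channel count).  Events may also be supplied
    as a two-column delimited file (sample, label).
    """
    path = str(path)
    if path.endswith((".edf", ".bdf")):
        import mne

        mne_raw = mne.io.read_raw(path, preload=True, verbose="error")
        data = mne_raw.get_data() * 1e6  # V -> µV
        events = []
        rate = float(mne_raw.info["sfreq"])
        labels = list(mne_raw.ch_names)
        reference = "unknown"
    else:
        with open(path + ".json") as fh:
            header = json.load(fh)
        dtype = np.dtype(header.get("dtype", "float64"))
        data = np.fromfile(path, dtype=dtype).reshape(
            header["n_channels"], -1
        ).astype(float)
        rate = float(header["rate"])
        labels = header.get("labels")
        events = [(int(s), str(lab)) for s, lab in header.get("events", [])]
        reference = header.get("reference", "Cz")
    if events_path is not None:
        events = []
        with open(events_path) as fh:
            for line in fh:
                parts = line.split()
                if parts:
                    events.append((int(parts[0]), parts[1] if len(parts) > 1 else ""))
    return RawEEG(data=data, rate=rate, events=events, labels=labels,
                  reference=reference)


def write_raw(raw: RawEEG, path) -> None:
    """Write the binary-matrix + JSON-header continuous format."""
    path = str(path)
    raw.data.astype(np.float32).tofile(path)
    header = {
        "rate": raw.rate,
        "n_channels": raw.n_channels,
        "dtype": "float32",
        "labels": raw.labels,
        "events": [[int(s), lab] for s, lab in raw.events],
        "reference": raw.reference,
    }
    with open(path + ".json", "w") as fh:
        json.dump(header, fh)


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data.astype(np.float32))
        fh.attrs["window"] = epochs.window
        fh.attrs["rate"] = epochs.rate
        fh.attrs["reference"] = epochs.reference
        fh.attrs["n_events_total"] = epochs.n_events_total
        fh.attrs["n_edge_dropped"] = epochs.n_edge_dropped
        fh.create_dataset("kept", data=np.asarray(epochs.kept, dtype=bool))
        fh.create_dataset(
            "condition",
            data=np.array(epochs.condition, dtype=h5py.string_dtype()),
        )


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        return EpochSet(
            data=fh["data"][()].astype(float),
            window=tuple(fh.attrs["window"]),
            rate=float(fh.attrs["rate"]),
            condition=[c.decode() if isinstance(c, bytes) else str(c)
                       for c in fh["condition"][()]],
            kept=fh["kept"][()],
            reference=str(fh.attrs["reference"]),
            n_events_total=int(fh.attrs["n_events_total"]),
            n_edge_dropped=int(fh.attrs["n_edge_dropped"]),
        )
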