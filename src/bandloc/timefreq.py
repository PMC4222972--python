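"""Complex Morlet decomposition, ERD/ERS maps and the sensor contiguity screen.

A Morlet family is parameterized by a cycles-to-frequency trade-off ratio
(default 7): at center frequency f the Gaussian envelope has
σ_t = ratio / (2π f), so temporal resolution sharpens and spectral
resolution broadens proportionally with frequency.  Wavelets are truncated
at ±3.5 σ_t (<0.1 % energy loss) and normalized to unit energy; the
truncated support defines, deterministically, which coefficients near the
epoch edges are flagged invalid instead of being silently zero-padded.

Relative power (ERD/ERS, percent) is the trial-averaged power change against
the mean over the −1000…−600 ms pre-movement baseline; negative values are
desynchronization, positive are synchronization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy.signal import fftconvolve

from .errors import ParameterError, UndefinedBaselineError
from .preprocess import EpochSet

__all__ = [
    "MorletFamily",
    "TFCoefficients",
    "BandScheme",
    "RelativePowerMap",
    "build_morlet_family",
    "wavelet_transform",
    "sensor_relative_power",
    "band_average",
    "threshold_top_percent",
    "contiguity_screen",
    "save_tf",
    "load_tf",
    "DEFAULT_BANDS",
]

SUPPORT_SIGMAS = 3.5  # wavelet truncated at ±3.5 σ_t


@dataclass
class MorletFamily:
    """Family of complex Morlet wavelets with a constant cycles ratio."""

    rate: float
    frequencies: np.ndarray
    ratio: float = 7.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies <= 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ParameterError("frequencies must be positive and ascending")

    def sigma_t(self, f: float) -> float:
        """Temporal Gaussian width in seconds: σ_t = ratio / (2π f)."""
        return self.ratio / (2.0 * np.pi * f)

    def half_support_ms(self, f: float) -> float:
        return SUPPORT_SIGMAS * self.sigma_t(f) * 1000.0

    def wavelet(self, f: float) -> np.ndarray:
        """Sampled unit-energy wavelet on its truncated support (odd length)."""
        st = self.sigma_t(f)
        half = int(np.floor(SUPPORT_SIGMAS * st * self.rate))
        t = np.arange(-half, half + 1) / self.rate
        psi = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * st**2))
        dt = 1.0 / self.rate
        energy = np.sum(np.abs(psi) ** 2) * dt
        return psi / np.sqrt(energy)


def build_morlet_family(
    rate: float,
    frequencies=None,
    ratio: float = 7.0,
) -> MorletFamily:
    """Morlet family over integer frequencies 1–120 Hz by default."""
    if frequencies is None:
        frequencies = np.arange(1.0, 121.0)
    frequencies = np.asarray(frequencies, dtype=float)
    if ratio <= 0:
        raise ParameterError("ratio must be positive")
    if ratio < 5:
        warnings.warn(
            f"cycles ratio {ratio} < 5: the wavelet spans less than one full "
            "cycle of margin; frequency resolution will be poor"
        )
    if rate < 2 * frequencies.max():
        raise ParameterError(
            f"rate {rate} Hz below Nyquist for {frequencies.max()} Hz"
        )
    return MorletFamily(rate=rate, frequencies=frequencies, ratio=ratio)


@dataclass
class TFCoefficients:
    """Complex coefficients over (trial, space, frequency, time)."""

    values: np.ndarray            # complex, (n_trials, n_space, n_freq, n_time)
    times: np.ndarray             # ms, 10 ms grid
    frequencies: np.ndarray       # Hz
    valid: np.ndarray             # (n_freq, n_time) bool: support inside the epoch
    space_kind: str = "sensor"    # 'sensor' | 'patch'

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_space(self) -> int:
        return self.values.shape[1]


@dataclass
class BandScheme:
    """Named closed integer frequency ranges (Hz, inclusive endpoints)."""

    bands: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if lo > hi or lo <= 0:
                raise ParameterError(f"band {name} has invalid range {(lo, hi)}")

    def items(self):
        return self.bands.items()


DEFAULT_BANDS = BandScheme(
    {"theta": (5, 8), "mu": (9, 13), "beta": (14, 30), "LG": (31, 60),
     "HG": (61, 120)}
)

#: Bins hidden by the 60 Hz line-noise notch, excluded from band averages.
NOTCH_EXCLUDE_HZ = (59, 60, 61)


@dataclass
class RelativePowerMap:
    """Percent power change per (space, frequency-or-band, time)."""

    values: np.ndarray                     # (n_space, n_freq_or_band, n_time)
    times: np.ndarray                      # ms
    axis: list                             # frequencies (Hz) or band names
    baseline_window: tuple[float, float]
    space_kind: str = "sensor"
    axis_kind: str = "frequency"           # 'frequency' | 'band'
    valid: np.ndarray | None = None        # (n_axis, n_time) bool


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------

def wavelet_transform(
    epochs: EpochSet | np.ndarray,
    family: MorletFamily,
    step_ms: float = 10.0,
    window: tuple[float, float] | None = None,
    dtype=np.complex64,
) -> TFCoefficients:
    """Complex Morlet coefficients of every trial and channel at 10 ms steps.

    The convolution kernel is the time-reversed conjugate wavelet, i.e. the
    coefficient at time t is the correlation of the data with the wavelet
    centered at t.  Grid points whose truncated support sticks out of the
    epoch are flagged invalid in ``valid`` (values are still computed
    against the implicit zero padding).
    """
    if isinstance(epochs, EpochSet):
        data = epochs.kept_data()
        w0, w1 = epochs.window
        rate = epochs.rate
    else:
        data = np.asarray(epochs, dtype=float)
        if window is None:
            raise ParameterError("window must be given with a bare array")
        w0, w1 = window
        rate = family.rate
    if data.ndim == 2:
        data = data[None]
    n_trials, n_space, n_samp = data.shape

    # 10 ms grid: every ms value in [w0, w1] divisible by step
    step_samp = step_ms * rate / 1000.0
    if abs(step_samp - round(step_samp)) > 1e-9:
        raise ParameterError("step_ms must be an integer number of samples")
    step_samp = int(round(step_samp))
    all_ms = w0 + np.arange(n_samp) * 1000.0 / rate
    grid_idx = np.flatnonzero(np.isclose(np.mod(all_ms, step_ms), 0)
                              | np.isclose(np.mod(all_ms, step_ms), step_ms))
    times = all_ms[grid_idx]

    freqs = family.frequencies
    out = np.empty((n_trials, n_space, len(freqs), len(grid_idx)), dtype=dtype)
    valid = np.zeros((len(freqs), len(grid_idx)), dtype=bool)
    flat = data.reshape(n_trials * n_space, n_samp)
    for fi, f in enumerate(freqs):
        psi = family.wavelet(f)
        kernel = np.conj(psi[::-1])
        coeffs = fftconvolve(flat, kernel[None, :], mode="same", axes=1)
        out[:, :, fi, :] = coeffs[:, grid_idx].reshape(
            n_trials, n_space, len(grid_idx)
        )
        half_ms = family.half_support_ms(f)
        valid[fi] = (times - half_ms >= w0 - 1e-9) & (times + half_ms <= w1 + 1e-9)
    return TFCoefficients(values=out, times=times, frequencies=freqs.copy(),
                          valid=valid, space_kind="sensor")


# ---------------------------------------------------------------------------
# relative power
# ---------------------------------------------------------------------------

def sensor_relative_power(
    coeffs: TFCoefficients,
    baseline: tuple[float, float] = (-1000.0, -600.0),
) -> RelativePowerMap:
    """Percent change of trial-averaged power against the baseline mean.

    Per space × frequency the trial-averaged power P̄(t) is referenced to
    B, the mean of P̄ over the *valid* baseline grid points; output is
    100·(P̄(t) − B)/B.  A frequency with no valid baseline sample, or a
    zero baseline, raises an error naming the frequency.
    """
    power = np.mean(np.abs(coeffs.values) ** 2, axis=0)  # (space, freq, time)
    b0, b1 = baseline
    in_window = (coeffs.times >= b0) & (coeffs.times <= b1)
    n_space, n_freq, n_time = power.shape
    out = np.empty_like(power, dtype=float)
    for fi, f in enumerate(coeffs.frequencies):
        use = in_window & coeffs.valid[fi]
        if not np.any(use):
            raise UndefinedBaselineError(
                f"no valid baseline sample at {f:g} Hz within {baseline} ms"
            )
        b = power[:, fi, use].mean(axis=1)  # (space,)
        if np.any(b == 0):
            raise UndefinedBaselineError(f"zero baseline power at {f:g} Hz")
        out[:, fi, :] = 100.0 * (power[:, fi, :] - b[:, None]) / b[:, None]
    return RelativePowerMap(
        values=out, times=coeffs.times.copy(),
        axis=list(coeffs.frequencies), baseline_window=baseline,
        space_kind=coeffs.space_kind, axis_kind="frequency",
        valid=coeffs.valid.copy(),
    )


def band_average(
    pmap: RelativePowerMap,
    bands: BandScheme = DEFAULT_BANDS,
    exclude_notch: bool = True,
) -> RelativePowerMap:
    """Unweighted mean over each band's integer bins (inclusive endpoints).

    Bins 59–61 Hz sit inside the line-noise notch and are excluded from the
    low/high gamma averages by default so the dead band does not bias them.
    """
    if pmap.axis_kind != "frequency":
        raise ParameterError("band_average needs a frequency-resolved map")
    freqs = np.asarray(pmap.axis, dtype=float)
    names, stacks, valids = [], [], []
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if exclude_notch:
            notch_sel = np.isin(freqs, NOTCH_EXCLUDE_HZ)
            if np.any(sel & ~notch_sel):
                sel = sel & ~notch_sel
        if not np.any(sel):
            raise ParameterError(
                f"band {name} {(lo, hi)} Hz lies outside the frequency axis"
            )
        names.append(name)
        stacks.append(pmap.values[:, sel, :].mean(axis=1))
        if pmap.valid is not None:
            valids.append(np.all(pmap.valid[sel], axis=0))
    return RelativePowerMap(
        values=np.stack(stacks, axis=1), times=pmap.times, axis=names,
        baseline_window=pmap.baseline_window, space_kind=pmap.space_kind,
        axis_kind="band",
        valid=np.stack(valids) if valids else None,
    )


# ---------------------------------------------------------------------------
# thresholding and contiguity
# ---------------------------------------------------------------------------

def threshold_top_percent(pmap: RelativePowerMap, top: float = 10.0) -> np.ndarray:
    """Suprathreshold mask keeping the top ``top`` percent of |values| per band.

    The cut is applied per axis entry (band or frequency) over all space ×
    time cells; the sign of the underlying value stays available in the map
    for ERD/ERS labeling.
    """
    if not 0 < top <= 100:
        raise ParameterError("top percent must be in (0, 100]")
    mags = np.abs(pmap.values)
    mask = np.zeros_like(mags, dtype=bool)
    for ai in range(mags.shape[1]):
        cut = np.percentile(mags[:, ai, :], 100.0 - top)
        mask[:, ai, :] = mags[:, ai, :] >= cut
    return mask


def contiguity_screen(
    mask: np.ndarray,
    adjacency: np.ndarray | None,
    min_channels: int = 4,
) -> np.ndarray:
    """Volume-conduction plausibility screen on a sensor suprathreshold mask.

    A (band, time) feature survives only where the suprathreshold channels
    contain a connected component of at least ``min_channels`` under the
    sensor adjacency; channels outside such components are cleared.  A
    single isolated hot channel is, with 256 sensors at ~2 cm pitch,
    physically implausible for a cortical source.
    """
    if adjacency is None:
        raise ParameterError("sensor adjacency is required for the contiguity screen")
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 1:
        mask = mask[:, None, None]
        squeeze = True
    else:
        squeeze = False
    n_space = mask.shape[0]
    adj = csr_matrix(np.asarray(adjacency, dtype=bool))
    out = np.zeros_like(mask)
    for ai in range(mask.shape[1]):
        for ti in range(mask.shape[2]):
            on = np.flatnonzero(mask[:, ai, ti])
            if len(on) < min_channels:
                continue
            sub = adj[np.ix_(on, on)]
            n_comp, labels = connected_components(sub, directed=False)
            sizes = np.bincount(labels, minlength=n_comp)
            keep = on[sizes[labels] >= min_channels]
            out[keep, ai, ti] = True
    return out[:, 0, 0] if squeeze else out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_tf(coeffs: TFCoefficients, path) -> None:
    """HDF5 with complex values stored as paired real/imag datasets."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("real", data=coeffs.values.real.astype(np.float32))
        fh.create_dataset("imag", data=coeffs.values.imag.astype(np.float32))
        fh.create_dataset("times", data=coeffs.times)
        fh.create_dataset("frequencies", data=coeffs.frequencies)
        fh.create_dataset("valid", data=coeffs.valid)
        fh.attrs["space_kind"] = coeffs.space_kind


def load_tf(path) -> TFCoefficients:
    with h5py.File(path, "r") as fh:
        values = fh["real"][()].astype(np.float32) + 1j * fh["imag"][()].astype(
            np.float32
        )
        return TFCoefficients(
            values=values.astype(np.complex64),
            times=fh["times"][()],
            frequencies=fh["frequencies"][()],
            valid=fh["valid"][()],
            space_kind=str(fh.attrs["space_kind"]),
        )
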