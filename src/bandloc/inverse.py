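"""sLORETA inverse operator and source-space ERD/ERS.

The forward model is linear, Φ = K J + ε, with K the common-average
referenced lead field and J one scalar amplitude per fixed-orientation
dipole patch.  The minimum-norm estimate is

    T = Kᵀ (K Kᵀ + λ H)⁺,     λ = λ_rel · trace(K Kᵀ) / n_sensors,

with H the average-reference centering projector on sensors (the natural
regularizer in the rank-deficient average-reference space) and ⁺ the
pseudoinverse.  sLORETA standardizes the MN estimate per patch by the
resolution-matrix diagonal S_jj = [T K]_jj: the standardized estimate is
(T y)_j / √S_jj, which has zero localization error for noiseless single
sources.

The operator is applied directly to the complex Morlet coefficients (real
and imaginary parts transformed identically); source power is the
trial-averaged squared modulus, and ERD/ERS is that power relative to a
per-frequency baseline coefficient whose wavelet support sits inside the
−1000…−600 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .errors import (
    BaselineInfeasibleError,
    NumericalError,
    ParameterError,
    ReferenceStateError,
    UndefinedBaselineError,
)
from .forward import LeadField
from .timefreq import (
    SUPPORT_SIGMAS,
    BandScheme,
    DEFAULT_BANDS,
    MorletFamily,
    RelativePowerMap,
    TFCoefficients,
    band_average,
)

__all__ = [
    "InverseOperator",
    "SourceTF",
    "SourcePowerMap",
    "compute_mn_operator",
    "sloreta_standardize",
    "apply_inverse_tf",
    "source_power",
    "baseline_power",
    "relative_power",
    "source_band_power",
    "save_operator",
    "load_operator",
]


@dataclass
class InverseOperator:
    """Minimum-norm transform plus the per-patch sLORETA standardization."""

    transform: np.ndarray        # (n_patches, n_sensors) MN matrix T
    standardization: np.ndarray  # (n_patches,) S_jj > 0
    lam: float
    reference: str = "common-average"

    def __post_init__(self) -> None:
        if np.any(self.standardization <= 0):
            raise NumericalError("standardization must be strictly positive")
        if not np.all(np.isfinite(self.transform)):
            raise NumericalError("inverse transform must be finite")

    @property
    def n_patches(self) -> int:
        return self.transform.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.transform.shape[1]

    def apply(self, y: np.ndarray) -> np.ndarray:
        """Standardized source estimate for sensor data ``y`` (…, sensors last axis is first)."""
        est = np.tensordot(self.transform, y, axes=(1, 0))
        return est / np.sqrt(self.standardization).reshape(
            (-1,) + (1,) * (est.ndim - 1)
        )


@dataclass
class SourceTF:
    """Complex source-space wavelet coefficients (trial, patch, freq, time)."""

    values: np.ndarray
    times: np.ndarray
    frequencies: np.ndarray
    valid: np.ndarray
    provenance: str = ""

    @property
    def n_patches(self) -> int:
        return self.values.shape[1]


@dataclass
class SourcePowerMap:
    """Per-patch relative power (%) indexed (patch, frequency-or-band, time)."""

    values: np.ndarray
    times: np.ndarray
    axis: list
    baseline: np.ndarray | None = None    # per (patch, frequency) baseline power
    axis_kind: str = "frequency"


# ---------------------------------------------------------------------------
# operator construction
# ---------------------------------------------------------------------------

def compute_mn_operator(K: LeadField, lambda_rel: float = 0.05) -> np.ndarray:
    """Minimum-norm transform T = Kᵀ (K Kᵀ + λH)⁺ for an average-referenced K."""
    if lambda_rel < 0:
        raise ParameterError("lambda_rel must be non-negative")
    if K.reference != "common-average":
        raise ReferenceStateError(
            "lead field must be common-average referenced before inversion"
        )
    k = K.matrix
    ns = k.shape[0]
    gram = k @ k.T
    lam = lambda_rel * np.trace(gram) / ns
    h = np.eye(ns) - np.full((ns, ns), 1.0 / ns)  # average-reference projector
    # pseudoinverse with relative cutoff; the all-ones direction is null
    inv = np.linalg.pinv(gram + lam * h, rcond=1e-10, hermitian=True)
    return k.T @ inv


def sloreta_standardize(T: np.ndarray, K: LeadField) -> InverseOperator:
    """Standardize the MN solution by the resolution-matrix diagonal.

    Under the fixed-orientation constraint each patch contributes a single
    scalar, so the sLORETA blocks reduce to the scalars S_jj = [T K]_jj.
    """
    if T.shape[1] != K.matrix.shape[0] or T.shape[0] != K.matrix.shape[1]:
        raise ParameterError("transform and lead field dimensions disagree")
    s = np.einsum("js,sj->j", T, K.matrix)
    bad = np.flatnonzero(s <= 0)
    if bad.size:
        raise NumericalError(
            f"non-positive standardization at patches {bad[:5].tolist()}"
        )
    return InverseOperator(transform=T, standardization=s, lam=0.0,
                           reference=K.reference)


def make_inverse_operator(K: LeadField, lambda_rel: float = 0.05) -> InverseOperator:
    """Convenience: MN transform + sLORETA standardization in one step."""
    T = compute_mn_operator(K, lambda_rel=lambda_rel)
    op = sloreta_standardize(T, K)
    op.lam = lambda_rel * np.trace(K.matrix @ K.matrix.T) / K.matrix.shape[0]
    return op


# ---------------------------------------------------------------------------
# application to wavelet coefficients
# ---------------------------------------------------------------------------

def apply_inverse_tf(op: InverseOperator, coeffs: TFCoefficients) -> SourceTF:
    """Map complex sensor coefficients to standardized source coefficients.

    The operator is real, so real and imaginary parts transform identically
    and the map commutes with any global phase rotation.
    """
    if coeffs.space_kind != "sensor":
        raise ParameterError("apply_inverse_tf needs sensor-space coefficients")
    if coeffs.values.shape[1] != op.n_sensors:
        raise ParameterError(
            f"coefficients have {coeffs.values.shape[1]} sensors, operator "
            f"expects {op.n_sensors}"
        )
    w = (op.transform / np.sqrt(op.standardization)[:, None]).astype(np.float32)
    n_tr, n_s, n_f, n_t = coeffs.values.shape
    flat = np.moveaxis(coeffs.values, 1, 0).reshape(n_s, -1)
    src = (w @ flat.real + 1j * (w @ flat.imag)).astype(np.complex64)
    src = np.moveaxis(src.reshape(op.n_patches, n_tr, n_f, n_t), 0, 1)
    return SourceTF(values=src, times=coeffs.times.copy(),
                    frequencies=coeffs.frequencies.copy(),
                    valid=coeffs.valid.copy(), provenance="sloreta")


def source_power(src: SourceTF) -> np.ndarray:
    """Trial-averaged power |X|² per (patch, frequency, time)."""
    if src.values.shape[0] < 1:
        raise ParameterError("source power needs at least one trial")
    return np.mean(np.abs(src.values.astype(np.complex64)) ** 2, axis=0)


def baseline_time(
    f: float,
    family: MorletFamily,
    baseline_window: tuple[float, float] = (-1000.0, -600.0),
    step_ms: float = 10.0,
    placement: str = "support-end",
) -> float:
    """Baseline time point for frequency ``f``, snapped to the 10 ms grid.

    ``support-end`` (default): the truncated wavelet support ends at the
    baseline window's end, t_b = b1 − 3.5 σ_t.  ``center`` places the
    wavelet center at the window end instead.  Raises when the support does
    not fit inside the window at this frequency (low frequencies).
    """
    b0, b1 = baseline_window
    half_ms = SUPPORT_SIGMAS * family.sigma_t(f) * 1000.0
    if placement == "support-end":
        if 2 * half_ms > (b1 - b0):
            raise BaselineInfeasibleError(
                f"wavelet support 2×{half_ms:.1f} ms exceeds the "
                f"{b1 - b0:.0f} ms baseline window at {f:g} Hz"
            )
        tb = b1 - half_ms
    elif placement == "center":
        tb = b1
    else:
        raise ParameterError(f"unknown baseline placement {placement!r}")
    return round(tb / step_ms) * step_ms


def baseline_power(
    src: SourceTF,
    family: MorletFamily,
    baseline_window: tuple[float, float] = (-1000.0, -600.0),
    placement: str = "support-end",
) -> np.ndarray:
    """Per-(patch, frequency) baseline power from one wavelet per frequency.

    The baseline coefficient at frequency f is taken at the single time
    point where the wavelet support lies just inside the baseline window;
    its trial-averaged squared modulus is B(f).
    """
    step = float(np.median(np.diff(src.times)))
    n_patch = src.n_patches
    out = np.empty((n_patch, len(src.frequencies)))
    for fi, f in enumerate(src.frequencies):
        tb = baseline_time(f, family, baseline_window, step_ms=step,
                           placement=placement)
        ti = int(np.argmin(np.abs(src.times - tb)))
        if abs(src.times[ti] - tb) > step / 2 + 1e-9:
            raise BaselineInfeasibleError(
                f"baseline time {tb} ms not on the coefficient grid at {f:g} Hz"
            )
        out[:, fi] = np.mean(np.abs(src.values[:, :, fi, ti]) ** 2, axis=0)
    return out


def relative_power(P: np.ndarray, B: np.ndarray, times, frequencies) -> SourcePowerMap:
    """100·(P − B)/B per patch, frequency and time; negative = ERD."""
    P = np.asarray(P, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(B <= 0):
        raise UndefinedBaselineError("baseline power must be strictly positive")
    values = 100.0 * (P - B[:, :, None]) / B[:, :, None]
    return SourcePowerMap(values=values, times=np.asarray(times),
                          axis=list(frequencies), baseline=B,
                          axis_kind="frequency")


def source_band_power(
    pmap: SourcePowerMap,
    bands: BandScheme = DEFAULT_BANDS,
    exclude_notch: bool = True,
) -> SourcePowerMap:
    """Band-aggregate a frequency-resolved source map (reuses band_average)."""
    shim = RelativePowerMap(
        values=pmap.values, times=pmap.times, axis=pmap.axis,
        baseline_window=(0.0, 0.0), space_kind="patch",
        axis_kind=pmap.axis_kind,
    )
    banded = band_average(shim, bands=bands, exclude_notch=exclude_notch)
    return SourcePowerMap(values=banded.values, times=banded.times,
                          axis=banded.axis, baseline=pmap.baseline,
                          axis_kind="band")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_operator(op: InverseOperator, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("transform", data=op.transform)
        fh.create_dataset("standardization", data=op.standardization)
        fh.attrs["lambda"] = op.lam
        fh.attrs["reference"] = op.reference


def load_operator(path) -> InverseOperator:
    with h5py.File(path, "r") as fh:
        return InverseOperator(
            transform=fh["transform"][()],
            standardization=fh["standardization"][()],
            lam=float(fh.attrs["lambda"]),
            reference=str(fh.attrs["reference"]),
        )
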