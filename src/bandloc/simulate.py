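"""Synthetic EEG sessions and BOLD volumes with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
self-paced button-press task at 0.5 Hz (one response every 2 s), epochs of
−1000…+1000 ms around each response, band-specific ERD/ERS emitted by a
small set of cortical patches (beta desynchronization starting ~500 ms
before the response; theta/gamma synchronization bursts), 1/f background
activity generated in source space, white sensor noise, and occasional
high-amplitude artifact channels and epochs.

Oscillatory sources carry trial-varying random phase (induced, not evoked,
activity) so that power — not the phase-locked average — holds the effect;
a phase-locked option exists for testing theta-like responses.  A source's
carrier is either a fixed sinusoid or band-limited Gaussian noise
("broadband"), the latter being the physiologically realistic choice for
band-wide ERD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .forward import (
    ConductivityProfile,
    CorticalPatchModel,
    LeadField,
    SensorArray,
    build_spherical_lead_field,
    make_adjacency,
    save_lead_field,
)
from .preprocess import RawEEG, write_raw
from .bold import StatVolume
from .metrics import ROISet

__all__ = [
    "SourceSpec",
    "NoiseSpec",
    "SimulationConfig",
    "GroundTruth",
    "geodesic_sensors",
    "synthetic_patch_model",
    "rois_around",
    "simulate_session",
    "simulate_stat_volume",
    "make_fixture_suite",
]


# ---------------------------------------------------------------------------
# geometry generators
# ---------------------------------------------------------------------------

def geodesic_sensors(n: int = 256, radius: float = 92.0,
                     coverage: float = -0.25) -> SensorArray:
    """Approximately uniform sensor layout on the upper head sphere.

    A Fibonacci lattice on the spherical cap z/R > ``coverage`` emulates the
    dense-array net's whole-head coverage (extending below the equator but
    not under the chin).
    """
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n)
    z = 1.0 - (1.0 - coverage) * (i + 0.5) / n  # from +1 down to `coverage`
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pos = radius * np.c_[rho * np.cos(theta), rho * np.sin(theta), z]
    labels = [f"E{k + 1}" for k in range(n)]
    return SensorArray(labels, pos, adjacency=make_adjacency(pos, 6))


def synthetic_patch_model(
    n_per_hemisphere: int = 1200,
    seed: int = 0,
    radius_range: tuple[float, float] = (30.0, 64.0),
) -> CorticalPatchModel:
    """Random dipole-patch model inside the brain shell, split by hemisphere.

    Patch centers are uniform in direction with radii in ``radius_range``
    (kept ≤ 64 mm so the spherical forward series converges at its default
    truncation); orientations are radial with tangential jitter, mimicking
    a surface-normal constraint on a convoluted cortex.  x < 0 is the left
    hemisphere.
    """
    rng = np.random.default_rng(seed)
    centers, hemis = [], []
    for hemi, sign in (("L", -1.0), ("R", 1.0)):
        k = 0
        while k < n_per_hemisphere:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if sign * v[0] < 0.02:  # keep a gap at the midline
                continue
            r = rng.uniform(*radius_range)
            centers.append(r * v)
            hemis.append(hemi)
            k += 1
    centers = np.array(centers)
    radial = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    jitter = rng.normal(scale=0.4, size=radial.shape)
    orient = radial + jitter
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    return CorticalPatchModel(centers, orient, np.array(hemis))


def rois_around(
    patches: CorticalPatchModel,
    target_patch: int,
    n_m1: int = 12,
    n_s1: int = 13,
) -> ROISet:
    """Hand-region stand-in ROIs: nearest same-hemisphere patches to a target.

    M1 is the target patch plus its nearest neighbors; S1 the next shell
    outward.  Combined size defaults to 25 per hemisphere, inside the 23–28
    range typical of a manual hand-knob delineation; the representative
    (central-sulcus) dipole is the target itself.
    """
    hemi = str(patches.hemisphere[target_patch])
    same = patches.hemisphere_indices(hemi)
    d = np.linalg.norm(patches.centers[same] - patches.centers[target_patch], axis=1)
    order = same[np.argsort(d)]
    m1 = set(int(i) for i in order[:n_m1])
    s1 = set(int(i) for i in order[n_m1 : n_m1 + n_s1])
    return ROISet(m1={hemi: m1}, s1={hemi: s1},
                  representative={hemi: int(target_patch)})


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SourceSpec:
    """One oscillating cortical patch with an ERD or ERS envelope."""

    patch: int
    kind: str = "ERD"                   # 'ERD' | 'ERS'
    band: tuple[float, float] = (14.0, 30.0)
    carrier: str | float = "broadband"  # 'broadband' or a fixed carrier in Hz
    onset_ms: float = -500.0            # envelope change relative to response
    offset_ms: float = 300.0            # end of the ERD plateau / burst tail
    depth: float = 0.5                  # ERD: amplitude drop fraction; ERS: burst gain
    burst_sd_ms: float = 100.0          # ERS burst width
    ers_base: float = 0.25              # ERS baseline amplitude fraction
    phase_locked: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("ERD", "ERS"):
            raise ParameterError(f"unknown source kind {self.kind!r}")
        if self.kind == "ERD" and not 0.0 <= self.depth <= 1.0:
            raise ParameterError("ERD depth fraction must be in [0, 1]")


@dataclass
class NoiseSpec:
    """Background and sensor noise levels.

    ``exponent`` is the power-spectral slope of the source-space background
    (power ∝ 1/f^exponent); ``background_rms`` is the mean per-sensor RMS of
    the projected background in µV; ``sensor_rms`` is white instrument
    noise in µV.
    """

    background_rms: float = 10.0
    exponent: float = 1.0
    sensor_rms: float = 2.0
    n_background_patches: int = 200


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic session."""

    seed: int
    n_trials: int = 180
    rate: float = 1000.0
    event_interval_ms: float = 2000.0
    condition: str = "RT"
    sources: list[SourceSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    snr: float = 5.0                    # best-sensor source RMS over in-band noise RMS
    bad_channel_prob: float = 0.03      # per trial: one saturated-drift channel
    blink_prob: float = 0.03            # per trial: high-amplitude blink epoch

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("a seed is mandatory")
        half = self.event_interval_ms / 2.0
        for s in self.sources:
            if not -half <= s.onset_ms <= half:
                raise ParameterError("source onset must lie within the epoch")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    source_patches: list[int]
    source_kinds: list[str]
    source_bands: list[tuple[float, float]]
    expected_rel_power: list[float]     # ERD: ((1-depth)^2 - 1)·100
    event_samples: list[int]
    bad_channel_trials: dict[int, int]  # trial -> channel
    blink_trials: list[int]
    bold_active: list[int]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------

def _one_over_f(rng, n_samples: int, rate: float, exponent: float,
                n_series: int) -> np.ndarray:
    """Rows of 1/f^exponent (power) Gaussian noise, unit RMS."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.ones_like(f)
    nz = f >= 1.0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[~nz] = shape[nz][0] if np.any(nz) else 1.0
    shape[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    return out / np.maximum(rms, 1e-30)


def _band_noise(rng, n_samples: int, rate: float,
                band: tuple[float, float]) -> np.ndarray:
    """Band-limited unit-RMS Gaussian noise (hard spectral window)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    out = np.fft.irfft(spec, n=n_samples)
    return out / np.sqrt(np.mean(out**2))


def _envelope(spec: SourceSpec, rel_ms: np.ndarray) -> np.ndarray:
    """Amplitude envelope over time relative to the response onset (ms)."""
    if spec.kind == "ERD":
        amp = np.ones_like(rel_ms)
        inside = (rel_ms >= spec.onset_ms) & (rel_ms <= spec.offset_ms)
        amp[inside] = 1.0 - spec.depth
        return amp
    burst = np.exp(-((rel_ms - spec.onset_ms) ** 2) / (2.0 * spec.burst_sd_ms**2))
    return spec.ers_base + spec.depth * burst


def simulate_session(
    cfg: SimulationConfig,
    lf: LeadField,
    patches: CorticalPatchModel | None = None,
) -> tuple[RawEEG, GroundTruth]:
    """Continuous sensor recording with response events and planted sources.

    Same seed, same output, bit for bit.  Source scaling: each source is
    scaled so its baseline-amplitude RMS at its best sensor is ``cfg.snr``
    times the RMS of the background + sensor noise *within the source's
    band* at that sensor — the usual narrow-band SNR convention, which
    keeps absolute amplitudes physiological (a few µV of beta at the
    scalp over a ~10 µV broadband background).
    """
    patches = patches or lf.patches
    if patches is None:
        raise ParameterError("a patch model is required")
    for s in cfg.sources:
        if not 0 <= s.patch < patches.n_patches:
            raise ParameterError(f"unknown patch id {s.patch}")
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate
    interval = int(round(cfg.event_interval_ms * rate / 1000.0))
    half = interval // 2
    n_samples = interval * (cfg.n_trials + 2)
    events = [(interval * (k + 1), cfg.condition) for k in range(cfg.n_trials)]
    event_samples = np.array([e[0] for e in events])

    # relative time (ms) to the nearest owning event, segments tiling exactly
    t_idx = np.arange(n_samples)
    seg = np.clip((t_idx + half) // interval, 1, cfg.n_trials) * interval
    rel_ms = (t_idx - seg) * 1000.0 / rate

    n_sensors = lf.n_sensors
    # --- background: 1/f source activity + white sensor noise ---
    n_bg = min(cfg.noise.n_background_patches, patches.n_patches)
    bg_patches = rng.choice(patches.n_patches, size=n_bg, replace=False)
    bg = _one_over_f(rng, n_samples, rate, cfg.noise.exponent, n_bg)
    sensor_bg = lf.matrix[:, bg_patches] @ bg
    bg_rms = np.sqrt(np.mean(sensor_bg**2, axis=1))
    sensor_bg *= cfg.noise.background_rms / max(np.mean(bg_rms), 1e-30)
    sensor_bg += cfg.noise.sensor_rms * rng.standard_normal((n_sensors, n_samples))

    def band_rms(channel: np.ndarray, band: tuple[float, float]) -> float:
        spec = np.fft.rfft(channel)
        f = np.fft.rfftfreq(len(channel), d=1.0 / rate)
        sel = (f >= band[0]) & (f <= band[1])
        return float(np.sqrt(np.sum(np.abs(spec[sel]) ** 2) / len(channel) ** 2 * 2))

    data = sensor_bg
    del bg
    # --- oscillatory sources ---
    for spec in cfg.sources:
        if spec.carrier == "broadband":
            carrier = _band_noise(rng, n_samples, rate, spec.band)
        else:
            f0 = float(spec.carrier)
            carrier = np.empty(n_samples)
            phase0 = 0.0 if spec.phase_locked else rng.uniform(0, 2 * np.pi)
            t_s = t_idx / rate
            carrier[:] = np.cos(2 * np.pi * f0 * t_s + phase0)
            for ev in event_samples:  # fresh phase each trial segment
                ph = 0.0 if spec.phase_locked else rng.uniform(0, 2 * np.pi)
                sl = slice(ev - half, ev + half)
                carrier[sl] = np.cos(2 * np.pi * f0 * t_s[sl] + ph)
            carrier *= np.sqrt(2.0)  # unit RMS
        wave = carrier * _envelope(spec, rel_ms)
        gain = lf.matrix[:, spec.patch]
        best = int(np.argmax(np.abs(gain)))
        # baseline-amplitude RMS of the carrier is 1 by construction
        noise_in_band = band_rms(sensor_bg[best], spec.band)
        scale = cfg.snr * noise_in_band / max(abs(gain[best]), 1e-30)
        data = data + np.outer(gain, wave) * scale

    # --- artifacts ---
    bad_channel_trials: dict[int, int] = {}
    blink_trials: list[int] = []
    frontal = np.argsort(-lf.sensors.positions[:, 1])[: max(4, n_sensors // 10)] \
        if lf.sensors is not None else np.arange(max(4, n_sensors // 10))
    for t, ev in enumerate(event_samples):
        sl = slice(ev - half, ev + half)
        if rng.uniform() < cfg.bad_channel_prob:
            ch = int(rng.integers(n_sensors))
            tt = np.arange(interval) / rate
            data[ch, sl] += 400.0 * np.sin(2 * np.pi * 2.0 * tt)  # electrode drift
            bad_channel_trials[t] = ch
        if rng.uniform() < cfg.blink_prob:
            start = ev - half + int(rng.integers(interval - 200))
            data[frontal, start : start + 150] += 300.0  # step-like blink
            blink_trials.append(t)

    raw = RawEEG(
        data=data, rate=rate, events=events,
        labels=(lf.sensors.labels if lf.sensors is not None else None),
        reference="Cz",
    )
    truth = GroundTruth(
        source_patches=[s.patch for s in cfg.sources],
        source_kinds=[s.kind for s in cfg.sources],
        source_bands=[tuple(s.band) for s in cfg.sources],
        expected_rel_power=[
            ((1.0 - s.depth) ** 2 - 1.0) * 100.0 if s.kind == "ERD" else np.nan
            for s in cfg.sources
        ],
        event_samples=event_samples.tolist(),
        bad_channel_trials=bad_channel_trials,
        blink_trials=blink_trials,
        bold_active=[s.patch for s in cfg.sources],
    )
    return raw, truth


# ---------------------------------------------------------------------------
# BOLD volume synthesis
# ---------------------------------------------------------------------------

def simulate_stat_volume(
    patches: CorticalPatchModel,
    active: list[int],
    shape: tuple[int, int, int] = (46, 46, 46),
    voxel_mm: float = 4.0,
    peak_z: float = 6.0,
    sigma_mm: float = 3.0,
    noise_sd: float = 1.0,
    mask_radius: float = 80.0,
    seed: int = 0,
) -> StatVolume:
    """Gaussian activation blobs on active patch centers plus voxel noise.

    The affine centers the grid on the head origin; voxels outside a
    spherical brain mask are NaN.
    """
    if not len(active):
        raise ParameterError("active set must be nonempty")
    rng = np.random.default_rng(seed)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    ijk = np.indices(shape).reshape(3, -1).T
    mm = ijk * voxel_mm + affine[:3, 3]
    z = np.zeros(len(mm))
    for pid in active:
        d2 = np.sum((mm - patches.centers[pid]) ** 2, axis=1)
        z = np.maximum(z, peak_z * np.exp(-d2 / (2.0 * sigma_mm**2)))
    if noise_sd > 0:
        z = z + noise_sd * rng.standard_normal(len(mm))
    outside = np.linalg.norm(mm, axis=1) > mask_radius
    z[outside] = np.nan
    return StatVolume(data=z.reshape(shape), affine=affine, resolution=f"{voxel_mm:g}mm")


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

def make_fixture_suite(out_dir, seed: int = 7) -> dict[str, str]:
    """Write the deterministic desk-scale fixtures used by tests and the CLI.

    Produces a 32-sensor array, a 40-patch model, its spherical lead field,
    a session with one broadband beta-ERD source inside a planted M1 ROI,
    the matching Z volume, and the ROI file.  All synthetic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sensors = geodesic_sensors(32)
    patches = synthetic_patch_model(20, seed=seed, radius_range=(35.0, 60.0))
    lf = build_spherical_lead_field(sensors, patches,
                                    conductivities=ConductivityProfile())
    # target: superior left-hemisphere patch, a hand-knob stand-in
    lh = patches.hemisphere_indices("L")
    target = int(lh[np.argmax(patches.centers[lh, 2])])
    rois = rois_around(patches, target, n_m1=6, n_s1=7)
    cfg = SimulationConfig(
        seed=seed, n_trials=40,
        sources=[SourceSpec(patch=target, kind="ERD", band=(14.0, 30.0),
                            carrier="broadband", onset_ms=-500.0, depth=0.5)],
    )
    raw, truth = simulate_session(cfg, lf, patches)
    vol = simulate_stat_volume(patches, truth.bold_active, noise_sd=0.5,
                               seed=seed + 1)

    paths = {
        "sensors": str(out / "sensors.txt"),
        "patches": str(out / "patches.txt"),
        "leadfield": str(out / "leadfield.h5"),
        "raw": str(out / "raw.dat"),
        "events": str(out / "events.txt"),
        "truth": str(out / "ground_truth.json"),
        "rois": str(out / "rois.txt"),
        "zvol": str(out / "zstat.nii"),
    }
    sensors.to_file(paths["sensors"])
    patches.to_file(paths["patches"])
    save_lead_field(lf, paths["leadfield"])
    write_raw(raw, paths["raw"])
    with open(paths["events"], "w") as fh:
        for s, lab in raw.events:
            fh.write(f"{s} {lab}\n")
    truth.to_json(paths["truth"])
    rois.to_file(paths["rois"])
    import nibabel as nib

    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine),
             paths["zvol"])
    return paths
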