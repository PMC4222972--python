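"""Localization performance metrics for EEG source maps and BOLD activations.

Five measures, computed per session and summarized as mean ± SEM:

* anatomical distance — Euclidean distance from a representative central-
  sulcus dipole to the peak and center-of-gravity (COG) of the activity,
  plus the activity-weighted mean distance Σ wᵢ ‖r_test − rᵢ‖ over the
  suprathreshold set;
* EEG-to-BOLD distance — peak-to-peak and COG-to-COG;
* ROI-AR — fraction of active dipoles within the combined M1+S1 ROI;
* ROI-SHR — mean ROI activity over mean same-hemisphere activity;
* ROI-BHR — mean ROI activity over mean both-hemisphere activity.

ERD maps enter all metrics through |relative power|: a desynchronization is
treated as positive-valued localizable activity, the sign being kept only
for ERD/ERS labeling upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ProcessingError
from .forward import CorticalPatchModel

__all__ = [
    "ROISet",
    "LocalizationReport",
    "threshold_activity",
    "peak_position",
    "center_of_gravity",
    "weighted_distance",
    "eeg_bold_distance",
    "roi_activity_ratio",
    "roi_hemisphere_ratios",
    "group_summary",
    "build_report",
]


@dataclass
class ROISet:
    """M1/S1 patch-id sets per hemisphere plus a representative dipole.

    The representative dipole stands on the central sulcus inside the
    combined M1+S1 region and anchors the anatomical distance measure.
    """

    m1: dict[str, set[int]]
    s1: dict[str, set[int]]
    representative: dict[str, int]

    def __post_init__(self) -> None:
        for hemi in self.m1:
            if self.m1[hemi] & self.s1.get(hemi, set()):
                raise ParameterError(f"M1 and S1 overlap in hemisphere {hemi}")
        for hemi, rep in self.representative.items():
            if rep not in self.combined(hemi):
                raise ParameterError(
                    f"representative {rep} not inside M1 ∪ S1 ({hemi})"
                )

    def combined(self, hemi: str) -> set[int]:
        return self.m1.get(hemi, set()) | self.s1.get(hemi, set())

    @classmethod
    def from_file(cls, path) -> "ROISet":
        """Delimited (roi_name, hemisphere, patch_id); roi_name ∈ {M1, S1,
        representative}."""
        m1: dict[str, set[int]] = {}
        s1: dict[str, set[int]] = {}
        rep: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                name, hemi, pid = parts[0], parts[1], int(parts[2])
                if name.upper() == "M1":
                    m1.setdefault(hemi, set()).add(pid)
                elif name.upper() == "S1":
                    s1.setdefault(hemi, set()).add(pid)
                elif name.lower() == "representative":
                    rep[hemi] = pid
                else:
                    raise ParameterError(f"unknown ROI row {name!r}")
        return cls(m1=m1, s1=s1, representative=rep)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for hemi, ids in self.m1.items():
                for pid in sorted(ids):
                    fh.write(f"M1 {hemi} {pid}\n")
            for hemi, ids in self.s1.items():
                for pid in sorted(ids):
                    fh.write(f"S1 {hemi} {pid}\n")
            for hemi, pid in self.representative.items():
                fh.write(f"representative {hemi} {pid}\n")


@dataclass
class LocalizationReport:
    """Per-session positions, distances (mm) and ROI ratio metrics."""

    peak_mm: np.ndarray | None = None
    cog_mm: np.ndarray | None = None
    anatomical_peak_mm: float | None = None
    anatomical_cog_mm: float | None = None
    weighted_mm: float | None = None
    eeg_bold_peak_mm: float | None = None
    eeg_bold_cog_mm: float | None = None
    roi_ar: float | None = None
    roi_shr: float | None = None
    roi_bhr: float | None = None
    session: str = ""
    missing: list[str] = field(default_factory=list)

    MEASURES = (
        "anatomical_peak_mm", "anatomical_cog_mm", "weighted_mm",
        "eeg_bold_peak_mm", "eeg_bold_cog_mm", "roi_ar", "roi_shr", "roi_bhr",
    )

    def to_dict(self) -> dict:
        d = {"session": self.session, "missing": self.missing}
        for k in self.MEASURES:
            d[k] = getattr(self, k)
        for k in ("peak_mm", "cog_mm"):
            v = getattr(self, k)
            d[k] = None if v is None else [float(x) for x in v]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        pd.DataFrame([self.to_dict()]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# thresholding and positions
# ---------------------------------------------------------------------------

def threshold_activity(values: np.ndarray, percent_of_max: float = 0.97) -> np.ndarray:
    """Active set {i : aᵢ ≥ p·max a} on the activity magnitudes.

    Callers pass |relative power| for ERD maps; BOLD patch values are
    already non-negative.
    """
    a = np.abs(np.asarray(values, dtype=float))
    amax = a.max() if a.size else 0.0
    if amax <= 0:
        raise ProcessingError("activity map is all zero; no active set exists")
    return np.flatnonzero(a >= percent_of_max * amax)


def peak_position(values: np.ndarray, patches: CorticalPatchModel) -> np.ndarray:
    """Center of the maximal-|activity| patch; ties resolve to the lowest id."""
    a = np.abs(np.asarray(values, dtype=float))
    return patches.centers[int(np.argmax(a))]


def center_of_gravity(
    values: np.ndarray,
    patches: CorticalPatchModel,
    active: np.ndarray,
) -> np.ndarray:
    """Activity-weighted mean position over the suprathreshold set."""
    a = np.abs(np.asarray(values, dtype=float))[active]
    total = a.sum()
    if total <= 0:
        raise ProcessingError("zero total activity in the active set")
    return (a[:, None] * patches.centers[active]).sum(axis=0) / total


def weighted_distance(
    values: np.ndarray,
    patches: CorticalPatchModel,
    r_test: np.ndarray,
    active: np.ndarray,
) -> float:
    """Activity-weighted mean Euclidean distance from the representative dipole."""
    a = np.abs(np.asarray(values, dtype=float))[active]
    total = a.sum()
    if total <= 0:
        raise ProcessingError("zero total activity in the active set")
    d = np.linalg.norm(patches.centers[active] - np.asarray(r_test), axis=1)
    return float((a * d).sum() / total)


def eeg_bold_distance(
    eeg: LocalizationReport,
    bold: LocalizationReport,
) -> tuple[float | None, float | None]:
    """Peak-to-peak and COG-to-COG distances; None marks a missing position."""
    def dist(p, q):
        if p is None or q is None:
            return None
        return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))

    return dist(eeg.peak_mm, bold.peak_mm), dist(eeg.cog_mm, bold.cog_mm)


# ---------------------------------------------------------------------------
# ROI ratios
# ---------------------------------------------------------------------------

def roi_activity_ratio(active: np.ndarray, rois: ROISet, hemisphere: str) -> float:
    """|active ∩ (M1 ∪ S1)| / |M1 ∪ S1| in the given (contralateral) hemisphere."""
    roi = rois.combined(hemisphere)
    if not roi:
        raise ParameterError(f"empty ROI set in hemisphere {hemisphere}")
    return len(roi & set(int(i) for i in active)) / len(roi)


def roi_hemisphere_ratios(
    values: np.ndarray,
    rois: ROISet,
    hemisphere: str,
    patches: CorticalPatchModel,
) -> tuple[float, float]:
    """(ROI-SHR, ROI-BHR): mean |activity| in M1∪S1 over hemisphere / both means.

    Computed on the unthresholded map, so the ratios measure how
    concentrated the raw activity is rather than how the threshold carved it.
    """
    a = np.abs(np.asarray(values, dtype=float))
    roi = sorted(rois.combined(hemisphere))
    if not roi:
        raise ParameterError(f"empty ROI set in hemisphere {hemisphere}")
    hemi_idx = patches.hemisphere_indices(hemisphere)
    if hemi_idx.size == 0:
        raise ParameterError(f"no patches in hemisphere {hemisphere}")
    roi_mean = a[roi].mean()
    hemi_mean = a[hemi_idx].mean()
    both_mean = a.mean()
    if hemi_mean == 0 or both_mean == 0:
        raise ProcessingError("zero mean activity in the denominator")
    return float(roi_mean / hemi_mean), float(roi_mean / both_mean)


def group_summary(
    reports: list[LocalizationReport],
    drop: list[str] | None = None,
) -> pd.DataFrame:
    """Across-session mean and SEM (sd/√n, ddof=1) per measure.

    ``drop`` removes named sessions (e.g. a documented outlier) before
    summarizing; the drop list is recorded in the output attributes.
    Sessions missing a measure are excluded from that measure's mean.
    """
    drop = drop or []
    use = [r for r in reports if r.session not in drop]
    if len(use) < 2:
        raise ParameterError("group summary needs at least 2 sessions after drops")
    rows = {}
    for m in LocalizationReport.MEASURES:
        vals = np.array([getattr(r, m) for r in use
                         if getattr(r, m) is not None], dtype=float)
        if vals.size == 0:
            rows[m] = {"mean": np.nan, "sem": np.nan, "n": 0}
            continue
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows[m] = {"mean": float(vals.mean()), "sem": sem, "n": len(vals)}
    df = pd.DataFrame(rows).T
    df.attrs["dropped_sessions"] = list(drop)
    return df


# ---------------------------------------------------------------------------
# per-session report assembly
# ---------------------------------------------------------------------------

def build_report(
    activity: np.ndarray,
    patches: CorticalPatchModel,
    rois: ROISet,
    hemisphere: str,
    percent_of_max: float = 0.97,
    bold: LocalizationReport | None = None,
    session: str = "",
) -> LocalizationReport:
    """Positions, distances and ROI ratios for one session's activity map.

    ``activity`` is one scalar per patch (|band relative power| for EEG, or
    a BOLD :class:`~bandloc.bold.PatchActivation` value vector).  When a
    BOLD report is supplied the EEG-to-BOLD distances are filled in; missing
    BOLD positions are flagged rather than fatal.
    """
    rep = LocalizationReport(session=session)
    a = np.abs(np.asarray(activity, dtype=float))
    r_test = patches.centers[rois.representative[hemisphere]]
    try:
        active = threshold_activity(a, percent_of_max)
    except ProcessingError:
        rep.missing.append("activity")
        return rep
    rep.peak_mm = peak_position(a, patches)
    rep.cog_mm = center_of_gravity(a, patches, active)
    rep.anatomical_peak_mm = float(np.linalg.norm(rep.peak_mm - r_test))
    rep.anatomical_cog_mm = float(np.linalg.norm(rep.cog_mm - r_test))
    rep.weighted_mm = weighted_distance(a, patches, r_test, active)
    rep.roi_ar = roi_activity_ratio(active, rois, hemisphere)
    rep.roi_shr, rep.roi_bhr = roi_hemisphere_ratios(a, rois, hemisphere, patches)
    if bold is not None:
        p2p, c2c = eeg_bold_distance(rep, bold)
        rep.eeg_bold_peak_mm = p2p
        rep.eeg_bold_cog_mm = c2c
        if p2p is None or c2c is None:
            rep.missing.append("bold-position")
    return rep
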