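"""Anomaly detection on diameter profiles and end-to-end vessel assessment.

Candidate anomalies are the diameter extrema of each centerline segment:
the global interior minimum (possible stenosis), the global interior
maximum (possible dilation), and any further local extrema exceeding a
prominence floor. A candidate is confirmed when the relative diameter
change against its surrounding reference — the median diameter in two
flanking windows that clear the lesion itself — reaches the confirmation
threshold (default 0.25, the boundary of clinically relevant stenosis).

For a confirmed finding the anomaly diameter is re-estimated directly from
the distance transform in a small neighborhood of the extremum, so the
reported percentage is not diluted by profile smoothing:

    stenosis percent = 1 - d_anom / d_ref
    dilation percent = d_anom / d_ref - 1

Complete occlusions are structurally invisible to this pipeline: an
occluded stretch has no lumen pixels, hence no skeleton, and simply splits
the vessel into separate components. Reports therefore carry
``occlusion_flag = "indeterminate"`` and never emit percent = 1.0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.signal import find_peaks

from . import __version__ as _pkg_version
from .config import RunConfig
from .diameters import DiameterProfile, distance_map, profiles_from_graph
from .errors import DegenerateMask, StenokitError
from .grading import grade_from_percent
from .skeleton import build_skeleton_graph, prune_short_branches, skeletonize

_REQUERY_HALF = 1  # px along the path re-queried around a confirmed extremum


@dataclass
class AnomalyFinding:
    """One detected narrowing or dilation on a centerline segment."""

    segment_id: str
    index: int
    location: tuple[int, int]
    kind: str  # "stenosis" | "dilation"
    d_anom: float
    d_ref: float
    percent: float
    change: float
    confirmed: bool

    def to_dict(self) -> dict[str, Any]:
        return {
            "segment_id": self.segment_id,
            "index": self.index,
            "location": [int(self.location[0]), int(self.location[1])],
            "kind": self.kind,
            "d_anom": round(self.d_anom, 3),
            "d_ref": round(self.d_ref, 3),
            "percent": round(self.percent, 4),
            "change": round(self.change, 4),
            "confirmed": self.confirmed,
        }


def find_extrema(profile: DiameterProfile, prominence: float = 0.5) -> list[tuple[int, str]]:
    """Candidate anomaly indices on the valid interior of a profile.

    Returns (index, kind) pairs: the interior global minimum as a stenosis
    candidate, the interior global maximum as a dilation candidate, plus
    local extrema with at least ``prominence`` px of diameter prominence.
    Profiles whose valid interior is shorter than 3 samples yield an empty
    list with a warning.
    """
    interior = profile.interior_indices()
    if len(interior) < 3:
        warnings.warn(f"profile {profile.segment_id} too short for anomaly search", stacklevel=2)
        return []
    d = profile.diam
    lo, hi = interior[0], interior[-1]
    sub = d[lo : hi + 1]
    cands: dict[int, str] = {}
    cands[int(lo + np.argmin(sub))] = "stenosis"
    imax = int(lo + np.argmax(sub))
    cands.setdefault(imax, "dilation")
    mins, _ = find_peaks(-sub, prominence=prominence)
    maxs, _ = find_peaks(sub, prominence=prominence)
    for i in mins:
        cands.setdefault(int(lo + i), "stenosis")
    for i in maxs:
        cands.setdefault(int(lo + i), "dilation")
    return sorted(cands.items())


def _reference_diameter(profile: DiameterProfile, index: int, window: int) -> float:
    """Median raw diameter of the two flanking windows around ``index``.

    The gap between the extremum and each flank is sized from the lesion's
    own extent (distance until the profile recovers to 90 % of a provisional
    far-flank reference), bounded by ``window``; this keeps the lesion out
    of its own reference. Falls back to a single flank at a segment end.
    """
    if window < 3:
        raise StenokitError("window must be >= 3")
    d = profile.diam_raw
    n = len(d)

    def flank_values(gap: int) -> np.ndarray:
        left = d[max(0, index - gap - window) : max(0, index - gap)]
        right = d[min(n, index + gap + 1) : min(n, index + gap + window + 1)]
        return np.concatenate([left, right])

    provisional = flank_values(window)
    if provisional.size == 0:
        # segment shorter than the flank layout: fall back to the whole
        # profile minus the extremum's immediate neighborhood
        keep = np.ones(n, dtype=bool)
        keep[max(0, index - 3) : index + 4] = False
        provisional = d[keep]
    if provisional.size == 0:
        raise StenokitError("segment too short for a reference window")
    d_ref0 = float(np.median(provisional))
    if d_ref0 <= 0:
        raise DegenerateMask("zero reference diameter")
    # lesion extent: walk outward until within 10% of the provisional reference
    gap = 0
    for off in range(1, window + 1):
        ok = True
        for j in (index - off, index + off):
            if 0 <= j < n and abs(d[j] - d_ref0) > 0.1 * d_ref0:
                ok = False
        if ok:
            break
        gap = off
    flanks = flank_values(gap)
    if flanks.size == 0 or flanks.size < provisional.size // 2:
        flanks = provisional
    d_ref = float(np.median(flanks))
    if d_ref <= 0:
        raise DegenerateMask("zero reference diameter")
    return d_ref


def percentile_change(profile: DiameterProfile, index: int, window: int = 15) -> float:
    """Relative diameter change |d_ref - d(index)| / d_ref at one position.

    Uses the raw (unsmoothed) diameter at ``index``: smoothing is for robust
    extremum localization, but it dilutes the depth of a sharp lesion.
    """
    d_ref = _reference_diameter(profile, index, window)
    return abs(d_ref - float(profile.diam_raw[index])) / d_ref


def confirm_anomalies(
    candidates: Sequence[tuple[int, str]],
    profile: DiameterProfile,
    dmap: np.ndarray,
    change_threshold: float = 0.25,
    window: int = 15,
) -> list[AnomalyFinding]:
    """Confirm candidates by the relative-change threshold and quantify them.

    A candidate is confirmed iff its relative diameter change (profile value
    vs flanking reference) reaches ``change_threshold`` *in the direction of
    its kind*. Confirmed or not, the finding's percent is computed from the
    raw distance transform in the immediate path neighborhood of the
    extremum.
    """
    if not 0.0 < change_threshold < 1.0:
        raise StenokitError("change_threshold must be in (0, 1)")
    findings: list[AnomalyFinding] = []
    for index, kind in candidates:
        d_ref = _reference_diameter(profile, index, window)
        d_here = float(profile.diam_raw[index])
        signed = (d_ref - d_here) / d_ref if kind == "stenosis" else (d_here - d_ref) / d_ref
        change = max(signed, 0.0)
        confirmed = change >= change_threshold
        # re-query the EDT ridge in the 3x3 neighborhood of the extremum:
        # the skeleton pixel can sit off the medial ridge, where the EDT
        # reads low, and profile smoothing dilutes narrow lesions
        r0, c0 = int(profile.positions[index, 0]), int(profile.positions[index, 1])
        h, w = dmap.shape
        win = dmap[max(0, r0 - _REQUERY_HALF) : min(h, r0 + _REQUERY_HALF + 1),
                   max(0, c0 - _REQUERY_HALF) : min(w, c0 + _REQUERY_HALF + 1)]
        d_anom = float(2.0 * win.max() - 1.0)
        if kind == "stenosis":
            percent = max(0.0, 1.0 - d_anom / d_ref)
        else:
            percent = max(0.0, d_anom / d_ref - 1.0)
        findings.append(
            AnomalyFinding(
                segment_id=profile.segment_id,
                index=int(index),
                location=(int(profile.positions[index, 0]), int(profile.positions[index, 1])),
                kind=kind,
                d_anom=d_anom,
                d_ref=d_ref,
                percent=percent,
                change=change,
                confirmed=bool(confirmed),
            )
        )
    return findings


@dataclass
class SegmentAssessment:
    segment_id: str
    length: float
    findings: list[AnomalyFinding]
    max_stenosis_percent: float | None
    grade: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "segment_id": self.segment_id,
            "length": round(self.length, 2),
            "findings": [f.to_dict() for f in self.findings],
            "max_stenosis_percent": None
            if self.max_stenosis_percent is None
            else round(self.max_stenosis_percent, 4),
            "grade": self.grade,
        }


@dataclass
class StenosisReport:
    """End-to-end assessment of one vessel mask.

    occlusion_flag is always ``"indeterminate"``: a fully occluded stretch
    has no skeleton and cannot be graded; gaps only surface as extra
    connected components (``n_components``).
    """

    segments: list[SegmentAssessment]
    n_components: int
    occlusion_flag: str
    notes: list[str]
    config_echo: dict[str, Any]
    version: str

    @property
    def max_stenosis_percent(self) -> float:
        vals = [s.max_stenosis_percent for s in self.segments if s.max_stenosis_percent is not None]
        return max(vals) if vals else 0.0

    @property
    def grade(self) -> int:
        return grade_from_percent(self.max_stenosis_percent)

    @property
    def confirmed_findings(self) -> list[AnomalyFinding]:
        return [f for s in self.segments for f in s.findings if f.confirmed]

    def to_dict(self) -> dict[str, Any]:
        return {
            "segments": [s.to_dict() for s in self.segments],
            "n_components": self.n_components,
            "max_stenosis_percent": round(self.max_stenosis_percent, 4),
            "grade": self.grade,
            "occlusion_flag": self.occlusion_flag,
            "notes": self.notes,
            "config_echo": self.config_echo,
            "version": self.version,
        }


def assess_vessel(mask: np.ndarray, config: RunConfig | None = None) -> StenosisReport:
    """Full morphometric assessment: skeleton -> prune -> profiles -> anomalies.

    Raises with a stage label if any stage fails on the given mask.
    """
    cfg = (config or RunConfig()).validate()
    mask = np.asarray(mask, dtype=bool)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StenokitError as e:
            raise type(e)(f"[{name}] {e}") from e

    skel = stage("skeletonize", skeletonize, mask)
    graph = stage("graph", build_skeleton_graph, skel)
    pruned = stage("prune", prune_short_branches, graph, cfg.min_branch_length)
    dmap = stage("distance_map", distance_map, mask)
    profiles = stage("profiles", profiles_from_graph, pruned, dmap, cfg.smooth_window)

    notes = [
        "occlusions are not detectable: a fully occluded stretch has no "
        "skeleton representation and is never reported as percent=1.0"
    ]
    n_comp = pruned.n_components
    if n_comp > 1:
        notes.append(
            f"mask splits into {n_comp} components; any gap between them "
            "(possible occlusion) is unanalyzed"
        )

    segments: list[SegmentAssessment] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for prof in profiles:
            cands = find_extrema(prof, prominence=cfg.prominence)
            findings = confirm_anomalies(
                cands, prof, dmap, change_threshold=cfg.change_threshold, window=cfg.window
            ) if cands else []
            sten = [f.percent for f in findings if f.confirmed and f.kind == "stenosis"]
            max_sten = max(sten) if sten else None
            segments.append(
                SegmentAssessment(
                    segment_id=prof.segment_id,
                    length=float(prof.arclength[-1]) if len(prof) else 0.0,
                    findings=findings,
                    max_stenosis_percent=max_sten,
                    grade=grade_from_percent(max_sten or 0.0),
                )
            )

    return StenosisReport(
        segments=segments,
        n_components=n_comp,
        occlusion_flag="indeterminate",
        notes=notes,
        config_echo=cfg.to_dict(),
        version=_pkg_version,
    )
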