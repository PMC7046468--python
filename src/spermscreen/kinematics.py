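"""CASA kinematic parameters and WHO motility classification.

For a tracked head path p_1..p_N sampled at interval dt over duration
T = (N-1)dt:

* VCL (curvilinear velocity)   = sum_i ||p_{i+1} - p_i|| / T
* VSL (straight-line velocity) = ||p_N - p_1|| / T
* VAP (average-path velocity)  = length of the moving-average smoothed
  path / T
* STR (straightness)           = 100 * VSL / VAP
* LIN (linearity)              = 100 * VSL / VCL

Tracks are assigned to the standard WHO classes with strict inequalities:
progressively motile (PM) when VAP > 25 µm/s AND STR > 80 %;
otherwise non-progressively motile (NPM) when VAP > 5 µm/s OR
VSL > 11 µm/s; otherwise immotile (IM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import Track

__all__ = [
    "PM",
    "NPM",
    "IM",
    "ClassThresholds",
    "KinematicSummary",
    "TrackExclusion",
    "WellMotilityResult",
    "smooth_path",
    "compute_kinematics",
    "classify_track",
    "summarize_well",
    "analyze_tracks",
]

PM = "PM"
NPM = "NPM"
IM = "IM"

#: default minimum number of points for a track to enter kinematic analysis
MIN_TRACK_POINTS = 12
#: default moving-average window (frames) for the VAP smoothed path
VAP_WINDOW = 5


@dataclass
class ClassThresholds:
    """WHO motility class cut-offs (µm/s and %), applied strictly (>)."""

    pm_vap_min: float = 25.0
    pm_str_min: float = 80.0
    npm_vap_min: float = 5.0
    npm_vsl_min: float = 11.0

    def __post_init__(self) -> None:
        if self.pm_vap_min <= self.npm_vap_min:
            raise ValueError("pm_vap_min must exceed npm_vap_min")


@dataclass
class KinematicSummary:
    track_id: int
    vcl: float
    vsl: float
    vap: float
    str_pct: float
    lin_pct: float
    n_points: int
    duration: float


@dataclass
class TrackExclusion:
    """A track kept out of kinematic analysis, with the reason why."""

    track_id: int
    reason: str


@dataclass
class WellMotilityResult:
    well: str
    n_tracks: int
    median_vcl: float            # nan when no tracks
    pm_pct: float
    npm_pct: float
    im_pct: float
    qc_flags: set = field(default_factory=set)


def smooth_path(xy: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average of a point sequence.

    Near the ends the window shrinks symmetrically (half-width
    ``min(w//2, i, n-1-i)``) so the output has the same length as the input
    and the end points are preserved.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least 2 points")
    if window == 1:
        return xy.copy()
    half = window // 2
    out = np.empty_like(xy)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = xy[i - h : i + h + 1].mean(axis=0)
    return out


def _path_length(xy: np.ndarray) -> float:
    return float(np.sqrt(((np.diff(xy, axis=0)) ** 2).sum(axis=1)).sum())


def compute_kinematics(
    track: Track,
    window: int = VAP_WINDOW,
    min_points: int = MIN_TRACK_POINTS,
) -> KinematicSummary | TrackExclusion:
    """Compute VCL/VSL/VAP/STR/LIN for one track.

    Tracks shorter than ``min_points`` are not an error: they are returned
    as a :class:`TrackExclusion` carrying the reason, so callers can count
    them without analysing them.  STR and LIN are defined as 0 when their
    denominator is 0.
    """
    if track.n_points < min_points:
        return TrackExclusion(track.track_id, f"short_track(<{min_points} points)")
    duration = track.duration
    vcl = _path_length(track.xy_um) / duration
    vsl = float(np.linalg.norm(track.xy_um[-1] - track.xy_um[0])) / duration
    vap = _path_length(smooth_path(track.xy_um, window)) / duration
    str_pct = 100.0 * vsl / vap if vap > 0 else 0.0
    lin_pct = 100.0 * vsl / vcl if vcl > 0 else 0.0
    return KinematicSummary(
        track_id=track.track_id,
        vcl=vcl,
        vsl=vsl,
        vap=vap,
        str_pct=str_pct,
        lin_pct=lin_pct,
        n_points=track.n_points,
        duration=duration,
    )


def classify_track(
    summary: KinematicSummary, thresholds: ClassThresholds | None = None
) -> str:
    """WHO class of one track; PM is evaluated first, all cuts strict."""
    t = thresholds or ClassThresholds()
    if summary.vap > t.pm_vap_min and summary.str_pct > t.pm_str_min:
        return PM
    if summary.vap > t.npm_vap_min or summary.vsl > t.npm_vsl_min:
        return NPM
    return IM


def summarize_well(
    summaries: list[KinematicSummary],
    well: str = "",
    qc_flags: set | None = None,
    thresholds: ClassThresholds | None = None,
) -> WellMotilityResult:
    """Aggregate per-track kinematics into the per-well motility readout.

    The well readout used for screening is the median VCL over analysed
    tracks; class fractions are percentages of classified tracks.  A well
    with zero analysable tracks gets the ``low_count`` flag and an
    undefined (NaN) median.
    """
    flags = set(qc_flags or ())
    n = len(summaries)
    if n == 0:
        flags.add("low_count")
        return WellMotilityResult(well, 0, float("nan"), 0.0, 0.0, 0.0, flags)
    classes = [classify_track(s, thresholds) for s in summaries]
    median_vcl = float(np.median([s.vcl for s in summaries]))
    return WellMotilityResult(
        well=well,
        n_tracks=n,
        median_vcl=median_vcl,
        pm_pct=100.0 * classes.count(PM) / n,
        npm_pct=100.0 * classes.count(NPM) / n,
        im_pct=100.0 * classes.count(IM) / n,
        qc_flags=flags,
    )


def analyze_tracks(
    tracks: list[Track],
    window: int = VAP_WINDOW,
    min_points: int = MIN_TRACK_POINTS,
    thresholds: ClassThresholds | None = None,
) -> tuple[list[KinematicSummary], list[TrackExclusion]]:
    """Kinematics for a whole track set, separating excluded tracks."""
    summaries: list[KinematicSummary] = []
    excluded: list[TrackExclusion] = []
    for tr in tracks:
        res = compute_kinematics(tr, window=window, min_points=min_points)
        if isinstance(res, TrackExclusion):
            excluded.append(res)
        else:
            summaries.append(res)
    return summaries, excluded
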