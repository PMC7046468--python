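"""Sperm-head detection and frame-to-frame track linking.

Detection follows the classic bright-feature scheme used throughout
single-particle tracking: a difference-of-Gaussians band-pass to suppress
pixel noise and slow background variation, local-maximum candidate search
with a minimum-separation constraint, and one pass of intensity-weighted
centroid refinement for sub-pixel localisation.  Linking assigns detections
in consecutive frames to open track heads by minimising total squared
displacement subject to a hard per-frame displacement ceiling; small
conflict subnetworks are solved exactly, large ones greedily by ascending
distance.  No gap closing is attempted by default: a conservative radius
plus zero memory is the standard defence against cross-track switches in
dense, fast fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.feature import peak_local_max

__all__ = [
    "ImageStack",
    "Detection",
    "Track",
    "DetectParams",
    "LinkParams",
    "detect_heads",
    "detect_stack",
    "link_tracks",
    "merge_positions",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Time-lapse stack: ``frames`` has shape (n_frames, height, width).

    Coordinates follow the image convention: origin top-left, x rightward
    (columns), y downward (rows); physical positions are pixels times
    ``pixel_size_um``.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("ImageStack requires >=2 frames of equal shape")
        if self.pixel_size_um <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size_um and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Detection:
    """One localised head: position in µm and integrated band-passed mass."""

    frame_index: int
    x_um: float
    y_um: float
    mass: float


@dataclass
class Track:
    """Ordered head positions of one cell.

    ``frames`` are strictly increasing 0-based indices with no gaps and
    ``xy_um`` is the matching (n, 2) array of (x, y) positions in µm.
    """

    track_id: int
    frames: np.ndarray
    xy_um: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 points")
        if self.xy_um.shape != (len(self.frames), 2):
            raise ValueError("xy_um must be (n_points, 2)")
        d = np.diff(self.frames)
        if np.any(d != 1):
            raise ValueError("frame indices must increase by 1 with no gaps")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return (self.n_points - 1) * self.frame_interval


@dataclass
class DetectParams:
    feature_diameter: int = 9        # px, odd; approximate head image size
    mass_threshold: float = 500.0    # integrated band-passed intensity
    min_separation: int = 9          # px between accepted maxima

    def __post_init__(self) -> None:
        if self.feature_diameter < 3 or self.feature_diameter % 2 == 0:
            raise ValueError("feature_diameter must be odd and >= 3")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


@dataclass
class LinkParams:
    # 12 µm/frame at 48 fps is a ~576 µm/s ceiling, far above any plausible
    # human-sperm VCL, while still short enough to suppress cross-links.
    max_displacement_um: float = 12.0
    min_track_length: int = 12
    memory: int = 0

    def __post_init__(self) -> None:
        if self.max_displacement_um <= 0:
            raise ValueError("max_displacement_um must be > 0")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def bandpass(frame: np.ndarray, feature_diameter: int) -> np.ndarray:
    """Difference-of-Gaussians band-pass, clipped at zero.

    The small scale (diameter / 7) suppresses single-pixel noise; the large
    scale (the feature diameter) estimates and removes slowly varying
    background.
    """
    frame = np.asarray(frame, dtype=float)
    small = gaussian_filter(frame, feature_diameter / 7.0)
    large = gaussian_filter(frame, float(feature_diameter))
    return np.clip(small - large, 0.0, None)


def detect_heads(
    frame: np.ndarray,
    params: DetectParams,
    pixel_size_um: float = 1.0,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect bright head-like features in one frame.

    Returns detections with positions in µm, refined to the
    intensity-weighted centroid of the band-passed image within the feature
    window, and with ``mass`` the integrated band-passed intensity there.
    Candidates with mass below ``params.mass_threshold`` are discarded.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    bp = bandpass(frame, params.feature_diameter)
    if not np.any(bp > 0):
        return []
    peaks = peak_local_max(
        bp,
        min_distance=params.min_separation,
        threshold_abs=np.finfo(float).tiny,
        exclude_border=False,
    )
    radius = params.feature_diameter // 2
    h, w = bp.shape
    out: list[Detection] = []
    for row, col in peaks:
        r0, r1 = max(row - radius, 0), min(row + radius + 1, h)
        c0, c1 = max(col - radius, 0), min(col + radius + 1, w)
        window = bp[r0:r1, c0:c1]
        mass = float(window.sum())
        if mass < params.mass_threshold or mass <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        cy = float((window * rr).sum() / mass)
        cx = float((window * cc).sum() / mass)
        out.append(
            Detection(
                frame_index=frame_index,
                x_um=cx * pixel_size_um,
                y_um=cy * pixel_size_um,
                mass=mass,
            )
        )
    return out


def detect_stack(stack: ImageStack, params: DetectParams) -> list[list[Detection]]:
    """Run :func:`detect_heads` on every frame of a stack."""
    return [
        detect_heads(f, params, stack.pixel_size_um, frame_index=i)
        for i, f in enumerate(stack.frames)
    ]


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

# Subnetworks up to this many particles on either side are solved as an
# exact minimum-cost assignment; beyond that, greedily by ascending distance.
_EXACT_LIMIT = 7


class _OpenTrack:
    __slots__ = ("frames", "points", "misses")

    def __init__(self, frame: int, xy: np.ndarray) -> None:
        self.frames = [frame]
        self.points = [xy]
        self.misses = 0


def _assign_component(cost: np.ndarray, max_cost: float) -> list[tuple[int, int]]:
    """Optimal link set for one conflict subnetwork.

    ``cost`` is the squared-distance matrix (np.inf where the link exceeds
    the displacement ceiling).  The matrix is padded with 'no link' dummies
    priced at ``max_cost`` (the squared ceiling) so that leaving a particle
    unlinked competes fairly with a maximal-length link.
    """
    nt, nd = cost.shape
    n = nt + nd
    big = 4.0 * max_cost * (n + 1)
    pad = np.full((n, n), big)
    pad[:nt, :nd] = np.where(np.isfinite(cost), cost, big)
    pad[:nt, nd:] = big
    pad[np.arange(nt), nd + np.arange(nt)] = max_cost
    pad[nt:, :nd] = big
    pad[nt + np.arange(nd), np.arange(nd)] = max_cost
    pad[nt:, nd:] = 0.0
    rows, cols = linear_sum_assignment(pad)
    return [
        (r, c)
        for r, c in zip(rows, cols)
        if r < nt and c < nd and np.isfinite(cost[r, c])
    ]


def _greedy_component(cost: np.ndarray) -> list[tuple[int, int]]:
    pairs = np.argwhere(np.isfinite(cost))
    order = np.argsort(cost[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_t: set[int] = set()
    used_d: set[int] = set()
    links = []
    for r, c in pairs[order]:
        if r in used_t or c in used_d:
            continue
        links.append((int(r), int(c)))
        used_t.add(int(r))
        used_d.add(int(c))
    return links


def link_tracks(
    detections: list[list[Detection]],
    params: LinkParams,
    frame_interval: float = 1.0 / 48.0,
) -> list[Track]:
    """Link per-frame detections into tracks.

    ``detections`` is a list over frames (index = frame number) of detection
    lists, e.g. the output of :func:`detect_stack`.  Every detection is used
    by at most one track.  With ``memory`` > 0 a track may survive short
    detection drop-outs; the missing positions are filled by linear
    interpolation so tracks remain gap-free.
    """
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    max_disp = params.max_displacement_um

    for f, dets in enumerate(detections):
        pts = np.array([[d.x_um, d.y_um] for d in dets], dtype=float).reshape(-1, 2)
        nd = len(pts)
        nt = len(open_tracks)
        links: list[tuple[int, int]] = []
        if nt and nd:
            heads = np.array([t.points[-1] for t in open_tracks])
            dist2 = ((heads[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(dist2 <= max_disp**2, dist2, np.inf)
            links = _resolve_links(cost, max_disp**2)
        linked_t = {r for r, _ in links}
        linked_d = {c for _, c in links}
        for r, c in links:
            tr = open_tracks[r]
            gap = f - tr.frames[-1]
            if gap > 1:  # fill drop-out frames by interpolation
                a, b = tr.points[-1], pts[c]
                for g in range(1, gap):
                    tr.frames.append(tr.frames[-1] + 1)
                    tr.points.append(a + (b - a) * (g / gap))
            tr.frames.append(f)
            tr.points.append(pts[c].copy())
            tr.misses = 0
        still_open = []
        for i, tr in enumerate(open_tracks):
            if i in linked_t:
                still_open.append(tr)
                continue
            tr.misses += 1
            if tr.misses > params.memory:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        for c in range(nd):
            if c not in linked_d:
                open_tracks.append(_OpenTrack(f, pts[c].copy()))
    closed.extend(open_tracks)

    tracks: list[Track] = []
    for tr in closed:
        if len(tr.frames) < max(params.min_track_length, 2):
            continue
        tracks.append(
            Track(
                track_id=len(tracks),
                frames=np.array(tr.frames),
                xy_um=np.array(tr.points),
                frame_interval=frame_interval,
            )
        )
    return tracks


def _resolve_links(cost: np.ndarray, max_cost: float) -> list[tuple[int, int]]:
    """Split the candidate-link graph into connected subnetworks and solve
    each exactly (small) or greedily (large)."""
    nt, nd = cost.shape
    finite = np.argwhere(np.isfinite(cost))
    if len(finite) == 0:
        return []
    graph = coo_matrix(
        (np.ones(len(finite)), (finite[:, 0], nt + finite[:, 1])),
        shape=(nt + nd, nt + nd),
    )
    n_comp, labels = connected_components(graph, directed=False)
    links: list[tuple[int, int]] = []
    for comp in range(n_comp):
        t_idx = np.where(labels[:nt] == comp)[0]
        d_idx = np.where(labels[nt:] == comp)[0]
        if len(t_idx) == 0 or len(d_idx) == 0:
            continue
        sub = cost[np.ix_(t_idx, d_idx)]
        if len(t_idx) <= _EXACT_LIMIT and len(d_idx) <= _EXACT_LIMIT:
            sub_links = _assign_component(sub, max_cost)
        else:
            sub_links = _greedy_component(sub)
        links.extend((int(t_idx[r]), int(d_idx[c])) for r, c in sub_links)
    return links


def merge_positions(tracks_pos1: list[Track], tracks_pos2: list[Track]) -> list[Track]:
    """Combine the track sets of the two imaging positions of one well.

    The positions are imaged with a gap wide enough that no cell appears in
    both, so the merge is a concatenation with fresh unique track ids.
    """
    merged = []
    for tr in list(tracks_pos1) + list(tracks_pos2):
        merged.append(
            Track(
                track_id=len(merged),
                frames=tr.frames.copy(),
                xy_um=tr.xy_um.copy(),
                frame_interval=tr.frame_interval,
            )
        )
    return merged
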