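"""File readers and writers and the run configuration.

CSV is the canonical interchange format: track tables
(well?, track_id, frame, x_um, y_um), per-track kinematics, per-well
results, plate maps (well, role, compound_id) and flow event tables
(FL1_A, FL3_A).  Image stacks are multi-page 16-bit TIFF with the physical
calibration stored in the image description.  Flow event tables can also be
read from and written to minimal FCS 3.0 files (list mode, float data),
with a configurable channel-name mapping for instrument exports.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .doseresponse import DoseResponseData
from .flow import EventTable
from .kinematics import ClassThresholds
from .plate import PlateLayout
from .tracking import DetectParams, ImageStack, LinkParams, Track

__all__ = [
    "DEFAULT_CHANNEL_MAP",
    "RunConfig",
    "read_image_stack",
    "write_image_stack",
    "read_tracks",
    "write_tracks",
    "read_events",
    "write_events_csv",
    "write_events_fcs",
    "read_plate_map",
    "write_plate_map",
    "read_dose_response",
]

#: internal column name -> FCS channel name ($PnN) used by the instrument
DEFAULT_CHANNEL_MAP = {"FL1_A": "FL1-A", "FL3_A": "FL3-A"}


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_image_stack(stack: ImageStack, path: "str | Path") -> None:
    """Write a stack as multi-page 16-bit TIFF; calibration goes into the
    image description as JSON."""
    frames = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval,
    }
    tifffile.imwrite(
        str(path), frames, photometric="minisblack", description=json.dumps(meta)
    )


def read_image_stack(
    path: "str | Path",
    pixel_size_um: "float | None" = None,
    frame_interval: "float | None" = None,
) -> ImageStack:
    """Read a multi-page TIFF stack.

    Calibration is taken from the JSON image description written by
    :func:`write_image_stack`; explicit arguments override it, and are
    required for foreign files without one.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            frames = tif.asarray().astype(float)
            desc = tif.pages[0].description or ""
    except Exception as exc:  # noqa: BLE001 - report the offending file
        raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if px is None or dt is None:
        raise ValueError(
            f"{path}: no calibration metadata; pass pixel_size_um and frame_interval"
        )
    return ImageStack(frames=frames, pixel_size_um=float(px), frame_interval=float(dt))


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def write_tracks(
    tracks: "dict[str, list[Track]] | list[Track]", path: "str | Path"
) -> None:
    """Track table CSV: (well, track_id, frame, x_um, y_um).

    A bare track list is written with an empty well id.
    """
    if isinstance(tracks, list):
        tracks = {"": tracks}
    rows = []
    for well, tlist in tracks.items():
        for tr in tlist:
            for f, (x, y) in zip(tr.frames, tr.xy_um):
                rows.append((well, tr.track_id, int(f), x, y))
    pd.DataFrame(
        rows, columns=["well", "track_id", "frame", "x_um", "y_um"]
    ).to_csv(path, index=False)


def read_tracks(
    path: "str | Path", frame_interval: float = 1.0 / 48.0
) -> "dict[str, list[Track]]":
    """Read a track table CSV back into per-well track lists."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    missing = {"track_id", "frame", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: track CSV missing columns {sorted(missing)}")
    if "well" not in df.columns:
        df["well"] = ""
    out: dict[str, list[Track]] = {}
    for (well, tid), grp in df.groupby(["well", "track_id"], sort=True):
        grp = grp.sort_values("frame")
        out.setdefault(str(well), []).append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(int),
                xy_um=grp[["x_um", "y_um"]].to_numpy(float),
                frame_interval=frame_interval,
            )
        )
    return out


# ---------------------------------------------------------------------------
# flow events: CSV and minimal FCS 3.0
# ---------------------------------------------------------------------------

def write_events_csv(
    events: "dict[str, EventTable] | EventTable", path: "str | Path"
) -> None:
    if isinstance(events, EventTable):
        events = {events.well: events}
    frames = []
    for well, tab in events.items():
        df = tab.data.copy()
        df.insert(0, "well", well)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _read_events_csv(path: Path, channel_map: dict) -> "dict[str, EventTable]":
    df = pd.read_csv(path, keep_default_na=False)
    rename = {v: k for k, v in channel_map.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = {"FL1_A", "FL3_A"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: event CSV missing channels {sorted(missing)}; "
            f"available columns: {list(df.columns)}"
        )
    if "well" not in df.columns:
        df["well"] = ""
    return {
        str(well): EventTable(well=str(well), data=grp[["FL1_A", "FL3_A"]])
        for well, grp in df.groupby("well")
    }


def write_events_fcs(table: EventTable, path: "str | Path", channel_map: "dict | None" = None) -> None:
    """Write one well's events as a minimal FCS 3.0 file.

    List mode, 32-bit little-endian floats, one parameter per channel; the
    ($PnN) names come from ``channel_map``.
    """
    cm = dict(channel_map or DEFAULT_CHANNEL_MAP)
    cols = ["FL1_A", "FL3_A"]
    data = table.data[cols].to_numpy(np.float32)
    n_events, n_par = data.shape
    payload = data.astype("<f4").tobytes()

    rng_max = int(max(float(data.max()) if n_events else 0.0, 1.0)) + 1
    kv = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$NEXTDATA": "0",
    }
    for i, col in enumerate(cols, start=1):
        kv[f"$P{i}N"] = cm.get(col, col)
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(rng_max)

    # assemble TEXT with placeholder offsets, then patch with fixed widths
    def build_text(begin_data: int, end_data: int) -> bytes:
        items = {
            "$BEGINDATA": f"{begin_data:010d}",
            "$ENDDATA": f"{end_data:010d}",
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            **kv,
        }
        text = "/" + "".join(f"{k}/{v}/" for k, v in items.items())
        return text.encode("ascii")

    header_len = 58
    text0 = build_text(0, 0)
    text_start = header_len
    text_end = text_start + len(text0) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1 if payload else 0
    text = build_text(data_start, data_end)
    assert len(text) == len(text0)
    header = (
        b"FCS3.0    "
        + f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}{0:8d}{0:8d}".encode("ascii")
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text + payload)


def _read_events_fcs(path: Path, channel_map: dict, well: str) -> EventTable:
    raw = path.read_bytes()
    if len(raw) < 58 or not raw[:6] == b"FCS3.0":
        raise ValueError(f"{path}: not an FCS 3.0 file")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FCS header offsets") from exc
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text[1:].split(delim)
    kv = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}
    try:
        n_par = int(kv["$PAR"])
        n_tot = int(kv["$TOT"])
        data_start = int(kv["$BEGINDATA"])
        data_end = int(kv["$ENDDATA"])
        datatype = kv["$DATATYPE"].strip()
    except KeyError as exc:
        raise ValueError(f"{path}: FCS TEXT segment missing keyword {exc}") from exc
    if datatype != "F":
        raise ValueError(f"{path}: only $DATATYPE F supported, got {datatype!r}")
    byteord = kv.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    names = [kv.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    n_values = n_par * n_tot
    payload = raw[data_start : data_end + 1] if n_tot else b""
    if len(payload) < 4 * n_values:
        raise ValueError(f"{path}: DATA segment truncated")
    values = np.frombuffer(payload[: 4 * n_values], dtype=f"{endian}f4").reshape(
        n_tot, n_par
    )
    df = pd.DataFrame(values.astype(float), columns=names)
    rename = {v: k for k, v in channel_map.items()}
    df = df.rename(columns=rename)
    missing = {"FL1_A", "FL3_A"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: channels {sorted(channel_map[m] for m in missing)} not found; "
            f"available channels: {names}"
        )
    return EventTable(well=well, data=df[["FL1_A", "FL3_A"]])


def read_events(
    path: "str | Path",
    channel_map: "dict | None" = None,
    well: str = "",
) -> "dict[str, EventTable]":
    """Read flow events from CSV (possibly multi-well) or FCS 3.0 (one well)."""
    path = Path(path)
    cm = dict(channel_map or DEFAULT_CHANNEL_MAP)
    if path.suffix.lower() == ".fcs":
        table = _read_events_fcs(path, cm, well or path.stem)
        return {table.well: table}
    return _read_events_csv(path, cm)


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

def write_plate_map(layout: PlateLayout, path: "str | Path") -> None:
    layout.wells.to_csv(path, index=False)


def read_plate_map(path: "str | Path", plate_id: "str | None" = None) -> PlateLayout:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    try:
        return PlateLayout(plate_id or path.stem, df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# dose-response tables
# ---------------------------------------------------------------------------

def read_dose_response(path: "str | Path") -> pd.DataFrame:
    """Long-form dose-response CSV: (compound_id, conc_um, replicate, response)."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    missing = {"compound_id", "conc_um", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: dose-response CSV missing {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline parameters in one place, serialisable to YAML.

    The defaults are the screen's stated operating point: WHO class cuts
    25/80/5/11, the 85 % motility hit cut-off (15 % VCL reduction), the
    15 % AR induction threshold and the 200-event flow QC floor.
    """

    seed: int = 0
    detect: DetectParams = field(default_factory=DetectParams)
    link: LinkParams = field(default_factory=LinkParams)
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    vap_window: int = 5
    min_track_points: int = 12
    hit_cutoff_pct: float = 85.0
    upregulator_cutoff_pct: float = 115.0
    ar_hit_threshold_pct: float = 15.0
    min_flow_events: int = 200
    min_pi_positive_frac: float = 0.02
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))

    def to_yaml(self, path: "str | Path") -> None:
        d = {
            "seed": self.seed,
            "detect": vars(self.detect),
            "link": vars(self.link),
            "thresholds": vars(self.thresholds),
            "vap_window": self.vap_window,
            "min_track_points": self.min_track_points,
            "hit_cutoff_pct": self.hit_cutoff_pct,
            "upregulator_cutoff_pct": self.upregulator_cutoff_pct,
            "ar_hit_threshold_pct": self.ar_hit_threshold_pct,
            "min_flow_events": self.min_flow_events,
            "min_pi_positive_frac": self.min_pi_positive_frac,
            "channel_map": self.channel_map,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=d.get("seed", 0),
            detect=DetectParams(**d.get("detect", {})),
            link=LinkParams(**d.get("link", {})),
            thresholds=ClassThresholds(**d.get("thresholds", {})),
            vap_window=d.get("vap_window", 5),
            min_track_points=d.get("min_track_points", 12),
            hit_cutoff_pct=d.get("hit_cutoff_pct", 85.0),
            upregulator_cutoff_pct=d.get("upregulator_cutoff_pct", 115.0),
            ar_hit_threshold_pct=d.get("ar_hit_threshold_pct", 15.0),
            min_flow_events=d.get("min_flow_events", 200),
            min_pi_positive_frac=d.get("min_pi_positive_frac", 0.02),
            channel_map=d.get("channel_map", dict(DEFAULT_CHANNEL_MAP)),
        )
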