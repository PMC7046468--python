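"""Acrosome-reaction flow cytometry: quadrant gating, hit calling, triage.

Events carry two fluorescence channels: FL1-A (Alexa488-conjugated peanut
agglutinin, PNA, marking the exposed acrosomal matrix of reacted sperm) and
FL3-A (propidium iodide, Pi, marking membrane-compromised 'dead' cells).
Quadrant gates partition events into four populations:

    Pi+ PNA-  dead, non-reacted          (upper left)
    Pi+ PNA+  dead, acrosome-reacted     (upper right)
    Pi- PNA-  unstained / live intact    (lower left)
    Pi- PNA+  live, acrosome-reacted     (lower right)

The screening readout is the percent of events in the live-reacted
(Pi- PNA+) quadrant; compounds pushing it beyond 15 % (the maximum
induction reached by the A23187 positive control) are primary hits.
Interference triage then removes intrinsically fluorescent compounds
(plate-reader signal at 520 or 670 nm far above the plate) and compounds
whose apparent signal survives with no dyes added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde, median_abs_deviation

__all__ = [
    "POPULATIONS",
    "EventTable",
    "GateThresholds",
    "QuadrantCounts",
    "ARWellResult",
    "GatingError",
    "derive_gates",
    "gate_events",
    "ar_well_result",
    "call_ar_hits",
    "triage_ar_hits",
]

# population order: (Pi-PNA-, Pi+PNA-, Pi+PNA+, Pi-PNA+)
POPULATIONS = ("Pi-PNA-", "Pi+PNA-", "Pi+PNA+", "Pi-PNA+")

AR_HIT_THRESHOLD_PCT = 15.0
MIN_EVENTS = 200
MIN_PI_POSITIVE_FRAC = 0.02   # 'low in Pi+' exclusion floor
MIN_CONTROL_EVENTS = 1000     # pooled vehicle events required for gating


class GatingError(ValueError):
    """Raised when gates cannot be derived for a plate."""


@dataclass
class EventTable:
    """Flow events of one well: DataFrame with FL1_A and FL3_A columns."""

    well: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("FL1_A", "FL3_A"):
            if col not in df.columns:
                raise ValueError(f"event table missing column {col}")
            if len(df) and not np.isfinite(df[col].to_numpy(float)).all():
                raise ValueError(f"non-finite intensities in {col}")
        self.data = df.reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return len(self.data)


@dataclass
class GateThresholds:
    fl1_cut: float
    fl3_cut: float
    method: str = "density_valley"
    source_plate: str = ""
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.fl1_cut <= 0 or self.fl3_cut <= 0:
            raise ValueError("gate thresholds must be > 0")


@dataclass
class QuadrantCounts:
    well: str
    unstained: int       # Pi- PNA-
    dead: int            # Pi+ PNA-
    dead_reacted: int    # Pi+ PNA+
    live_reacted: int    # Pi- PNA+

    @property
    def total(self) -> int:
        return self.unstained + self.dead + self.dead_reacted + self.live_reacted


@dataclass
class ARWellResult:
    well: str
    total_events: int
    unstained_pct: float
    dead_pct: float
    dead_reacted_pct: float
    live_reacted_pct: float
    qc_flags: set = field(default_factory=set)
    hit_call: str = "none"

    @property
    def excluded(self) -> bool:
        return bool(self.qc_flags)


# ---------------------------------------------------------------------------
# gate derivation
# ---------------------------------------------------------------------------

def _channel_threshold(values: np.ndarray) -> tuple[float, bool]:
    """Threshold for one channel on log10 intensity.

    Kernel-density estimate (Silverman bandwidth) on log10 values; the
    threshold is the deepest valley between the two most prominent modes.
    When the density is unimodal the 99.5th percentile of the (single) mode
    is used instead; the second return value reports that fallback.
    """
    logv = np.log10(np.clip(values, 1e-12, None))
    kde = gaussian_kde(logv, bw_method="silverman")
    grid = np.linspace(logv.min() - 0.25, logv.max() + 0.25, 512)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=0.02 * dens.max())
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(dens[peaks])[-2:]]
        lo, hi = sorted(top2)
        valley = lo + int(np.argmin(dens[lo : hi + 1]))
        return float(grid[valley]), False
    return float(np.percentile(logv, 99.5)), True


def derive_gates(
    control_event_tables: "list[EventTable]",
    method: str = "density_valley",
    source_plate: str = "",
) -> GateThresholds:
    """Per-plate quadrant gates from the pooled vehicle (DMSO) wells.

    Thresholds are derived independently per channel on the log10 scale and
    returned on the linear fluorescence scale.
    """
    if method not in ("density_valley", "percentile"):
        raise ValueError(f"unknown gating method: {method}")
    pooled = pd.concat([t.data for t in control_event_tables], ignore_index=True)
    if len(pooled) < MIN_CONTROL_EVENTS:
        raise GatingError(
            f"only {len(pooled)} pooled control events; "
            f"need >= {MIN_CONTROL_EVENTS}"
        )
    flags: set = set()
    cuts = {}
    for name, col in (("fl1", "FL1_A"), ("fl3", "FL3_A")):
        vals = pooled[col].to_numpy(float)
        if method == "percentile":
            log_cut, fell_back = np.percentile(
                np.log10(np.clip(vals, 1e-12, None)), 99.5
            ), False
        else:
            log_cut, fell_back = _channel_threshold(vals)
        if fell_back:
            flags.add(f"{name}_percentile_fallback")
        cuts[name] = 10.0 ** log_cut
    return GateThresholds(
        fl1_cut=cuts["fl1"],
        fl3_cut=cuts["fl3"],
        method=method,
        source_plate=source_plate,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# gating and per-well results
# ---------------------------------------------------------------------------

def gate_events(table: EventTable, thresholds: GateThresholds) -> QuadrantCounts:
    """Partition events into the four Pi/PNA quadrants.

    Membership is strict: an event is Pi+ iff FL3_A > fl3_cut and PNA+ iff
    FL1_A > fl1_cut; events exactly on a boundary count as negative.
    """
    fl1 = table.data["FL1_A"].to_numpy(float)
    fl3 = table.data["FL3_A"].to_numpy(float)
    pna = fl1 > thresholds.fl1_cut
    pi = fl3 > thresholds.fl3_cut
    return QuadrantCounts(
        well=table.well,
        unstained=int(np.sum(~pi & ~pna)),
        dead=int(np.sum(pi & ~pna)),
        dead_reacted=int(np.sum(pi & pna)),
        live_reacted=int(np.sum(~pi & pna)),
    )


def ar_well_result(
    counts: QuadrantCounts,
    min_events: int = MIN_EVENTS,
    min_pi_positive_frac: float = MIN_PI_POSITIVE_FRAC,
) -> ARWellResult:
    """Percent events per quadrant with the well-level QC rules.

    Wells below ``min_events`` total events, or with an implausibly small
    Pi-positive (dead + dead-reacted) fraction — a staining irregularity —
    are flagged and kept out of hit calling.
    """
    total = counts.total
    flags: set = set()
    if total < min_events:
        flags.add("low_events")
    if total == 0:
        return ARWellResult(counts.well, 0, 0.0, 0.0, 0.0, 0.0, flags)
    pi_pos_frac = (counts.dead + counts.dead_reacted) / total
    if pi_pos_frac < min_pi_positive_frac:
        flags.add("low_pi_positive")
    return ARWellResult(
        well=counts.well,
        total_events=total,
        unstained_pct=100.0 * counts.unstained / total,
        dead_pct=100.0 * counts.dead / total,
        dead_reacted_pct=100.0 * counts.dead_reacted / total,
        live_reacted_pct=100.0 * counts.live_reacted / total,
        qc_flags=flags,
    )


def call_ar_hits(
    results: "list[ARWellResult]",
    roles: "dict[str, str]",
    induction_threshold_pct: float = AR_HIT_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Call acrosome-reaction hits on a plate of per-well AR results.

    A compound well is a hit when its live-reacted (Pi- PNA+) percentage
    strictly exceeds the threshold (default 15 %, the maximum induction of
    the positive control).  QC-flagged wells and control wells are never
    called.
    """
    rows = []
    for res in results:
        role = roles.get(res.well, "compound")
        is_hit = (
            role == "compound"
            and not res.excluded
            and res.live_reacted_pct > induction_threshold_pct
        )
        res.hit_call = "ar_hit" if is_hit else "none"
        rows.append(
            {
                "well": res.well,
                "role": role,
                "total_events": res.total_events,
                "unstained_pct": res.unstained_pct,
                "dead_pct": res.dead_pct,
                "dead_reacted_pct": res.dead_reacted_pct,
                "live_reacted_pct": res.live_reacted_pct,
                "flags": ";".join(sorted(res.qc_flags)),
                "call": res.hit_call,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interference triage
# ---------------------------------------------------------------------------

def triage_ar_hits(
    hits: pd.DataFrame,
    triage_records: pd.DataFrame,
    induction_threshold_pct: float = AR_HIT_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Flag interference false-positives among primary AR hits.

    ``triage_records`` has one row per well with columns (well, signal_520,
    signal_670, nodye_live_reacted_pct).  A hit is flagged

    * ``autofluorescent`` when its 520 nm or 670 nm plate-reader signal
      exceeds the plate median by more than 3 robust standard deviations
      (median absolute deviation scaled to the normal distribution);
    * ``dye_independent`` when the no-dye replicate still shows an apparent
      live-reacted percentage above the hit threshold.

    Hits without a triage record are retained but marked ``untriaged``.
    Surviving hits are the unflagged ones.
    """
    rec = triage_records.set_index("well")
    cut = {}
    for col in ("signal_520", "signal_670"):
        vals = rec[col].to_numpy(float)
        mad = median_abs_deviation(vals, scale="normal")
        cut[col] = float(np.median(vals) + 3.0 * mad)
    rows = []
    for _, hit in hits[hits["call"] == "ar_hit"].iterrows():
        well = hit["well"]
        flags = []
        if well not in rec.index:
            flags.append("untriaged")
            survived = True
        else:
            r = rec.loc[well]
            if r["signal_520"] > cut["signal_520"] or r["signal_670"] > cut["signal_670"]:
                flags.append("autofluorescent")
            if r["nodye_live_reacted_pct"] > induction_threshold_pct:
                flags.append("dye_independent")
            survived = not flags
        rows.append(
            {
                "well": well,
                "live_reacted_pct": hit["live_reacted_pct"],
                "triage_flags": ";".join(flags),
                "survived": survived,
            }
        )
    return pd.DataFrame(
        rows, columns=["well", "live_reacted_pct", "triage_flags", "survived"]
    )
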