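"""End-to-end orchestration: simulate -> kinematics -> plate/AR reports.

These functions tie the modules together in the order the screen runs:
per-well tracks (simulated, or detected from image stacks) are reduced to
CASA kinematics and WHO class fractions, normalised to the plate's DMSO
wells and hit-called; flow events are gated against plate-derived
thresholds, AR hits called and triaged.  Each stage consumes and produces
plain tables, so every step is re-runnable from its on-disk outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import flow as flow_mod
from .io import RunConfig
from .kinematics import analyze_tracks, summarize_well
from .plate import PlateLayout, analyze_plate
from .simulate import PlateBundle

__all__ = [
    "wells_motility",
    "motility_report",
    "ar_report",
    "run_screen",
]


def wells_motility(
    tracks_by_well: dict, config: "RunConfig | None" = None
) -> dict:
    """Per-well kinematic aggregation of a plate's track sets."""
    cfg = config or RunConfig()
    results = {}
    for well, tracks in tracks_by_well.items():
        summaries, _excluded = analyze_tracks(
            tracks,
            window=cfg.vap_window,
            min_points=cfg.min_track_points,
            thresholds=cfg.thresholds,
        )
        results[well] = summarize_well(summaries, well=well, thresholds=cfg.thresholds)
    return results


def motility_report(
    tracks_by_well: dict,
    layout: PlateLayout,
    config: "RunConfig | None" = None,
    exclusion_flags: "dict | None" = None,
) -> tuple[pd.DataFrame, dict]:
    """Tracks -> per-well motility table with percent-of-control, Z', calls."""
    well_results = wells_motility(tracks_by_well, config)
    return analyze_plate(well_results, layout, exclusion_flags)


def ar_report(
    events_by_well: dict,
    layout: PlateLayout,
    config: "RunConfig | None" = None,
) -> tuple[pd.DataFrame, flow_mod.GateThresholds]:
    """Flow events -> gated AR result table with hit calls.

    Gates are derived per plate from the pooled DMSO wells.
    """
    cfg = config or RunConfig()
    roles = layout.roles
    dmso_tables = [
        events_by_well[w] for w in layout.wells_with_role("dmso")
        if w in events_by_well
    ]
    gates = flow_mod.derive_gates(dmso_tables, source_plate=layout.plate_id)
    results = []
    for well, table in events_by_well.items():
        counts = flow_mod.gate_events(table, gates)
        results.append(
            flow_mod.ar_well_result(
                counts,
                min_events=cfg.min_flow_events,
                min_pi_positive_frac=cfg.min_pi_positive_frac,
            )
        )
    df = flow_mod.call_ar_hits(results, roles, cfg.ar_hit_threshold_pct)
    return df, gates


def run_screen(
    bundle: PlateBundle, config: "RunConfig | None" = None
) -> dict:
    """Full screen analysis of one simulated plate bundle.

    Returns a dict with the motility table, plate QC record, AR table,
    derived gates and the triage report of the primary AR hits.
    """
    cfg = config or RunConfig()
    motility, qc = motility_report(bundle.tracks, bundle.layout, cfg)
    ar, gates = ar_report(bundle.events, bundle.layout, cfg)
    triage = flow_mod.triage_ar_hits(ar, bundle.triage, cfg.ar_hit_threshold_pct)
    return {
        "motility": motility,
        "plate_qc": qc,
        "ar": ar,
        "gates": gates,
        "triage": triage,
    }
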