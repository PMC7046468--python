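"""Plate-level screening analytics for the motility assay.

A 384-well screening plate carries compound wells, vehicle (DMSO) wells
used as the negative control and normalisation reference, and
positive-control wells (Pristimerin for motility inhibition, the calcium
ionophore A23187 for acrosome-reaction induction).  The screening readout
per well is the median curvilinear velocity (VCL) of its tracks, expressed
as percent of the plate's DMSO reference:

    pct_control = 100 * VCL_median(well) / VCL_median(DMSO)

Assay robustness is summarised per plate by the Z'-factor,

    Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|,

and hits are wells whose VCL falls more than 15 % below the vehicle
reference (pct_control < 85, strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "PlateLayout",
    "default_384_layout",
    "percent_of_control",
    "zprime",
    "call_motility_hits",
    "exclude_wells",
    "plate_heatmap",
    "analyze_plate",
    "vehicle_final_concentration_pct",
    "screen_rates",
    "NormalizationError",
]

ROLES = ("compound", "dmso", "pristimerin", "a23187", "empty")

PLATE_ROWS = "ABCDEFGHIJKLMNOP"      # 16 rows
PLATE_COLS = tuple(range(1, 25))     # 24 columns

HIT_CUTOFF_PCT = 85.0                # 15 % reduction of VCL
UPREGULATOR_CUTOFF_PCT = 115.0       # symmetric to the reduction rule
ZPRIME_QC_GATE = 0.4                 # plate flagged (not rejected) below this


class NormalizationError(ValueError):
    """Raised when a plate cannot be normalised to its DMSO reference."""


def well_name(row: int, col: int) -> str:
    return f"{PLATE_ROWS[row]}{col:02d}"


def well_row_col(well: str) -> tuple[int, int]:
    return PLATE_ROWS.index(well[0]), int(well[1:]) - 1


@dataclass
class PlateLayout:
    """Role map of one 384-well plate.

    ``wells`` is a DataFrame with columns (well, role, compound_id);
    compound_id is empty for non-compound wells.
    """

    plate_id: str
    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells.reset_index(drop=True).copy()
        required = {"well", "role", "compound_id"}
        if not required.issubset(df.columns):
            raise ValueError(f"layout needs columns {sorted(required)}")
        if df["well"].duplicated().any():
            dup = df.loc[df["well"].duplicated(), "well"].iloc[0]
            raise ValueError(f"duplicate well in layout: {dup}")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles in layout: {sorted(bad)}")
        if (df["role"] == "dmso").sum() < 1:
            raise ValueError("layout needs at least one DMSO well")
        self.wells = df

    def wells_with_role(self, role: str) -> list[str]:
        return list(self.wells.loc[self.wells["role"] == role, "well"])

    @property
    def roles(self) -> dict[str, str]:
        return dict(zip(self.wells["well"], self.wells["role"]))


def default_384_layout(plate_id: str = "plate01") -> PlateLayout:
    """Standard screening layout: vehicle and positive controls on the edge
    columns (16 DMSO wells in column 1; Pristimerin rows A-H and A23187
    rows I-P of column 24), compounds everywhere else."""
    records = []
    n_cpd = 0
    for r in range(16):
        for c in range(24):
            w = well_name(r, c + 1)
            if c == 0:
                records.append((w, "dmso", ""))
            elif c == 23:
                records.append((w, "pristimerin" if r < 8 else "a23187", ""))
            else:
                n_cpd += 1
                records.append((w, "compound", f"CPD{n_cpd:04d}"))
    return PlateLayout(
        plate_id, pd.DataFrame(records, columns=["well", "role", "compound_id"])
    )


# ---------------------------------------------------------------------------
# normalisation and QC
# ---------------------------------------------------------------------------

def percent_of_control(
    well_median_vcl: float, dmso_median_vcls: "list[float] | np.ndarray"
) -> float:
    """Percent-of-control VCL for one well.

    The DMSO reference is the median of the per-well medians of the plate's
    vehicle wells (robust to a single bad control well).
    """
    ref_values = np.asarray(dmso_median_vcls, dtype=float)
    ref_values = ref_values[np.isfinite(ref_values)]
    if len(ref_values) == 0:
        raise NormalizationError("no DMSO reference wells available")
    ref = float(np.median(ref_values))
    if ref <= 0:
        raise NormalizationError(f"DMSO reference VCL is {ref}")
    return 100.0 * well_median_vcl / ref


def zprime(negative_values, positive_values) -> float:
    """Z'-factor from negative- and positive-control readouts.

    Uses sample means and sample standard deviations (ddof=1).  Both
    variances zero gives the limit value 1; identical control means leave
    Z' undefined and NaN is returned as the failed-QC sentinel.
    """
    neg = np.asarray(negative_values, dtype=float)
    pos = np.asarray(positive_values, dtype=float)
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("need >=2 values per control group")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        return float("nan")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def exclude_wells(results: pd.DataFrame, flags: "dict[str, str]") -> pd.DataFrame:
    """Drop flagged wells (autofocus errors, sticky compounds, ...) before
    normalisation and hit calling; the reasons are recorded on the result.

    ``flags`` maps well name -> reason.  Returns the filtered frame with an
    ``excluded_reason`` column retained on the attrs for logging.
    """
    out = results[~results["well"].isin(flags)].reset_index(drop=True)
    out.attrs["excluded_wells"] = dict(flags)
    return out


def call_motility_hits(
    plate_result: pd.DataFrame,
    hit_cutoff_pct: float = HIT_CUTOFF_PCT,
    upregulator_cutoff_pct: float = UPREGULATOR_CUTOFF_PCT,
) -> pd.DataFrame:
    """Assign per-well calls on a normalised plate result.

    A compound well is an ``inhibitor_hit`` when pct_control < 85 (strict;
    the screen's 15 %-reduction rule) and an ``upregulator_flag`` when
    pct_control > 115.  Control wells are never called.
    """
    out = plate_result.copy()

    def _call(row) -> str:
        if row["role"] != "compound":
            return "none"
        if row["pct_control"] < hit_cutoff_pct:
            return "inhibitor_hit"
        if row["pct_control"] > upregulator_cutoff_pct:
            return "upregulator_flag"
        return "none"

    out["call"] = out.apply(_call, axis=1)
    return out


def analyze_plate(
    well_results: "dict",
    layout: PlateLayout,
    exclusion_flags: "dict[str, str] | None" = None,
) -> tuple[pd.DataFrame, dict]:
    """Normalise a plate of :class:`~spermscreen.kinematics.WellMotilityResult`
    objects, compute Z' on the control wells, and call hits.

    Returns (per-well result table, plate QC record).  Wells named in
    ``exclusion_flags`` are removed before the DMSO reference is formed.
    """
    rows = []
    for well, res in well_results.items():
        rows.append(
            {
                "well": well,
                "n_tracks": res.n_tracks,
                "median_vcl": res.median_vcl,
                "pm_pct": res.pm_pct,
                "npm_pct": res.npm_pct,
                "im_pct": res.im_pct,
                "flags": ";".join(sorted(res.qc_flags)),
            }
        )
    df = pd.DataFrame(rows).merge(layout.wells, on="well", how="left")
    flags = dict(exclusion_flags or {})
    # wells whose own QC flags mark them unusable are excluded as well
    for _, row in df.iterrows():
        if row["flags"]:
            for f in row["flags"].split(";"):
                if f in ("autofocus_error", "sticky_compound", "low_count"):
                    flags.setdefault(row["well"], f)
    df = exclude_wells(df, flags)

    dmso = df.loc[df["role"] == "dmso", "median_vcl"]
    df["pct_control"] = [
        percent_of_control(v, dmso.values) for v in df["median_vcl"]
    ]
    df = call_motility_hits(df)

    neg = df.loc[df["role"] == "dmso", "pct_control"].values
    pos = df.loc[df["role"] == "pristimerin", "pct_control"].values
    zp = zprime(neg, pos) if len(neg) >= 2 and len(pos) >= 2 else float("nan")
    qc = {
        "plate_id": layout.plate_id,
        "zprime": zp,
        "zprime_flag": bool(not np.isfinite(zp) or zp < ZPRIME_QC_GATE),
        "n_excluded": len(flags),
        "excluded_wells": flags,
        "n_inhibitor_hits": int((df["call"] == "inhibitor_hit").sum()),
        "n_upregulator_flags": int((df["call"] == "upregulator_flag").sum()),
    }
    return df, qc


# ---------------------------------------------------------------------------
# heatmap export
# ---------------------------------------------------------------------------

def plate_heatmap(
    plate_result: pd.DataFrame,
    metric: str,
    csv_path: "str | Path | None" = None,
    png_path: "str | Path | None" = None,
) -> pd.DataFrame:
    """16 x 24 grid of one per-well metric for edge-effect inspection.

    Row and column means are appended (``row_mean`` column, ``col_mean``
    row).  Optionally written to CSV and rendered to PNG.
    """
    if metric not in ("pct_control", "median_vcl", "n_tracks"):
        raise ValueError(f"unsupported heatmap metric: {metric}")
    grid = np.full((16, 24), np.nan)
    for _, row in plate_result.iterrows():
        r, c = well_row_col(row["well"])
        grid[r, c] = row[metric]
    df = pd.DataFrame(
        grid, index=list(PLATE_ROWS), columns=[str(c) for c in PLATE_COLS]
    )
    out = df.copy()
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows/cols
            row_means = np.nanmean(grid, axis=1)
            col_vals = np.nanmean(grid, axis=0)
    out["row_mean"] = row_means
    col_means = pd.Series(col_vals, index=out.columns[:-1])
    col_means["row_mean"] = np.nan
    out.loc["col_mean"] = col_means
    if csv_path is not None:
        out.to_csv(csv_path)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 6))
        im = ax.imshow(grid, aspect="auto", cmap="viridis")
        ax.set_xticks(range(24), [str(c) for c in PLATE_COLS], fontsize=6)
        ax.set_yticks(range(16), list(PLATE_ROWS), fontsize=6)
        ax.set_title(metric)
        fig.colorbar(im, ax=ax)
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return out


# ---------------------------------------------------------------------------
# screen bookkeeping
# ---------------------------------------------------------------------------

def vehicle_final_concentration_pct(
    spot_volume_nl: float = 12.5, added_volumes_ul: tuple = (10.0, 10.0)
) -> float:
    """Final vehicle (DMSO) concentration in % v/v after assay assembly.

    A compound spot of pure DMSO (default 12.5 nL) is diluted by the listed
    additions (default 10 µL media plus 10 µL sperm suspension).
    """
    spot_ul = spot_volume_nl / 1000.0
    total_ul = spot_ul + float(sum(added_volumes_ul))
    if total_ul <= 0:
        raise ValueError("total volume must be positive")
    return 100.0 * spot_ul / total_ul


def screen_rates(n_hits: int, n_screened: int, n_confirmed: int) -> dict:
    """Primary-screen bookkeeping: hit, confirmation and reconfirmation
    rates in percent."""
    if n_screened <= 0 or not (0 <= n_confirmed <= n_hits <= n_screened):
        raise ValueError("inconsistent screen counts")
    return {
        "hit_rate_pct": 100.0 * n_hits / n_screened,
        "confirmation_rate_pct": 100.0 * n_confirmed / n_hits if n_hits else 0.0,
        "reconfirmation_rate_pct": 100.0 * n_confirmed / n_screened,
    }
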