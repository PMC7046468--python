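"""Ground-truthed synthetic data for the screening pipeline.

Three layers of simulation mirror the screen's data types:

* 2-D swimming tracks in three kinematic classes — progressively motile
  (PM: straight drift plus a sinusoidal lateral head oscillation),
  non-progressively motile (NPM: correlated jitter around a slowly
  wandering centre) and immotile (IM: isotropic Gaussian jitter) — with
  parameters chosen so that measured CASA kinematics land in the WHO
  classification regimes;
* rendering of tracks into brightfield-like image stacks (heads as 2-D
  Gaussian spots on a noisy background; dark-on-bright available via the
  ``invert`` flag);
* four-population Pi/PNA fluorescence event clouds as a log-normal mixture
  with controllable proportions.

Whole plates combine these per well with a role layout, per-well compound
effects, and two realistic noise sources: a per-well global kinematic
factor (donor-pool, temperature and focus variation scaling every motion
amplitude) and a per-well effect-size factor on the compound response.

Randomness contract: one root seed; each well draws from an independent
stream keyed by ``SeedSequence([seed, well_index])``, so wells are
reproducible independently of simulation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flow import POPULATIONS, EventTable
from .plate import PlateLayout, default_384_layout, well_row_col
from .tracking import ImageStack, Track, merge_positions

__all__ = [
    "MotilitySimConfig",
    "FlowSimConfig",
    "WellEffect",
    "PlateSimConfig",
    "GroundTruth",
    "PlateBundle",
    "simulate_track",
    "simulate_field",
    "render_stack",
    "simulate_flow_well",
    "simulate_plate",
]


def stream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for sub-stream ``key`` of root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MotilitySimConfig:
    """Acquisition geometry and per-class motion parameters.

    Defaults reproduce the screen's acquisition (24 frames in 0.5 s, i.e.
    48 fps; 20x-like optics at 0.65 µm/px over a 1024 x 1024 px field) and
    a density-gradient-selected, motile-enriched cell population: 70 PM,
    10 NPM and 20 IM cells per imaging position, PM speed ~ N(100, 15) µm/s
    with a 2 µm / 14 Hz lateral head beat.
    """

    n_frames: int = 24
    frame_interval: float = 1.0 / 48.0       # s
    field_size_um: tuple = (665.6, 665.6)    # 1024 px * 0.65 µm/px
    pixel_size_um: float = 0.65
    n_cells_per_class: tuple = (70, 10, 20)  # (PM, NPM, IM)
    pm_speed_mean: float = 100.0             # µm/s
    pm_speed_sd: float = 15.0                # µm/s
    pm_beat_amplitude: float = 2.0           # µm
    pm_beat_frequency: float = 14.0          # Hz
    npm_drift_speed: float = 8.0             # µm/s, wandering centre
    npm_jitter_scale: float = 1.2            # µm, stationary AR(1) sd
    im_jitter_scale: float = 0.15            # µm, iid Gaussian sd
    psf_sigma: float = 1.5                   # px
    spot_amplitude: float = 600.0            # intensity units above background
    background_level: float = 100.0
    noise_sd: float = 8.0
    invert: bool = False                     # True: dark heads on bright field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        for name in ("pixel_size_um", "psf_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(s <= 0 for s in self.field_size_um):
            raise ValueError("field_size_um must be positive")
        if any(n < 0 for n in self.n_cells_per_class):
            raise ValueError("cell counts must be >= 0")
        for name in (
            "pm_speed_mean", "pm_beat_amplitude", "npm_drift_speed",
            "npm_jitter_scale", "im_jitter_scale", "noise_sd",
            "pm_speed_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def frames_per_second(self) -> float:
        """Effective acquisition rate, n_frames / total span."""
        return 1.0 / self.frame_interval

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class FlowSimConfig:
    """Four-population Pi/PNA mixture on log10 fluorescence axes.

    Population order follows :data:`~spermscreen.flow.POPULATIONS`:
    (Pi-PNA-, Pi+PNA-, Pi+PNA+, Pi-PNA+).  Default proportions describe a
    vehicle well: mostly unstained live cells, ~32 % Pi-positive, 8 %
    spontaneously acrosome-reacted live cells.  Centres put negative
    populations at log10 = 2 and positive at log10 = 4 on each axis.
    """

    n_events: int = 2000
    proportions: tuple = (0.60, 0.22, 0.10, 0.08)
    # per population: (log10 FL1 centre, log10 FL3 centre)
    population_centres: tuple = ((2.0, 2.0), (2.0, 4.0), (4.0, 4.0), (4.0, 2.0))
    population_spreads: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be 4 non-negatives summing to 1")
        if len(self.population_centres) != 4 or len(self.population_spreads) != 4:
            raise ValueError("need centres and spreads for 4 populations")


@dataclass
class WellEffect:
    """True per-well compound effect.

    ``motility_scale`` multiplies the speed and beat amplitude of every PM
    cell (1 = inactive, 0 = full paralysis); cells slowed below the
    progressive thresholds then classify NPM/IM, so the PM fraction drops
    with the scale as well.  ``ar_induction`` is the added live-reacted
    fraction in the flow assay.  The interference fields drive the triage
    simulation only.
    """

    motility_scale: float = 1.0
    ar_induction: float = 0.0
    fluorescent_520: bool = False
    fluorescent_670: bool = False
    dye_independent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.motility_scale <= 1.5:
            raise ValueError("motility_scale must be in [0, 1.5]")
        if not 0.0 <= self.ar_induction <= 1.0:
            raise ValueError("ar_induction must be in [0, 1]")


@dataclass
class PlateSimConfig:
    layout: PlateLayout = field(default_factory=default_384_layout)
    well_effects: dict = field(default_factory=dict)   # well -> WellEffect
    pristimerin_scale: float = 0.15   # strong motility reduction (20 µM)
    a23187_induction: float = 0.07    # positive control tops out near 15 %
    well_cv: float = 0.045            # per-well global kinematic factor
    response_cv: float = 0.05         # per-well effect-size variability
    motility: MotilitySimConfig = field(default_factory=MotilitySimConfig)
    flow: FlowSimConfig = field(default_factory=FlowSimConfig)
    n_positions: int = 2              # imaging positions per well
    seed: int = 0

    def __post_init__(self) -> None:
        roles = set(self.layout.wells["role"])
        if "dmso" not in roles:
            raise ValueError("plate layout needs DMSO wells")
        if not roles & {"pristimerin", "a23187"}:
            raise ValueError("plate layout needs positive-control wells")
        wells = set(self.layout.wells["well"])
        unknown = set(self.well_effects) - wells
        if unknown:
            raise ValueError(f"effects given for wells not in layout: {sorted(unknown)}")
        # every well gets an effect entry; unspecified compound wells are inactive
        effects = {}
        for w in self.layout.wells["well"]:
            effects[w] = self.well_effects.get(w, WellEffect())
        self.well_effects = effects


@dataclass
class GroundTruth:
    """Generator-side truth: exactly one label per generated track/event."""

    track_classes: "dict[int, str] | None" = None
    event_labels: "np.ndarray | None" = None
    well_effects: "pd.DataFrame | None" = None


@dataclass
class PlateBundle:
    layout: PlateLayout
    tracks: dict                 # well -> list[Track] (positions merged)
    events: dict                 # well -> EventTable
    ground_truth: GroundTruth    # well_effects table + per-well track classes
    track_classes: dict          # well -> {track_id: class}
    triage: pd.DataFrame         # well, signal_520, signal_670, nodye pct


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _reflect(xy: np.ndarray, field_size: tuple) -> np.ndarray:
    """Fold positions back into the field by mirror reflection at the edges."""
    out = xy.copy()
    for ax in range(2):
        span = field_size[ax]
        folded = np.mod(out[:, ax], 2.0 * span)
        out[:, ax] = span - np.abs(folded - span)
    return out


def simulate_track(
    class_label: str,
    config: MotilitySimConfig,
    rng: np.random.Generator,
    track_id: int = 0,
) -> Track:
    """One ground-truth track of the requested kinematic class.

    PM: straight drift at a speed drawn from the configured normal, plus a
    sinusoidal lateral oscillation (the head trace of the flagellar beat);
    the start position keeps the whole path in-field so progressive tracks
    never reflect.  NPM: AR(1)-correlated jitter around a centre drifting
    slowly along a wandering heading.  IM: iid isotropic Gaussian jitter.
    """
    n = config.n_frames
    dt = config.frame_interval
    t = np.arange(n) * dt
    fx, fy = config.field_size_um

    if class_label == "PM":
        speed = max(float(rng.normal(config.pm_speed_mean, config.pm_speed_sd)), 0.0)
        heading = rng.uniform(0.0, 2.0 * np.pi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array([np.cos(heading), np.sin(heading)])
        v = np.array([-u[1], u[0]])
        margin = speed * t[-1] + config.pm_beat_amplitude + 1.0
        start = np.array(
            [
                rng.uniform(min(margin, fx / 2), max(fx - margin, fx / 2)),
                rng.uniform(min(margin, fy / 2), max(fy - margin, fy / 2)),
            ]
        )
        lateral = config.pm_beat_amplitude * np.sin(
            2.0 * np.pi * config.pm_beat_frequency * t + phase
        )
        xy = start[None, :] + (speed * t)[:, None] * u[None, :] + lateral[:, None] * v[None, :]
    elif class_label == "NPM":
        drift = max(float(rng.normal(config.npm_drift_speed, 0.25 * config.npm_drift_speed)), 0.0)
        heading = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(rng.normal(0.0, 0.5, size=n))
        steps = drift * dt * np.stack([np.cos(heading), np.sin(heading)], axis=1)
        centre = np.cumsum(steps, axis=0)
        centre += np.array([rng.uniform(20.0, fx - 20.0), rng.uniform(20.0, fy - 20.0)])
        rho, scale = 0.7, config.npm_jitter_scale
        jitter = np.empty((n, 2))
        jitter[0] = rng.normal(0.0, scale, size=2) if scale > 0 else 0.0
        innov_sd = scale * np.sqrt(1.0 - rho**2)
        for i in range(1, n):
            jitter[i] = rho * jitter[i - 1] + rng.normal(0.0, innov_sd, size=2)
        xy = centre + jitter
    elif class_label == "IM":
        start = np.array([rng.uniform(5.0, fx - 5.0), rng.uniform(5.0, fy - 5.0)])
        xy = start[None, :] + rng.normal(0.0, config.im_jitter_scale, size=(n, 2))
    else:
        raise ValueError(f"unknown motility class: {class_label!r}")

    xy = _reflect(xy, config.field_size_um)
    return Track(track_id=track_id, frames=np.arange(n), xy_um=xy, frame_interval=dt)


def simulate_field(
    config: MotilitySimConfig, rng: "np.random.Generator | None" = None
) -> tuple[list[Track], GroundTruth]:
    """One imaging position: the configured number of tracks per class."""
    if rng is None:
        rng = stream(config.seed)
    tracks: list[Track] = []
    classes: dict[int, str] = {}
    for label, count in zip(("PM", "NPM", "IM"), config.n_cells_per_class):
        for _ in range(count):
            tid = len(tracks)
            tracks.append(simulate_track(label, config, rng, track_id=tid))
            classes[tid] = label
    return tracks, GroundTruth(track_classes=classes)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def render_stack(
    tracks: list[Track],
    config: MotilitySimConfig,
    rng: "np.random.Generator | None" = None,
) -> ImageStack:
    """Render tracks into a time-lapse stack.

    Each head is a 2-D Gaussian of ``psf_sigma`` pixels centred at the
    track position (µm / pixel_size), drawn on a flat background with
    additive Gaussian noise.  With ``invert`` the heads are dark on bright,
    the contrast convention of raw brightfield images.
    """
    if rng is None:
        rng = stream(config.seed, 1)
    px = config.pixel_size_um
    h = int(round(config.field_size_um[1] / px))
    w = int(round(config.field_size_um[0] / px))
    for tr in tracks:
        if (
            np.any(tr.xy_um < 0)
            or np.any(tr.xy_um[:, 0] > config.field_size_um[0])
            or np.any(tr.xy_um[:, 1] > config.field_size_um[1])
        ):
            raise ValueError(f"track {tr.track_id} has points outside the field")
    sigma = config.psf_sigma
    radius = int(np.ceil(4.0 * sigma))
    signal = np.zeros((config.n_frames, h, w))
    for tr in tracks:
        for f, (x_um, y_um) in zip(tr.frames, tr.xy_um):
            cx, cy = x_um / px, y_um / px
            c0 = max(int(np.floor(cx)) - radius, 0)
            c1 = min(int(np.floor(cx)) + radius + 2, w)
            r0 = max(int(np.floor(cy)) - radius, 0)
            r1 = min(int(np.floor(cy)) + radius + 2, h)
            if c0 >= c1 or r0 >= r1:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            signal[f, r0:r1, c0:c1] += config.spot_amplitude * np.exp(
                -((cc - cx) ** 2 + (rr - cy) ** 2) / (2.0 * sigma**2)
            )
    if config.invert:
        frames = config.background_level - signal
    else:
        frames = config.background_level + signal
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)
    return ImageStack(
        frames=frames,
        pixel_size_um=px,
        frame_interval=config.frame_interval,
    )


# ---------------------------------------------------------------------------
# flow events
# ---------------------------------------------------------------------------

def simulate_flow_well(
    config: FlowSimConfig,
    rng: "np.random.Generator | None" = None,
    well: str = "",
) -> tuple[EventTable, GroundTruth]:
    """Events of one well drawn from the 4-component log-normal mixture.

    Counts per population are multinomial in the configured proportions;
    intensities are sampled on the log10 scale and exported linear.
    """
    if rng is None:
        rng = stream(config.seed)
    counts = rng.multinomial(config.n_events, np.asarray(config.proportions, float))
    fl1, fl3, labels = [], [], []
    for pop, cnt, (c1, c3), sd in zip(
        POPULATIONS, counts, config.population_centres, config.population_spreads
    ):
        fl1.append(rng.normal(c1, sd, size=cnt))
        fl3.append(rng.normal(c3, sd, size=cnt))
        labels.extend([pop] * cnt)
    fl1 = 10.0 ** np.concatenate(fl1) if len(fl1) else np.array([])
    fl3 = 10.0 ** np.concatenate(fl3) if len(fl3) else np.array([])
    labels = np.array(labels, dtype=object)
    order = rng.permutation(len(labels))
    table = EventTable(
        well=well,
        data=pd.DataFrame({"FL1_A": fl1[order], "FL3_A": fl3[order]}),
    )
    return table, GroundTruth(event_labels=labels[order])


def _induced_proportions(base: tuple, induction: float) -> tuple:
    """Move ``induction`` of the total mass into the live-reacted population."""
    p = np.asarray(base, dtype=float) * (1.0 - induction)
    p[POPULATIONS.index("Pi-PNA+")] += induction
    return tuple(p)


# ---------------------------------------------------------------------------
# whole plates
# ---------------------------------------------------------------------------

def _scaled_motility(
    config: MotilitySimConfig, kinematic_factor: float, motility_scale: float
) -> MotilitySimConfig:
    """Apply the per-well global factor and the compound effect.

    The compound effect scales PM speed and beat amplitude (a slowed,
    weakened flagellar beat); the global factor scales every motion
    amplitude of every class.
    """
    f, m = kinematic_factor, motility_scale
    return replace(
        config,
        pm_speed_mean=config.pm_speed_mean * f * m,
        pm_speed_sd=config.pm_speed_sd * f * m,
        pm_beat_amplitude=config.pm_beat_amplitude * f * m,
        npm_drift_speed=config.npm_drift_speed * f,
        npm_jitter_scale=config.npm_jitter_scale * f,
        im_jitter_scale=config.im_jitter_scale * f,
    )


def _role_effect(role: str, config: PlateSimConfig, well: str) -> WellEffect:
    if role == "dmso":
        return WellEffect()
    if role == "pristimerin":
        return WellEffect(motility_scale=config.pristimerin_scale)
    if role == "a23187":
        return WellEffect(ar_induction=config.a23187_induction)
    return config.well_effects[well]


def simulate_plate(config: PlateSimConfig) -> PlateBundle:
    """Simulate a whole screening plate: tracks, flow events, triage reads.

    DMSO wells are inactive; Pristimerin wells carry the configured strong
    motility reduction; A23187 wells the configured AR induction; compound
    wells their per-well effects.  Fully reproducible from the root seed,
    independently per well.
    """
    layout = config.layout
    tracks: dict = {}
    events: dict = {}
    classes: dict = {}
    truth_rows = []
    triage_rows = []
    for _, lw in layout.wells.iterrows():
        well, role = lw["well"], lw["role"]
        if role == "empty":
            continue
        r, c = well_row_col(well)
        rng = stream(config.seed, r * 24 + c)
        effect = _role_effect(role, config, well)

        f_well = float(np.exp(rng.normal(0.0, config.well_cv)))
        m_eff = 1.0 - (1.0 - effect.motility_scale) * float(
            np.exp(rng.normal(0.0, config.response_cv))
        )
        m_eff = float(np.clip(m_eff, 0.0, 1.5))
        a_eff = float(
            np.clip(
                effect.ar_induction * np.exp(rng.normal(0.0, config.response_cv)),
                0.0,
                1.0,
            )
        )

        mcfg = _scaled_motility(config.motility, f_well, m_eff)
        positions = [simulate_field(mcfg, rng) for _ in range(config.n_positions)]
        well_tracks = positions[0][0]
        well_classes = dict(positions[0][1].track_classes)
        for pos_tracks, pos_truth in positions[1:]:
            offset = len(well_tracks)
            well_tracks = merge_positions(well_tracks, pos_tracks)
            for tid, lab in pos_truth.track_classes.items():
                well_classes[offset + tid] = lab
        tracks[well] = well_tracks
        classes[well] = well_classes

        fcfg = replace(
            config.flow,
            proportions=_induced_proportions(config.flow.proportions, a_eff),
        )
        events[well], _ = simulate_flow_well(fcfg, rng, well=well)

        s520 = rng.normal(1000.0, 50.0) * (8.0 if effect.fluorescent_520 else 1.0)
        s670 = rng.normal(1000.0, 50.0) * (8.0 if effect.fluorescent_670 else 1.0)
        nodye = (
            rng.normal(40.0, 5.0)
            if effect.dye_independent
            else abs(rng.normal(1.0, 0.5))
        )
        triage_rows.append(
            {
                "well": well,
                "signal_520": float(s520),
                "signal_670": float(s670),
                "nodye_live_reacted_pct": float(np.clip(nodye, 0.0, 100.0)),
            }
        )
        truth_rows.append(
            {
                "well": well,
                "role": role,
                "compound_id": lw["compound_id"],
                "motility_scale": effect.motility_scale,
                "ar_induction": effect.ar_induction,
                "motility_scale_realized": m_eff,
                "ar_induction_realized": a_eff,
                "kinematic_factor": f_well,
            }
        )
    truth = GroundTruth(well_effects=pd.DataFrame(truth_rows))
    return PlateBundle(
        layout=layout,
        tracks=tracks,
        events=events,
        ground_truth=truth,
        track_classes=classes,
        triage=pd.DataFrame(triage_rows),
    )
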