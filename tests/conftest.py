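"""Shared fixtures: small simulated worlds kept cheap enough for CI."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spermscreen import (
    MotilitySimConfig,
    PlateLayout,
    PlateSimConfig,
    Track,
    WellEffect,
    simulate_plate,
)


def gaussian_frame(
    shape: tuple,
    centres: list,
    amplitude: float = 600.0,
    sigma: float = 1.5,
    background: float = 100.0,
) -> np.ndarray:
    """Noise-free frame with Gaussian spots at (x, y) pixel positions."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    frame = np.full(shape, background, dtype=float)
    for cx, cy in centres:
        frame += amplitude * np.exp(-((cc - cx) ** 2 + (rr - cy) ** 2) / (2 * sigma**2))
    return frame


def straight_track(
    speed: float = 100.0,
    n: int = 24,
    dt: float = 1.0 / 48.0,
    start=(10.0, 10.0),
    heading=(1.0, 0.0),
    track_id: int = 0,
) -> Track:
    t = np.arange(n) * dt
    u = np.asarray(heading, dtype=float)
    u = u / np.linalg.norm(u)
    xy = np.asarray(start) + (speed * t)[:, None] * u[None, :]
    return Track(track_id=track_id, frames=np.arange(n), xy_um=xy, frame_interval=dt)


def small_layout(
    n_compound: int = 6, n_dmso: int = 4, n_pristimerin: int = 4, n_a23187: int = 2
) -> PlateLayout:
    """A few-well layout reusing valid 384-well names, for cheap plate sims."""
    rows = []
    names = [f"{r}{c:02d}" for r in "ABCD" for c in range(1, 25)]
    it = iter(names)
    for _ in range(n_dmso):
        rows.append((next(it), "dmso", ""))
    for _ in range(n_pristimerin):
        rows.append((next(it), "pristimerin", ""))
    for _ in range(n_a23187):
        rows.append((next(it), "a23187", ""))
    for i in range(n_compound):
        rows.append((next(it), "compound", f"CPD{i + 1:04d}"))
    return PlateLayout(
        "mini", pd.DataFrame(rows, columns=["well", "role", "compound_id"])
    )


@pytest.fixture(scope="session")
def mini_plate_bundle():
    """A small simulated plate with one strong planted motility inhibitor
    and one strong AR inducer, shared across tests (read-only)."""
    layout = small_layout(n_compound=8)
    compounds = layout.wells_with_role("compound")
    effects = {
        compounds[0]: WellEffect(motility_scale=0.2),
        compounds[1]: WellEffect(ar_induction=0.5),
    }
    cfg = PlateSimConfig(layout=layout, well_effects=effects, seed=42)
    return cfg, simulate_plate(cfg)


@pytest.fixture()
def fast_motility_config():
    """Small field and few cells: renderable + trackable in well under a second."""
    return MotilitySimConfig(
        field_size_um=(332.8, 332.8),  # 512 px
        n_cells_per_class=(6, 3, 3),
        seed=5,
    )
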