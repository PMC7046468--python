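"""Generator tests: motion classes, rendering, flow mixtures, whole plates."""

import numpy as np
import pandas as pd
import pytest

from spermscreen import (
    FlowSimConfig,
    MotilitySimConfig,
    PlateLayout,
    PlateSimConfig,
    WellEffect,
    simulate_field,
    simulate_flow_well,
    simulate_plate,
    simulate_track,
    render_stack,
)
from spermscreen.flow import POPULATIONS
from spermscreen.kinematics import analyze_tracks, classify_track, compute_kinematics
from spermscreen.simulate import stream

from conftest import small_layout


class TestTracks:
    def test_im_zero_jitter_is_stationary(self):
        cfg = MotilitySimConfig(im_jitter_scale=0.0)
        tr = simulate_track("IM", cfg, stream(0))
        assert tr.n_points == 24
        assert np.allclose(tr.xy_um, tr.xy_um[0])

    def test_pm_straight_line_has_equal_velocities(self):
        """A PM cell with no speed spread and no beat is a straight
        constant-velocity line: VCL = VSL = VAP = the drawn speed."""
        cfg = MotilitySimConfig(
            pm_speed_mean=100.0, pm_speed_sd=0.0, pm_beat_amplitude=0.0
        )
        tr = simulate_track("PM", cfg, stream(1))
        s = compute_kinematics(tr)
        assert s.vcl == pytest.approx(100.0, abs=1e-9)
        assert s.vsl == pytest.approx(100.0, abs=1e-9)
        assert s.vap == pytest.approx(100.0, abs=1e-9)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown motility class"):
            simulate_track("XX", MotilitySimConfig(), stream(0))

    def test_tracks_stay_in_field(self):
        cfg = MotilitySimConfig(field_size_um=(120.0, 120.0), seed=3)
        rng = stream(3)
        for label in ("PM", "NPM", "IM"):
            for _ in range(50):
                tr = simulate_track(label, cfg, rng)
                assert np.all(tr.xy_um >= 0)
                assert np.all(tr.xy_um[:, 0] <= 120.0)
                assert np.all(tr.xy_um[:, 1] <= 120.0)

    @pytest.mark.parametrize(
        "label, min_fraction", [("PM", 0.95), ("IM", 0.90), ("NPM", 0.90)]
    )
    def test_class_realism(self, label, min_fraction):
        """Generated tracks of each class are recovered by the CASA
        classifier at the stated rates under the default configuration."""
        cfg = MotilitySimConfig()
        rng = stream(12)
        tracks = [simulate_track(label, cfg, rng, i) for i in range(400)]
        summaries, excluded = analyze_tracks(tracks)
        assert not excluded
        classes = [classify_track(s) for s in summaries]
        assert classes.count(label) / len(classes) >= min_fraction


class TestField:
    def test_empty_counts_give_empty_field(self):
        cfg = MotilitySimConfig(n_cells_per_class=(0, 0, 0))
        tracks, truth = simulate_field(cfg)
        assert tracks == [] and truth.track_classes == {}

    def test_ground_truth_covers_every_track_once(self):
        cfg = MotilitySimConfig(n_cells_per_class=(100, 50, 50), seed=9)
        tracks, truth = simulate_field(cfg)
        assert len(tracks) == 200
        assert sorted(truth.track_classes) == [t.track_id for t in tracks]
        counts = pd.Series(list(truth.track_classes.values())).value_counts()
        assert counts["PM"] == 100 and counts["NPM"] == 50 and counts["IM"] == 50

    def test_determinism(self):
        cfg = MotilitySimConfig(n_cells_per_class=(10, 5, 5), seed=77)
        a, _ = simulate_field(cfg)
        b, _ = simulate_field(cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.xy_um, tb.xy_um)


class TestRender:
    def test_single_head_argmax_at_position(self, fast_motility_config):
        cfg = MotilitySimConfig(
            field_size_um=(65.0, 65.0),
            n_cells_per_class=(0, 0, 0),
            noise_sd=0.0,
            im_jitter_scale=0.0,
        )
        from spermscreen.tracking import Track

        xy = np.tile([32.5, 19.5], (24, 1))
        tr = Track(0, np.arange(24), xy, cfg.frame_interval)
        stack = render_stack([tr], cfg)
        for frame in stack.frames:
            r, c = np.unravel_index(np.argmax(frame), frame.shape)
            assert c == round(32.5 / cfg.pixel_size_um)
            assert r == round(19.5 / cfg.pixel_size_um)

    def test_empty_track_set_is_pure_background(self):
        cfg = MotilitySimConfig(field_size_um=(65.0, 65.0), noise_sd=0.0)
        stack = render_stack([], cfg)
        assert np.allclose(stack.frames, cfg.background_level)

    def test_two_separated_heads_give_two_maxima(self):
        """Heads >= 6 psf sigma apart stay resolved: each frame has exactly
        two local maxima above background (brute-force pixel check)."""
        cfg = MotilitySimConfig(
            field_size_um=(65.0, 65.0), noise_sd=0.0, psf_sigma=1.5
        )
        from spermscreen.tracking import Track

        sep_um = 8 * cfg.psf_sigma * cfg.pixel_size_um
        t1 = Track(0, np.arange(24), np.tile([20.0, 30.0], (24, 1)), cfg.frame_interval)
        t2 = Track(
            1, np.arange(24), np.tile([20.0 + sep_um, 30.0], (24, 1)), cfg.frame_interval
        )
        frame = render_stack([t1, t2], cfg).frames[0]
        interior = frame[1:-1, 1:-1]
        is_max = np.ones_like(interior, dtype=bool)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                shifted = frame[1 + dr : frame.shape[0] - 1 + dr,
                                1 + dc : frame.shape[1] - 1 + dc]
                is_max &= interior >= shifted
        n_maxima = int(np.sum(is_max & (interior > cfg.background_level + 1)))
        assert n_maxima == 2

    def test_out_of_field_track_rejected(self):
        cfg = MotilitySimConfig(field_size_um=(65.0, 65.0))
        from spermscreen.tracking import Track

        tr = Track(0, np.arange(24), np.tile([70.0, 10.0], (24, 1)), cfg.frame_interval)
        with pytest.raises(ValueError, match="outside the field"):
            render_stack([tr], cfg)

    def test_inverted_rendering_darkens_heads(self):
        cfg = MotilitySimConfig(
            field_size_um=(65.0, 65.0), noise_sd=0.0, invert=True,
            background_level=700.0,
        )
        from spermscreen.tracking import Track

        tr = Track(0, np.arange(24), np.tile([32.0, 32.0], (24, 1)), cfg.frame_interval)
        frame = render_stack([tr], cfg).frames[0]
        assert frame.min() < 700.0 - 500.0
        assert frame.max() == pytest.approx(700.0)


class TestFlow:
    def test_single_population(self):
        cfg = FlowSimConfig(n_events=500, proportions=(1.0, 0.0, 0.0, 0.0), seed=2)
        table, truth = simulate_flow_well(cfg)
        assert table.n_events == 500
        assert set(truth.event_labels) == {"Pi-PNA-"}

    def test_zero_events(self):
        table, truth = simulate_flow_well(FlowSimConfig(n_events=0))
        assert table.n_events == 0 and len(truth.event_labels) == 0

    def test_label_fractions_within_three_binomial_sd(self):
        props = (0.55, 0.2, 0.15, 0.1)
        n = 10_000
        table, truth = simulate_flow_well(FlowSimConfig(n_events=n, proportions=props, seed=8))
        assert len(truth.event_labels) == n
        for pop, p in zip(POPULATIONS, props):
            frac = np.mean(truth.event_labels == pop)
            assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            FlowSimConfig(proportions=(0.5, 0.5, 0.5, -0.5))
        with pytest.raises(ValueError):
            FlowSimConfig(proportions=(0.5, 0.2, 0.2, 0.2))


class TestPlate:
    def test_missing_controls_rejected(self):
        layout = PlateLayout(
            "bad",
            pd.DataFrame(
                [("A01", "dmso", ""), ("A02", "compound", "C1")],
                columns=["well", "role", "compound_id"],
            ),
        )
        with pytest.raises(ValueError, match="positive-control"):
            PlateSimConfig(layout=layout)

    def test_effect_for_unknown_well_rejected(self):
        with pytest.raises(ValueError, match="not in layout"):
            PlateSimConfig(
                layout=small_layout(), well_effects={"Z99": WellEffect()}
            )

    def test_every_well_gets_an_effect_entry(self):
        cfg = PlateSimConfig(layout=small_layout())
        assert set(cfg.well_effects) == set(cfg.layout.wells["well"])

    def test_plate_determinism(self):
        cfg = small_layout(n_compound=2)
        a = simulate_plate(PlateSimConfig(layout=cfg, seed=11))
        b = simulate_plate(PlateSimConfig(layout=cfg, seed=11))
        pd.testing.assert_frame_equal(a.triage, b.triage)
        pd.testing.assert_frame_equal(
            a.ground_truth.well_effects, b.ground_truth.well_effects
        )
        for well in a.tracks:
            for ta, tb in zip(a.tracks[well], b.tracks[well]):
                assert np.array_equal(ta.xy_um, tb.xy_um)
            pd.testing.assert_frame_equal(a.events[well].data, b.events[well].data)

    def test_roles_carry_expected_effects(self, mini_plate_bundle):
        _, bundle = mini_plate_bundle
        truth = bundle.ground_truth.well_effects.set_index("well")
        assert (truth.loc[truth["role"] == "dmso", "motility_scale"] == 1.0).all()
        assert (truth.loc[truth["role"] == "dmso", "ar_induction"] == 0.0).all()
        assert (truth.loc[truth["role"] == "pristimerin", "motility_scale"] == 0.15).all()
        assert (truth.loc[truth["role"] == "a23187", "ar_induction"] == 0.07).all()
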