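"""Flow-cytometry gating, AR hit calling and interference triage tests."""

import numpy as np
import pandas as pd
import pytest

from spermscreen import (
    EventTable,
    FlowSimConfig,
    GateThresholds,
    ar_well_result,
    call_ar_hits,
    derive_gates,
    gate_events,
    simulate_flow_well,
    triage_ar_hits,
)
from spermscreen.flow import POPULATIONS, GatingError, QuadrantCounts
from spermscreen.simulate import stream


def _table(fl1, fl3, well="W"):
    return EventTable(well=well, data=pd.DataFrame({"FL1_A": fl1, "FL3_A": fl3}))


class TestGateDerivation:
    def test_valley_between_two_modes(self):
        """Two synthetic log10 modes at 2 and 4: the derived cut falls in
        (2.5, 3.5), in agreement with a brute-force histogram valley scan."""
        rng = np.random.default_rng(0)
        logv = np.concatenate([rng.normal(2, 0.25, 4000), rng.normal(4, 0.25, 4000)])
        tab = _table(10.0**logv, 10.0**logv)
        gates = derive_gates([tab])
        assert 2.5 < np.log10(gates.fl1_cut) < 3.5
        # oracle: coarse histogram valley between the two peak bins
        hist, edges = np.histogram(logv, bins=60)
        peaks = np.argsort(hist)[-2:]
        lo, hi = sorted(peaks)
        valley_bin = lo + int(np.argmin(hist[lo : hi + 1]))
        valley = 0.5 * (edges[valley_bin] + edges[valley_bin + 1])
        assert abs(np.log10(gates.fl1_cut) - valley) < 0.4

    def test_threshold_between_population_medians(self):
        cfg = FlowSimConfig(n_events=8000, seed=3)
        tab, truth = simulate_flow_well(cfg)
        gates = derive_gates([tab])
        fl1 = tab.data["FL1_A"].to_numpy()
        pna_neg = np.isin(truth.event_labels, ["Pi-PNA-", "Pi+PNA-"])
        assert np.median(fl1[pna_neg]) < gates.fl1_cut < np.median(fl1[~pna_neg])

    def test_unimodal_fallback_percentile(self):
        rng = np.random.default_rng(1)
        logv = rng.normal(2, 0.2, 5000)
        gates = derive_gates([_table(10.0**logv, 10.0**logv)])
        assert "fl1_percentile_fallback" in gates.flags
        assert np.log10(gates.fl1_cut) == pytest.approx(np.percentile(logv, 99.5), abs=1e-6)

    def test_too_few_control_events(self):
        with pytest.raises(GatingError, match="pooled control events"):
            derive_gates([_table([100.0] * 10, [100.0] * 10)])

    def test_threshold_stability_across_simulations(self):
        """Gates derived from two independent draws of the same mixture
        agree to better than 0.1 log10 units at large n."""
        g = []
        for seed in (101, 202):
            tab, _ = simulate_flow_well(FlowSimConfig(n_events=20_000, seed=seed))
            g.append(derive_gates([tab]))
        assert abs(np.log10(g[0].fl1_cut) - np.log10(g[1].fl1_cut)) < 0.1
        assert abs(np.log10(g[0].fl3_cut) - np.log10(g[1].fl3_cut)) < 0.1


class TestGating:
    GATES = GateThresholds(fl1_cut=1000.0, fl3_cut=1000.0)

    @pytest.mark.parametrize(
        "fl1, fl3, quadrant",
        [
            (10.0, 10.0, "unstained"),
            (10.0, 5000.0, "dead"),
            (5000.0, 5000.0, "dead_reacted"),
            (5000.0, 10.0, "live_reacted"),
            (1000.0, 1000.0, "unstained"),  # boundary events are negative
        ],
    )
    def test_quadrant_assignment(self, fl1, fl3, quadrant):
        q = gate_events(_table([fl1], [fl3]), self.GATES)
        assert getattr(q, quadrant) == 1 and q.total == 1

    def test_empty_table(self):
        q = gate_events(_table([], []), self.GATES)
        assert q.total == 0

    def test_counts_conserved_and_fractions_match_truth(self):
        cfg = FlowSimConfig(n_events=10_000, seed=5)
        tab, truth = simulate_flow_well(cfg)
        gates = derive_gates([tab])
        q = gate_events(tab, gates)
        assert q.total == 10_000
        expected = {
            "unstained": "Pi-PNA-",
            "dead": "Pi+PNA-",
            "dead_reacted": "Pi+PNA+",
            "live_reacted": "Pi-PNA+",
        }
        for attr, pop in expected.items():
            p = cfg.proportions[POPULATIONS.index(pop)]
            frac = getattr(q, attr) / q.total
            assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / q.total) + 0.01

    def test_gating_monotonicity(self):
        """Raising fl1_cut never increases the PNA-positive count."""
        tab, _ = simulate_flow_well(FlowSimConfig(n_events=3000, seed=6))
        counts = []
        for cut in (10.0, 100.0, 1000.0, 10_000.0, 1e6):
            q = gate_events(tab, GateThresholds(fl1_cut=cut, fl3_cut=1000.0))
            counts.append(q.dead_reacted + q.live_reacted)
        assert counts == sorted(counts, reverse=True)


class TestARWellResult:
    def test_low_event_exclusion(self):
        q = QuadrantCounts("W", 50, 50, 25, 25)   # 150 events, below the floor
        res = ar_well_result(q)
        assert "low_events" in res.qc_flags and res.excluded

    def test_equal_quadrants(self):
        res = ar_well_result(QuadrantCounts("W", 100, 100, 100, 100))
        assert res.unstained_pct == res.dead_pct == res.dead_reacted_pct == res.live_reacted_pct == 25.0
        total = (
            res.unstained_pct + res.dead_pct + res.dead_reacted_pct + res.live_reacted_pct
        )
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_zero_events(self):
        res = ar_well_result(QuadrantCounts("W", 0, 0, 0, 0))
        assert res.excluded and res.total_events == 0

    def test_low_pi_positive_flag(self):
        res = ar_well_result(QuadrantCounts("W", 990, 5, 0, 5))
        assert "low_pi_positive" in res.qc_flags

    def test_ionophore_raises_live_reacted_over_vehicle(self):
        """A23187-style induction shifts events into the live-reacted
        quadrant relative to a vehicle well."""
        base = FlowSimConfig(n_events=4000, seed=7)
        dmso_tab, _ = simulate_flow_well(base, stream(7, 0), well="dmso")
        from spermscreen.simulate import _induced_proportions

        induced = FlowSimConfig(
            n_events=4000,
            proportions=_induced_proportions(base.proportions, 0.3),
            seed=7,
        )
        iono_tab, _ = simulate_flow_well(induced, stream(7, 1), well="iono")
        gates = derive_gates([dmso_tab])
        r_dmso = ar_well_result(gate_events(dmso_tab, gates))
        r_iono = ar_well_result(gate_events(iono_tab, gates))
        assert r_iono.live_reacted_pct > r_dmso.live_reacted_pct + 10


class TestARHits:
    def _result(self, well, live_pct, flags=()):
        from spermscreen.flow import ARWellResult

        return ARWellResult(well, 2000, 100 - live_pct - 30, 20, 10, live_pct,
                            set(flags))

    def test_hit_above_threshold(self):
        df = call_ar_hits([self._result("B02", 65.0)], {"B02": "compound"})
        assert df.loc[0, "call"] == "ar_hit"

    @pytest.mark.parametrize("pct, call", [(14.9, "none"), (15.0, "none"), (15.1, "ar_hit")])
    def test_threshold_strict(self, pct, call):
        df = call_ar_hits([self._result("B02", pct)], {"B02": "compound"})
        assert df.loc[0, "call"] == call

    def test_controls_and_flagged_wells_never_called(self):
        results = [
            self._result("A01", 60.0),
            self._result("B02", 60.0, flags=("low_events",)),
        ]
        df = call_ar_hits(results, {"A01": "a23187", "B02": "compound"})
        assert (df["call"] == "none").all()


class TestTriage:
    def _records(self, n=20, rng=None):
        rng = rng or np.random.default_rng(9)
        return pd.DataFrame(
            {
                "well": [f"A{i + 1:02d}" for i in range(n)],
                "signal_520": rng.normal(1000, 40, n),
                "signal_670": rng.normal(1000, 40, n),
                "nodye_live_reacted_pct": np.abs(rng.normal(1, 0.5, n)),
            }
        )

    def _hits(self, wells):
        return pd.DataFrame(
            {"well": wells, "live_reacted_pct": 40.0, "call": "ar_hit"}
        )

    def test_clean_hit_survives(self):
        rec = self._records()
        rec.loc[0, "signal_520"] = rec["signal_520"].median()
        out = triage_ar_hits(self._hits(["A01"]), rec)
        assert out.loc[0, "survived"]
        assert out.loc[0, "triage_flags"] == ""

    def test_autofluorescent_hit_eliminated(self):
        rec = self._records()
        rec.loc[0, "signal_670"] = 9000.0
        out = triage_ar_hits(self._hits(["A01"]), rec)
        assert not out.loc[0, "survived"]
        assert "autofluorescent" in out.loc[0, "triage_flags"]

    def test_dye_independent_hit_eliminated(self):
        rec = self._records()
        rec.loc[2, "nodye_live_reacted_pct"] = 40.0
        out = triage_ar_hits(self._hits(["A03"]), rec)
        assert not out.loc[0, "survived"]
        assert "dye_independent" in out.loc[0, "triage_flags"]

    def test_missing_record_marked_untriaged_but_retained(self):
        out = triage_ar_hits(self._hits(["Z99"]), self._records())
        assert out.loc[0, "survived"]
        assert out.loc[0, "triage_flags"] == "untriaged"

    def test_soundness_no_interference_no_elimination(self):
        """Wells with unremarkable reader signals and clean no-dye
        replicates are never eliminated."""
        rec = self._records(n=40)
        wells = list(rec["well"][:10])
        out = triage_ar_hits(self._hits(wells), rec)
        assert out["survived"].all()

    def test_all_hits_interfering_none_survive(self):
        """A screen whose apparent AR hits are all interference compounds
        ends with zero confirmed hits after triage."""
        rec = self._records(n=30)
        hit_wells = list(rec["well"][:5])
        rec.loc[rec["well"].isin(hit_wells[:3]), "signal_520"] = 12_000.0
        rec.loc[rec["well"].isin(hit_wells[3:]), "nodye_live_reacted_pct"] = 35.0
        out = triage_ar_hits(self._hits(hit_wells), rec)
        assert len(out) == 5
        assert not out["survived"].any()
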