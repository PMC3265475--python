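"""Digital-trace algebra, gate logic and motif configuration validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscimotif.motifs import (
    FFL_SIGN_TABLE,
    DigitalTrace,
    GeneStage,
    MotifConfig,
    MotifError,
    RegulatoryEdge,
    digitize,
    gate_combine,
    synthesis_rate_trace,
)
from oscimotif.signals import PeriodicSignal


def _trace(window, switches, initial):
    return DigitalTrace(window, switches, initial)


@st.composite
def digital_traces(draw, window=(0.0, 10.0)):
    n = draw(st.integers(0, 8))
    times = sorted(
        draw(
            st.lists(
                st.floats(window[0] + 0.01, window[1] - 0.01),
                min_size=n, max_size=n, unique=True,
            )
        )
    )
    # enforce strict separation so traces are non-degenerate
    ok = [t for i, t in enumerate(times) if i == 0 or t - times[i - 1] > 1e-6]
    return DigitalTrace(window, ok, draw(st.integers(0, 1)))


class TestDigitalTrace:
    def test_states_partition_window(self):
        tr = _trace((0, 10), [2.0, 5.0, 7.0], 0)
        spans = tr.states()
        assert spans[0][0] == 0 and spans[-1][1] == 10
        assert sum(b - a for a, b, _ in spans) == pytest.approx(10.0)
        assert [s for _, _, s in spans] == [0, 1, 0, 1]

    def test_value_right_continuous_at_switch(self):
        tr = _trace((0, 10), [2.0], 0)
        assert tr.value(2.0) == 1
        assert tr.value(1.999999) == 0

    def test_measure_counts_on_time(self):
        tr = _trace((0, 10), [2.0, 5.0], 0)
        assert tr.measure(1) == pytest.approx(3.0)
        assert tr.measure(0) == pytest.approx(7.0)

    def test_unsorted_switches_rejected(self):
        with pytest.raises(MotifError):
            _trace((0, 10), [5.0, 2.0], 0)


class TestDigitize:
    def test_left_skewed_threshold_interval(self, profiles):
        sig = PeriodicSignal(profiles["left_skewed"], 1.0)
        edge = RegulatoryEdge("X", "Y", threshold=0.1)
        tr = digitize(sig, edge, (0.0, 1.0))
        assert tr.intervals(1) == [(0.05, 0.8)]

    def test_threshold_above_max_constant_zero(self, profiles):
        sig = PeriodicSignal(profiles["symmetric"], 1.0)
        tr = digitize(sig, RegulatoryEdge("X", "Y", 2.0), (0.0, 3.0))
        assert tr.switch_times.size == 0 and tr.initial_state == 0

    def test_threshold_above_max_active_below_constant_one(self, profiles):
        sig = PeriodicSignal(profiles["symmetric"], 1.0)
        tr = digitize(sig, RegulatoryEdge("X", "Y", 2.0, "active_below"), (0.0, 3.0))
        assert tr.switch_times.size == 0 and tr.initial_state == 1

    def test_period_stretch_scales_switch_times(self, profiles):
        edge = RegulatoryEdge("X", "Y", 0.5)
        t1 = digitize(PeriodicSignal(profiles["symmetric"], 1.0), edge, (0, 1))
        t3 = digitize(PeriodicSignal(profiles["symmetric"], 3.0), edge, (0, 3))
        assert np.allclose(t3.switch_times, 3.0 * t1.switch_times, rtol=1e-12)

    def test_matches_dense_sampling_conjunction(self, profiles):
        # CFFL-1 style drive: AND of direct and intermediate-threshold digital
        # signals agrees with pointwise conjunction sampled at 1e-5 resolution.
        sig = PeriodicSignal(profiles["symmetric"], 1.0)
        a = digitize(sig, RegulatoryEdge("X", "Z", 0.75), (0.0, 2.0))
        b = digitize(sig, RegulatoryEdge("X", "Y", 0.1), (0.0, 2.0))
        g = gate_combine("AND", a, b)
        ts = np.arange(0.0, 2.0, 1e-5) + 3e-6  # avoid exact switch instants
        expect = (np.asarray(sig(ts)) > 0.75) & (np.asarray(sig(ts)) > 0.1)
        assert np.array_equal(np.asarray(g.value(ts), bool), expect)


class TestGateCombine:
    @given(a=digital_traces())
    @settings(max_examples=30, deadline=None)
    def test_idempotence(self, a):
        for gate in ("AND", "OR"):
            g = gate_combine(gate, a, a)
            assert g.initial_state == a.initial_state
            assert np.allclose(g.switch_times, a.switch_times)

    @given(a=digital_traces())
    @settings(max_examples=30, deadline=None)
    def test_complement_annihilates_and(self, a):
        g = gate_combine("AND", a, a.complement())
        assert g.initial_state == 0 and g.switch_times.size == 0

    @given(a=digital_traces(), b=digital_traces())
    @settings(max_examples=50, deadline=None)
    def test_de_morgan(self, a, b):
        lhs = gate_combine("AND", a, b).complement()
        rhs = gate_combine("OR", a.complement(), b.complement())
        assert lhs.initial_state == rhs.initial_state
        assert np.allclose(lhs.switch_times, rhs.switch_times)

    def test_mismatched_windows_rejected(self):
        with pytest.raises(MotifError, match="window"):
            gate_combine("AND", _trace((0, 5), [], 0), _trace((0, 6), [], 0))


class TestSynthesisRateTrace:
    def test_constant_drives(self, stage):
        on = synthesis_rate_trace(stage, _trace((0, 4), [], 1))
        off = synthesis_rate_trace(stage, _trace((0, 4), [], 0))
        assert on == [(0, 4, stage.synth_on)]
        assert off == [(0, 4, stage.synth_off)]

    def test_alternating_drive_switches_rate(self, stage):
        tr = synthesis_rate_trace(stage, _trace((0, 4), [1.0, 3.0], 0))
        assert [r for _, _, r in tr] == [
            stage.synth_off, stage.synth_on, stage.synth_off,
        ]


def _ffl_config(signs, gate="AND"):
    s_xy, s_yz, s_xz = signs
    y = GeneStage("Y", synth_off=0.2 if s_xy < 0 else 0.0,
                  synth_on=0.0 if s_xy < 0 else 1.0, degradation=1.0)
    z = GeneStage("Z", 0.0, 1.0, 1.0)
    edges = (
        RegulatoryEdge("X", "Y", 0.5, "active_above"),
        RegulatoryEdge("X", "Z", 0.5, "active_above" if s_xz > 0 else "active_below"),
        RegulatoryEdge("Y", "Z", 0.3, "active_above" if s_yz > 0 else "active_below"),
    )
    ffl_type = next(k for k, v in FFL_SIGN_TABLE.items() if v == tuple(signs))
    return MotifConfig(
        topology="ffl", stages={"Y": y, "Z": z}, edges=edges,
        ffl_type=ffl_type, gate=gate,
    )


class TestMotifConfig:
    @pytest.mark.parametrize("ffl_type, signs", sorted(FFL_SIGN_TABLE.items()))
    def test_all_eight_ffl_types_instantiate_and_self_validate(
        self, ffl_type, signs
    ):
        cfg = _ffl_config(signs)
        assert cfg.ffl_type == ffl_type
        s_xy, s_yz, s_xz = cfg.derived_signs()
        # coherent iff the two paths carry the same net sign
        assert cfg.is_coherent == (s_xy * s_yz == s_xz)
        assert cfg.is_coherent == (ffl_type <= 4)

    def test_mismatched_type_rejected(self):
        with pytest.raises(MotifError, match="ffl_type"):
            cfg = _ffl_config(FFL_SIGN_TABLE[1])
            MotifConfig(
                topology="ffl", stages=cfg.stages, edges=cfg.edges,
                ffl_type=5, gate="AND",
            )

    def test_cyclic_edges_rejected(self, stage):
        edges = (
            RegulatoryEdge("X", "Y", 0.5),
            RegulatoryEdge("Y", "Z", 0.5),
            RegulatoryEdge("Z", "Y", 0.5),
        )
        with pytest.raises(MotifError, match="cyclic|requires edges"):
            MotifConfig(
                topology="ffl",
                stages={"Y": stage, "Z": GeneStage("Z", 0.0, 1.0, 1.0)},
                edges=edges, ffl_type=1, gate="AND",
            )

    def test_zero_degradation_rejected(self):
        with pytest.raises(MotifError, match="degradation"):
            GeneStage("Y", 0.0, 1.0, 0.0)

    def test_direct_requires_single_edge(self, stage):
        with pytest.raises(MotifError, match="requires edges"):
            MotifConfig(
                topology="direct", stages={"Y": stage},
                edges=(RegulatoryEdge("X", "Y", 0.5), RegulatoryEdge("Y", "Z", 0.5)),
            )
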