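"""Beat segmentation, transit-time series and the six response metrics."""

import numpy as np
import pytest

from cuffsim import (
    BeatSeries,
    CircuitParams,
    CuffProtocol,
    PTTSeries,
    SystemicInput,
    beats_from_batch,
    compute_ptt_series,
    detect_onset,
    equilibrium_closed_form,
    extract_metrics,
    metrics_matrix,
    occlusion_time,
    segment_beats,
    simulate,
    simulate_batch,
)
from cuffsim.beat_metrics import (
    ONSET_MAP_THRESHOLD_MMHG,
    _first_sustained,
    _metrics_arrays,
)


class TestSegmentBeats:
    def test_beat_count_and_order_statistics(self, reference_beats):
        beats = reference_beats
        assert beats.n_beats >= 80
        assert np.all(beats.dbp <= beats.map + 1e-9)
        assert np.all(beats.map <= beats.sbp + 1e-9)
        # consecutive trough-aligned windows, one per cardiac period
        assert np.allclose(np.diff(beats.t_start), 1.0)

    def test_stationary_baseline(self, reference_beats):
        base = reference_beats.baseline_index()
        assert len(base) == 5
        assert np.ptp(reference_beats.map[base]) < 0.2

    def test_requires_two_beats(self, reference_run, reference_input):
        import dataclasses

        short = dataclasses.replace(
            reference_run,
            time=reference_run.time[:1000],
            p_art_sys=reference_run.p_art_sys[:1000],
            p_cuff=reference_run.p_cuff[:1000],
            p_art_distal=reference_run.p_art_distal[:1000],
            p_ven_distal=reference_run.p_ven_distal[:1000],
        )
        with pytest.raises(ValueError):
            segment_beats(short, reference_input)


class TestPTTSeries:
    def test_decomposition_identity(self, reference_ptt):
        """The total PAT change is exactly the sum of its cuff and distal
        components wherever the pulse transmits."""
        tr = reference_ptt.transmitting
        np.testing.assert_array_equal(
            reference_ptt.dpat_total[tr],
            (reference_ptt.dptt_cuff + reference_ptt.dptt_distal)[tr],
        )

    def test_baseline_beats_are_zero(self, reference_beats, reference_ptt):
        base = reference_beats.baseline_index()
        assert np.all(np.abs(reference_ptt.dptt_cuff[base]) < 0.02)
        assert np.all(np.abs(reference_ptt.dptt_distal[base]) < 0.02)

    def test_distal_ptt_drops_while_dbp_elevated(
        self, reference_beats, reference_ptt
    ):
        """Distal filling raises distal DBP, which stiffens the distal artery
        and speeds up propagation: dPTT_distal goes negative."""
        elevated = reference_beats.dbp > reference_beats.sys_dbp + 2.0
        assert elevated.any()
        assert reference_ptt.dptt_distal[elevated].min() < -0.5

    def test_transmission_ends_at_systolic_cuff_pressure(
        self, reference_beats, reference_ptt
    ):
        above = reference_beats.p_cuff >= reference_beats.sys_sbp
        assert not reference_ptt.transmitting[above].any()
        assert reference_ptt.transmitting[~above].all()


class TestOnsetDetection:
    @staticmethod
    def _fake_series(dptt):
        dptt = np.asarray(dptt, dtype=float)
        n = len(dptt)
        beats = BeatSeries(
            t_start=np.arange(n, dtype=float),
            sbp=np.full(n, 110.0),
            dbp=np.full(n, 80.0),
            map=np.full(n, 95.0),
            p_cuff=np.arange(n, dtype=float) * 6.0,
            sys_dbp=np.asarray(80.0),
            sys_sbp=np.asarray(120.0),
            sys_map=np.asarray(100.0),
        )
        ptt = PTTSeries(
            dptt_cuff=np.zeros(n),
            dptt_distal=dptt,
            dpat_total=dptt,
            transmitting=np.ones(n, dtype=bool),
            t_cuff=np.zeros(n),
            t_distal=np.zeros(n),
        )
        return beats, ptt

    def test_flat_series_has_no_onset(self):
        beats, ptt = self._fake_series(np.zeros(20))
        assert detect_onset(beats, ptt) is None

    def test_sustained_step_detected_at_first_beat(self):
        d = np.zeros(20)
        d[7:] = -1.0  # crosses the threshold at beat 7 and stays
        beats, ptt = self._fake_series(d)
        idx, p_cuff = detect_onset(beats, ptt)
        assert idx == 7
        assert p_cuff == pytest.approx(42.0)

    def test_transient_dip_ignored(self):
        d = np.zeros(20)
        d[5] = -1.0  # one-beat glitch, not sustained
        beats, ptt = self._fake_series(d)
        assert detect_onset(beats, ptt) is None

    def test_first_sustained_helper(self):
        cond = np.array([0, 0, 1, 1, 0, 1, 1, 1, 1], dtype=bool)
        assert _first_sustained(cond, 3) == 5
        assert _first_sustained(cond, 5) == -1

    def test_onset_simultaneous_with_map_rise(
        self, reference_beats, reference_ptt
    ):
        """The distal-PTT onset and the distal-MAP onset mark the same event
        (within two beats): both are signatures of the filling effect."""
        idx_ptt, _ = detect_onset(reference_beats, reference_ptt)
        base = reference_beats.baseline_index()
        map_rise = (
            reference_beats.map - reference_beats.map[base].mean()
            > ONSET_MAP_THRESHOLD_MMHG
        )
        idx_map = _first_sustained(map_rise, 3)
        assert abs(idx_ptt - idx_map) <= 2


class TestExtractMetrics:
    def test_reference_metrics_sanity(self, reference_metrics):
        m = reference_metrics
        assert m.max_dptt_distal_ms > 1.0
        assert m.max_dpat_total_ms > 5.0
        assert m.max_dmap_mmhg > 1.0
        assert m.max_ddbp_mmhg > 5.0
        assert 20.0 < m.p_eq_mmhg < 60.0
        assert np.isfinite(m.dptt_onset_mmhg)

    def test_p_eq_matches_conservation_closed_form(
        self, reference_run, reference_input, reference_metrics
    ):
        """After full occlusion the compliance-weighted charge is conserved,
        so P_eq must equal the closed-form weighted average at occlusion."""
        circuit = CircuitParams()
        tocc = occlusion_time(reference_run, reference_input)
        i = np.searchsorted(reference_run.time, tocc)
        expected = equilibrium_closed_form(
            reference_run.p_art_distal[i], reference_run.p_ven_distal[i], circuit
        )
        assert reference_metrics.p_eq_mmhg == pytest.approx(expected, abs=0.5)

    def test_distal_map_bounded_by_systolic(self, reference_beats, reference_input):
        """Every pressure source feeding the distal node is bounded by SBP,
        so the distal pressure can never exceed it."""
        assert reference_beats.sbp.max() <= reference_input.sbp + 0.5

    def test_short_hold_fails_p_eq_guard(self, reference_input):
        proto = CuffProtocol(hold_s=3.0)
        res = simulate(reference_input, proto, dt=1e-3)
        beats = segment_beats(res, reference_input)
        ptt = compute_ptt_series(beats)
        with pytest.raises(ValueError, match="drift"):
            extract_metrics(res, beats, ptt, reference_input)

    def test_slower_inflation_more_pronounced_distal_effect(self):
        """Slower inflations pump more blood into the occluded limb: larger
        distal MAP rise and higher equilibrium pressure."""
        inp = SystemicInput()
        run = simulate_batch(
            sbp=inp.sbp, pp=inp.pp, rate=[4.0, 8.0],
            a=0.03, c=0.1, d=0.08, cuff_length_m=0.14, dt=1e-3,
        )
        beats = beats_from_batch(run, inp.sbp, inp.pp, inp)
        metrics = metrics_matrix(run, beats, compute_ptt_series(beats))
        dmap, p_eq = metrics[:, 2], metrics[:, 3]
        assert dmap[0] > dmap[1]
        assert p_eq[0] > p_eq[1]

    def test_longer_cuff_larger_pat_change(self):
        inp = SystemicInput()
        run = simulate_batch(
            sbp=inp.sbp, pp=inp.pp, rate=6.0,
            a=0.03, c=0.1, d=0.08, cuff_length_m=[0.10, 0.18], dt=1e-3,
        )
        beats = beats_from_batch(run, inp.sbp, inp.pp, inp)
        from cuffsim.mechanics import ArmGeometry

        geometry = ArmGeometry(cuff_length_m=np.array([0.10, 0.18]))
        metrics = metrics_matrix(
            run, beats, compute_ptt_series(beats, geometry)
        )
        assert metrics[1, 1] > metrics[0, 1]

    def test_batch_metrics_match_single_run(
        self, reference_run, reference_beats, reference_ptt,
        reference_metrics, reference_input,
    ):
        run = simulate_batch(
            sbp=[120.0], pp=[40.0], rate=[6.0],
            a=[0.03], c=[0.1], d=0.08, cuff_length_m=[0.14], dt=5e-4,
        )
        beats = beats_from_batch(run, [120.0], [40.0], reference_input)
        mm = metrics_matrix(run, beats, compute_ptt_series(beats))
        single = np.array(list(reference_metrics.as_dict().values()))
        np.testing.assert_allclose(mm[0], single, atol=0.01)
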