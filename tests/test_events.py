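"""Event-calling filter tests and Gaussian-sum mixture fitting."""
import numpy as np
import pytest

from replicycle import events as ev
from conftest import make_toy_supercell, make_track


class TestCallInitiations:
    def test_clean_track_called(self):
        sc = make_toy_supercell()
        tracks = [make_track(0, start=5, length=11)]
        evs = ev.call_initiations(tracks, sc)
        assert len(evs) == 1
        assert evs[0].frame == 5
        assert evs[0].supercell_area == pytest.approx(
            sc.area_at_frame(5))

    def test_short_track_rejected(self):
        sc = make_toy_supercell()
        evs = ev.call_initiations([make_track(0, start=5, length=10)], sc)
        assert evs == []

    def test_acetate_preset_accepts_nine(self):
        sc = make_toy_supercell()
        tracks = [make_track(0, start=5, length=9)]
        assert ev.call_initiations(tracks, sc) == []
        evs = ev.call_initiations(
            tracks, sc, min_track_len=ev.PRESETS["acetate"]["min_track_len"])
        assert len(evs) == 1

    def test_toy_filter_enumeration(self):
        """Five candidate starts -> two initiations: length-10 too short,
        frame-1 start in the edge zone, split-born start excluded."""
        sc = make_toy_supercell()
        tracks = [
            make_track(0, start=5, length=12),
            make_track(1, start=20, length=11),
            make_track(2, start=30, length=10),
            make_track(3, start=1, length=12),
            make_track(4, start=40, length=15, split_born=True),
        ]
        counts = {}
        evs = ev.call_initiations(tracks, sc, counts=counts)
        assert len(evs) == 2
        assert {e.track_id for e in evs} == {0, 1}
        assert counts == {"accepted": 2, "split_born": 1, "too_short": 1,
                          "edge": 1, "qc": 0}
        # conservation of candidates
        assert sum(counts.values()) == len(tracks)

    def test_bad_qc_near_start_rejected(self):
        sc = make_toy_supercell(qc_bad_frames=(6,))
        evs = ev.call_initiations([make_track(0, start=5, length=11)], sc)
        assert evs == []
        # same track away from the bad frame is fine
        evs2 = ev.call_initiations([make_track(0, start=10, length=11)], sc)
        assert len(evs2) == 1

    def test_filters_switchable(self):
        sc = make_toy_supercell()
        tracks = [make_track(0, start=1, length=5)]
        evs = ev.call_initiations(tracks, sc, min_track_len=None,
                                  edge_exclusion=None, qc_window=None)
        assert len(evs) == 1


class TestCallTerminations:
    def test_end_on_last_frames_rejected(self):
        sc = make_toy_supercell()
        last = sc.last_frame
        tracks = [make_track(0, start=last - 15, length=16, cell_id="c2")]
        assert ev.call_terminations(tracks, sc) == []

    def test_toy_enumeration(self):
        """Four track ends -> two terminations: inside the daughter cell,
        6 px off midcell for a round initiated close to division, a clean
        mid-supercell end, and one consumed by a merge."""
        sc = make_toy_supercell()
        g1 = sc.generations[1]
        g0 = sc.generations[0]
        # (a) ends inside generation-1 cell, started mid generation 0
        in_g1 = 0.5 * (g1.seg_lo + g1.seg_hi) * g1.A_t[5]
        a = make_track(0, start=g0.frames[5], length=41, coord=in_g1,
                       cell_id="c1")
        # (b) started close to g0's division, ends 6 px from g1 midcell
        mid_g1 = 0.5 * (g1.seg_lo + g1.seg_hi) * g1.A_t[10]
        b = make_track(1, start=g0.frames[-4], length=15,
                       coord=mid_g1 + 6 * 0.08, cell_id="c1")
        # (c) clean end mid-supercell, inside generation 0
        in_g0 = 0.5 * (g0.seg_lo + g0.seg_hi) * g0.A_t[20]
        c = make_track(2, start=5, length=16, coord=in_g0, cell_id="c0")
        # (d) merged away
        d = make_track(3, start=g0.frames[5], length=20, coord=in_g0,
                       merged=True, cell_id="c0")
        counts = {}
        evs = ev.call_terminations([a, b, c, d], sc,
                                   close_to_div_frames=10, counts=counts)
        assert len(evs) == 2
        assert {e.track_id for e in evs} == {0, 2}
        assert counts["merged"] == 1 and counts["midcell"] == 1
        assert sum(counts.values()) == 4

    def test_end_within_tolerance_accepted(self):
        sc = make_toy_supercell()
        g0 = sc.generations[0]
        g1 = sc.generations[1]
        mid_g1 = 0.5 * (g1.seg_lo + g1.seg_hi) * g1.A_t[10]
        tr = make_track(0, start=g0.frames[-4], length=15,
                        coord=mid_g1 + 0.3, cell_id="c1")
        evs = ev.call_terminations([tr], sc, midcell_tol_px=5.0,
                                   pixel_size=0.08, close_to_div_frames=10)
        assert len(evs) == 1  # 0.3 µm < 5 px * 0.08 µm/px = 0.4 µm


def test_filter_supercells_requires_both_event_types():
    sc_a = make_toy_supercell()
    sc_b = make_toy_supercell()
    sc_b.supercell_id = 1
    ev_i = ev.ReplicationEvent("initiation", 0, 5, 10.0, 1.0, 0, 0, 0)
    ev_t = ev.ReplicationEvent("termination", 0, 30, 60.0, 1.5, 0, 0, 0)
    ev_i2 = ev.ReplicationEvent("initiation", 1, 5, 10.0, 1.0, 0, 0, 0)
    kept, kept_evs, report = ev.filter_supercells(
        {0: [ev_i, ev_t], 1: [ev_i2, ev_i2]}, [sc_a, sc_b])
    assert [sc.supercell_id for sc in kept] == [0]
    assert report == {"total": 2, "kept": 1, "dropped": 1}


class TestMixtureFit:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(8)
        s = rng.normal(2.0, 0.2, 5000)
        fit = ev.fit_initiation_size_mixture(s)
        assert fit.k == 1
        assert fit.means[0] == pytest.approx(2.0, abs=0.01)
        assert fit.cvs[0] == pytest.approx(0.10, abs=0.01)

    def test_two_separated_components_ordered(self):
        rng = np.random.default_rng(9)
        s = np.concatenate([rng.normal(2.0, 0.2, 3000),
                            rng.normal(4.0, 0.3, 3000)])
        fit = ev.fit_initiation_size_mixture(s)
        assert fit.k == 2
        assert fit.means[0] == pytest.approx(2.0, abs=0.05)
        assert fit.means[1] == pytest.approx(4.0, abs=0.05)

    def test_four_rounds_doubling_means(self):
        """Supercells spanning four replication rounds: four components with
        successive means ~2x apart."""
        rng = np.random.default_rng(10)
        s = np.concatenate([rng.normal(m, 0.09 * m, 2000)
                            for m in (1.0, 2.0, 4.0, 8.0)])
        fit = ev.fit_initiation_size_mixture(s)
        assert fit.k == 4
        ratios = fit.means[1:] / fit.means[:-1]
        assert np.allclose(ratios, 2.0, atol=0.15)
        # central component far from the span edges
        assert fit.central_index in (1, 2)

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(11)
        s = np.concatenate([rng.normal(m, 0.09 * m, 2000)
                            for m in (1.0, 2.0, 4.0)])
        f1 = ev.fit_initiation_size_mixture(s)
        f2 = ev.fit_initiation_size_mixture(s * 3.7)
        assert np.allclose(f1.cvs, f2.cvs, atol=1e-6)
        assert np.allclose(f2.means, 3.7 * f1.means, rtol=1e-6)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            ev.fit_initiation_size_mixture(np.ones(30))
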