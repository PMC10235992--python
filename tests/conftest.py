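"""Shared fixtures: simulation runs reused across the suite.

Heavy simulations are session-scoped so each study condition is generated
once; all randomness is fixed-seeded for reproducible assertions.
"""
import numpy as np
import pandas as pd
import pytest

from replicycle import events as ev
from replicycle import lineage as lin
from replicycle import simulate as sim


@pytest.fixture(scope="session")
def adder_truth():
    """Large adder-model run under the consecutive-initiation study
    conditions: symmetric division, delta_cv 0.15, growth_rate_cv 0.05."""
    cfg = sim.SimConfig(control_model="adder", n_lineages=700,
                        n_generations=3, division_fraction_sd=0.0,
                        burnin_generations=4, seed=11)
    _, truth = sim.simulate_lineages(cfg, frames=False)
    return cfg, truth


@pytest.fixture(scope="session")
def sizer_truth():
    cfg = sim.SimConfig(control_model="sizer", n_lineages=700,
                        n_generations=3, division_fraction_sd=0.0,
                        burnin_generations=4, seed=12)
    _, truth = sim.simulate_lineages(cfg, frames=False)
    return cfg, truth


@pytest.fixture(scope="session")
def imaging_run():
    """Full imaging pipeline inputs: frames, near-perfect detections and
    assembled supercells (detection_prob 0.97, small jitter)."""
    cfg = sim.SimConfig(control_model="adder", n_lineages=25,
                        n_generations=5, seed=21)
    cells, truth = sim.simulate_lineages(cfg)
    img = sim.ImagingConfig(detection_prob=0.97, position_jitter_sd=0.03,
                            false_positive_rate=0.0)
    det = sim.emulate_detections(cells, truth, img, seed=22)
    scs = lin.build_supercells(cells, n_generations=3, min_frames=8)
    return cells, truth, det, scs


# ---------------------------------------------------------------------------
# toy supercell / track builders for the event-filter tests
# ---------------------------------------------------------------------------

def make_toy_supercell(frames_per_gen=(40, 40, 40), area0=1.0,
                       growth_per_frame=1.02, qc_bad_frames=()):
    """A 3-generation supercell with exact symmetric division."""
    gens = []
    frame0 = 0
    a_birth = area0
    A_last = 0.0
    for i, nf in enumerate(frames_per_gen):
        frames = np.arange(frame0, frame0 + nf)
        areas = a_birth * growth_per_frame ** np.arange(nf)
        if i == 0:
            A_t = areas.copy()
        else:
            A_t = A_last + 2.0 ** i * (areas - 0.5 * a_p_last)
        qc = np.array([f not in qc_bad_frames for f in frames])
        gens.append(lin._Gen(cell_id=f"c{i}", generation_index=i,
                             frames=frames, times=frames * 2.0, areas=areas,
                             lengths=areas, qc=qc, dfrac=0.5, A_last=A_last,
                             A_t=A_t))
        a_p_last = areas[-1]
        A_last = float(A_t[-1])
        a_birth = 0.5 * a_p_last
        frame0 += nf
    lo, hi = 0.0, 1.0
    for i, g in enumerate(gens):
        if i > 0:
            hi = lo + 0.5 * (hi - lo)
        g.seg_lo, g.seg_hi = lo, hi
    return lin.SuperCell(supercell_id=0, lineage_id=0, generations=gens)


def make_track(track_id, start, length, coord=0.5, split_born=False,
               merged=False, cell_id="c0", coords=None):
    from replicycle.tracking import FocusTrack
    tr = FocusTrack(track_id=track_id)
    tr.frames = list(range(start, start + length))
    cs = [coord] * length if coords is None else list(coords)
    tr.coords = cs
    tr.cell_ids = [cell_id] * length
    tr.interpolated = [False] * length
    tr.split_born = split_born
    tr.merged_into = 99 if merged else None
    return tr
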