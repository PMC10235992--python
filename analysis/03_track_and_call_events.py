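#!/usr/bin/env python
"""Link foci into tracks within each supercell and call replication events.

Track starts that survive the length/edge/QC filters are initiations; track
ends away from the supercell edges that lie in the daughter cell (or at
midcell for rounds initiated close to division) are terminations.  The
initiation-size distribution is then fitted with a sum of Gaussians, one
per distinct peak.
"""
from pathlib import Path

import pandas as pd

from replicycle import events as ev, io, lineage as lin, tracking as trk

ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main():
    cells = io.read_tsv(RUN / "cells.tsv")
    det = io.read_tsv(RUN / "detections.tsv")
    scs = lin.build_supercells(cells, n_generations=3, min_frames=8)
    all_tracks, by_sc = [], {}
    i_counts, t_counts = {}, {}
    for sc in scs:
        mapped = lin.map_detections_to_supercell(det, sc)
        tracks = trk.link_detections(mapped)
        all_tracks.append(trk.tracks_to_table(tracks, sc.supercell_id))
        evs = ev.call_initiations(tracks, sc, counts=i_counts)
        evs += ev.call_terminations(tracks, sc, counts=t_counts)
        by_sc[sc.supercell_id] = evs
    io.write_tsv(pd.concat(all_tracks, ignore_index=True),
                 RUN / "tracks.tsv")
    kept, kept_evs, report = ev.filter_supercells(by_sc, scs)
    events = [e for evs in kept_evs.values() for e in evs]
    io.write_tsv(ev.events_to_table(events), RESULTS / "events.tsv")
    print(f"initiation filters: {i_counts}")
    print(f"termination filters: {t_counts}")
    print(f"supercells kept (>=1 initiation and termination): "
          f"{report['kept']}/{report['total']}")

    sizes = [e.supercell_area for e in events if e.event_type == "initiation"]
    fit = ev.fit_initiation_size_mixture(sizes)
    doc = {"k": fit.k, "means_um2": [round(m, 3) for m in fit.means],
           "cvs": [round(c, 3) for c in fit.cvs],
           "weights": [round(w, 3) for w in fit.weights],
           "central_component": fit.central_index}
    io.write_json(doc, RESULTS / "mixture.json")
    print(f"initiation-size mixture: k={fit.k}, means "
          f"{[float(round(m, 2)) for m in fit.means]} µm² "
          f"(successive rounds double), central CV "
          f"{fit.central_cv:.3f}")


if __name__ == "__main__":
    main()
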