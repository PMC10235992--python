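"""Link foci detections within a supercell into tracks.

Track starts and ends are the candidate replication initiation and
termination events consumed by the events module.  The linker is a greedy
reciprocal nearest-neighbour assignment on the supercell long-axis
coordinate, frame by frame, with gap closing (a track missing detections for
up to ``max_gap`` frames may be resumed), proximity-based merging (a track
converging onto another within ``merge_radius`` is marked merged and its end
is not a termination candidate) and split detection (a new track appearing
within ``merge_radius`` of a live track is flagged split-born and its start
is not an initiation candidate).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FocusTrack", "link_detections", "tracks_to_table"]


@dataclass
class FocusTrack:
    track_id: int
    frames: list = field(default_factory=list)
    coords: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    interpolated: list = field(default_factory=list)
    merged_into: int | None = None  # end consumed by a merge
    split_born: bool = False

    @property
    def start_frame(self) -> int:
        return self.frames[0]

    @property
    def end_frame(self) -> int:
        return self.frames[-1]

    @property
    def length(self) -> int:
        """Track length in frames (span, gap-closed frames included)."""
        return self.end_frame - self.start_frame + 1

    @property
    def start_coord(self) -> float:
        return self.coords[0]

    @property
    def end_coord(self) -> float:
        return self.coords[-1]


def link_detections(detections: pd.DataFrame, max_disp: float = 0.5,
                    max_gap: int = 2, merge_radius: float = 0.25) -> list:
    """Link a supercell's detections (columns ``frame``, ``coord_um`` and
    optionally ``cell_id``) into :class:`FocusTrack` objects.

    Links minimise displacement greedily with a reciprocal nearest-neighbour
    check; a frame-to-frame displacement larger than ``max_disp`` µm per
    elapsed frame is never linked.  Detections are processed in a canonical
    order, so the result is independent of input row order.
    """
    if detections.empty:
        return []
    det = detections.sort_values(["frame", "coord_um"],
                                 kind="mergesort").reset_index(drop=True)
    has_cell = "cell_id" in det.columns
    frames = det["frame"].to_numpy()
    coords = det["coord_um"].to_numpy(dtype=float)
    cells = det["cell_id"].to_numpy() if has_cell else np.full(len(det), "")

    tracks: list[FocusTrack] = []
    open_tracks: list[FocusTrack] = []  # may still be extended

    for f in np.unique(frames):
        sel = np.nonzero(frames == f)[0]
        pts = coords[sel]
        # candidate tracks: last detection within the allowed gap window
        cand = [tr for tr in open_tracks
                if tr.merged_into is None and 0 < f - tr.end_frame <= max_gap + 1]
        # cost matrix: displacement, invalid if above per-frame budget
        pairs = []
        for ti, tr in enumerate(cand):
            dt = f - tr.end_frame
            for pi, p in enumerate(pts):
                d = abs(p - tr.end_coord)
                if d <= max_disp * dt:
                    pairs.append((d, tr.track_id, ti, pi))
        pairs.sort()
        assigned_t: set = set()
        assigned_p: set = set()
        links = []
        # greedy reciprocal nearest neighbour: repeatedly take the globally
        # cheapest remaining pair (it is mutual-nearest among what is left)
        for d, _tid, ti, pi in pairs:
            if ti in assigned_t or pi in assigned_p:
                continue
            assigned_t.add(ti)
            assigned_p.add(pi)
            links.append((ti, pi))
        linked_pts = {pi for _, pi in links}
        # merges: an unassigned candidate track converging within
        # merge_radius of a linked detection is consumed; the merged
        # continuation extends the longer of the two tracks
        for ti, tr in enumerate(cand):
            if ti in assigned_t:
                continue
            for li, (lti, pi) in enumerate(links):
                if abs(pts[pi] - tr.end_coord) <= merge_radius:
                    other = cand[lti]
                    if tr.length > other.length:
                        # reassign the continuation to the longer track
                        links[li] = (ti, pi)
                        other.merged_into = tr.track_id
                    else:
                        tr.merged_into = other.track_id
                    break
        # extend linked tracks (fill gap frames by linear interpolation)
        for ti, pi in links:
            tr = cand[ti]
            gap = f - tr.end_frame
            if gap > 1:
                c0, c1 = tr.end_coord, pts[pi]
                for k in range(1, gap):
                    tr.frames.append(tr.end_frame + 1)
                    tr.coords.append(c0 + (c1 - c0) * k / gap)
                    tr.cell_ids.append(tr.cell_ids[-1])
                    tr.interpolated.append(True)
            tr.frames.append(int(f))
            tr.coords.append(float(pts[pi]))
            tr.cell_ids.append(cells[sel[pi]])
            tr.interpolated.append(False)
        # new tracks for unlinked detections; flag split-born starts
        live_coords = [(tr.end_coord, tr) for tr in cand
                       if tr.merged_into is None]
        for pi, p in enumerate(pts):
            if pi in linked_pts:
                continue
            tr = FocusTrack(track_id=len(tracks))
            tr.frames.append(int(f))
            tr.coords.append(float(p))
            tr.cell_ids.append(cells[sel[pi]])
            tr.interpolated.append(False)
            tr.split_born = any(abs(p - c) <= merge_radius
                                for c, _ in live_coords)
            tracks.append(tr)
            open_tracks.append(tr)
        open_tracks = [tr for tr in open_tracks
                       if tr.merged_into is None and f - tr.end_frame <= max_gap]
    return tracks


def tracks_to_table(tracks: list, supercell_id: int | None = None) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for k in range(len(tr.frames)):
            rows.append((tr.track_id, supercell_id, tr.frames[k],
                         tr.coords[k], tr.cell_ids[k],
                         int(tr.interpolated[k]),
                         int(tr.merged_into is not None), int(tr.split_born)))
    return pd.DataFrame(rows, columns=["track_id", "supercell_id", "frame",
                                       "coord_um", "cell_id", "interpolated",
                                       "merged", "split_born"])
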