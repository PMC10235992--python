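"""Supercell assembly: concatenate 3-5 tracked generations of a lineage into a
virtual undivided cell.

A supercell follows one line of descent.  Generation 0 contributes its raw
area; for generation ``i >= 1`` the virtual area at time ``t`` is

    A_t = A_last + 2^i * (a_c(t) - dfrac * a_p_last)

where ``A_last`` is the supercell area just before the parent divided,
``a_c`` the area of the generation-``i`` cell, ``dfrac`` its area fraction of
the two sisters right after division and ``a_p_last`` the parent's area right
before division.  The formula makes ``A_t`` continuous across divisions (at
the division instant ``a_c = dfrac * a_p_last`` exactly) and, under perfectly
symmetric division, equal to ``2^i * a_c(t)``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SuperCell", "supercell_area", "build_supercells",
           "supercells_to_table", "map_detections_to_supercell"]

log = logging.getLogger(__name__)


def supercell_area(A_last: float, i: int, a_c, dfrac: float,
                   a_p_last: float):
    """Virtual undivided area of a generation-``i`` cell with area ``a_c``.

    Generation 0 returns ``a_c`` directly.  Accepts scalar or array ``a_c``.
    """
    if i < 0:
        raise ValueError("generation index must be >= 0")
    if i == 0:
        return a_c
    return A_last + (2.0 ** i) * (np.asarray(a_c) - dfrac * a_p_last)


@dataclass
class _Gen:
    cell_id: str
    generation_index: int
    frames: np.ndarray
    times: np.ndarray
    areas: np.ndarray
    lengths: np.ndarray
    qc: np.ndarray
    dfrac: float
    A_last: float  # supercell area just before this generation's parent divided
    A_t: np.ndarray = field(default=None, repr=False)
    seg_lo: float = 0.0  # sub-segment of the supercell long axis, relative
    seg_hi: float = 1.0
    area_flagged: np.ndarray = field(default=None, repr=False)


@dataclass
class SuperCell:
    supercell_id: int
    lineage_id: int
    generations: list  # list of _Gen, ordered

    @property
    def first_frame(self) -> int:
        return int(self.generations[0].frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.generations[-1].frames[-1])

    @property
    def cell_ids(self) -> list:
        return [g.cell_id for g in self.generations]

    def gen_at_frame(self, frame: int) -> "_Gen | None":
        for g in self.generations:
            if g.frames[0] <= frame <= g.frames[-1]:
                return g
        return None

    def area_at_frame(self, frame: int) -> float:
        g = self.gen_at_frame(frame)
        if g is None:
            raise KeyError(f"frame {frame} not in supercell {self.supercell_id}")
        return float(g.A_t[np.searchsorted(g.frames, frame)])

    def qc_at_frame(self, frame: int) -> bool:
        g = self.gen_at_frame(frame)
        if g is None:
            return False
        return bool(g.qc[np.searchsorted(g.frames, frame)])

    def size_span(self) -> tuple:
        return (float(self.generations[0].A_t[0]),
                float(self.generations[-1].A_t[-1]))


def _per_cell(cells: pd.DataFrame) -> dict:
    info = {}
    for cid, g in cells.groupby("cell_id", sort=False):
        g = g.sort_values("frame")
        info[cid] = {
            "frames": g["frame"].to_numpy(),
            "times": g["time_min"].to_numpy(),
            "areas": g["area_um2"].to_numpy(),
            "lengths": g["length_um"].to_numpy(),
            "qc": g["qc_ok"].to_numpy().astype(bool),
            "parent": g["parent_id"].iloc[0],
            "sister": g["sister_id"].iloc[0],
            "dfrac": g["dfrac"].iloc[0],
            "lineage": g["lineage_id"].iloc[0],
            "n_frames": len(g),
        }
    daughters: dict = {}
    for cid, rec in info.items():
        p = rec["parent"]
        if isinstance(p, str) and p:
            daughters.setdefault(p, []).append(cid)
    return info, daughters


def build_supercells(cells: pd.DataFrame, n_generations: int = 3,
                     min_frames: int = 8) -> list:
    """Assemble supercells from a per-frame cell table.

    A lineage path of ``n_generations`` consecutive cells qualifies only if
    every member, its parent, its sister and both its daughters are tracked
    for at least ``min_frames`` frames.  Cells are unique across supercells
    except in the parent (first) generation, which may be shared by paths
    through its two daughters.
    """
    if n_generations not in (3, 4, 5):
        raise ValueError("n_generations must be 3, 4 or 5")
    info, daughters = _per_cell(cells)

    def tracked(cid) -> bool:
        return isinstance(cid, str) and cid in info and \
            info[cid]["n_frames"] >= min_frames

    def eligible(cid) -> bool:
        rec = info.get(cid)
        if rec is None or rec["n_frames"] < min_frames:
            return False
        if not tracked(rec["parent"]) or not tracked(rec["sister"]):
            return False
        kids = daughters.get(cid, [])
        if len(kids) != 2 or not all(tracked(k) for k in kids):
            return False
        return True

    paths = []
    for root in sorted(info):
        if not eligible(root):
            continue
        stack = [[root]]
        while stack:
            path = stack.pop()
            if len(path) == n_generations:
                paths.append(path)
                continue
            for d in sorted(daughters.get(path[-1], [])):
                if eligible(d):
                    stack.append(path + [d])
    paths.sort()

    used = set()
    supercells = []
    sc_id = 0
    for path in paths:
        if any(c in used for c in path[1:]):
            continue
        used.update(path[1:])
        gens = []
        ok = True
        for i, cid in enumerate(path):
            rec = info[cid]
            if i == 0:
                A_last, dfrac, a_p_last = 0.0, 0.5, 0.0
                A_t = rec["areas"].astype(float)
            else:
                prev = gens[-1]
                A_last = float(prev.A_t[-1])
                dfrac = float(rec["dfrac"])
                if not np.isfinite(dfrac):
                    log.info("path %s skipped: missing dfrac for %s", path, cid)
                    ok = False
                    break
                a_p_last = float(info[path[i - 1]]["areas"][-1])
                A_t = supercell_area(A_last, i, rec["areas"].astype(float),
                                     dfrac, a_p_last)
            flagged = np.asarray(A_t) <= 0
            if np.any(flagged):
                log.warning("supercell %d gen %d: %d non-positive A_t frames "
                            "flagged", sc_id, i, int(flagged.sum()))
            gens.append(_Gen(cell_id=cid, generation_index=i,
                             frames=rec["frames"], times=rec["times"],
                             areas=rec["areas"], lengths=rec["lengths"],
                             qc=rec["qc"] & ~flagged, dfrac=dfrac,
                             A_last=A_last, A_t=np.asarray(A_t, dtype=float),
                             area_flagged=flagged))
        if not ok:
            continue
        # long-axis coordinate map: generation 0 spans [0, 1]; each later
        # generation occupies the sub-segment implied by its dfrac
        lo, hi = 0.0, 1.0
        for i, g in enumerate(gens):
            if i > 0:
                hi = lo + g.dfrac * (hi - lo)
            g.seg_lo, g.seg_hi = lo, hi
        supercells.append(SuperCell(supercell_id=sc_id,
                                    lineage_id=info[path[0]]["lineage"],
                                    generations=gens))
        sc_id += 1
    return supercells


def supercells_to_table(supercells: list) -> pd.DataFrame:
    rows = []
    for sc in supercells:
        for g in sc.generations:
            for k in range(len(g.frames)):
                rows.append((sc.supercell_id, g.generation_index, g.cell_id,
                             int(g.frames[k]), float(g.times[k]),
                             float(g.A_t[k]), int(g.qc[k])))
    return pd.DataFrame(rows, columns=["supercell_id", "generation_index",
                                       "cell_id", "frame", "time_min",
                                       "A_t_um2", "qc_ok"])


def map_detections_to_supercell(detections: pd.DataFrame, sc: SuperCell,
                                cell_width: float = 1.0) -> pd.DataFrame:
    """Map per-cell foci detections into the supercell coordinate system.

    Positions are expressed in µm along the virtual undivided long axis
    (length ``A_t / cell_width``); a focus at relative position ``u`` within
    a generation-``i`` cell maps to ``seg_lo + u * (seg_hi - seg_lo)`` of the
    full axis, so positions are continuous across divisions.
    """
    out = []
    for g in sc.generations:
        sub = detections[detections.cell_id == g.cell_id]
        if sub.empty:
            continue
        idx = np.searchsorted(g.frames, sub["frame"].to_numpy())
        valid = (idx < len(g.frames)) & \
            (g.frames[np.minimum(idx, len(g.frames) - 1)]
             == sub["frame"].to_numpy())
        sub = sub[valid]
        idx = idx[valid]
        L_cell = g.lengths[idx]
        u = 0.5 + sub["pos_in_cell_um"].to_numpy() / L_cell
        r = g.seg_lo + u * (g.seg_hi - g.seg_lo)
        L_super = g.A_t[idx] / cell_width
        for k in range(len(sub)):
            out.append((sc.supercell_id, int(sub["frame"].to_numpy()[k]),
                        float(sub["time_min"].to_numpy()[k]), g.cell_id,
                        g.generation_index, float(r[k] * L_super[k]),
                        float(r[k])))
    df = pd.DataFrame(out, columns=["supercell_id", "frame", "time_min",
                                    "cell_id", "generation_index", "coord_um",
                                    "coord_rel"])
    return df.sort_values(["frame", "coord_um"], kind="mergesort") \
             .reset_index(drop=True)
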