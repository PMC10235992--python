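"""Fork plots: 2D histograms of replisome-focus long-axis position versus
cell (or supercell) size, whose dense branches trace replication rounds.

Markers record the population means of birth size, division size and
(optionally) initiation size, plus the mean cell-pole positions per size
bin, matching the dashed/solid guide lines conventionally drawn on these
plots.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ForkPlotGrid", "forkplot_one_generation", "forkplot_supercell",
           "forkplot_binned", "default_bins"]


@dataclass
class ForkPlotGrid:
    counts: np.ndarray  # shape (n_size_bins, n_pos_bins)
    size_edges: np.ndarray  # µm²
    pos_edges: np.ndarray  # µm, midcell = 0 (or supercell coordinate)
    orientation: str = "size-by-position"
    markers: dict = field(default_factory=dict)
    n_dropped: int = 0
    empty: bool = False

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_json_sidecar(self) -> str:
        return json.dumps({
            "size_edges": list(map(float, self.size_edges)),
            "pos_edges": list(map(float, self.pos_edges)),
            "orientation": self.orientation,
            "markers": {k: (list(map(float, np.atleast_1d(v))))
                        for k, v in self.markers.items()},
            "n_dropped": self.n_dropped,
        }, indent=1)

    def save_png(self, path, mirror: bool = False) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        counts = self.counts
        if mirror:
            counts = 0.5 * (counts + counts[:, ::-1])
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.pcolormesh(self.size_edges, self.pos_edges, counts.T,
                      cmap="inferno")
        for key, style in (("birth_size", "w--"), ("division_size", "w--"),
                           ("initiation_size", "r--")):
            if key in self.markers:
                for v in np.atleast_1d(self.markers[key]):
                    ax.axvline(v, ls="--",
                               color="w" if style.startswith("w") else "r",
                               lw=0.8)
        ax.set_xlabel("cell size (µm²)")
        ax.set_ylabel("long-axis position (µm)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def default_bins(sizes, positions, n_size: int = 40, n_pos: int = 60):
    """Bin edges spanning the 1st-99th size percentile and the position range."""
    sizes = np.asarray(sizes, float)
    positions = np.asarray(positions, float)
    lo, hi = np.percentile(sizes, [1, 99])
    if hi <= lo:
        hi = lo + 1e-6
    p_lo, p_hi = positions.min(), positions.max()
    if p_hi <= p_lo:
        p_hi = p_lo + 1e-6
    return (np.linspace(lo, hi, n_size + 1), np.linspace(p_lo, p_hi, n_pos + 1))


def _pole_positions(sizes, half_lengths, size_edges):
    pole = np.full(len(size_edges) - 1, np.nan)
    idx = np.digitize(sizes, size_edges) - 1
    for b in range(len(size_edges) - 1):
        m = idx == b
        if m.any():
            pole[b] = float(np.mean(half_lengths[m]))
    return pole


def forkplot_one_generation(cells: pd.DataFrame, detections: pd.DataFrame,
                            bins=None, initiation_sizes=None) -> ForkPlotGrid:
    """Fork plot of signed in-cell focus position against host-cell area.

    Detections without a host row in ``cells`` are dropped and counted.
    """
    key = ["cell_id", "frame"]
    host = cells.set_index(key)[["area_um2", "length_um"]]
    det = detections.join(host, on=key, how="left")
    dropped = int(det["area_um2"].isna().sum())
    det = det.dropna(subset=["area_um2"])
    sizes = det["area_um2"].to_numpy(float)
    pos = det["pos_in_cell_um"].to_numpy(float)
    if bins is None:
        bins = default_bins(sizes, pos)
    counts, se, pe = np.histogram2d(sizes, pos, bins=bins)
    dropped += len(sizes) - int(counts.sum())  # outside the bin ranges
    markers = {
        "birth_size": float(cells.groupby("cell_id")["area_um2"].first().mean()),
        "division_size": float(cells.groupby("cell_id")["area_um2"].last().mean()),
        "pole_per_size_bin": _pole_positions(
            sizes, 0.5 * det["length_um"].to_numpy(float), se),
    }
    if initiation_sizes is not None and len(initiation_sizes):
        markers["initiation_size"] = float(np.mean(initiation_sizes))
    return ForkPlotGrid(counts=counts, size_edges=se, pos_edges=pe,
                        markers=markers, n_dropped=dropped)


def forkplot_supercell(supercells: list, mapped_detections: pd.DataFrame,
                       bins=None, cell_width: float = 1.0,
                       initiation_sizes=None) -> ForkPlotGrid:
    """Fork plot in supercell coordinates: x = virtual undivided area A_t,
    y = position along the supercell long axis (µm).  Markers include
    per-generation mean birth and division sizes."""
    by_id = {sc.supercell_id: sc for sc in supercells}
    sizes, pos = [], []
    dropped = 0
    for row in mapped_detections.itertuples():
        sc = by_id.get(row.supercell_id)
        if sc is None:
            dropped += 1
            continue
        try:
            sizes.append(sc.area_at_frame(row.frame))
        except KeyError:
            dropped += 1
            continue
        pos.append(row.coord_um)
    sizes = np.asarray(sizes, float)
    pos = np.asarray(pos, float)
    if len(sizes) == 0:
        return ForkPlotGrid(counts=np.zeros((1, 1)),
                            size_edges=np.array([0.0, 1.0]),
                            pos_edges=np.array([0.0, 1.0]),
                            n_dropped=dropped, empty=True)
    if bins is None:
        bins = default_bins(sizes, pos)
    counts, se, pe = np.histogram2d(sizes, pos, bins=bins)
    dropped += len(sizes) - int(counts.sum())  # outside the bin ranges
    birth, division = {}, {}
    for sc in supercells:
        for g in sc.generations:
            birth.setdefault(g.generation_index, []).append(float(g.A_t[0]))
            division.setdefault(g.generation_index, []).append(float(g.A_t[-1]))
    markers = {
        "birth_size_per_generation": np.array(
            [np.mean(birth[i]) for i in sorted(birth)]),
        "division_size_per_generation": np.array(
            [np.mean(division[i]) for i in sorted(division)]),
    }
    if initiation_sizes is not None and len(initiation_sizes):
        markers["initiation_size"] = float(np.mean(initiation_sizes))
    return ForkPlotGrid(counts=counts, size_edges=se, pos_edges=pe,
                        markers=markers, n_dropped=dropped)


def forkplot_binned(cells: pd.DataFrame, detections: pd.DataFrame,
                    time_bins, bins=None) -> list:
    """One fork plot per ``(t0, t1)`` experiment-time interval.

    Shared histogram bins across intervals (computed on the full data when
    not given) so that per-interval grids partition the unbinned grid.
    """
    if bins is None:
        key = ["cell_id", "frame"]
        host = cells.set_index(key)[["area_um2"]]
        det = detections.join(host, on=key, how="left").dropna(
            subset=["area_um2"])
        bins = default_bins(det["area_um2"].to_numpy(float),
                            det["pos_in_cell_um"].to_numpy(float))
    grids = []
    for (t0, t1) in time_bins:
        m = (detections["time_min"] >= t0) & (detections["time_min"] < t1)
        sub = detections[m]
        if sub.empty:
            g = ForkPlotGrid(counts=np.zeros((len(bins[0]) - 1,
                                              len(bins[1]) - 1)),
                             size_edges=np.asarray(bins[0]),
                             pos_edges=np.asarray(bins[1]), empty=True)
            g.markers["time_bin"] = (t0, t1)
            grids.append(g)
            continue
        cm = (cells["time_min"] >= t0) & (cells["time_min"] < t1)
        g = forkplot_one_generation(cells[cm], sub, bins=bins)
        g.markers["time_bin"] = (t0, t1)
        grids.append(g)
    return grids
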