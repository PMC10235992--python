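"""Call replication initiation and termination events from focus tracks.

An initiation is the start of a sufficiently long track (>= 11 frames by
default, 9 for the slow-growth acetate preset) that does not begin on the
first frames of the supercell, is not split-born, and whose neighbouring
frames are well segmented.  A termination is a track end away from the last
frames of the supercell that either lies within the boundary of the current
(daughter) generation cell or, when the round initiated close to division,
ends within a few pixels of the current generation's midcell.  Event sizes
are the supercell area ``A_t`` at the event frame, i.e. the cell size as if
the cells had not divided.

Also fits the distribution of initiation sizes with a sum of Gaussians, one
component per distinct peak, mirroring a least-squares multi-Gaussian
regression of the binned size histogram.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = ["ReplicationEvent", "MixtureFit", "call_initiations",
           "call_terminations", "filter_supercells",
           "fit_initiation_size_mixture", "events_to_table", "PRESETS"]

#: per-condition filter presets; min_track_len per the growth condition
PRESETS = {
    "default": {"min_track_len": 11},
    "acetate": {"min_track_len": 9},
}


@dataclass
class ReplicationEvent:
    event_type: str  # "initiation" | "termination"
    supercell_id: int
    frame: int
    time_min: float
    supercell_area: float  # A_t at the event frame
    generation_index: int
    round_index: int
    track_id: int


@dataclass
class MixtureFit:
    means: np.ndarray  # ascending
    sds: np.ndarray
    weights: np.ndarray
    residual: float
    central_index: int  # component farthest from the supercell size-span edges

    @property
    def k(self) -> int:
        return len(self.means)

    @property
    def cvs(self) -> np.ndarray:
        return self.sds / self.means

    @property
    def central_mean(self) -> float:
        return float(self.means[self.central_index])

    @property
    def central_cv(self) -> float:
        return float(self.cvs[self.central_index])


def call_initiations(tracks: list, supercell, min_track_len: int = 11,
                     edge_exclusion: int = 2, qc_window: int = 2,
                     counts: dict | None = None) -> list:
    """Return initiation events for one supercell's tracks.

    Each filter can be disabled by passing ``None``; per-filter rejection
    counts are accumulated into ``counts`` when given (a candidate is charged
    to the first filter it fails, in the order split-born, length, edge, QC).
    """
    if counts is None:
        counts = {}
    for key in ("accepted", "split_born", "too_short", "edge", "qc"):
        counts.setdefault(key, 0)
    f0 = supercell.first_frame
    events = []
    for tr in tracks:
        if tr.split_born:
            counts["split_born"] += 1
            continue
        if min_track_len is not None and tr.length < min_track_len:
            counts["too_short"] += 1
            continue
        if edge_exclusion is not None and tr.start_frame - f0 < edge_exclusion:
            counts["edge"] += 1
            continue
        if qc_window is not None:
            lo = max(tr.start_frame - qc_window, f0)
            hi = min(tr.start_frame + qc_window, supercell.last_frame)
            if not all(supercell.qc_at_frame(f) for f in range(lo, hi + 1)):
                counts["qc"] += 1
                continue
        g = supercell.gen_at_frame(tr.start_frame)
        if g is None:
            counts["edge"] += 1
            continue
        counts["accepted"] += 1
        events.append(ReplicationEvent(
            event_type="initiation", supercell_id=supercell.supercell_id,
            frame=tr.start_frame,
            time_min=float(g.times[np.searchsorted(g.frames, tr.start_frame)]),
            supercell_area=supercell.area_at_frame(tr.start_frame),
            generation_index=g.generation_index, round_index=-1,
            track_id=tr.track_id))
    events.sort(key=lambda e: e.frame)
    for i, e in enumerate(events):
        e.round_index = i
    return events


def call_terminations(tracks: list, supercell, edge_exclusion: int = 2,
                      midcell_tol_px: float = 5.0, pixel_size: float = 0.08,
                      close_to_div_frames: int = 10,
                      counts: dict | None = None) -> list:
    """Return termination events for one supercell's tracks.

    A track end qualifies if it does not fall on the last ``edge_exclusion``
    frames, was not consumed by a merge, and passes the position rule: tracks
    whose round initiated close to division (start within
    ``close_to_div_frames`` of its generation's last frame) must end within
    ``midcell_tol_px * pixel_size`` µm of the current generation's midcell;
    all others must end within the boundary of the current generation cell.
    """
    if counts is None:
        counts = {}
    for key in ("accepted", "merged", "edge", "outside", "midcell"):
        counts.setdefault(key, 0)
    f_last = supercell.last_frame
    events = []
    for tr in tracks:
        if tr.merged_into is not None:
            counts["merged"] += 1
            continue
        if edge_exclusion is not None and f_last - tr.end_frame < edge_exclusion:
            counts["edge"] += 1
            continue
        g_end = supercell.gen_at_frame(tr.end_frame)
        if g_end is None:
            counts["outside"] += 1
            continue
        idx = np.searchsorted(g_end.frames, tr.end_frame)
        # the cell's segment of the supercell axis, in µm at the end frame
        L_super = float(g_end.A_t[idx])  # area; length = area/width below
        g_start = supercell.gen_at_frame(tr.start_frame)
        close_to_div = (g_start is not None and close_to_div_frames is not None
                        and g_start.frames[-1] - tr.start_frame
                        <= close_to_div_frames)
        width = _width_estimate(supercell)
        L_um = L_super / width
        lo_um, hi_um = g_end.seg_lo * L_um, g_end.seg_hi * L_um
        if close_to_div:
            mid = 0.5 * (lo_um + hi_um)
            if abs(tr.end_coord - mid) > midcell_tol_px * pixel_size:
                counts["midcell"] += 1
                continue
        else:
            if not (lo_um - 1e-9 <= tr.end_coord <= hi_um + 1e-9):
                counts["outside"] += 1
                continue
        counts["accepted"] += 1
        events.append(ReplicationEvent(
            event_type="termination", supercell_id=supercell.supercell_id,
            frame=tr.end_frame,
            time_min=float(g_end.times[idx]),
            supercell_area=supercell.area_at_frame(tr.end_frame),
            generation_index=g_end.generation_index, round_index=-1,
            track_id=tr.track_id))
    events.sort(key=lambda e: e.frame)
    for i, e in enumerate(events):
        e.round_index = i
    return events


def _width_estimate(supercell) -> float:
    g = supercell.generations[0]
    with np.errstate(invalid="ignore"):
        w = np.nanmean(np.asarray(g.areas, float)
                       / np.asarray(g.lengths, float))
    return float(w) if np.isfinite(w) and w > 0 else 1.0


def filter_supercells(events_by_supercell: dict, supercells: list):
    """Keep only supercells with at least one initiation and one termination.

    ``events_by_supercell`` maps supercell_id -> list of ReplicationEvent.
    Returns (retained supercells, retained events dict, report dict).
    """
    retained, kept_events = [], {}
    report = {"total": len(supercells), "kept": 0, "dropped": 0}
    by_id = {sc.supercell_id: sc for sc in supercells}
    for sc_id, evs in events_by_supercell.items():
        has_i = any(e.event_type == "initiation" for e in evs)
        has_t = any(e.event_type == "termination" for e in evs)
        if has_i and has_t and sc_id in by_id:
            retained.append(by_id[sc_id])
            kept_events[sc_id] = evs
    report["kept"] = len(retained)
    report["dropped"] = report["total"] - report["kept"]
    return retained, kept_events, report


def _gauss_sum(x, *params):
    y = np.zeros_like(x, dtype=float)
    for i in range(len(params) // 3):
        a, m, s = params[3 * i: 3 * i + 3]
        y += a * np.exp(-0.5 * ((x - m) / s) ** 2)
    return y


def fit_initiation_size_mixture(sizes, k: int | str = "auto",
                                n_bins: int = 60,
                                peak_prominence_frac: float = 0.10,
                                size_span: tuple | None = None) -> MixtureFit:
    """Least-squares fit of a sum of ``k`` Gaussians to the binned initiation
    size distribution.

    With ``k='auto'`` the component count is the number of local maxima of a
    kernel-smoothed density whose prominence exceeds
    ``peak_prominence_frac`` of the density maximum (the "distinct peaks" of
    the distribution).  The central component — the one farthest from the
    edges of the supercell size span — is flagged for summary statistics, to
    avoid truncation effects at the span edges.
    """
    sizes = np.asarray(sizes, dtype=float)
    sizes = sizes[np.isfinite(sizes) & (sizes > 0)]
    if len(sizes) < 50:
        raise ValueError("need >= 50 events for a stable mixture fit")
    # peaks are counted in log size: replication rounds sit at 2x spacings,
    # so components are evenly spaced there with comparable widths
    logs = np.log(sizes)
    kde = gaussian_kde(logs)
    grid = np.linspace(logs.min(), logs.max(), 512)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=peak_prominence_frac * dens.max())
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    if k == "auto":
        k_fit = len(peaks)
        peak_pos = np.exp(grid[peaks])
    else:
        k_fit = int(k)
        if len(peaks) >= k_fit:
            order = np.argsort(dens[peaks])[::-1][:k_fit]
            peak_pos = np.sort(np.exp(grid[peaks[order]]))
        else:
            peak_pos = np.quantile(sizes, (np.arange(k_fit) + 0.5) / k_fit)

    hist, edges = np.histogram(sizes, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0, lower, upper = [], [], []
    for m in peak_pos:
        # linear-space density at the peak; ~10% CV starting width
        p0 += [float(kde(np.log(m))[0] / m), float(m), float(0.1 * m)]
        lower += [0.0, sizes.min(), 1e-6]
        upper += [np.inf, sizes.max(), sizes.max() - sizes.min()]
    try:
        popt, _ = curve_fit(_gauss_sum, centers, hist, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
    except RuntimeError:
        # retry from histogram-peak initial values
        p0b = list(p0)
        for i in range(k_fit):
            j = int(np.argmin(np.abs(centers - peak_pos[i])))
            p0b[3 * i] = hist[j]
        try:
            popt, _ = curve_fit(_gauss_sum, centers, hist, p0=p0b,
                                bounds=(lower, upper), maxfev=40000)
        except RuntimeError as err:
            raise RuntimeError(
                f"mixture fit failed for k={k_fit}: {err}; "
                f"n={len(sizes)}, range=({sizes.min():.3g},{sizes.max():.3g})"
            ) from err
    amps = popt[0::3]
    means = popt[1::3]
    sds = popt[2::3]
    order = np.argsort(means)
    amps, means, sds = amps[order], means[order], sds[order]
    weights = amps * sds * np.sqrt(2 * np.pi)
    weights = weights / weights.sum()
    resid = float(np.sqrt(np.mean((_gauss_sum(centers, *popt) - hist) ** 2)))
    if size_span is None:
        size_span = (sizes.min(), sizes.max())
    edge_dist = np.minimum(means - size_span[0], size_span[1] - means)
    central = int(np.argmax(edge_dist))
    return MixtureFit(means=means, sds=sds, weights=weights, residual=resid,
                      central_index=central)


def events_to_table(events: list) -> pd.DataFrame:
    rows = [(e.event_type, e.supercell_id, e.frame, e.time_min,
             e.supercell_area, e.generation_index, e.round_index, e.track_id)
            for e in events]
    return pd.DataFrame(rows, columns=["event_type", "supercell_id", "frame",
                                       "time_min", "supercell_area",
                                       "generation_index", "round_index",
                                       "track_id"])
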