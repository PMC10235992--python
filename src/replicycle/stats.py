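"""Correlation statistics of cell-cycle events and the DnaA-dilution analysis.

Event sizes at two consecutive initiations (I1, I2) and at the termination T
of the I1 round are matched within each supercell; each pairing produces a
clustered scatter whose selected cluster is fitted with the sum of a
bivariate Gaussian and a constant background, the correlation coefficient
being read off the fitted covariance.  The partial correlation
rho_T,I2|I1 removes the confounding effect of I1 on the T-I2 correlation.

The dilution analysis aligns a DnaA turn-off initiation-size series to a
constant-expression reference, converts time to expected concentration
(halving per generation) and fits the initiation-size fold change to a
power law ``[DnaA]^(-a)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde, norm

__all__ = [
    "EventPairScatter", "CorrelationEstimate", "DilutionFit",
    "pair_events", "select_cluster", "fit_bivariate_gaussian_bg",
    "pearson_estimate", "partial_correlation",
    "dilution_align_and_foldchange", "fit_power_law_exponent",
    "consecutive_initiation_pairs", "initiation_termination_triples",
]

_Z67 = norm.ppf(0.5 + 0.67 / 2.0)  # two-sided 67% interval half-width in SDs


@dataclass
class EventPairScatter:
    relation: str
    data: pd.DataFrame  # columns x, y, offset, supercell_id, span_lo, span_hi
    mask: np.ndarray | None = None  # selected-cluster mask

    @property
    def selected(self) -> pd.DataFrame:
        return self.data if self.mask is None else self.data[self.mask]


@dataclass
class CorrelationEstimate:
    rho: float
    ci67: tuple  # (lo, hi)
    n: int
    mean: tuple = (np.nan, np.nan)
    sd: tuple = (np.nan, np.nan)
    background: float = 0.0
    weight: float = 1.0
    estimator: str = "bivariate_gaussian_bg"


@dataclass
class DilutionFit:
    table: pd.DataFrame  # per experiment/bin: times, fold change, expected conc
    exponent_a: float = np.nan
    residual: float = np.nan
    align_bins: dict = field(default_factory=dict)  # experiment -> bin index


# ---------------------------------------------------------------------------
# pairing and cluster selection
# ---------------------------------------------------------------------------

_RELATIONS = {"I-I", "I-T", "T-I", "birth-I", "I-division", "birth-T",
              "T-division"}


def pair_events(events: pd.DataFrame, relation: str = "I-I",
                max_offset: int | None = None) -> EventPairScatter:
    """Match events within each supercell into an ordered pair scatter.

    ``events`` is a table with columns ``event_type, supercell_id,
    supercell_area, round_index`` (birth/division pseudo-events use types
    ``birth``/``division``).  For each supercell all ordered pairs of the two
    requested types are formed; the round offset is the index difference
    between the paired events (consecutive events have offset 1, while the
    termination belonging to initiation round i has offset 0 in I-T pairs).
    """
    if relation not in _RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    t1, t2 = relation.split("-")
    names = {"I": "initiation", "T": "termination",
             "birth": "birth", "division": "division"}
    rows = []
    for sc_id, grp in events.groupby("supercell_id"):
        a = grp[grp.event_type == names[t1]].sort_values("round_index")
        b = grp[grp.event_type == names[t2]].sort_values("round_index")
        span_lo = grp["supercell_area"].min()
        span_hi = grp["supercell_area"].max()
        if "span_lo" in grp.columns:
            span_lo = grp["span_lo"].iloc[0]
            span_hi = grp["span_hi"].iloc[0]
        for i, ea in a.reset_index().iterrows():
            for j, eb in b.reset_index().iterrows():
                if names[t1] == names[t2] and j <= i:
                    continue
                offset = j - i  # I-T same round -> 0; T with next I -> 1
                if max_offset is not None and abs(offset) > max_offset:
                    continue
                rows.append((float(ea.supercell_area),
                             float(eb.supercell_area), int(offset), i, j,
                             sc_id, float(span_lo), float(span_hi)))
    df = pd.DataFrame(rows, columns=["x", "y", "offset", "round_x", "round_y",
                                     "supercell_id", "span_lo", "span_hi"])
    return EventPairScatter(relation=relation, data=df)


def select_cluster(scatter: EventPairScatter, strategy: str = "offset",
                   offset: int = 1, edge_margin_sds: float = 1.0,
                   density_frac: float = 0.25) -> EventPairScatter:
    """Select the cluster of pairs used for the correlation fit.

    ``offset`` strategy (default): keep pairs at the requested round offset,
    then drop whole round clusters whose sizes lie within ``edge_margin_sds``
    of that cluster's standard deviation from the supercell size-span
    extremes (truncation avoidance; a cluster at the span edge is size-biased
    because events beyond the edge are unobservable).  ``density`` strategy:
    keep pairs whose 2D kernel density exceeds ``density_frac`` of the
    densest mode.
    """
    df = scatter.data
    if df.empty:
        raise ValueError("empty scatter")
    if strategy == "offset":
        m = (df["offset"] == offset).to_numpy()
        if not m.any():
            counts = df["offset"].value_counts().to_dict()
            raise ValueError(f"no pairs at offset {offset}; offsets: {counts}")
        keep = m.copy()
        if edge_margin_sds > 0 and "round_x" in df.columns:
            sub = df[m]
            scores, masks = [], []
            for rx, grp in sub.groupby("round_x"):
                lo = float(grp["span_lo"].median())
                hi = float(grp["span_hi"].median())
                dist = min(grp["x"].mean() - lo, hi - grp["x"].mean(),
                           grp["y"].mean() - lo, hi - grp["y"].mean())
                sd = max(float(grp["x"].std() or 0.0),
                         float(grp["y"].std() or 0.0))
                gm = m & (df["round_x"] == rx).to_numpy()
                scores.append((dist, sd, gm))
            ok = [gm for dist, sd, gm in scores if dist >= edge_margin_sds * sd]
            if ok:
                keep = np.logical_or.reduce(ok)
            else:
                # all clusters near an edge: keep the one farthest from it
                keep = max(scores, key=lambda s: s[0])[2]
    elif strategy == "density":
        xy = df[["x", "y"]].to_numpy(float).T
        dens = gaussian_kde(xy)(xy)
        keep = dens >= density_frac * dens.max()
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return EventPairScatter(relation=scatter.relation, data=df,
                            mask=np.asarray(keep))


# ---------------------------------------------------------------------------
# correlation estimation
# ---------------------------------------------------------------------------

def _bvg_bg(coords, amp, mx, my, sx, sy, rho, b):
    x, y = coords
    zx = (x - mx) / sx
    zy = (y - my) / sy
    q = (zx ** 2 - 2 * rho * zx * zy + zy ** 2) / (1 - rho ** 2)
    return amp * np.exp(-0.5 * q) + b


def fit_bivariate_gaussian_bg(x, y=None, grid_bins: int = 40) -> CorrelationEstimate:
    """Fit ``w * G2(mu, Sigma) + b`` to the 2D histogram of a pair scatter.

    Accepts an :class:`EventPairScatter` (its selected pairs) or two arrays.
    Returns the correlation coefficient ``rho = Sigma12/sqrt(Sigma11*Sigma22)``
    with a 67% confidence interval from the fit covariance (delta method on
    the directly parameterised rho).
    """
    if y is None:
        sel = x.selected
        x, y = sel["x"].to_numpy(float), sel["y"].to_numpy(float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 100:
        raise ValueError("need >= 100 pairs for the histogram fit")
    counts, xe, ye = np.histogram2d(x, y, bins=grid_bins)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    coords = (X.ravel(), Y.ravel())
    z = counts.ravel()
    r0 = float(np.clip(np.corrcoef(x, y)[0, 1], -0.9, 0.9))
    p0 = [z.max() or 1.0, x.mean(), y.mean(), x.std() or 1.0, y.std() or 1.0,
          r0, 0.0]
    lo = [0.0, xe[0], ye[0], 1e-9, 1e-9, -0.999, 0.0]
    hi = [np.inf, xe[-1], ye[-1], np.inf, np.inf, 0.999, np.inf]
    popt, pcov = curve_fit(_bvg_bg, coords, z, p0=p0, bounds=(lo, hi),
                           maxfev=40000)
    amp, mx, my, sx, sy, rho, b = popt
    if np.all(np.isfinite(pcov)):
        sd_rho = math.sqrt(max(pcov[5, 5], 0.0))
    else:
        sd_rho = float("nan")
    if abs(sx) < 1e-12 or abs(sy) < 1e-12:
        raise RuntimeError("singular covariance in bivariate fit")
    return CorrelationEstimate(
        rho=float(rho), ci67=(float(rho - _Z67 * sd_rho),
                              float(rho + _Z67 * sd_rho)),
        n=n, mean=(float(mx), float(my)), sd=(float(sx), float(sy)),
        background=float(b),
        weight=float(amp * 2 * math.pi * sx * sy * math.sqrt(1 - rho ** 2)))


def pearson_estimate(x, y=None) -> CorrelationEstimate:
    """Plain Pearson correlation on the selected cluster, for cross-checking
    the histogram-fit estimate.  67% CI via the Fisher z-transform."""
    if y is None:
        sel = x.selected
        x, y = sel["x"].to_numpy(float), sel["y"].to_numpy(float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if n > 3:
        z = np.arctanh(r)
        hw = _Z67 / math.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    else:
        ci = (float("nan"), float("nan"))
    return CorrelationEstimate(rho=r, ci67=ci, n=n, estimator="pearson")


def partial_correlation(rho_TI2: float, rho_TI1: float,
                        rho_I1I2: float) -> float:
    """Partial correlation of T and I2 given I1:
    ``(rho_TI2 - rho_TI1*rho_I1I2) / sqrt((1-rho_TI1^2)(1-rho_I1I2^2))``."""
    for r in (rho_TI2, rho_TI1, rho_I1I2):
        if abs(r) >= 1.0:
            raise ValueError("all correlations must satisfy |rho| < 1")
    denom = math.sqrt((1 - rho_TI1 ** 2) * (1 - rho_I1I2 ** 2))
    if denom == 0:
        raise ValueError("degenerate partial-correlation denominator")
    return (rho_TI2 - rho_TI1 * rho_I1I2) / denom


# ---------------------------------------------------------------------------
# ground-truth pairing helpers (simulated event tables)
# ---------------------------------------------------------------------------

def consecutive_initiation_pairs(truth: pd.DataFrame) -> pd.DataFrame:
    """Pair each initiation with the next one along the line of descent.

    Sizes are expressed in the supercell frame rooted at the earlier event's
    cell: ``x`` is the cell area at the earlier initiation and ``y`` the
    later initiation's area divided by the intervening division fraction —
    the virtual area "as if the cells had not divided".  Consecutive
    initiations within one cell (overlapping rounds) pair directly.  Returns
    a DataFrame with columns ``x, y, offset`` (offset 1 throughout).
    """
    init = truth[truth.event_type == "initiation"].sort_values(
        ["lineage_id", "cell_id", "time_min"])
    by_cell: dict = {}
    for r in init.itertuples():
        by_cell.setdefault(r.cell_id, []).append(r)
    rows = []
    for cid, evs in by_cell.items():
        for e1, e2 in zip(evs, evs[1:]):
            if e2.generation >= 0:
                rows.append((e1.area_um2, e2.area_um2, 1))
    for cid, evs in by_cell.items():
        first = evs[0]
        if first.generation < 0:
            continue
        parent_evs = by_cell.get(first.parent_cell_id)
        if parent_evs:
            rows.append((parent_evs[-1].area_um2,
                         first.area_um2 / first.dfrac, 1))
    return pd.DataFrame(rows, columns=["x", "y", "offset"])


def initiation_termination_triples(truth: pd.DataFrame) -> pd.DataFrame:
    """Per replication round, the sizes at initiation I1, at the round's
    termination T, and at the next initiation I2 in a daughter, all in the
    I1 cell's frame.  Returns columns ``i1, t, i2``."""
    ini = truth[truth.event_type == "initiation"]
    ter = truth[truth.event_type == "termination"]
    term_by_round = {}
    for r in ter.itertuples():
        # only rounds terminating in the cell they initiated in
        term_by_round[(r.cell_id, r.round_id)] = r.area_um2
    by_cell: dict = {}
    for r in ini.sort_values(["lineage_id", "cell_id", "time_min"]).itertuples():
        by_cell.setdefault(r.cell_id, []).append(r)
    rows = []
    for cid, evs in by_cell.items():
        first = evs[0]
        if first.generation < 0:
            continue
        parent_evs = by_cell.get(first.parent_cell_id)
        if not parent_evs:
            continue
        p = parent_evs[-1]
        t_area = term_by_round.get((p.cell_id, p.round_id))
        if t_area is None:
            continue
        rows.append((p.area_um2, t_area, first.area_um2 / first.dfrac))
    return pd.DataFrame(rows, columns=["i1", "t", "i2"])


# ---------------------------------------------------------------------------
# dilution analysis
# ---------------------------------------------------------------------------

def dilution_align_and_foldchange(bins: pd.DataFrame,
                                  mean_generation_time: float | None = None,
                                  turnoff_time_rel: float = 0.0,
                                  override_bin: dict | int | None = None,
                                  smooth_window: int = 3) -> DilutionFit:
    """Align turn-off series to the reference and compute fold changes.

    ``bins`` is the tidy table from ``simulate_dilution_experiment`` (or
    equivalent): columns ``experiment, strain, bin_index, time_min`` (relative
    to turn-off), ``mean_init_size, mean_gen_time``.  Per experiment the
    alignment bin is the one minimising the relative test/reference
    initiation-size difference (``override_bin`` forces it, as a mapping
    experiment -> bin or a single index for all); fold change is the test
    size relative to its value at that bin; normalized time is measured from
    the alignment bin in units of the experiment's mean generation time; and
    the expected concentration halves per normalized generation after
    turn-off.

    The relative difference is evaluated on a ``smooth_window``-bin running
    mean of the log size ratio so that the alignment does not chase
    single-bin noise (``smooth_window=1`` uses the raw per-bin values).
    """
    out_rows = []
    align_bins = {}
    for exp, grp in bins.groupby("experiment"):
        test = grp[grp.strain == "test"].set_index("bin_index")
        ref = grp[grp.strain == "reference"].set_index("bin_index")
        common = test.index.intersection(ref.index)
        if len(common) == 0:
            continue
        log_ratio = np.log(test.loc[common, "mean_init_size"].to_numpy()
                           / ref.loc[common, "mean_init_size"].to_numpy())
        if smooth_window > 1 and len(log_ratio) > smooth_window:
            half = smooth_window // 2
            sm = np.array([np.mean(log_ratio[max(0, i - half):i + half + 1])
                           for i in range(len(log_ratio))])
        else:
            sm = log_ratio
        if override_bin is None:
            b_align = int(common[int(np.argmin(np.abs(sm)))])
        elif isinstance(override_bin, dict):
            b_align = int(override_bin.get(
                exp, common[int(np.argmin(np.abs(sm)))]))
        else:
            b_align = int(override_bin)
        align_bins[exp] = b_align
        # dilution clock: the unperturbed reference strain's generation times
        # (the test strain's division interval stretches once initiation sizes
        # grow, but growth dilution still halves DnaA per volume doubling)
        tau = (mean_generation_time if mean_generation_time is not None
               else float(ref["mean_gen_time"].mean()))
        s0 = float(test.loc[b_align, "mean_init_size"])
        t0 = float(test.loc[b_align, "time_min"])
        for b in test.index:
            t = float(test.loc[b, "time_min"])
            # DnaA only dilutes after turn-off: clamp times at the swap
            g = (max(t, turnoff_time_rel) - max(t0, turnoff_time_rel)) / tau
            out_rows.append((exp, int(b), t, (t - t0) / tau,
                             float(test.loc[b, "mean_init_size"]) / s0,
                             2.0 ** (-g)))
    table = pd.DataFrame(out_rows, columns=["experiment", "bin_index",
                                            "time_min", "norm_time",
                                            "fold_change", "expected_conc"])
    return DilutionFit(table=table, align_bins=align_bins)


def fit_power_law_exponent(fold_changes, concentrations) -> float:
    """Zero-intercept least squares of log fold change on -log concentration.

    Fits initiation-size fold change = concentration^(-a); returns a >= 0.
    """
    f = np.asarray(fold_changes, float)
    c = np.asarray(concentrations, float)
    m = np.isfinite(f) & np.isfinite(c)
    f, c = f[m], c[m]
    if np.any(f <= 0) or np.any(c <= 0):
        raise ValueError("fold changes and concentrations must be > 0")
    if len(f) < 3:
        raise ValueError("need at least 3 points")
    x = -np.log(c)
    y = np.log(f)
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return max(0.0, float(np.dot(x, y) / denom))


def fit_dilution_exponent(fit: DilutionFit) -> DilutionFit:
    """Fill in the power-law exponent for an aligned dilution table."""
    t = fit.table
    a = fit_power_law_exponent(t["fold_change"], t["expected_conc"])
    pred = t["expected_conc"] ** (-a)
    fit.exponent_a = a
    fit.residual = float(np.sqrt(np.mean(
        (np.log(t["fold_change"]) - np.log(pred)) ** 2)))
    return fit
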