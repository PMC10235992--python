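"""Stochastic simulator of replicating, dividing cell lineages in a mother machine.

Cells grow exponentially in area and trigger chromosome-replication initiation
according to one of three control models:

``sizer``
    initiate when the per-origin cell area reaches a fixed threshold ``s*``
    (with i.i.d. relative noise per event); no memory between events.
``adder``
    per-origin initiator accumulation: a constant area increment ``delta`` is
    added per origin between consecutive initiations, so the per-origin size at
    initiation follows the AR(1) recursion ``s' = s/2 + delta``.
``fluxbalance``
    initiator activation/deactivation cycling: a per-cell activity ``x`` obeys
    ``dx/dt = k_on*V - k_off*F*x/(K+x)`` (``F`` = active fork pairs) and
    initiation fires when the concentration ``x/V`` reaches ``theta``.

Each initiation fires concurrently on all origins, doubling the origin count;
termination follows one C period later and cell division one C+D after
initiation (Cooper-Helmstetter coupling).  An imaging emulator converts the
ground truth into per-frame foci-detection tables with localization jitter,
missed detections and false positives, mimicking the output of a spot-detection
pipeline on mother-machine movies.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "ImagingConfig",
    "DilutionScenario",
    "FluxBalanceIntegrationError",
    "simulate_lineages",
    "emulate_detections",
    "dnaA_fold_change",
    "simulate_dilution_experiment",
    "SCENARIOS",
]

LN2 = math.log(2.0)


class FluxBalanceIntegrationError(RuntimeError):
    """Raised when the Euler integration of the flux-balance model produces a
    negative activity, i.e. ``dt_sub`` is too large for the chosen rates."""


@dataclass
class SimConfig:
    """Parameters of the lineage simulation.

    Sizes are areas in µm² (constant cell width, so area is proportional to
    length), times in minutes, rates in 1/min.
    """

    growth_rate_mean: float = LN2 / 90.0  # exponential area growth, 90 min doubling
    growth_rate_cv: float = 0.05
    cell_width: float = 1.0
    frame_interval: float = 2.0
    n_lineages: int = 20
    n_generations: int = 4
    division_fraction_sd: float = 0.03
    C_period: float = 42.0
    D_period: float = 18.0
    C_period_cv: float = 0.10
    division_timing_sd: float = 2.0
    control_model: str = "adder"
    # sizer parameters
    s_star: float = 1.0  # per-origin initiation area threshold
    sizer_cv: float = 0.10
    # adder parameters
    delta_mean: float = 0.5  # per-origin added area between initiations
    delta_cv: float = 0.15
    # flux-balance parameters (k_on=None -> steady-state balance, see validate)
    k_on: float | None = None
    k_off: float = 0.01
    theta: float = 1.0
    K_sat: float | None = None  # saturation constant; default theta/10
    dt_sub: float = 0.5
    division_rule: str = "initiation_coupled"
    div_adder_mean: float = 1.0  # birth-to-division added area (independent_adder)
    div_adder_cv: float = 0.10
    burnin_generations: int = 2
    seed: int = 0

    def validated(self) -> "SimConfig":
        if self.control_model not in ("sizer", "adder", "fluxbalance"):
            raise ValueError(f"unknown control_model {self.control_model!r}")
        if self.division_rule not in ("initiation_coupled", "independent_adder"):
            raise ValueError(f"unknown division_rule {self.division_rule!r}")
        for name in ("growth_rate_mean", "C_period", "D_period", "frame_interval",
                     "cell_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.division_fraction_sd < 0.2):
            # 0 = perfectly symmetric division
            raise ValueError("division_fraction_sd must be in [0, 0.2)")
        cfg = self
        if cfg.control_model == "fluxbalance":
            if cfg.K_sat is None:
                cfg = replace(cfg, K_sat=cfg.theta / 10.0)
            if cfg.k_on is None:
                # steady-state flux balance at per-origin initiation size s_star:
                # theta*2*s = k_on*s/lambda - k_off*C  =>  solve for k_on
                k_on = cfg.growth_rate_mean * (
                    2.0 * cfg.theta * cfg.s_star + cfg.k_off * cfg.C_period
                ) / cfg.s_star
                cfg = replace(cfg, k_on=k_on)
            if cfg.dt_sub <= 0:
                raise ValueError("dt_sub must be > 0")
        if cfg.control_model == "sizer" and cfg.s_star <= 0:
            raise ValueError("s_star must be > 0")
        if cfg.control_model == "adder" and cfg.delta_mean <= 0:
            raise ValueError("delta_mean must be > 0")
        return cfg


@dataclass
class ImagingConfig:
    """Emulated foci-detection characteristics (upstream of postprocessing)."""

    position_jitter_sd: float = 0.05  # µm, localization noise along long axis
    detection_prob: float = 0.9  # per focus per frame
    false_positive_rate: float = 0.01  # expected spurious foci per cell per frame
    pixel_size: float = 0.08  # µm / pixel

    def validated(self) -> "ImagingConfig":
        if not (0.0 <= self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be in [0, 1]")
        if self.position_jitter_sd < 0:
            raise ValueError("position_jitter_sd must be >= 0")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")
        return self


@dataclass
class DilutionScenario:
    """A DnaA turn-off experiment: after ``turnoff_time`` the initiator
    concentration halves each generation by dilution, and the per-origin
    initiation size scales as ``[DnaA]^(-exponent_a)``."""

    exponent_a: float = 0.2
    turnoff_time: float = 110.0  # min from start of recording window
    pre_induction_fold: float = 2.0  # DnaA level vs reference before turn-off
    n_experiments: int = 6
    bin_width: float = 30.0  # min
    pre_duration: float = 90.0  # recorded window before turn-off
    post_duration: float = 240.0  # recorded window after turn-off
    bin_noise_cv: float = 0.05  # multiplicative lognormal noise per bin
    n_lines: int = 100  # mother lines per experiment per strain

    def validated(self) -> "DilutionScenario":
        if self.exponent_a < 0:
            raise ValueError("exponent_a must be >= 0")
        if self.pre_induction_fold <= 0:
            raise ValueError("pre_induction_fold must be > 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        return self


#: default turn-off scenarios; the exponents are the generative ground truth
SCENARIOS = {
    "wt-turnoff": DilutionScenario(exponent_a=0.2),
    "triple-turnoff": DilutionScenario(exponent_a=0.4),
}


def dnaA_fold_change(t: float, turnoff_time: float, mean_generation_time: float,
                     pre_induction_fold: float = 1.0) -> float:
    """Expected DnaA concentration relative to the reference level.

    Before ``turnoff_time`` the level is ``pre_induction_fold``; afterwards the
    concentration halves each generation by growth dilution.
    """
    if mean_generation_time <= 0:
        raise ValueError("mean_generation_time must be > 0")
    t = np.asarray(t, dtype=float)
    gens = np.maximum(0.0, t - turnoff_time) / mean_generation_time
    out = pre_induction_fold * np.power(2.0, -gens)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# lineage simulation
# ---------------------------------------------------------------------------

def _founder_birth_area(cfg: SimConfig, rng: np.random.Generator) -> float:
    """Founder cells start near the model's steady-state birth size so the
    transient is short.  The founder spread follows the model's own noise
    scale; in the noise-free limit the adder starts exactly at its fixed
    point (per-origin birth size = ``delta_mean``)."""
    if cfg.control_model == "adder":
        base, cv = cfg.delta_mean, cfg.delta_cv
    elif cfg.control_model == "sizer":
        base, cv = 0.55 * cfg.s_star, cfg.sizer_cv
    else:
        base, cv = 0.4 * cfg.s_star, 0.1
    return base * max(1.0 + cv * rng.standard_normal(), 0.2)


class _Cell:
    __slots__ = (
        "cell_id", "lineage", "path", "depth", "birth_time", "birth_area",
        "lam", "n_ori", "super_scale", "dfrac", "parent_id", "sister_id",
        "pending_divisions", "rounds", "fire_area", "sizer_eps", "x_act",
        "div_target",
    )

    def __init__(self):
        self.pending_divisions = []
        self.rounds = []  # active rounds: dicts with t_init, t_term, home, firing

    def area(self, t: float) -> float:
        return self.birth_area * math.exp(self.lam * (t - self.birth_time))


def _next_initiation(cell: _Cell, t0: float, t_end: float, cfg: SimConfig,
                     rng: np.random.Generator,
                     size_mult=None) -> float | None:
    """Earliest initiation time in (t0, t_end] for the configured model, or
    None.  ``size_mult(t)`` optionally scales the model's size scale (used by
    the DnaA-dilution scenarios)."""
    if cfg.control_model == "sizer":
        thr = cell.n_ori * cfg.s_star * cell.sizer_eps
        if size_mult is None:
            t_i = cell.birth_time + (math.log(max(thr, 1e-12) / cell.birth_area)
                                     / cell.lam)
            t_i = max(t_i, t0 + 1e-9)
        else:
            # threshold varies slowly in time: fixed-point iteration
            t_i = max(t0, cell.birth_time)
            for _ in range(12):
                eff = thr * size_mult(t_i)
                t_new = cell.birth_time + math.log(eff / cell.birth_area) / cell.lam
                t_new = max(t_new, t0 + 1e-9)
                if abs(t_new - t_i) < 1e-6:
                    t_i = t_new
                    break
                t_i = t_new
        return t_i if t_i <= t_end else None
    if cfg.control_model == "adder":
        mult = 1.0 if size_mult is None else size_mult(t0)
        fire_area = cell.fire_area * mult
        if fire_area <= cell.area(t0):
            return t0 + 1e-9
        t_i = cell.birth_time + math.log(fire_area / cell.birth_area) / cell.lam
        return t_i if t_i <= t_end else None
    # fluxbalance: Euler integration of dx/dt = k_on*V - k_off*F*x/(K+x)
    dt = cfg.dt_sub
    t = t0
    x = cell.x_act
    while t < t_end:
        h = min(dt, t_end - t)
        a = cell.area(t)
        F = sum(1 for r in cell.rounds if r["t_init"] <= t < r["t_term"])
        dx = cfg.k_on * a - cfg.k_off * F * x / (cfg.K_sat + x)
        x_new = x + h * dx
        if x_new < 0:
            raise FluxBalanceIntegrationError(
                f"negative activity x={x_new:.3g} at t={t:.2f}; decrease dt_sub")
        t += h
        x = x_new
        cell.x_act = x
        if x / cell.area(t) >= cfg.theta * (1.0 if size_mult is None
                                            else size_mult(t)):
            return t
    return None


def _fire_initiation(cell: _Cell, t_i: float, cfg: SimConfig,
                     rng: np.random.Generator, firing_id: int,
                     events: list | None, record: bool) -> None:
    """Apply an initiation at time ``t_i``: all origins fire, C/D clocks start."""
    O = cell.n_ori
    a_i = cell.area(t_i)
    C_eff = cfg.C_period * (1.0 + cfg.C_period_cv * rng.standard_normal())
    C_eff = max(C_eff, 0.25 * cfg.C_period)
    t_term = t_i + C_eff
    # one spatial focus (colocalized sister forks) per origin that fired
    for j in range(O):
        cell.rounds.append({
            "t_init": t_i, "t_term": t_term,
            "home": (2 * j + 1) / (2.0 * O),
            "firing": firing_id,
        })
    if cfg.division_rule == "initiation_coupled":
        t_div = t_term + cfg.D_period + cfg.division_timing_sd * rng.standard_normal()
        cell.pending_divisions.append(max(t_div, t_i + 1e-6))
    cell.n_ori = 2 * O
    if cfg.control_model == "adder":
        delta = cfg.delta_mean * (1.0 + cfg.delta_cv * rng.standard_normal())
        delta = max(delta, 0.05 * cfg.delta_mean)
        cell.fire_area = a_i + cell.n_ori * delta
    elif cfg.control_model == "sizer":
        cell.sizer_eps = max(1.0 + cfg.sizer_cv * rng.standard_normal(), 0.1)
    else:
        cell.x_act = 0.0
    if record and events is not None:
        events.append((cell.lineage, cell.cell_id, "initiation", t_i,
                       a_i * cell.super_scale, O, cell.depth, firing_id,
                       a_i, cell.super_scale, cell.parent_id, cell.dfrac))
        events.append((cell.lineage, cell.cell_id, "termination", t_term,
                       cell.area(t_term) * cell.super_scale, O, cell.depth,
                       firing_id, cell.area(t_term), cell.super_scale,
                       cell.parent_id, cell.dfrac))


def simulate_lineages(config: SimConfig, frames: bool = True):
    """Simulate full binary pedigrees and return ``(cells, truth)`` tables.

    ``cells`` holds one row per cell per imaging frame (areas, long-axis
    extents in channel coordinates, lineage links, division fraction, QC flag).
    ``truth`` lists every ground-truth initiation, termination and division
    with its time and virtual undivided ("supercell") area.  Generations with
    index < 0 are the stationarity burn-in.  ``frames=False`` skips the
    per-frame records (empty ``cells`` table) for event-level studies that
    only consume the ground truth.
    """
    cfg = config.validated()
    root_ss = np.random.SeedSequence(cfg.seed)
    lineage_seeds = root_ss.spawn(cfg.n_lineages)
    max_depth = cfg.burnin_generations + cfg.n_generations  # exclusive

    frame_rows = []  # (cell_id, lineage, frame, t, area, parent, sister, dfrac, gen)
    events = []
    cell_meta = {}

    for li in range(cfg.n_lineages):
        rng = np.random.default_rng(lineage_seeds[li])
        counter = 0

        founder = _Cell()
        founder.lineage = li
        founder.cell_id = f"L{li:03d}C{counter:05d}"
        counter += 1
        founder.path = ""
        founder.depth = 0
        founder.birth_time = 0.0
        founder.birth_area = _founder_birth_area(cfg, rng)
        founder.lam = cfg.growth_rate_mean * (
            1.0 + cfg.growth_rate_cv * rng.standard_normal())
        founder.n_ori = 1
        founder.super_scale = 1.0
        founder.dfrac = 0.5
        founder.parent_id = ""
        founder.sister_id = ""
        if cfg.control_model == "adder":
            founder.fire_area = founder.birth_area + cfg.delta_mean
        elif cfg.control_model == "sizer":
            founder.sizer_eps = max(1.0 + cfg.sizer_cv * rng.standard_normal(), 0.1)
        else:
            founder.x_act = 0.0
        if cfg.division_rule == "independent_adder":
            inc = cfg.div_adder_mean * (1 + cfg.div_adder_cv * rng.standard_normal())
            founder.div_target = founder.birth_area + max(inc, 0.1 * cfg.div_adder_mean)

        stack = [founder]
        lineage_recorded_inits = 0
        firing_counter = 0

        while stack:
            cell = stack.pop()
            # truth is recorded for every generation; the burn-in transient
            # is marked by generation < 0 and filtered by the analyses
            record = True
            is_stationary = cell.depth >= cfg.burnin_generations
            t = cell.birth_time
            # division time: earliest pending, or set by initiations to come
            while True:
                if cfg.division_rule == "independent_adder":
                    t_div = cell.birth_time + math.log(
                        cell.div_target / cell.birth_area) / cell.lam
                else:
                    pend = [d for d in cell.pending_divisions if d > t]
                    t_div = min(pend) if pend else math.inf
                t_i = _next_initiation(cell, t, min(t_div, t + 1e5), cfg, rng)
                if t_i is None or t_i >= t_div:
                    break
                fid = f"L{li:03d}R{firing_counter:05d}"
                firing_counter += 1
                _fire_initiation(cell, t_i, cfg, rng, fid, events, record)
                if is_stationary:
                    lineage_recorded_inits += 1
                t = t_i
            if math.isinf(t_div):
                warnings.warn(
                    f"lineage {li}: cell {cell.cell_id} never initiated, "
                    "no division scheduled; truncating branch")
                t_div = cell.birth_time + 3.0 * LN2 / cfg.growth_rate_mean
                make_daughters = False
            else:
                make_daughters = cell.depth + 1 < max_depth

            a_div = cell.area(t_div)
            cell_meta[cell.cell_id] = {
                "lineage_id": li, "parent_id": cell.parent_id,
                "sister_id": cell.sister_id, "dfrac": cell.dfrac,
                "generation": cell.depth - cfg.burnin_generations,
                "path": cell.path, "birth_time": cell.birth_time,
                "division_time": t_div, "growth_rate": cell.lam,
                "super_scale": cell.super_scale,
            }
            if record:
                # for division rows the origin column holds the origin count
                # handed to the daughters (cell's origins at division)
                events.append((li, cell.cell_id, "division", t_div,
                               a_div * cell.super_scale, cell.n_ori,
                               cell.depth, "", a_div, cell.super_scale,
                               cell.parent_id, cell.dfrac))
            # per-frame records
            if not frames:
                f0, f1 = 0, -1
            else:
                f0 = int(math.ceil(cell.birth_time / cfg.frame_interval - 1e-9))
                f1 = int(math.floor(t_div / cfg.frame_interval + 1e-9))
            for f in range(f0, f1 + 1):
                tf = f * cfg.frame_interval
                if tf < cell.birth_time - 1e-9 or tf >= t_div - 1e-9:
                    continue
                frame_rows.append((cell.cell_id, li, f, tf, cell.area(tf),
                                   cell.parent_id, cell.sister_id, cell.dfrac,
                                   cell.depth - cfg.burnin_generations,
                                   cell.path))
            if not make_daughters:
                continue
            # divide
            dfrac = 0.5 + cfg.division_fraction_sd * rng.standard_normal()
            dfrac = min(max(dfrac, 0.30), 0.70)
            still_active = [r for r in cell.rounds if r["t_term"] > t_div]
            pend_after = [d for d in cell.pending_divisions if d > t_div]
            n_lo = cell.n_ori // 2
            n_hi = cell.n_ori - n_lo
            if cell.n_ori % 2 == 1 and rng.random() < 0.5:
                n_lo, n_hi = n_hi, n_lo
            kids = []
            for side, (frac, n_ori_d) in enumerate(
                    (((dfrac), n_lo), ((1.0 - dfrac), n_hi))):
                d = _Cell()
                d.lineage = li
                d.cell_id = f"L{li:03d}C{counter:05d}"
                counter += 1
                d.path = cell.path + str(side)
                d.depth = cell.depth + 1
                d.birth_time = t_div
                d.birth_area = frac * a_div
                d.lam = cfg.growth_rate_mean * (
                    1.0 + cfg.growth_rate_cv * rng.standard_normal())
                d.n_ori = max(n_ori_d, 1)
                d.super_scale = cell.super_scale / frac
                d.dfrac = frac
                d.parent_id = cell.cell_id
                d.pending_divisions = list(pend_after)
                lo_rounds = [r for r in still_active if r["home"] < dfrac]
                hi_rounds = [r for r in still_active if r["home"] >= dfrac]
                sel = lo_rounds if side == 0 else hi_rounds
                d.rounds = [dict(r, home=(r["home"] / dfrac if side == 0 else
                                          (r["home"] - dfrac) / (1 - dfrac)))
                            for r in sel]
                if cfg.control_model == "adder":
                    d.fire_area = frac * cell.fire_area
                elif cfg.control_model == "sizer":
                    # the pending event keeps its threshold draw across
                    # division (noise is per event, not per cell)
                    d.sizer_eps = cell.sizer_eps
                else:
                    d.x_act = frac * cell.x_act
                if cfg.division_rule == "independent_adder":
                    inc = cfg.div_adder_mean * (
                        1 + cfg.div_adder_cv * rng.standard_normal())
                    d.div_target = d.birth_area + max(inc, 0.1 * cfg.div_adder_mean)
                kids.append(d)
            kids[0].sister_id = kids[1].cell_id
            kids[1].sister_id = kids[0].cell_id
            # deterministic traversal order for reproducibility
            stack.append(kids[1])
            stack.append(kids[0])

        if lineage_recorded_inits == 0:
            warnings.warn(f"lineage {li}: zero recorded initiations")

    cells = pd.DataFrame(frame_rows, columns=[
        "cell_id", "lineage_id", "frame", "time_min", "area_um2",
        "parent_id", "sister_id", "dfrac", "generation", "path"])
    cells["length_um"] = cells["area_um2"].astype(float) / cfg.cell_width
    # stack cells into the channel: closed end at x=0, ordered by pedigree path
    cells = cells.sort_values(["lineage_id", "frame", "path"],
                              kind="mergesort").reset_index(drop=True)
    if len(cells):
        grp = cells.groupby(["lineage_id", "frame"], sort=False)["length_um"]
        cells["x_high_um"] = grp.cumsum()
    else:
        cells["x_high_um"] = cells["length_um"]
    cells["x_low_um"] = cells["x_high_um"] - cells["length_um"]
    cells["qc_ok"] = 1
    cells = cells[["cell_id", "lineage_id", "frame", "time_min", "area_um2",
                   "length_um", "x_low_um", "x_high_um", "parent_id",
                   "sister_id", "dfrac", "qc_ok", "generation", "path"]]

    truth = pd.DataFrame(events, columns=[
        "lineage_id", "cell_id", "event_type", "time_min",
        "true_supercell_area", "n_origins_initiated", "depth", "round_id",
        "area_um2", "super_scale", "parent_cell_id", "dfrac"])
    truth["generation"] = truth["depth"] - cfg.burnin_generations
    truth = truth.sort_values(["lineage_id", "time_min", "event_type"],
                              kind="mergesort").reset_index(drop=True)
    return cells, truth


def initiations_per_origin_per_generation(truth: pd.DataFrame) -> float:
    """Steady-state initiation rate: origins fired per origin per generation.

    Counts, over recorded generations, the total number of origins on which
    initiation fired divided by the total origins present at birth (half the
    origin count of each recorded dividing cell).  One new round per origin
    per generation gives 1.0.
    """
    rec = truth[truth.generation >= 0]
    fired = rec.loc[rec.event_type == "initiation",
                    "n_origins_initiated"].sum()
    at_birth = rec.loc[rec.event_type == "division",
                       "n_origins_initiated"].sum() / 2.0
    if at_birth == 0:
        raise ValueError("no recorded divisions")
    return float(fired / at_birth)


# ---------------------------------------------------------------------------
# imaging emulation
# ---------------------------------------------------------------------------

def emulate_detections(cells: pd.DataFrame, truth: pd.DataFrame,
                       imaging: ImagingConfig, seed: int = 0) -> pd.DataFrame:
    """Emulate foci detection on the simulated movie.

    One candidate focus per active replication round per frame, placed at the
    home long-axis position of its origin ((2j-1)/(2O) of the cell length for
    O concurrently initiated origins) plus Gaussian jitter.  Foci are present
    from initiation to termination, dropped with probability
    ``1 - detection_prob``; false positives are uniform along the cell.
    Detections falling outside the cell extent are rejected at emission.
    """
    img = imaging.validated()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    init = truth[truth.event_type == "initiation"]
    term = truth[truth.event_type == "termination"].set_index("round_id")

    # cell lifetimes and daughters (ordered by channel position at birth)
    first = cells.groupby("cell_id", sort=False).first()
    last_t = cells.groupby("cell_id", sort=False)["time_min"].max()
    daughters: dict[str, list] = {}
    for cid, row in first.iterrows():
        p = row["parent_id"]
        if isinstance(p, str) and p:
            daughters.setdefault(p, []).append(
                (float(row["x_low_um"]), cid, float(row["dfrac"])))
    for v in daughters.values():
        v.sort()

    # propagate each focus from its natal cell through divisions until the
    # round terminates: the focus follows the daughter on its side of the
    # division plane, with its home fraction remapped to the new cell
    per_cell: dict[str, list] = {}
    queue = []
    for r in init.itertuples():
        t_end = term.loc[r.round_id, "time_min"] if r.round_id in term.index \
            else np.inf
        O = int(r.n_origins_initiated)
        for j in range(O):
            queue.append((r.cell_id, r.time_min, float(t_end),
                          (2 * j + 1) / (2.0 * O), f"{r.round_id}.{j}"))
    while queue:
        cid, t0, t1, home, rid = queue.pop()
        per_cell.setdefault(cid, []).append((t0, t1, home, rid))
        if cid in daughters and len(daughters[cid]) == 2 and \
                t1 > last_t.get(cid, np.inf):
            (_, d_lo, f_lo), (_, d_hi, _f_hi) = daughters[cid]
            if home < f_lo:
                queue.append((d_lo, t0, t1, home / f_lo, rid))
            else:
                queue.append((d_hi, t0, t1,
                              (home - f_lo) / max(1.0 - f_lo, 1e-9), rid))

    rows = []
    for row in cells.itertuples():
        L = row.length_um
        foci = per_cell.get(row.cell_id, ())
        for (t0, t1, home, rid) in foci:
            if not (t0 <= row.time_min < t1):
                continue
            if rng.random() >= img.detection_prob:
                continue
            pos = home * L + img.position_jitter_sd * rng.standard_normal()
            if pos < 0.0 or pos > L:
                continue
            rows.append((row.frame, row.time_min, row.cell_id,
                         row.x_low_um + pos, pos - 0.5 * L,
                         1.0 + 0.1 * rng.standard_normal(), rid))
        n_fp = rng.poisson(img.false_positive_rate)
        for _ in range(n_fp):
            pos = rng.uniform(0.0, L)
            rows.append((row.frame, row.time_min, row.cell_id,
                         row.x_low_um + pos, pos - 0.5 * L,
                         0.7 + 0.1 * rng.standard_normal(), ""))
    # round_id is ground-truth linkage for validation; empty for false
    # positives.  Real detection tables would not carry it.
    det = pd.DataFrame(rows, columns=["frame", "time_min", "cell_id", "x_um",
                                      "pos_in_cell_um", "intensity",
                                      "round_id"])
    return det.sort_values(["frame", "x_um"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# DnaA turn-off dilution experiments
# ---------------------------------------------------------------------------

def simulate_dilution_experiment(scenario: DilutionScenario,
                                 config: SimConfig | None = None) -> pd.DataFrame:
    """Simulate DnaA turn-off experiments for a test and a reference strain.

    The test strain's per-origin initiation size is multiplied by
    ``fold^(-exponent_a)`` where ``fold`` follows :func:`dnaA_fold_change`
    (halving per generation after turn-off); the reference strain sees a
    constant fold of 1.  Lineages are simulated as single lines of descent
    ("mother lines") since only event sizes and times are consumed downstream.

    Returns a tidy per-bin table with columns ``experiment, strain, bin_index,
    time_min`` (mean event time relative to turn-off), ``mean_init_size``,
    ``mean_gen_time`` and ``n_events``.  Empty bins are omitted.
    """
    sc = scenario.validated()
    cfg = (config if config is not None else SimConfig(control_model="sizer"))
    cfg = cfg.validated()
    tau = LN2 / cfg.growth_rate_mean
    t_start = sc.turnoff_time - sc.pre_duration - 3.0 * tau  # warm-up
    t_stop = sc.turnoff_time + sc.post_duration
    edges = np.arange(-sc.pre_duration, sc.post_duration + 1e-9, sc.bin_width)

    root_ss = np.random.SeedSequence(cfg.seed)
    exp_seeds = root_ss.spawn(sc.n_experiments)
    out = []
    for e in range(sc.n_experiments):
        strain_seeds = exp_seeds[e].spawn(3)
        for strain, sseed in (("test", strain_seeds[0]),
                              ("reference", strain_seeds[1])):
            rng = np.random.default_rng(sseed)
            if strain == "test":
                def mult(t):
                    f = dnaA_fold_change(t, sc.turnoff_time, tau,
                                         sc.pre_induction_fold)
                    return float(f) ** (-sc.exponent_a)
            else:
                def mult(t):
                    return 1.0
            inits, gens = _simulate_mother_lines(cfg, sc, rng, t_start, t_stop,
                                                 mult)
            noise_rng = np.random.default_rng(strain_seeds[2].spawn(2)[
                0 if strain == "test" else 1])
            t_ev = np.array([t for t, _ in inits]) - sc.turnoff_time
            s_ev = np.array([s for _, s in inits])
            t_dv = np.array([t for t, _ in gens]) - sc.turnoff_time
            g_dv = np.array([g for _, g in gens])
            for b in range(len(edges) - 1):
                m = (t_ev >= edges[b]) & (t_ev < edges[b + 1])
                if not m.any():
                    continue  # empty bin emitted as missing
                md = (t_dv >= edges[b]) & (t_dv < edges[b + 1])
                noise = math.exp(sc.bin_noise_cv * noise_rng.standard_normal())
                out.append((e, strain, b, float(t_ev[m].mean()),
                            float(s_ev[m].mean()) * noise,
                            float(g_dv[md].mean()) if md.any() else tau,
                            int(m.sum())))
    return pd.DataFrame(out, columns=["experiment", "strain", "bin_index",
                                      "time_min", "mean_init_size",
                                      "mean_gen_time", "n_events"])


def _simulate_mother_lines(cfg: SimConfig, sc: DilutionScenario,
                           rng: np.random.Generator, t_start: float,
                           t_stop: float, size_mult):
    """Single-line-of-descent simulation used by the dilution scenarios.

    Returns (initiations, generations): lists of (time, per-origin size) and
    (division time, generation time).
    """
    record_from = sc.turnoff_time - sc.pre_duration
    inits, gens = [], []
    for _ in range(sc.n_lines):
        cell = _Cell()
        cell.lineage = 0
        cell.cell_id = "m"
        cell.birth_time = t_start + rng.uniform(0, LN2 / cfg.growth_rate_mean)
        cell.birth_area = _founder_birth_area(cfg, rng)
        cell.lam = cfg.growth_rate_mean * (
            1.0 + cfg.growth_rate_cv * rng.standard_normal())
        cell.n_ori = 1
        cell.super_scale = 1.0
        cell.dfrac = 0.5
        cell.parent_id = cell.sister_id = ""
        if cfg.control_model == "adder":
            cell.fire_area = cell.birth_area + cfg.delta_mean
        elif cfg.control_model == "sizer":
            cell.sizer_eps = max(1.0 + cfg.sizer_cv * rng.standard_normal(), 0.1)
        else:
            cell.x_act = 0.0
        while cell.birth_time < t_stop:
            t = cell.birth_time
            while True:
                pend = [d for d in cell.pending_divisions if d > t]
                t_div = min(pend) if pend else math.inf
                t_i = _next_initiation(cell, t, min(t_div, t_stop + 200.0),
                                       cfg, rng, size_mult=size_mult)
                if t_i is None or t_i >= t_div:
                    break
                O = cell.n_ori
                a_i = cell.area(t_i)
                if record_from <= t_i < t_stop:
                    inits.append((t_i, a_i / O))
                _fire_initiation(cell, t_i, cfg, rng, "", None, False)
                t = t_i
            if math.isinf(t_div):
                break
            if record_from <= t_div < t_stop:
                gens.append((t_div, t_div - cell.birth_time))
            # keep one daughter (the mother at the channel bottom)
            dfrac = min(max(0.5 + cfg.division_fraction_sd
                            * rng.standard_normal(), 0.30), 0.70)
            a_div = cell.area(t_div)
            child = _Cell()
            child.lineage = 0
            child.cell_id = "m"
            child.birth_time = t_div
            child.birth_area = dfrac * a_div
            child.lam = cfg.growth_rate_mean * (
                1.0 + cfg.growth_rate_cv * rng.standard_normal())
            child.n_ori = max(cell.n_ori // 2, 1)
            child.super_scale = 1.0
            child.dfrac = dfrac
            child.parent_id = child.sister_id = ""
            child.pending_divisions = [d for d in cell.pending_divisions
                                       if d > t_div]
            child.rounds = [dict(r) for r in cell.rounds if r["t_term"] > t_div]
            if cfg.control_model == "adder":
                child.fire_area = dfrac * cell.fire_area
            elif cfg.control_model == "sizer":
                child.sizer_eps = cell.sizer_eps
            else:
                child.x_act = dfrac * cell.x_act
            cell = child
    return inits, gens
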