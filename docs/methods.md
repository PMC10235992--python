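# Methods

`replicycle` re-implements a single-cell analysis of bacterial
replication-initiation control: it simulates mother-machine lineages under
three candidate control models, emulates replisome-foci detection, and runs
the full postprocessing chain — supercell assembly, focus tracking, event
calling, fork plots, and the correlation / dilution statistics that
discriminate between the models.  This note documents the models, the
conventions and parameter choices, and what the synthetic data can and
cannot establish.

## Cell and cell-cycle model

Cells are described by their area (µm²) at constant width, so area is
proportional to length.  Each cell grows exponentially,
`a(t) = a_birth · e^{λt}`, with a per-cell growth rate drawn as
`λ ~ Normal(λ̄, cv·λ̄)`.  The default doubling time is 90 min
(`growth_rate_mean = ln2/90`), a slow-growth condition in which replication
rounds do not overlap: with the default C = 42 min (replication) and
D = 18 min (termination-to-division), initiation falls ~30 min into the
cycle and termination ~18 min before division.  Faster growth
(doubling < C+D) produces overlapping rounds and two-origin initiations;
the simulator supports this regime and the fork-plot tests exercise it.

Division follows Cooper–Helmstetter coupling: every initiation schedules a
division C + D later (Gaussian timing noise, `division_timing_sd` = 2 min).
The C period itself varies per round (`C_period_cv` = 0.10), reflecting
biological variability in replication speed; without it the termination
size would be a deterministic function of the initiation size and the
partial-correlation analysis would degenerate.  Division splits the area
into fractions `dfrac` and `1 − dfrac` (`dfrac ~ Normal(0.5,
division_fraction_sd)`, default sd 0.03; 0 gives perfectly symmetric
division), and origins, replication forks (by position), the
initiation-control state and any pending division times are partitioned
between the daughters.  An alternative `independent_adder` division rule
(a birth-to-division area adder, uncoupled from replication) is available
because replication and division are known to decouple.

## Initiation-control models

All models fire on every origin simultaneously, doubling the origin count;
per-origin quantities divide by the number of origins that fired.

**Sizer.**  Initiation fires when the per-origin area reaches
`s*·(1 + ε)`, `ε ~ Normal(0, sizer_cv)` drawn independently per event.  The
pending event's threshold draw is inherited across division (noise is
attached to the event, not the cell); redrawing it at division would let a
daughter be "born past" a threshold its mother never crossed, creating a
spurious negative correlation between consecutive initiation sizes.
Consecutive per-origin initiation sizes are independent: ρ = 0.

**Per-origin adder (initiator accumulation).**  After an initiation at
area `a` with `2O` origins present, the next initiation fires when the cell
(or its descendants, proportionally to `dfrac`) has added `2O·δ` of area,
`δ ~ Normal(δ̄, cv·δ̄)` i.i.d. per event.  In per-origin units this is the
AR(1) recursion `s' = s/2 + δ`: stationary mean `2δ̄`, stationary variance
`(4/3)·Var(δ)`, and correlation between consecutive initiation sizes
exactly 1/2.  The defaults (`δ̄ = 0.5 µm²`, cv 0.15) put the per-origin
initiation size at 1 µm².  With asymmetric-division noise switched on the
measured correlation rises slightly above 1/2 (division noise feeds extra
variance into the physical size while the increment noise is unchanged);
the adder-signature checks therefore run with symmetric division, which is
also the condition under which the ρ = 1/2 result is derived.

**Flux balance (initiator activation/deactivation cycling).**  A per-cell
activity `x` follows `dx/dt = k_on·V − k_off·F·x/(K + x)` (Euler substeps
`dt_sub`, default 0.5 min; a substep coarse enough to drive `x` negative
raises an error rather than clipping), where `F` is the number of active
fork pairs.  Initiation fires when `x/V ≥ θ` and `x` resets to 0.  `K`
defaults to `θ/10` so the deactivation is effectively saturated (a sharp
switch).  `k_on` defaults to the steady-state balance
`λ·(2θ·s* + k_off·C)/s*`, derived by integrating production and (saturated)
deactivation over one generation at the target per-origin initiation size
`s*`.  Note a structural property of this fork-coupled variant at slow
growth: between termination and the next initiation there are no active
forks, deactivation vanishes, and the accumulated activity carries memory
of the previous cycle — consecutive initiation sizes are then strongly
correlated rather than sizer-like.  This matches the biological argument
that fork-dependent deactivation (RIDA-like) cannot be the dominant
controller in slow growth; the model still maintains exactly one
initiation per origin per generation, which is the property asserted in
tests.

Founder cells start near their model's steady-state birth size (the
adder's fixed point is a per-origin birth size of exactly `δ̄`), and a
burn-in of `burnin_generations` (default 2; 3–4 in the statistical tests)
is marked with negative generation indices so analyses can restrict to the
stationary regime.  Full binary pedigrees are simulated (every daughter),
since supercell assembly requires sisters and daughters to be tracked.

## Imaging emulation

One focus per active replication round per frame (sister forks are treated
as one colocalized spot), at the origin "home" position: with `O`
concurrently fired origins, fractions `(2j−1)/2O` of the cell length,
j = 1..O — one round at midcell, two rounds at ±L/4.  Foci persist from
initiation to termination and follow the daughter on their side of the
division plane, with the home fraction remapped.  Gaussian localization
jitter (default sd 0.05 µm), missed detections (`detection_prob`, default
0.9), and uniform false positives (default 0.01 per cell per frame) are
applied; detections falling outside the cell are rejected at emission.
The detection table carries a ground-truth `round_id` column (empty for
false positives) used only for validation — a real detection table would
not have it.

## Supercells

Three to five tracked generations along one line of descent are
concatenated into a "supercell" whose area is the size the cell would have
had if its ancestors had not divided: generation 0 contributes its raw
area, and for generation i ≥ 1

    A_t = A_last + 2^i · (a_c(t) − dfrac · a_p_last),

with `A_last` the supercell area just before the parent divided, `a_c` the
current cell's area, `dfrac` its area fraction of the two sisters right
after division and `a_p_last` the parent's final area.  The factor is read
as `2^i`: it is the only reading that makes `A_t` continuous at divisions
and reduces to `A_t = 2^i·a_c` under perfect halving.  Negative `A_t`
(pathological segmentation) flags the frame out of downstream fits.

A lineage qualifies only if every path member, its parent, its sister and
both daughters are tracked for at least `min_frames` frames (default 8, a
per-dataset setting).  Supercells share cells only in their first (parent)
generation; deeper overlap is resolved deterministically in favour of the
lexicographically first path, so the supercell set is reproducible.
Positions are mapped onto the supercell long axis by assigning each
generation the sub-segment implied by its cumulative division fractions
(generation 0 spans the whole axis; each daughter takes the low end of its
parent's segment), scaled to µm by `A_t / width`.

## Tracking

A deliberately simple linker stands in for full LAP/Kalman particle
tracking: greedy reciprocal nearest-neighbour assignment per frame pair
(globally cheapest remaining link first, which is mutual-nearest among the
remainder), a displacement budget of `max_disp` (0.5 µm) per elapsed
frame, gap closing up to `max_gap` (2) frames with linear interpolation, a
`merge_radius` (0.25 µm) within which a converging track is consumed by
the longer one (its end is then not a termination candidate), and
split-born flags for tracks appearing next to a live one (their starts are
not initiation candidates).  Track length is the frame span including
gap-closed frames.  The downstream contracts only need reliable track
starts and ends; the linker is validated against ground truth on simulated
data rather than against a reference tracker.  Detections are processed in
a canonical sort order, so results do not depend on input row order.

## Event calling

A track start is an initiation iff the track is at least `min_track_len`
frames long (11 by default, 9 in the slow-growth `acetate` preset), starts
more than `edge_exclusion` (2) frames after the supercell begins, is not
split-born, and the ±`qc_window` (2) frames around the start are well
segmented (`qc_ok`, consumed as a boolean; the upstream segmentation
quality metric is out of scope).  A track end is a termination iff it ends
more than `edge_exclusion` frames before the supercell ends, was not
consumed by a merge, and passes the position rule: for rounds initiated
close to division (start within `close_to_div_frames` ≈ C/2 of the
generation's last frame) the end must lie within `midcell_tol_px ·
pixel_size` (5 px · 0.08 µm) of the current generation's midcell;
otherwise it must lie within the boundary of the current (daughter)
generation's segment.  Every filter is individually switchable and every
rejection is counted, so accepted + per-filter rejections = candidates.
Supercells without at least one initiation and one termination are
dropped.  Event size is `A_t` at the event frame.

The initiation-size distribution is fitted by least squares with a sum of
Gaussians on the binned histogram.  The component count (when `k='auto'`)
is the number of distinct peaks of a kernel-smoothed density computed in
log size — replication rounds sit at 2× spacings, so components are evenly
spaced there with comparable widths — using a prominence threshold of 10%
of the density maximum.  Summary statistics are read from the component
farthest from the supercell size-span edges, where truncation bias is
smallest.

## Correlation statistics

All ordered event pairs of a requested relation are formed within each
supercell, annotated with their round offset.  The default cluster
selection keeps the requested offset (1 for consecutive relations) and
drops whole round clusters whose sizes lie within one cluster standard
deviation of the supercell size-span extremes (edge clusters are
size-biased because events beyond the span are unobservable); a
density-mode strategy is available as a fallback.  The selected cluster's
2D histogram is fitted with `w·G₂(µ, Σ) + b` (constant background, `b ≥
0`), ρ being a direct fit parameter with a 67% CI from the fit covariance;
a plain Pearson estimator is available for cross-validation.  The partial
correlation `ρ_T,I2|I1 = (ρ_TI2 − ρ_TI1·ρ_I1I2)/√((1−ρ_TI1²)(1−ρ_I1I2²))`
removes the confounding of the termination/next-initiation relation by the
shared previous initiation; it is property-tested against the
residual-regression oracle.

## DnaA turn-off dilution analysis

In a turn-off scenario the initiator concentration is
`pre_induction_fold · 2^{−max(0, t − t_off)/τ}` (halving per generation by
growth dilution) and the test strain's per-origin initiation size is
multiplied by `fold^{−a}`; the reference strain sees fold 1.  Default
scenarios: `wt-turnoff` (a = 0.2) and `triple-turnoff` (a = 0.4, emulating
loss of DARS1/DARS2/datA), each with 6 replicate experiments, 30-min bins
over −90..+240 min around the swap, `pre_induction_fold = 2` (the test
strain starts mildly over-expressed, so its phenotype crosses the
reference about one generation after the swap — the alignment bin then
falls naturally on an early post-swap bin), 100 mother lines per strain
per experiment, and 5% multiplicative lognormal noise per bin.  Dilution
runs use single lines of descent (one surviving daughter per division)
because only event sizes/times and generation times are consumed.

The analysis aligns each experiment at the bin minimising the relative
test/reference size difference, evaluated on a 3-bin running mean of the
log ratio so the choice does not chase single-bin noise (raw argmin
selection correlates the normalisation with the noise and biases the
exponent low by ~0.02); a manual override is supported.  Fold change is
normalised to 1 at that bin, time to generations using the *reference*
strain's mean generation time — after turn-off the test strain's division
interval stretches to τ/(1−a) while growth dilution still halves the
concentration per volume-doubling time, so the unperturbed reference is
the correct clock.  Expected concentration is `2^{−normalized
generations}` with times clamped at the swap.  The exponent is the
zero-intercept least-squares slope of log fold change on −log
concentration, clipped at 0.

## Problem sizes and numerical choices

The statistical checks use ~700 pedigrees × 3 recorded generations
(≈ 65,000 consecutive-initiation pairs, a few seconds each), dilution
scenarios as configured above, and an imaging-scale run of 25–30 pedigrees
× 5 generations for the end-to-end pipeline checks.  Histogram fits use 40
bins per axis (2D) or 60 bins (1D); fork plots default to 40 size × 60
position bins spanning the 1st–99th size percentile.  Mixture fits retry
from histogram-peak initial values before failing with diagnostics.  All
randomness flows from a single seed through `numpy` `SeedSequence` spawns
(one per lineage/experiment), so identical configurations reproduce
byte-identical tables.

## What the synthetic data does and does not show

The generator reproduces the structural features the pipeline depends on:
exponential growth, C+D-coupled division, origin-indexed foci with
detection noise, supercell geometry, and the distinct correlation
signatures of the control models.  It does not emulate segmentation
artifacts (the `qc_ok` flag is always clean in generated data; QC-filter
behaviour is tested on toy inputs), focus mobility beyond i.i.d. jitter,
intensity-dependent detection, width variation across media, sister-fork
splitting into two resolvable foci late in the C period, or replication
fork stalling.  Passing tests therefore demonstrate correctness of the
postprocessing chain under known ground truth, not performance on real
microscopy, where tracking and segmentation errors dominate.  Known
limitations: in the `independent_adder` division rule, rounds can span
divisions and their recorded ground-truth termination sizes extrapolate
the natal cell's growth; and the flux-balance model's consecutive-size
correlation is a consequence of its fork-coupled deactivation, not a
tunable target.
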