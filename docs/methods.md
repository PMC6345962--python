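# Methods

## The model

A population of `N` hippocampal place cells encodes the connectivity of an
arena through temporal coactivity.  The simulation is phenomenological
throughout: spiking is an inhomogeneous Poisson process, synapses are
probabilities, and the cognitive map is a simplicial complex.

**Arena and trajectory.**  The arena is a `w × h` cm rectangle with optional
disc obstacles (default: 100 × 100 cm with one central disc of radius
20 cm).  The trajectory is a correlated random walk: speed lognormal around
`speed_mean` (default 20 cm/s, CV 0.3), heading diffusing with standard
deviation `turn_rate·√dt` rad per step (`turn_rate` = 2 rad/√s), specular
reflection at walls and obstacle rims, timestep `dt` = 25 ms.  These values
give even coverage — after one simulated hour every accessible 10-cm bin is
visited and the dwell-time CV across bins is below 0.5 — which is what
"non-preferential exploration" must deliver for learning-time estimates to
be meaningful; the walk has no goals, rewards or behavioural structure
beyond that.

**Place-cell spiking.**  Cell `c` fires at rate
`λ_c(r) = f_c · exp(−|r − r_c|²/(2 s_c²))`, θ-modulated by
`m(t) = 1 + d·cos(2π f_θ t + φ_c)` with `f_θ = 8 Hz`, depth `d = 0.7` and a
uniform random per-cell phase.  The modulation time-averages to one, so it
redistributes spikes within θ cycles without changing spatial rate maps.
Spikes are drawn per trajectory timestep (piecewise-constant rate within
each 25-ms step), placed uniformly in the step, and are exactly reproducible
per seed.

**Ensemble statistics.**  The parameters quoted for an ensemble are the mean
peak rate `f` (Hz) and the mean place-field *size* `s` (cm) — the field's
visible extent, about three Gaussian widths (`s_c = size_c/3`).  Peak rates
and field sizes are lognormal with variances `a·f` (Hz²) and `b·s` (cm²),
`a = 1.2`, `b = 1.7`; at the default `f = 20`, `s = 15` this gives CVs of
about 0.25 and 0.34.  This convention is a deliberate design decision: field
sizes quoted for recorded place cells are extents, not Gaussian widths, and
dispersion must be moderate for map formation to be possible at all.  We
verified the alternative readings empirically: with the dispersion read as a
standard-deviation ratio (CV 1.2/1.7), every 150-cell ensemble contains
several giant-field "hub" cells whose spikes bridge the obstacle, the
obstacle loop is filled in every seed, and no parameter regime forms a
correct map — the model would contradict its own headline behaviour.  With
the conventions above, correct maps form reliably (see below), in minutes,
and degrade as synapses weaken.  Mean Gaussian widths above ≈7 cm likewise
fill the 40-cm obstacle hole regardless of dispersion, which is the model's
version of "overly large place fields prevent learning".

**Synapses.**  Transmission (`p_k`, one per cell) and readout response
(`q`, one readout per unordered cell pair) are lognormal with modes `p̂`,
`q̂` and variances `c_p·p̂²`, `c_q·q̂²` (`c_p = c_q = 0.04`, i.e. an SD of
0.2 of the mode — a config choice; the proportionality to the squared mode
makes the distribution shape mode-independent).  Values are truncated to
(0, 1] by inverse-CDF sampling of the conditional-below-one distribution;
this is distributionally identical to resampling and, because a single
uniform per unit is reused across modes, it is *quantile-coupled*: lowering
the mode lowers every realized probability.  Spike screening keeps each
spike of cell `k` with probability `p_k` (i.i.d., no plasticity), using one
fixed uniform per base spike; coactivity detection partitions time into
consecutive windows of `w = 250 ms` (two θ periods; also the timestep of all
topological computations), and each (pair, window) with at least one
retained spike from each cell is accepted with probability `q` of that
pair's readout, using a counter-based uniform keyed by (seed, pair, window).
The three couplings together make sweeps over `p̂` or `q̂` monotone: the
detected event set at a lower mode is a subset of the one at a higher mode,
so the effective graph and complex are nested — an exact, testable version
of "the effective complex is a subcomplex of the original".

**Coactivity complex.**  Vertices are cells with at least one retained
spike (weight = spike count, time = window of first spike); edges are pairs
with at least one detected coactivity (time = first detection window,
weight = Pearson correlation of the two cells' per-window spike-count
vectors, NaN-safe).  Cliques of this graph are cell assemblies; a clique
enters the filtration at the *maximum* of its edges' first-detection times —
cumulative, not simultaneous: an assembly counts once all of its pairwise
coactivities have ever been seen.  A consequence worth stating: a 3-clique
is never born after its boundary cycle, so transient ("spurious") loops are
always chord-free cycles of length ≥ 4 — they die when a missing diagonal
coactivity is finally detected.  The default dimension cap is 2
(vertices/edges/triangles), which determines `b_0` and `b_1`; `b_2` of the
final complex is verified separately (below).

**Persistence.**  Homology is over GF(2).  Dimension 0 uses union-find with
the elder rule; higher dimensions use the standard boundary-matrix column
reduction with columns stored as Python-integer bitsets (XOR = column
addition, highest set bit = pivot), dimension by dimension.  Zero-length
intervals are dropped.  Representative cycles for 1D classes are shortest
cycles through the creating edge in the birth-time 1-skeleton (BFS);
representatives are not unique, and the reported loop length is the length
of this particular minimal representative.  The engine is cross-checked
interval-for-interval against an independent, naive dense GF(2) reduction
(in `tests/gf2_oracle.py`) on random filtered clique complexes, and the
Euler–Poincaré identity is asserted at every sampled time.

**Final Betti numbers of large complexes.**  Full clique enumeration of a
dense 150-vertex graph is infeasible beyond dimension 2, so final Betti
numbers (including `b_2`) are computed after a *strong collapse*: iterated
removal of dominated vertices (closed neighbourhood contained in another
vertex's), which preserves the homotopy type of the flag complex and
typically shrinks the coactivity graph to a small core in milliseconds; the
core's clique complex is then small enough for exact GF(2) ranks.

**Learning time.**  `b_k(t)` is sampled once per coactivity window.
`T_min` is the earliest sampled time from which every later sample matches
the target Betti tuple — `(1, 1)` for the one-obstacle arena — up to the
horizon; if the final sample mismatches, the outcome is a failure and
`T_min` is undefined.

**Forman curvature.**  For an edge `e = (v₁, v₂)`:
`R_F(e) = w(v₁) + w(v₂) − Σ_{e'∋v₁, e'≠e} w(v₁)√(w(e)/w(e')) −
Σ_{e'∋v₂, e'≠e} w(v₂)√(w(e)/w(e'))`, the two sums running over the other
edges at each endpoint; vertex curvature is the mean over incident edges.
Non-positive correlation weights are floored at 10⁻³ (the square root
requires positive weights; the estimator and sign handling are config
choices).  On unit weights this reduces exactly to `4 − deg(v₁) − deg(v₂)`,
which fixes the sign convention: densely connected, heavily weighted cores
are the most *negative*.  Accordingly, in this package's results the
"importance" of an edge is the curvature magnitude — edge survival under
synaptic weakening anti-correlates with raw `R_F` and correlates positively
with `|R_F|`, and the mean curvature magnitude of the effective graph
decreases as `p̂` decays.

## Fits and sweeps

Learning-time divergence is fitted as `T = A(x − x_crit)^−κ` by least
squares of `log T` against `log(x − x_crit)` over a coarse-to-fine grid of
critical-point candidates; medians over repeats are fitted, for robustness
where times become highly variable near criticality.  Fits with exponent
below 0.05 or dynamic range below a factor of two are flagged
non-divergent.  The critical mode from a success/failure sweep is the
threshold crossing (default 50%) of the success-fraction curve, refined by
a logistic fit; a sharp 0→1 step returns the first successful grid point.
Saturating tails in log–log critical-surface fits (successive slope
magnitude < 0.05 or sign reversal) are excluded and flagged.  The
compensation relation `δq̂ = −(κ/ϰ)·δp̂·(q̂ − q̂_crit)/(p̂ − p̂_crit)`
follows from equating the two first-order learning-time variations.

All sweeps share the session (trajectory, ensemble, base spikes) across
grid points within a repeat (common random numbers) and run sequentially;
results are bit-identical for identical configuration and seeds.

## The nine-field toy

`make_fig2_fixture` builds a deterministic miniature: seven fields on a ring
(radius 24 cm, width 6 cm, 10 Hz) around a 12-cm obstacle plus two outer
bulge fields (25 Hz, width 5.5 cm), traversed in id order by a scripted
waypoint path (parking dwells on specific overlaps).  The ideal pipeline on
it yields exactly one immortal component; one immortal loop born when the
path first closes around the obstacle; and a spurious quadrilateral loop
(two ring + two bulge cells) born when the quad's last side is detected and
killed when the path parks on a diagonal overlap.  Because transient loops
require chord-free 4-cycles (see above), the classical "return before the
triple overlap is visited" story cannot produce one here; the bulge
construction is its honest counterpart under the cumulative clique
convention.  The toy's geometry, path and default spike seed are fixture
design: they were chosen so that the scripted narrative is realized (11 of
12 spike seeds show it; the default seed does).

## Problem sizes and what the tests show

Desk-scale study conditions, used by the test suite and the acceptance
script: `N = 150` cells, `f = 20 Hz`, `s = 15 cm`, 30 simulated minutes in
the 100 × 100 cm arena with a 20-cm obstacle.  One full run (72 000
trajectory steps, ~10⁵ spikes, 7 200 windows, ~2 000 edges, ~10⁴
triangles) takes about two seconds; the acceptance script (15 full runs)
about a minute.  Under these conditions ideal synapses recover
`b₀ = b₁ = 1`, `b₂ = 0` in ≥ 8 of 10 seeds with learning times of one to
six minutes; learning degrades monotonically as `p̂` decreases, with
failures appearing below `p̂ ≈ 0.3` at this scale (smaller, sparser
ensembles fail earlier).  The critical mode therefore sits lower than in
cluster-scale ensembles whose pairs coactivate only a handful of times per
session — edge survival through screening depends directly on per-pair
coactivity counts, which these desk-scale conditions make large.

The synthetic generator emulates stationary Gaussian place fields, Poisson
spiking and stationary synaptic statistics.  It does not emulate phase
precession, bursting, refractoriness, plasticity, behavioural structure
(goals, rewards, head direction), or remapping; passing tests therefore
show that the topological machinery and the synaptic screening behave as
specified under the model's assumptions, not that real CA3/CA1 populations
would show the same critical values.

## Known limitations

* Edge weights use Pearson correlation of windowed counts; other estimators
  (e.g. jittered coincidence counts) would change curvature values, though
  not the unit-weight closed form.
* Representative-cycle lengths depend on the BFS tie-breaking.
* The strong-collapse route computes final Betti numbers only; the
  persistence timeline is capped at dimension 1 by default.
* Truncating the lognormal synaptic distributions at 1 means that for modes
  near 1 the realized mean lies below the mode; this is inherent to placing
  a lognormal mode near the upper end of the probability range.
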