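# Methods

## Template model

A template is a pair `(C, M)` of `q1 × q2` binary arrays: phase bits and an
occlusion mask (1 = valid).  The default geometry is 8 × 128 = 1024 bits, one
channel of a Gabor-type iris code.  Rows are circular (column 1 and column
q2 are horizontally adjacent), which models the angular wrap of an unwrapped
iris ring; vertical adjacency is open.  A minimum of three columns is
enforced because a two-column circular row would make the same pair of sites
adjacent twice, and adjacency is a set of edges.

Coordinates are 0-based `(row, col)` internally.  The 1-based column-major
linear index `k = i + (j − 1) q1` used in the lattice-model notation is an
explicit conversion layer (`univariate_index` / `univariate_position`), so
positions quoted in that convention can be tested without off-by-one drift.
Bits are stored as `{0, 1}`; the Ising modules view them as spins via the
fixed bijection `0 ↔ −1`, `1 ↔ +1`.

Serialization is deliberately plain: a text format for templates (header,
phase block, blank line, mask block) and JSON for partial templates.  Both
are artifact conventions — no standard format exists for this data.

## Distances

Scores are accumulated as integer counts (mismatches, overlap size `l`,
lattice size `N`) with one final division, so equal inputs give
bit-identical scores and the distributed-matching equivalence below can be
asserted as exact rational equality.

`d_H` is undefined at `l = 0` and raises; `d_H′` is defined there and equals
0.5.  This asymmetry is deliberate — a probe that hides every bit is exactly
the hole the occlusion attack exploits, and the modified metric's purpose is
to price it.  The bridge `d_H′ = 0.5 − (0.5 − d_H)·l/N` is exposed
separately (`modified_from_plain`) because the central matching server uses
it on pooled counts without access to bits.

## Division schemes

All three schemes partition the lattice and divide the mask identically.
Block-form uses a configurable `(rows, cols)` grid; the default for `m`
partials is the column-band grid `(1, m)` (8 × 128/m blocks), which respects
the row-circular rotation topology.  R-dispersion randomly permutes all
positions into `m` equal groups.  Z-dispersion shuffles the 0-positions over
`m/2` partials and the 1-positions over the other `m/2` — the simplest
construction giving value-homogeneous partials; group sizes are as equal as
integer splitting allows, so partial sizes are reported alongside any
experiment that uses them.  Every scheme takes a single RNG seed and no
global state; `reassemble` is the shared partition oracle.

## Distributed matching

Rotation is modeled as integer circular column shifts, the standard
iris-code alignment convention; the default grid is ±8 columns.  A padded
partial probe carries the probe's bits at every position a silo could need
across the whole shift grid, so one transfer serves all angles.  Silos
return `(d_ij, a_ij)` only — the `Silo` object keeps its partial private, so
aggregation physically cannot read bits.  The per-angle pool is computed as
summed integer numerators, making "distributed = monolithic" an exact
identity rather than a floating-point approximation; the final score is the
minimum over angles, with ties resolved toward the smallest `|shift|`, then
toward the negative shift.  Cells with `a_ij = 0` carry weight zero; an
angle with no defined cell is skipped; if every angle is skipped the
comparison is rejected explicitly (this corner is undefined in the source
formulation and must not silently score).

## Seeded Ising model and sampler

The Gibbs law on spin lattices conditioned on frozen seeds uses couplings
`J = (J_v, J_h) = (0.2, 0.3)` (vertical, horizontal).  Up to normalization,
`π(x) = exp(−2 J_v d_v − 2 J_h d_h)` with `d_v, d_h` the disagreeing edge
counts — vertical edges `q2 (q1 − 1)` in total (open), horizontal `q1 q2`
(circular rows).

The sampler is single-site Metropolis.  One iteration is one proposal: a
free (non-seed) site is drawn uniformly, the flip ratio is computed from the
site's neighborhood as `exp(−2 x_k (J_v S_v + J_h S_h))` with `S_v, S_h` the
neighbor spin sums, and the flip is accepted when the uniform draw falls
below `min(1, ratio)`.  Snapshot indices are proposal counts; index 0 is the
initial state.  Initialization defaults to i.i.d. uniform free spins from
the run's own generator (maximum-entropy choice; the procedure only requires
*some* state in the seed-consistent space); a caller-supplied initial state
is accepted for trajectory replay and validated against the seeds.  Draw
order is fixed and documented — initialization first, then proposal indices
and acceptance uniforms in pre-drawn blocks from the same generator — so
trajectories are bit-reproducible from one seed.  No separate burn-in is
applied: the r-type attacks vote over snapshots from `n_1` on, matching the
reference procedure literally.

Correctness is established against `enumerate_gibbs`, an independent
exact-enumeration oracle (refused above 20 free bits): on a 2 × 3 lattice
with two frozen seeds, 10^6 proposals thinned 1:10 land within total
variation 0.05 of the exact law (measured ≈ 0.004), and the local flip ratio
is checked against the full `π` ratio to 1e−12 plus detailed balance on
random instances.

## Attacks

The occlusion attack places the leaked bits in an otherwise zeroed phase
array and validates exactly the leaked positions.  Reconstruction attacks
freeze the leaked bits as seeds; `t^n` is a chain endpoint (default
`n = 10^5`), `r^n` the per-position majority over snapshots at
`n_j = 1000 j`, `j = 1..100`, with the tie rule sum ≥ 0 → +1.  Leaked
partials are used as seeds verbatim, including any occluded positions —
the reconstruction procedure treats a partial purely as bit values.

Z-dispersion leaks are value-homogeneous, which an unadjusted Ising chain
would propagate into unrealistic single-value templates, so they are first
extended to a complementary partial `c(s)`: a uniformly drawn disjoint
position set `I′` with `|I′| = |I|`, values placed randomly so 0-bits make
up 50% of `I ∪ I′` (rounded up when odd).  Bagged variants draw `k`
independent complementary partials (default 10) and majority-vote the `k`
reconstructions; each bag runs on its own deterministic sub-stream of the
attack seed, so the whole attack is replayable.  Reconstructed templates
carry an all-valid mask — they pose as complete probes — while the
occlusion-attack probe carries the leak-shaped mask; this is the only
reading under which both attack families face the same thresholds.

## Evaluation harness

`match_rate` is the empirical CDF with inclusive threshold; FMR and
1 − FNMR are the same functional applied to impostor and genuine scores, and
IMR is it applied to intruder scores (for r-type attacks, the scheme's risk
of leakage).  EER is the crossing of the two empirical curves, linearly
interpolated on a 1e−3 threshold grid (no canonical procedure exists; this
one is deterministic and exact for separable or identical score sets).
Default thresholds are 0.4 and 0.431 — the operating point under `d_H` and
its FMR-equivalent under `d_H′` — each applied to both metrics.

`run_leakage_experiment` replays the full pipeline per subject: divide the
reference, leak one uniformly chosen partial, mount the configured attacks
(occlusion, `t^n`, `r^n` everywhere; bagged variants for Z-dispersion),
score against the original reference (*Leaked Template Not Replaced*) or a
fresh recapture (*Leaked Template Replaced*) under both metrics, and
tabulate IMR per (scheme, attack, size, metric, threshold) cell with
comparison counts and mean partial sizes.  All randomness derives from one
master seed through named spawn keys, so tables are reproducible
element-for-element.

## Synthetic population

Subject patterns are drawn from the package's own sampler: ~1/6 of the
sites are frozen at random spins and the chain is run 20 proposals per site.
This yields the two properties the experiments need — ≈50% zero bits and
spatial clustering, so reconstruction attacks have real structure to exploit
(i.i.d. bits would show no attack signal at all).  Recaptures flip each bit
independently at rate 0.2, placing genuine scores at ≈0.20 and impostor
scores at ≈0.50; with the 8 × 128 geometry both distributions clear the 0.4
threshold by several standard deviations (≥95% on each side is asserted).
Optional occlusion masks are a contiguous band plus i.i.d. speckle with
calibrated expected fraction.

What the generator does *not* emulate: correlated recapture noise
(real same-eye differences concentrate near mask boundaries), realistic
occlusion statistics, subject-dependent quality variation, and the exact
score histograms of any real dataset.  Consequently the harness reproduces
the *ordering structure* of the reference results — IMR non-increasing in
division count, majority-vote attacks at least as strong as endpoint
attacks, the modified metric suppressing the occlusion attack — but not
their numerical values, which are dataset-bound.

## Problem sizes and numerical choices

The structural IMR experiment in the test suite runs 50 subjects with
`n = 10^4` proposals, snapshot schedule `1000·(1..10)`, and `k = 5` bags —
large enough for the orderings to be stable under the fixed seeds, small
enough to keep the whole suite under a minute of sampling.  Production-scale
defaults (`n = 10^5`, schedule `1000·(1..100)`, `k = 10`) remain the
constructor defaults.  Monte-Carlo averages in the acceptance script use
2000 replicates (standard error ≈ 0.0006 on the 0.2 mean).  All stochastic
tests pin their seeds; property tests iterate ≥100 (round-trips), ≥200
(distributed equivalence), or ≥500 (flip-ratio) random instances.

## Known limitations

- Single binary channel only; real deployments combine two Gabor channels.
- Silos are process-local objects: the architecture is modeled, not the
  transport or authentication around it.
- `(J_v, J_h)` is fixed at (0.2, 0.3); no estimation from data.
- The EER of the synthetic population is an artifact of the generator's
  noise model and should not be read as a biometric accuracy claim.
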