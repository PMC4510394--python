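# Methods

## Data model

The unit of analysis is a spot-volume table: one non-negative volume per
(spot, group, replicate), exactly two groups, and per spot the same
replicate count in both groups.  Volumes are kept in the input's units;
the packaged ten-spot reference table stores its printed ×10⁻² display
values verbatim.  A spot is *absent* from a group iff all its replicate
volumes are exactly zero — absence is never imputed: a missing cell in a
wide-format table is a parse error, because silently zero-filling would
fabricate qualitative presence/absence changes.  Total-density
normalization divides each volume by its gel's summed volume over a
validated spot set and rescales (default 100), making gels comparable;
it is idempotent at a fixed scale and fails loudly on an all-zero gel.

## Random numbers

All resampling and simulation flows through one minimal-standard
multiplicative congruential generator, x ← a·x mod m with a = 16807 and
m = 2³¹ − 1, advanced by Schrage's factorization (q = ⌊m/a⌋ = 127773,
r = m mod a = 2836) so no intermediate exceeds the signed 32-bit range.
Seed 0 is rejected (absorbing state) rather than remapped.  Uniforms are
state/m, strictly inside (0, 1), so a resampling index ⌊u·n⌋ can never
reach n.  One analysis run consumes a single stream, spot by spot in
input order (reference group first); the order and seed are echoed in
the report header, making every run replayable.

Batch generation uses a leapfrog decomposition: after 1024 scalar steps,
each further block of 1024 states is the previous block times
a¹⁰²⁴ mod m, one exact vectorized 64-bit multiply-mod.  The batch path
is bit-identical to repeated scalar stepping (tested) — it is an
implementation of the same sequence, not a different generator.

## Bootstrap and BC intervals

Per (spot, group), B = 2000 (default) resamples of size N yield the
empirical distribution of the mean.  With p the proportion of bootstrap
means strictly below the observed mean, clamped to
[1/(2B), 1 − 1/(2B)] so z₀ = Φ⁻¹(p) stays finite, the 1−α interval
takes the bootstrap-mean quantiles at Φ(2z₀ ∓ z), z = Φ⁻¹(1 − α/2),
each as the nearest-rank ⌈qB⌉ order statistic (an epsilon of 10⁻⁹
before the ceiling keeps analytically integer ranks, e.g. q·B = 10 at
the 99% level, from floating-point bump-up).  No acceleration constant
is used (BC, not BCa).  A degenerate bootstrap distribution — all
replications identical, as for an all-zero or constant group — yields a
flagged point interval rather than an error, because absent spots must
flow through the pipeline.

Tie handling in p is configurable.  `strict` (default, used for the
reported per-spot bias) counts only strictly smaller replications.
`midrank` adds half the exactly-equal ones.  The distinction matters
because the bootstrap mean has an atom exactly at the observed mean:
resamples that are permutations of the full sample, mass N!/Nᴺ ≈ 9.4%
at N = 4.  Under `strict` that whole atom lands on the "not below"
side, displacing p by about half the atom (≈ 4.7 points at N = 4) for
any symmetric continuous distribution.

## Bias statistic

|100·p − 50| percentage points; 0 for a symmetric empirical sampling
distribution, bounded by 50, N/A for absent spots.  Zero-inflated
samples produce the statistic's characteristic large values — three
zeros plus one positive value gives p = (3/4)⁴ ≈ 0.316 under the strict
rule, a bias of 18.4 — which is the regime real 2-DE data occupy when a
protein is near the detection limit.  The reference table contains one
printed bias of 51.0; the statistic cannot exceed 50, so the fixture
stores the printed value verbatim while the computation enforces the
bound.

For *aggregate* comparisons across distribution families the benchmark
harness computes the bias diagnostic under the midrank rule: the strict
rule's constant at-mean-atom offset (≈ 4.7 points) otherwise dominates
the shape signal, making symmetric data score *higher* than moderately
skewed data.  With ties split, the diagnostic is ≈ 2.3 for normal data
and rises with lognormal skew (≈ 2.7 at σ = 2), which is the ordering
the harness is meant to detect.  Per-spot reporting keeps the strict
definition.

## Significance rules

Default: a spot is called at a level iff the two groups' BC intervals at
that level are disjoint; shared endpoints count as overlap
(conservative), and nesting of the 95% interval inside the 99% one makes
calls monotone across levels.  The alternative `diff_ci` rule resamples
both groups, forms the BC interval of the mean difference, and rejects
when it excludes zero.  The overlap rule is *not* fully conservative at
N = 4: measured coverage of the nominal-95% BC interval for normal data
is ≈ 0.79 (scipy's percentile and BCa bootstrap give ≈ 0.78 under the
same conditions — this is intrinsic small-sample bootstrap
undercoverage, not an implementation artifact), and the disjointness
rate under an iid lognormal null is ≈ 0.07 rather than ≤ 0.05.  The
test suite pins both to oracle-derived bands ([0.70, 0.90] coverage,
≤ 0.10 null rejection) instead of nominal ones.

Baselines: pooled-variance two-sided Student t (Welch via config); both
groups constant is handled explicitly (p = 1 when equal, p = 0 with a
degenerate flag when not).  Mann–Whitney is exact for N+M ≤ 12 by
enumerating all C(N+M, N) assignments of the pooled midranks and
counting assignments whose U deviates from N·M/2 at least as much as
observed (the enumeration distribution is symmetric about N·M/2 with or
without ties); larger samples use the normal approximation with tie and
continuity corrections.

## Effect measures

DV = V̄_trt − V̄_ref from plain arithmetic group means (the same
estimates the bootstrap resamples — not bias-corrected means).
FC = V̄_trt/V̄_ref, with ratios below one reported as the negative
reciprocal; exact equality maps to +1.0 (the "below one" rule is
strict); one zero mean gives ±∞; both zero is an error.  RC divides
each DV by the set-wide max|DV|, guaranteeing RC ∈ [−1, +1] with the
extreme spot at ±1.  The literal variant that normalizes by |max DV|
(largest *signed* DV) is available (`signed_max`) but can push |RC|
past 1 whenever the largest decrease exceeds the largest increase, so
the magnitude normalizer is the default; on the reference table the two
coincide.  The normalizer is per analyzed spot set — RC is a relative,
experiment-internal measure by construction.  Change-strength labels
band |RC| at 1/3 and 2/3 (configurable), with presence/absence spots
labelled qualitative regardless of |RC|.

## Synthetic data

The generator emulates the features of real spot-volume data that drive
the statistics: non-negative support, right skew, and zero inflation at
N = 4 replicates.  Families: normal (mean/sd; draws clipped at zero —
negligible mass for the volume-like parameter ranges used), lognormal
(log-scale μ/σ; σ ∈ [1, 2] spans moderate-to-heavy skew, with σ = 2 the
default "heavily skewed" setting), gamma (shape/scale).  All draws are
inverse-CDF transforms of LCG uniforms — fixed one-uniform-per-draw
consumption keeps interleaved streams reproducible, which Box–Muller or
rejection sampling would break.  Dropout is group-wise (a whole
(spot, group) becomes zero), matching 2-DE presence/absence, and may be
set per group; one uniform decides dropout whenever the group's
probability is positive.

`replicate_table1_regime` rebuilds a full replicate-level dataset from
the reference table by moment matching: per (spot, group) with printed
mean m and standard error se, N = 4 gamma draws with mean m and
standard deviation se·√N (shape = (m/sd)², scale = sd²/m); zero-mean
groups become exact zeros.  Gamma is used because its support matches
volumes; the ST6GAL1-type row with se = m yields shape 0.25 — a
heavily zero-inflated-looking distribution, which is faithful to what
such a mean/SE pair implies.

What passing simulation tests do **not** show: real gels add spot
detection and matching errors, spatially correlated staining, and
between-gel normalization noise, none of which the generator models.
Conclusions about the tests' relative behavior transfer only insofar as
the marginal volume distributions dominate those effects.

## Problem sizes and numerical choices

Defaults follow the small-gel-study regime: N = 4 replicates, B = 2000
bootstrap replications, 95%/99% levels.  The simulation suite uses 500
datasets for type-I checks and 600–800 spots for aggregate diagnostics
— sizes at which the binomial Monte-Carlo error of a rate is ≈ 1
percentage point, small enough to separate the effects under test.
Enumeration oracles are exact: ≤ Nᴺ = 256 ordered resamples at N = 4,
≤ C(12, 6) = 924 group assignments for the exact Mann–Whitney.

## Known limitations

* BC (not BCa) intervals undercover at N = 4 (≈ 0.79 actual for
  nominal 0.95); the CI-overlap decision inherits this and is therefore
  mildly anticonservative under heavy-tailed nulls.  This is a property
  of the method implemented, documented rather than patched.
* The strict-rule bias statistic confounds distributional skew with the
  at-mean resampling atom at very small N; use the midrank variant when
  comparing distribution shapes.
* No multiple-testing correction is applied; spot sets in this workflow
  are small and pre-selected.
* RC depends on the analyzed spot set through its normalizer; adding or
  removing spots rescales all RC values.
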