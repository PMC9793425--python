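# Methods

## The model

`founderfit` estimates the parameters of a founder event from the
genetic-length spectrum of long haplotype sharing: identity-by-descent (IBD)
segments between individuals of a modern cohort, and runs of homozygosity
(ROH) within modern or ancient individuals.

The size history is piecewise with three epochs (diploid sizes, discrete
generations, time `t` counted backward from the present):

- **ancestral**: constant `N_a` for `t >= T_b`;
- **bottleneck**: constant `N_b` for `T_b - d <= t < T_b`;
- **expansion**: exponential interpolation from the size at the end of the
  bottleneck to the present-day size `N_c`,
  `N(t) = N_c (N_start / N_c)^{t/(T_b - d)}`.

Epoch boundaries are older-closed: `t = T_b` belongs to the ancestral epoch,
`t = T_b - d` to the bottleneck.

The two-population variant splits the population at `T_b` into a founder
subgroup of size `N_b` and an unsampled subgroup of size `N_a - N_b`; the
two are isolated (no migration) until they merge at the end of the
bottleneck with proportions `f : 1 - f`, after which the merged pool grows
exponentially from `N_g` (default: tied to `N_b`) to `N_c`.

### Coalescence-time distributions

For a pair of haplotypes the time to the most recent common ancestor
(TMRCA), counted in generations before the sampling time `t_s`, follows the
discrete-generation coalescent: hazard `h(u) = 1 / (2 N(t_s + u))` in
generation `u`, so `q(u) = h(u) prod_{v<u} (1 - h(v))`.  Computation is
truncated at `U_max` (default: 5 N_a generations past `T_b`); the remaining
mass is carried analytically as a geometric tail at rate `1/(2 N_a)`,
which is exact because the history is constant there.  Sizes below one
diploid individual (hazard > 0.5) are rejected as outside the model's
regime.

ROH-specific features:

- **No sib mating**: zero hazard in the `no_recent_coalescence` most recent
  generations (default 2 in ROH mode, 0 in IBD mode), applied to ancient
  and modern ROH alike.
- **Consanguinity**: a fraction `kappa` of individuals are children of
  first cousins.  Such an individual's haplotype pair coalesces through the
  pedigree loop with probability 1/16 (the first-cousin inbreeding
  coefficient) exactly 3 generations before sampling, and otherwise follows
  the population distribution.  The headline analyses here default to
  `kappa = 0`; the mixture is exposed for sensitivity work.

In the two-population model, lineages can coalesce during the split epoch
only if they occupy the same subgroup.  IBD pairs sampled after the merge
enter the epoch in states (both-founder, both-other, split) with
probabilities `(f^2, (1-f)^2, 2f(1-f))` — independent assignment of each
lineage by its merge-time origin.  ROH pairs are a single individual's two
haplotypes: when the individual was sampled before the merge (an ancient
genome inside the split epoch), both lineages necessarily occupy that
individual's subgroup (`subpop_assignment`), for however many split-epoch
generations remain above the sampling time.

### Expected segment counts

Conditional on a TMRCA of `u` generations before sampling, the two
haplotypes are separated by `2u` meioses, so recombination breakpoints fall
at rate `a = 2u` per Morgan.  On a chromosome of map length `L` Morgans the
expected number of shared segments of length `l` has density
`[a^2 (L - l) + 2a] e^{-a l}` for `0 < l < L` plus an atom `e^{-a L}` at
`l = L` (the whole chromosome co-inherited).  Both chromosome-edge segments
and the whole-chromosome event are included.  Bin integrals use the
antiderivative `F(l) = e^{-a l} (a (l - L) - 1)`; the expected count over
all lengths is `1 + a L`, i.e. breakpoints + 1 — an identity used as a test.

The expectation per length bin marginalizes over the TMRCA distribution and
scales by the number of haplotype pairs `P`: `lambda_b = P [ sum_u q(u)
E_b(u) + tail ]`.  From `n` diploid individuals, `P = C(2n, 2) - n`
between-individual pairs in IBD mode and `P = n` within-individual pairs in
ROH mode.  The `u`-sum is truncated at the analytic horizon
`u* = 60 / (2 l_min)` Morgans⁻¹ — beyond it every bin is suppressed by at
least `e^{-60}` — and the geometric tail is summed in blocks until an
increment falls below 1e-12 of the running total.  Because the horizon
argument needs `l_min > 0`, the lowest bin edge must be strictly positive
(the analysis bins all start at 4 cM).

### Composite likelihood and fitting

Counts per bin are modeled as independent Poisson with means `lambda_b`;
the composite log-likelihood sums `K_b ln(lambda_b) - lambda_b - ln(K_b!)`
over bins (log-gamma factorials retained, so absolute values are
comparable).  Datasets combine on the **per-pair** scale — the joint
objective is the sum of per-pair composite log-likelihoods — so a
16-individual ancient ROH cohort contributes on equal footing with ~810k
modern IBD pairs.

Fitting maximizes the objective by differential evolution within bounds
(`N_a` in [5e2, 1e5], `N_b` in [50, 1e5], `N_c` in [1e4, 1e8], sizes on a
log10 scale; `T_b` in [20, 100], `d` in [1, 60], `f` in [0.01, 0.99]),
seeded and deterministic.  Constraint violations (`d > T_b - 1`, `N_b >
N_a - 1`, invalid models) return a sentinel value below every finite
likelihood rather than raising, so the population search can traverse them.

**Integer timing search.** Under the discrete-generation hazard the
likelihood is piecewise in `T_b` and `d`: moving either continuously
changes nothing until an epoch boundary crosses an integer generation, at
which point the objective jumps.  The surface over integer timing cells has
narrow interleaved diagonal valleys (onset and duration compensating at
nearly constant expansion-start time `T_b - d`) with several local optima.
The fitter therefore rounds the timings to integers inside the objective
and, after the stochastic search, runs a windowed grid refinement over
timing cells (±10 generations): every cell gets a coarse Nelder-Mead polish
of the continuous size parameters, warm-started from the best adjacent
cell; the leading cells are polished fully, re-seeded from the overall best
sizes (cells can hide secondary size basins); the window re-centers until
the best cell is a fixed point.  On noiseless study-scale counts this
recovers the generating parameters exactly; continuous-timing search with
generic polish stalls on the ridge.

**Identifiability caveat.** With 11 length bins the composite likelihood
constrains the bottleneck intensity strongly but the timing/size
combination only through a curved ridge.  For some Poisson noise draws at
study scale the *global* maximum lies at a distant parameter combination of
nearly equal fit quality.  Point estimates should always be read together
with bootstrap intervals; the acceptance script reports medians over three
replicate studies for this reason.

### Bootstrap and model selection

Confidence intervals are parametric-bootstrap percentiles ([2.5, 97.5], 100
replicates by default): each observed bin count is redrawn as
`Poisson(K_b)` and the free parameters refit, starting from the point
estimate's neighborhood with a full-space restart on failure; replicate
failures are excluded (error if more than 20% fail).

Model selection compares the two-population against the single-population
fit via the gain `Delta` in joint per-pair log-likelihood.  The null
distribution is generated parametrically: counts simulated as Poisson at
the single-population fit's expectations, both models refit, and `p = (1 +
#{Delta* >= Delta}) / (n + 1)` — the add-one convention avoids zero
p-values.  Because `f = 1` is outside the open search box, the
two-population fit additionally polishes the embedding of the single-model
optimum (`f` at its upper bound, `N_g = N_b`), which keeps the nesting
inequality `Delta >= 0` within optimizer tolerance.

## Synthetic data

`sample_counts` draws binned counts as independent Poisson at the analytic
means — the same generative convention the parametric bootstrap uses.
`simulate_segments_mc` is an independent segment-level oracle: per pair it
draws a TMRCA from the coalescent distribution (inverse transform,
geometric tail included), then scatters `Poisson(2uL)` breakpoints
uniformly per chromosome and emits every inter-breakpoint interval
(terminal intervals and whole chromosomes included).  The TMRCA is held
constant along the genome within a pair — deliberately the same
approximation the closed form makes, so the two routes must agree; a full
ancestral-recombination-graph simulation would not match the formula
exactly and is out of scope.  The optional `max_tmrca` argument suppresses
segment emission for pairs with older coalescence; such pairs contribute
`< e^{-16}` expected segments above 4 cM by `u = 200`, so comparisons
restricted to the analysis bins are unaffected while the breakpoint count
stays tractable.

`generate_study` packages the study conditions: a modern cohort of 637
diploid genomes observed through IBD in 11 one-cM bins on [4, 15) cM
(810,264 haplotype pairs), and an ancient cohort of 16 individuals sampled
26 generations before present observed through ROH in one-cM bins to 15 cM
plus [15,20), [20,30), [30,40) — a 40-cM cap.  The default generating model
is the split/merge bottleneck (`N_b = 627`, `T_b = 46`, `d = 22`,
`f = 0.52`); `StudyConfig.single_pop_default()` gives the single-population
variant (`N_b = 1563`, `T_b = 41`, `d = 20`).  The ancestral and modern
sizes are not constrained by the sources the defaults emulate; they are
fixed once at `N_a = 5000` (comfortably above both bottleneck sizes, in the
range of effective-size estimates for medieval European and Jewish
populations) and `N_c = 1e6` (modern Ashkenazi effective size, order
millions; at study scale the data barely constrain `N_c` beyond "large").

What the generator does *not* emulate: segment-detection error (false
positives, length biases, power loss for short segments), correlation
between overlapping haplotype pairs (the composite likelihood ignores it,
and so does the Poisson generator), linkage of TMRCA along the genome, and
phasing or genotyping error.  Passing tests therefore demonstrate
correctness of the inference machinery under its own model assumptions, not
robustness to caller artifacts in real data.

## Post-processing rules

`merge_roh_gaps` merges two adjacent ROH when the gap is ≤ 0.5 cM, both are
≥ 2 cM, and at least one is ≥ 4 cM, iterating left-to-right until stable —
a merged run can anchor a further merge (the single-pass variant is not
idempotent; iteration makes the operation idempotent, which is tested).
`filter_high_roh_individuals` drops individuals whose segments strictly
longer than 4 cM sum to strictly more than 50 cM (likely close-kin
parents); both inequalities are strict, so exactly 50 cM is retained.

## Numerical and design choices

- All internal lengths in Morgans; every interface is in centimorgans.
- Bin membership is half-open `[lo, hi)`; a segment exactly on a lower edge
  belongs to that bin; segments at or beyond the top edge are dropped and
  counted.
- Readers require the `_cM` suffix on coordinate columns and reject
  undeclared or Morgan/bp units rather than guessing.
- Two-sided exact tests use the method of small p-values with a (1 + 1e-7)
  relative tie tolerance — the convention of standard statistical software;
  p-values are rounded to two decimals only at the reporting layer.
- The founder-allele simulation is pseudo-haploid: each genotyped ancient
  individual contributes one binomial draw (`n_i` trials, not `2 n_i`).
- Determinism: every stochastic routine takes a seed; derived seeds come
  from `numpy.random.default_rng(seed)` integer streams, and two runs with
  the same seed produce identical outputs.

## Problem sizes used in the test suite

Scaled to desk hardware as the package's own test design: Monte-Carlo
oracle comparisons use 1e5 segment-simulator pairs and 1e6 lineage-pair
replicates; single-population recovery uses the full 810,264-pair spectrum
with all five parameters free; the joint two-population demonstration runs
10 seeded studies freeing `(N_b, f)` with the timing epoch conditioned on
its generating values (16 ancient pairs do not identify `T_b, d` jointly
with them — see the identifiability caveat); model-selection calibration
runs 20 studies × 50 bootstrap replicates at 200,000 IBD pairs with `N_b`
(and `f`) free.

## Known limitations

- Composite likelihood: no correlation between pairs or bins; intervals
  are parametric-bootstrap under the same independence assumptions.
- No migration during the split epoch, at most two subgroups, no external
  gene flow.
- The consanguinity model is a single point-mass pedigree loop; real
  pedigrees are more varied.
- X chromosome and genetic-map interpolation from physical coordinates are
  out of scope; segment tables must already carry genetic lengths.
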