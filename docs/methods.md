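# Methods

This note records the models implemented in purgekit, the conventions chosen
where the literature leaves room, and what the validation machinery does and
does not establish.

## Pedigree conventions

A pedigree is a table of (id, sire, dam) with optional sex, fitness and time
columns.  Identities are opaque strings compared exactly after whitespace
trimming (no case folding, to avoid silent aliasing).  `0`, `NA`, `*` and
empty fields are accepted as unknown-parent codes on input (configurable);
output always writes `NA`.  All coefficients operate on a topologically
sorted pedigree (parents before offspring, ties broken by input order) with
individuals renumbered to dense indices internally.

Two conventions matter downstream:

- **One known parent.** The unknown side of a record behaves as an
  unrelated, non-inbred founder line in every coefficient.  Consequently the
  founder partition of partial inbreeding includes one column per
  unknown-parent slot (labelled `<id/sire>` / `<id/dam>`); without these
  columns the partition Σ_j F_i(j) = F_i would not close, because an allele
  entering through an unknown parent can still coalesce in descendants.
- **Selfing** (sire = dam) is accepted with a warning; every recursion
  handles it (the parent pair degenerates to a self-kinship).

## Inbreeding coefficients

`F` is computed by memoized recursive kinship: `F_i = f(s_i, d_i)`,
`f(x, x) = (1 + F_x)/2`, expanding the younger member of a pair into its
parents.  The test suite holds this implementation against two independent
oracles — Wright's path-counting formula over common ancestors and the dense
tabular relationship matrix — with exact (1e-12) agreement on random
pedigrees.

`Fa` follows Ballou's recursion,
`Fa_i = ½ Σ_{p ∈ {s,d}} [Fa_p + (1 − Fa_p) F_p]`.  This treats "the parent
is autozygous now" and "the parent's allele was autozygous earlier" as
independent events.  They are not independent in pedigrees where an ancestor
is autozygous *for an intermediate ancestor's alleles* (closed lines inbred
every generation, or the correction fixture in the test suite): there the
recursion overstates the probability that gene dropping measures, by a few
percent.  The package therefore ships both: `compute_Fa` (the field's
standard recursion) and `gene_drop(..., statistic="Fa")` (the unbiased Monte
Carlo estimate).  The acceptance suite asserts their agreement where the
independence assumption holds and asserts (rather than hides) the
divergence on the autozygous-intermediate fixture.

### Partial inbreeding F_i(j)

`F_i(j)` uses **label-at-j semantics**: the two alleles present in ancestor
`j` are the origin labels; `i` is autozygous-from-`j` when its two alleles
are copies of the same label, or copies of the two distinct labels and those
are themselves IBD (probability `F_j`).  The recursion is a kinship
restricted to the labelled pair (`φ(j,j) = (1+F_j)/2`; lineages not passing
through `j` contribute 0; the self-pair term tracks the single-allele
descent probability), evaluated bottom-up as a vectorised tabular fill (a
numba kernel) so that all ancestors of a 1000+-individual pedigree are
feasible.

An alternative reading ("`i` is autozygous for an allele that was *carried
by* `j`") counts IBD events whose coalescent ancestor is older than `j` but
whose lineage passes through `j`.  The two definitions differ for
non-founder `j`: e.g. for the child of two inbred full sibs, label-at-j
attributes all autozygosity to the founders and none to the sibs, so the
expressed opportunity of purging contributed by such sib ancestors is 0.
Label-at-j was chosen because it makes the founder partition exact, matches
the gene-dropping experiment (labels seeded at `j`), and is self-consistent
with the `2 F_i(j) F_j` term of `Oe` (the `F_j` factor is precisely the
distinct-label IBD case).  The gene-drop oracle embodies the same semantics,
so Monte Carlo concordance verifies the implementation, not the choice.

## Opportunity of purging

Raw coefficients: `O(i) = Σ_j Σ_k (1/2)^(n−1) F_j` over inbred ancestors `j`
and all paths `k` from `i` to `j` (`n` individuals on the path including
both ends), and `Oe(i) = Σ_j 2 F_i(j) F_j`.  Path weights are accumulated by
the expected-contribution recursion `W_i = (W_s + W_d)/2`, `W_{j,j} = 1`,
which sums `(1/2)^(n−1)` over all paths without enumerating them; an
exhaustive path-enumeration oracle checks exact agreement in the tests.

**Heuristic correction.** When several autozygous individuals lie on one
line of descent the same exposure is counted repeatedly.  Instead of the
exact (non-scalable, deeply nested) corrections, the entire contribution of
a far ancestor `k` to `O(i)`/`Oe(i)` is dropped whenever some intermediate
ancestor `j` (ancestor of `i`, descendant of `k`) has `F_j(k) > 0`
(strictly, > 1e-12).  The decision is per ancestor, not per path: if any
qualifying intermediate exists on any `i -> k` line, `k` is dropped.  The
correction can only remove contributions, so corrected ≤ raw always.

**Capping.** In lines inbred every consecutive generation the intermediates
have `F_j(k) = 0`, the correction cannot fire, and the sums overshoot
(`O > 1`, `Oe > F`).  Such values are clamped to `O = 1`, `Oe = F` and
flagged.  Raw and corrected/capped values are both reported because they act
as upper and lower bounds on the expected load decline.

## Purged inbreeding g(d)

The purging coefficient `d ∈ [0, 0.5]` is the recessive component of
deleterious effects; `g(d)` is the expected frequency of still-surviving
deleterious recessives in homozygosis.  The ideal-population recursion is

    g_t = [1/(2N) + (1 − 1/(2N)) g_{t−1}] · (1 − 2 d g_{t−1}),  g_0 = 0,

implemented in `g_recursion`.  For pedigrees the package uses a purged
kinship table filled in sorted order:

- pairs where neither member is an ancestor of the other expand **both**
  members into their parents at once, multiplied by `1 − 2d·(g_x + g_y)/2` —
  one attenuation per generation step;
- ancestor–descendant pairs expand the descendant only, multiplied by
  `1 − 2d·g_descendant`;
- purged self-kinship is `(1 + g_x)(1 − 2d·g_x)/2`, and `g_i` is the purged
  kinship of `i`'s parents.

At `d = 0` every factor is 1 and the table is exactly the ordinary kinship
matrix, so `g(0) = F` to machine precision.  Under ideal Wright–Fisher
mating the expectation of this recursion reproduces the `g_t` series term by
term (the derivation matches the new-coalescence, carried-over and selfing
terms separately).  Empirically, 400 neutral replicates (N = 25, 50
generations) show no detectable bias at `d = 0` and a residual second-order
bias ≤ 0.003 at `d = 0.25` (covariance between realized pair attenuation and
transmitted kinship), well inside the between-replicate noise of any
10-replicate comparison.  `0 ≤ g(d') ≤ g(d) ≤ F` for `d' > d` holds by
construction and is property-tested.

## Expected load

`B = B0 (1 − Oe/F)`, with the convention that `Oe/F = 0` when `F = 0` (no
opportunity without inbreeding, so the prediction stays at the base load
`B0`).  Computed with raw `Oe` the curve is an aggressive (upper-bound)
decline that can go negative in late cohorts; with corrected/capped `Oe` it
is conservative.  The observed decline in simulations falls between the two.

## Demography

Equivalent complete generations: `t_i = ((t_s + 1) + (t_d + 1))/2`, an
unknown parent contributing 0.  Realized effective size uses the individual
increase in inbreeding: `ΔF_i = 1 − (1 − F_i)^{1/(t_i − 1)}` over
individuals with `t_i > 1`, `Ne = 1/(2·mean ΔF)` with a delta-method SE.
This estimator needs only the pedigree; in neutral simulations at census 25
it recovers ~22–23 (a known mild downward bias from shallow early cohorts,
within the 20% band used in validation).  Founder statistics use expected
founder-genome proportions (`q` vectors propagated as parent means);
`effective founders = 1/Σ q_k²` over known founders (anonymous unknown-parent
lines are excluded from the sum — pooling them would understate diversity).
Cohort summaries group by the `time` column when present, else by `round(t)`
(documented approximation).

## Forward simulator

Diploid individuals carry unique (infinite-sites) mutations with selection
coefficient `s` (point mass or gamma, optional extra lethal mass) and
dominance `h` (constant, or decreasing with `s`).  Fitness is
multiplicative: `W = Π(1 − h s) · Π(1 − s)` over heterozygous and homozygous
sites; mutation count per offspring is Poisson(`U`).  Selection is soft —
parents are drawn with probability proportional to `W`, census fixed by the
schedule — under `random` (with replacement; the ideal Wright–Fisher
reference used for calibration), `random_no_selfing` (default) or
`monogamous` mating.  The recorded pedigree starts at the last base-
population cohort (the founders, time 0); the burn-in only shapes their
mutational composition.  Per-individual inbreeding load is
`B_i = ½ Σ_het s(1 − 2h)`, the expected log-fitness decline per unit F if
heterozygous sites were made homozygous at random — homozygous sites are
already expressed and contribute nothing.

The **purging-favorable preset** uses fully recessive lethals
(`s = 1, h = 0`) at `U = 0.5` per diploid per generation, with a base
population of 200 for 200 generations and a bottleneck of 25 for 50
generations.  These are deliberately harsh, desk-scale study conditions
under which purging is strong and quick to measure: the founder cohort
carries a mean load of B0 ≈ 8 lethal equivalents, and the bottleneck
typically halves the expressed load.  What the simulator does *not* emulate:
linkage and recombination structure (every site is independent),
environmental fitness variance, mildly deleterious variation (whose purging
the opportunity-of-purging model deliberately ignores), overlapping
generations, and unequal sex ratios.  Passing validation on these pedigrees
therefore shows the coefficient machinery is internally correct and that the
load predictions bracket the truth under the model's own assumptions — not
that any particular real studbook satisfies those assumptions.

## Validation statistics

Monte Carlo comparisons use binomial standard errors computed from the exact
probability at 1e5 replicates, with the panel-wide rule "≥ 99% of
comparisons within 3 SE, none beyond 5" (≈ 80 simultaneous comparisons make
isolated 3 SE excursions expected).  Trajectory comparisons (cohort-mean F
and g against the ideal series, 10 replicates, every one of 50 generations)
estimate the between-replicate SE with a 5-generation rolling pooled
variance: the replicate SD is nearly constant across generations, and the
pooling stabilises an otherwise 9-df estimate whose chance excursions would
otherwise dominate a 50-fold simultaneous 3 SE check.  Qualitative curve
shapes (non-increasing predicted load) are asserted on 5-generation block
means of replicate-pooled curves with a 1%-of-B0 numerical tolerance,
because single-cohort means jitter with cohort composition.

## Numerical choices and edge cases

- Probability-sum checks (founder partition) use 1e-10 absolute tolerance;
  oracle equivalences use 1e-12; the strict-positivity test in the
  correction uses 1e-12.
- Gene dropping derives one RNG stream per individual from the master seed,
  so estimates are independent of traversal order and bit-reproducible.
- Degenerate inputs: founders have `F = Fa = g = O = Oe = 0` identically; a
  pedigree with no individual deeper than `t = 1` refuses to estimate `Ne`
  with an explanatory error; `d` outside `[0, 0.5]` and negative `B0` are
  rejected before any computation.
- `ancestor_paths` reports paths distinct as node sequences (under selfing
  the sire and dam slots trace the same chain once); the path-weight
  recursion used for `O` counts both transmission routes, as the
  `(1/2)^(n−1)` weights require.

## Known limitations

- Ballou's `Fa` is an approximation wherever ancestral autozygosity is
  correlated with current autozygosity (see above); use `gene_drop` when an
  unbiased estimate matters.
- The heuristic correction is per-ancestor; in pedigrees where an
  intermediate lies on some but not all lines to a far ancestor it discards
  slightly more than the exact nested correction would.
- `g(d)` on pedigrees carries a second-order (≲ 0.003 at d = 0.25, N = 25)
  downward bias relative to the ideal-population series; the estimator of
  `d` itself (regression against fitness) is out of scope.
- The simulator's soft selection keeps census exactly fixed; extinction
  dynamics and demographic rescue are out of scope.
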