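# purgekit

Inbreeding and genetic-purging analysis for pedigreed populations.

Small populations accumulate inbreeding (F), which exposes deleterious
recessive alleles in homozygosis.  Exposure lets selection remove ("purge")
those alleles, so the fitness cost of inbreeding — the inbreeding load B, in
lethal equivalents — can decline over generations.  Detecting and quantifying
that decline from studbook pedigrees is the purpose of this package.  It is
aimed at conservation geneticists and breeders who keep pedigree records
(individual, sire, dam, optionally sex, fitness and birth cohort) and want
per-individual coefficients rather than population averages.

## What it computes

For every individual `i` in a pedigree:

- **Wright's inbreeding** `F_i`: the probability its two alleles at a neutral
  locus are identical by descent (IBD), computed by the recursive kinship
  method (`F_i = f(sire, dam)`, `f(x,x) = (1+F_x)/2`).
- **Ancestral inbreeding** `Fa_i` (Ballou's recursion): the probability a
  random allele of `i` has already been exposed in IBD homozygosity in an
  ancestor, `Fa_i = ½ Σ_p [Fa_p + (1−Fa_p) F_p]` over the two parents.
- **Partial inbreeding** `F_i(j)`: the probability `i` is autozygous for
  alleles derived from ancestor `j` (the two allele labels at `j`); summed
  over founder lines it partitions `F_i` exactly.
- **Opportunity of purging** (for inbred ancestors `j`, paths `k` with `n`
  individuals each):

      O(i)  = Σ_j Σ_k (1/2)^(n−1) F_j          (total)
      Oe(i) = Σ_j 2 F_i(j) F_j                 (expressed)

  with a heuristic correction that drops a far ancestor's contribution when
  an intermediate ancestor is already autozygous for its alleles, and caps
  `O ≤ 1`, `Oe ≤ F` where the heuristic overshoots.  Raw and corrected values
  are always reported side by side: they bracket the expected load decline.
- **Purged inbreeding** `g(d)`: `F` discounted by the purging coefficient
  `d ∈ [0, 0.5]` for the expected removal of deleterious recessives; `g(0) = F`.
- **Expected load** `B = B0 (1 − Oe/F)` per individual and per cohort.
- **Demography**: equivalent complete generations `t`, per-individual
  `ΔF = 1 − (1−F)^{1/(t−1)}`, realized `Ne = 1/(2 mean ΔF)`, founder counts
  and effective founders, cohort summaries.

A forward simulator (`purgekit.simulate_population`) generates
purging-favorable pedigrees — a large base population at mutation–selection
balance under recessive deleterious mutations, bottlenecked to a small census
— with per-individual fitness and true inbreeding load, so the coefficient
pipeline can be validated against a known truth.

## Worked example

A pedigree in which half sibs `H1`, `H2` share an inbred sire `J`
(`F_J = 1/4`, the child of full sibs `P x Q`), and `I = H1 x H2`:

```sh
$ purgekit coef -i demo.tsv -o demo_coef.tsv --what F,Fa,O,Oe,g --d 0.25
$ cat demo_coef.tsv
id   F        Fa     O_raw  O      O_capped  Oe_raw    Oe        Oe_capped  capped_flag  g_d0.25
...
J    0.25     0.0    0.0    0.0    0.0       0.0       0.0       0.0        False        0.25
H1   0.0      0.125  0.125  0.125  0.125     0.0       0.0       0.0        False        0.0
I    0.15625  0.125  0.125  0.125  0.125     0.078125  0.078125  0.078125   False        0.13671875
```

Reading the `I` row: `F = 5/32` (half-sib mating through an inbred sire);
`Fa = 1/8` (each parental allele passed through `J`, which was autozygous
with probability 1/4); `O = 1/8` (two paths of three individuals to `J`:
`2 · (1/2)² · 1/4`); `Oe = 2 · F_I(J) · F_J = 2 · 5/32 · 1/4 = 5/64` — all of
`I`'s autozygosity is for alleles carried by its inbred ancestor, so most of
its load is expected to have been exposable in `J`.  `g(0.25) < F` because
part of the IBD burden is expected to have been purged.  No value needed
correction or capping here (`O_raw = O`, `capped_flag` false).

The demography summary for the same file:

```sh
$ purgekit pop -i demo.tsv -o demo_pop.tsv
$ cat demo_pop.json
{ "n": 10, "founder_count": 4, "effective_founders": 3.67,
  "mean_F": 0.0406, "max_t": 3.0, "Ne": 6.03, "Ne_se": 4.29 }
```

The other subcommands are `purgekit validate` (pedigree QC),
`purgekit simulate` (forward simulation; writes pedigree, trajectory and
provenance files) and `purgekit predict-load` (cohort-level `B0 (1 − Oe/F)`
curves).  Everything is also available as library functions
(`purgekit.compute_F`, `compute_Fa`, `partial_F_matrix`,
`compute_opportunity`, `compute_g`, `g_recursion`, `expected_load`,
`realized_Ne`, `founder_stats`, `gene_drop`, ...).

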