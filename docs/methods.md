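# Methods

This note documents the models, defaults and numerical choices behind
`paraseg`, and what the synthetic data can and cannot establish.

## Sliding-bin pooling

Per-cytosine methylated/unmethylated call counts (strand-resolved,
1-based positions, contexts CG/CHG/CHH with H ∈ {A,C,T}) are pooled
over both strands into windows of `bin_size` = 300 bp sliding by
`step` = 200 bp, anchored at position 1 of each chromosome.
Consecutive windows overlap by 100 bp, so a cytosine contributes to up
to two windows: pooled bins must never be summed across bins (counts
would be double-counted). Window enumeration stops at the first
window reaching the chromosome end; that last window is truncated
rather than dropped, leaving under-covered tails to the coverage
filter instead of silently discarding positions. Zero-coverage sites
are kept at parse time; all filtering is the DMR caller's
responsibility.

Coordinates are 1-based inclusive everywhere in memory; conversion to
0-based half-open happens only when writing BED.

## Per-bin differential test

A bin is excluded if, in any library, its total call count is below
`min_counts` = 10 (strictly fewer) or above that library's per-context
99th coverage percentile, computed over all bins before any removal.
Both cutoffs are inclusive-to-keep: a bin exactly at 10 calls or
exactly at the percentile is retained.

The test regresses the per-library methylated proportion on a genotype
indicator with binomial errors, libraries entering as observations
weighted by their totals. The reported p-value is the
likelihood-ratio test of the genotype term. Because genotype is the
sole covariate, the profile likelihood depends on the data only
through per-genotype pooled counts, so the LRT reduces to the
two-proportion G-test

  LR = 2·[ℓ(p̂₁) + ℓ(p̂₂) − ℓ(p̂_pooled)],  p ≈ χ²₁,

which is evaluated in closed form, vectorised over all bins (a
typical screen tests ~10⁵ bins per comparison per context). The LRT
is well defined under complete separation (0% vs 100%), where the Wald
statistic degenerates; a Wald flavour fitted with statsmodels is
provided per bin and falls back to 0.5 pseudo-counts per cell when the
two genotypes are completely separated. Identical groups give LR = 0,
p = 1; a genotype with zero total calls gives NaN (such bins are
removed by the filter).

The effect size is deliberately different from the test statistic: it
is the *unweighted* mean of replicate proportions per genotype
(an average of replicates, not of reads), so one deep library cannot
dominate the reported difference. Benjamini–Hochberg correction is
applied per context; flagging requires q ≤ 0.05 and |Δ| ≥ 0.25 / 0.20 /
0.10 for CG / CHG / CHH, all comparisons inclusive.

## Merging, exclusion, intersection

Flagged bins merge into DMRs by transitive interval overlap (≥ 1
shared bp) within a (context, direction) group; hyper and hypo bins
never merge, and adjacent-but-disjoint bins stay separate. Merging is
idempotent. Regions overlapping an introgressed segment by ≥ 1 bp are
removed (defaults: ch01 1–86 Mb, ch02 44–54 Mb, ch08 61 Mb–chromosome
end at 65,866,657 bp), because sequence divergence there confounds a
methylation comparison; a manual allow-list keeps individually argued
candidates.

Cross-line intersection uses **union-consensus**: all per-line DMR
intervals of one (context, direction) are union-merged, and a
consensus interval is reported iff it overlaps at least one DMR from
every required line, with per-line supporters listed. The result is
invariant to line order. Per-line raw DMR counts are reported
alongside, since a consensus region and its supporters can legitimately
be counted either way in Venn-style tallies. Regions differential in
all three contexts are obtained by the same consensus rule applied
across contexts.

Gene annotation associates a DMR with a gene if it overlaps the
transcribed span or a strand-aware 2-kb window upstream of the
transcription start (genes without strand get no promoter window, with
a warning); locus lists (e.g. small-RNA clusters) associate by plain
overlap.

## McrBC arithmetic and classes

With amplification efficiency E per cycle (default 2.0, perfect
doubling; configurable because instruments differ), the surviving
unmethylated fraction after digestion is u = E^−ΔCt, ΔCt =
Ct(digested) − Ct(mock), and the methylated fraction is clamp(1 − u,
0, 1). This is the standard interpretation of the
digestion-then-qPCR principle; the assay itself does not fix a unique
formula. No reference-gene normalisation is applied by default (input
DNA is equalised by design); technical-replicate Ct values are
averaged before ΔCt. A digested reaction that never amplifies is a
fully methylated template: fraction 1.0, flagged censored.

Classes on the fraction: low ≤ 1/3 < intermediate ≤ 2/3 < high, upper
bounds inclusive, partitioning [0, 1].

## Segregation null models

All tests are exact binomial tails (summation via the regularised
incomplete beta, never a normal approximation).

- **BC1** (upper tail, p₀ = 1/2, class high): the null conditions on a
  fully methylated F1 — primary paramutation converted the
  recurrent-parent allele — whose converted allele is *not* itself
  paramutagenic. Half the backcross progeny then inherit the naive
  donor allele and become fully methylated; half inherit the converted
  allele and stay half-methylated. An excess of high plants is
  evidence of secondary paramutation. (Under a rates-all-zero model
  no BC1 plant is high at all and the test never rejects; the
  conditioned null above is the one with 5%-scale type-I error, ≈3.8%
  at n = 26 given discreteness.)
- **F2** (lower tail, p₀ = 1/4, class low): Mendelian segregation of a
  stable epiallele pair leaves 1/4 of F2 plants unmethylated; a
  deficit indicates the F1's recurrent-parent allele gained
  methylation. Exact type-I error ≈2.1% at n = 33.
- **F1** excess methylation is summarised descriptively (class counts
  and the number of high plants); with a single expected class there
  is no sampling null to test.

P-values are kept at full precision; no multiple-testing correction is
applied across candidate loci by default (per-locus reporting), BH
being available on request. Loci whose parental controls straddle
classes are flagged inconclusive rather than tested.

## Epiallele inheritance model

One locus, two epialleles (u, m); a methylated allele carries a
provenance bit: *naive* (methylation inherited) or *converted*
(gained by paramutation). Per organismal generation each plant takes
one stochastic soma step, in fixed order:

1. paramutation in heterozygotes: u → m(converted) with probability
   π₁ if the methylated partner is naive, π₂ if converted — provenance
   tracking is what lets secondary paramutation be weaker (π₂ < π₁);
2. spontaneous epimutation per allele: u → m with ε_gain, m → u with
   ε_loss (reversion erases provenance).

Gametes are drawn uniformly from the (post-step) parental alleles;
each offspring runs its own soma step before readout. Two conversion
timings are exposed, since segregation data alone rarely distinguishes
them: `somatic` (default) converts before the measured tissue is read,
`meiotic` converts only in the reproductive lineage, so a measured F1
reads 50% while its gametes already carry the converted allele (the
pattern of loci whose F2s are methylated despite Mendelian-looking
F1s). Neither timing is claimed as the mechanism.

Readout is (methylated alleles)/2 + N(0, σ), clamped to [0, 1] — a
deliberately simple error model, as the assay provides none. The
clamp never moves a readout across a class boundary, because both
boundaries are interior to (0, 1).

Exact class probabilities come from enumerating the 9 ordered
(allele₁, allele₂) states over {u, m-naive, m-converted}: the
paramutation and epimutation steps are 9×9 stochastic matrices, selfing
uses the joint two-gametes-from-one-plant distribution, and crosses use
per-parent marginal gamete distributions. Grid-search maximum
likelihood over (π₁, ε_loss) (default grid step 0.02 on π₁) maximises
the multinomial likelihood of observed class counts; ties resolve to
the smallest parameters. With ~500 BC1 plants the π₁ estimate is
reliable to better than ±0.1; note that estimation error floors at the
intermediate-generation size (offspring sharing few F1 parents are
correlated), so consistency checks scale the F1 population with the
measured one.

## Synthetic bisulfite data

The generator emulates a leaf-methylome screen: shared site positions
per chromosome (densities CG 0.03, CHG 0.03, CHH 0.10 per bp, both
strands pooled), per-site-per-library negative-binomial coverage
(mean 20, size 10), and binomial methylated counts at euchromatin-like
baselines (CG 0.30, CHG 0.20, CHH 0.08). Truth DMRs override the
level per genotype inside their interval; the standard screen spec
implants hyper regions (effects CG +0.40, CHG +0.35, CHH +0.25,
900 bp wide, ≥ 2 kb apart) identically in all introgression-line
genotypes and leaves the recurrent parent at baseline. Effects sit
comfortably above the caller's decision thresholds: implants *at* the
threshold would make per-bin recovery a coin flip by construction
(the observed difference straddles an inclusive cutoff), telling one
about sampling noise rather than the caller. Default problem size
for end-to-end validation is 5 × 1 Mb chromosomes, 4 genotypes × 2
replicates — large enough for ~25k bins per context and stable
percentile filtering, small enough to run in seconds.

What passing on these data does **not** show: robustness to PCR
duplicates and conversion failure, spatially autocorrelated coverage
(repeats, copy-number), context misannotation, biological replicate
overdispersion beyond binomial, or hemimethylation — real methylomes
violate all of these to some degree. The generator draws sites
uniformly, so CpG-island-like clustering is absent; recovery rates on
real data will be lower at equal effect size.

## Determinism

Every stochastic routine takes a seed or `numpy.random.Generator`; no
global RNG state is used. The same spec and seed produce
byte-identical cytosine reports, and a screen rerun from the same
config yields bit-identical outputs, recorded in a manifest (config
hash, input SHA-256, library versions).
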