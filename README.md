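# paraseg

Tools for discovering and validating **paramutation-like loci** in plant
genomes — loci where a methylated epiallele converts its unmethylated
homologue in *trans*, so that DNA methylation is inherited in
non-Mendelian ratios.

The package is aimed at epigenomics groups working with crosses between
a recurrent parent and donor-derived lines (e.g. tomato M82 ×
*S. pennellii* introgression lines). It covers the full desk-side
workflow:

1. **DMR screen** (`paraseg.methylation_data`, `paraseg.dmr_caller`) —
   per-cytosine bisulfite counts are pooled over both strands into
   300-bp bins sliding by 200 bp, separately for the CG, CHG and CHH
   contexts. Bins with fewer than 10 calls, or above the per-library
   99th coverage percentile, are excluded. Each bin is tested with a
   binomial regression of the methylated proportion on genotype,

   logit p = β₀ + β₁·genotype,

   where the p-value is the likelihood-ratio test of β₁ (with genotype
   as the only covariate this is the two-proportion G-test on pooled
   counts, evaluated vectorised; a Wald flavour is available).
   P-values are Benjamini–Hochberg corrected (FDR 5%) and bins must
   additionally show an absolute methylation difference — average of
   replicates — of ≥ 25% (CG), 20% (CHG) or 10% (CHH). Overlapping
   flagged bins merge into DMRs, DMRs inside introgressed segments are
   dropped, and DMR sets are intersected across lines: a locus
   differentially methylated in *every* line, outside its introgressed
   DNA, behaves non-Mendelianly and is a paramutation candidate.
2. **McrBC-qPCR quantification** (`paraseg.mcrbc`) — McrBC cleaves
   methylated DNA, so with amplification efficiency E the methylated
   molecule fraction at an amplicon is 1 − E^−ΔCt, ΔCt = Ct(digested) −
   Ct(mock). Plants are classed low (≤ 1/3), intermediate (≤ 2/3) or
   high (> 2/3).
3. **Segregation tests** (`paraseg.segregation`) — exact one-sided
   binomial tests against Mendelian nulls: P(X ≥ k), X ~ Bin(n, 1/2)
   for an excess of highly methylated BC1 plants (secondary
   paramutation), and P(X ≤ k), X ~ Bin(n, 1/4) for a deficit of
   unmethylated F2 plants (methylation gain in the F1).
4. **Epiallele simulator** (`paraseg.episim`) — a stochastic model of a
   diploid locus with four configurations {uu, um, mu, mm}, per-allele
   spontaneous epimutation rates (ε_gain, ε_loss), and paramutation in
   heterozygotes at rate π₁ (naive methylated partner) or π₂ (converted
   partner), with a noisy McrBC-like readout. It simulates F1/F2/BC
   designs, computes exact class probabilities by 9-state enumeration,
   fits (π₁, ε_loss) by grid-search maximum likelihood, and generates
   synthetic per-cytosine bisulfite reports with implanted DMRs so the
   whole screen can be validated against known truth.

## Worked example

Scripts under `examples/` each exercise one capability. The
segregation tests on the canonical backcross and F2 counts
(`examples/03_segregation_tests.py`):

```
BC1: 18/26 high, p = 0.03776 (one-sided, p0 = 0.5) -> secondary-paramutation evidence
F2:  3/33 low,  p = 0.021 (one-sided, p0 = 0.25) -> non-Mendelian F2 segregation
```

18 of 26 backcross plants with fully methylated DNA is more than the
half expected if the converted allele were not itself paramutagenic
(p = 0.03776); only 3 unmethylated plants among 33 F2s is fewer than
the quarter expected under Mendelian segregation (p = 0.021). Both
reject the Mendelian null at α = 0.05.

The synthetic end-to-end screen (`examples/01_dmr_screen.py`) prints:

```
IL1: 18 DMRs vs M82
IL2: 19 DMRs vs M82
IL8: 18 DMRs vs M82
shared in all three lines: {'CG': 6, 'CHG': 6, 'CHH': 6}
implanted regions recovered: 100% of 18
false-discovery proportion over flagged bins: 0.0%
```

i.e. every implanted shared DMR is recovered per context and no flagged
bin falls outside a truth region.

A thin CLI mirrors the library: `paraseg dmr-call --config run.yaml`,
`paraseg segregate --ct ct.tsv --pedigree ped.tsv`,
`paraseg simulate-cross`, `paraseg simulate-bs`. All outputs are plain
TSV/BED, and every screen run writes a `manifest.json` with config and
input hashes for bit-identical re-execution.

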