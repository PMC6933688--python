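# Methods

## Synthetic panel generator

The generator produces phased diploid haplotypes for several breeds plus
named crossbred samples, over `n_chromosomes` chromosomes of `n_markers`
biallelic SNPs each (default 2 × 2,500). Positions are uniformly spaced
(1 kb); no genetic map is modelled.

1. **Ancestral frequencies** follow a 1/x density on [0.01, 0.99]
   (inverse-CDF sampling), a neutral-ish site frequency spectrum that
   yields the strong rare-variant excess the rare-enriched research chip
   is designed around.
2. **Breed frequencies** are Balding–Nichols draws,
   Beta(p(1−F)/F, (1−p)(1−F)/F), with per-breed F_ST defaults between
   0.08 and 0.15 (taurine-like vs more diverged indicine-like breeds).
3. **Founders**: `n_founders_per_breed` (default 30) haplotypes of
   independent per-site Bernoulli draws at the breed frequency.
4. **Haplotypes** are left-to-right founder mosaics: at each marker the
   founder is redrawn with probability `mosaic_switch_rate`, and always at
   a chromosome start. Crossbred samples draw each segment's founder from
   breed *b* with probability equal to their ancestry proportion.

`mosaic_switch_rate` defaults to 5×10⁻⁴, i.e. founder segments of ~2,000
markers. This is the package's LD calibration: it places the emulated
assay densities in the regime real cattle data occupy, where a 50K-scale
chip tracks shared haplotypes well and only the ultra-low-density chip is
clearly starved. The generator is non-genealogical by design — LD comes
from segment copying, not a coalescent — which is orders of magnitude
cheaper and creates exactly the haplotype-sharing structure a copying
model exploits.

**Breed layout.** Defaults mirror the published reference composition
pattern: one dominant breed (~50% of the 615-sample reference), one
mid-sized, several sparse, the diverged breeds sparsest; dual-genotyped
test candidates per breed sized so the 50-per-breed masking cap binds for
the well-represented breeds (about 50 test animals each, 185 + 10
crossbreds in total).

**Assays.** Marker counts preserve the real filtered-density ratios
(6,394 : 16,854 : 44,366 : 70,581 : 125,446 : 201,236 : 753,715), scaled
so the common-variant research chip covers 80% of the simulated markers.
The common chip prefers markers with MAF ≥ 0.05, evenly spaced; the
rare-enriched chip copies a fixed overlap block from it (scaled from the
31,392 shared markers) and samples the remainder with 9:1 weight on
MAF < 0.1; the five commercial chips are evenly spaced nested subsets of
the common chip.

**Genotyping error** replaces a call with one of the other two classes
uniformly, at 0.2% per genotype — the accepted platform error rate. Error
is applied over the *full* research-assay marker set of test animals, so
the scoring truth itself carries platform error, exactly as treating
observed high-density calls as correct does. This matters: a single
truth-error discordance at a rare variant collapses its chance-corrected
score while barely moving a common variant's, and it is a substantial
part of why rare bins score lower.

## QC

Non-autosomal markers are removed first, then markers with call rate
strictly below 0.90, then samples below 0.90 on the surviving markers
(marker-before-sample order follows PLINK convention; the threshold
comparison is strict, so exactly 0.90 survives). No MAF filter and no
Hardy–Weinberg filter are applied — monomorphic and rare markers are the
point, not noise.

## Masking

Per breed, min(50, ⌊0.5 · breed size⌋, eligible pool) individuals are
drawn uniformly (sorted ids, seeded) into the test set; only
dual-genotyped candidates are eligible, and the 50% cap is computed on
the full breed so masking never depletes a breed's reference below half.
Masking restricts genotypes to one assay's markers and keeps the
(error-bearing) full-density truth plus the simulator's phase for the
observed markers; where an injected error changed a call, the stored
phase is rewritten to match it.

## Imputation engine

A Li–Stephens copying HMM over K reference haplotypes on the typed-marker
grid, run independently per chromosome (as production imputers do):

- transition per typed interval: stay with (1−s) + s/K, move to each
  other state with s/K (default s = 0.01);
- emission: 1−ε on allele match, ε on mismatch (default ε = 0.002);
  missing target alleles emit 1;
- scaled forward–backward recursions, posteriors normalized at every
  typed site (no underflow at any practical length);
- untyped markers take the copying posterior of the nearest typed marker
  to their left applied to the reference alleles at the untyped position
  (markers before a chromosome's first typed site use that first site).
  The left-flank rule is the simplest defensible interpolation; a
  two-flank interval interpolation would roughly halve boundary error and
  is a known alternative.

Diploid targets are threaded as two pre-phased haplotypes; the sample
dosage is the sum of the two haploid posteriors, the best-guess genotype
is the rounded dosage with exact .5 ties resolved to the heterozygote
(fixed, documented, arbitrary). Observed genotypes pass through untouched
and are flagged `observed`; everything else is `imputed`. Phasing is
taken from the simulator by default (`truth-phase`); `switch-error` mode
flips phase at heterozygous sites with probability 0.02 per het to
emulate statistical phasing noise. Reference panels above
`max_reference_haplotypes` (default 200) are subsampled seeded and
stratified by breed; the benchmark study instead passes a cap large
enough to keep its whole 1,230-haplotype reference, mirroring how
production tools consume the full panel.

## Reference panels and strategies

Reference samples are assigned per breed to common-chip-only,
rare-chip-only, or dual-genotyped (overlap) groups (defaults 25% / 65% /
10%; the breed used for the breed-panel contrast gets 35% dual coverage,
reflecting that the corresponding real breed had the most complete
dual-assay genotypes). The **one-round composite** fills each sample's
missing assay by reciprocal cross-imputation through the overlap block,
hard-calling haploid posteriors at 0.5 (ties to the panel major allele)
because the copying model consumes discrete alleles; every filled entry
is flagged `cross-imputed`, observed entries are never altered. The
**two-round strategy** imputes the test set to the common-chip marker set
against common-chip-genotyped samples only, then imputes the
rare-chip-exclusive markers against rare-chip-genotyped samples, feeding
step-1 haplotypes (hard-called, observed overlap alleles kept exact) as
step-2 input. Both strategies cover the union marker set and agree
exactly at typed markers.

## Metrics

IQS is computed from the 3×3 table as (P₀−P_c)/(1−P_c); when both vectors
are constant and identical (P₀ = P_c = 1) it is defined as 1; when
exactly one side is constant the algebra forces 0; it may be negative.
Only entries flagged `imputed` with non-missing truth are scored. MAF
bins are half-open, (0, 0.05] through (0.45, 0.50], with MAF = 0 markers
in a separate `fixed` bin; binning and centering MAF comes from the full
study panel (reference plus test). Undefined correlations are NaN
sentinels and are counted per bin, never dropped silently. The region
scan flags non-overlapping windows (default 50 markers) in which more
than 20% of markers breach IQS < 0.8 or > 10 errors. Panel comparisons
report the paired mean IQS difference with an exact paired-t (direct
formula, scipy only for the tail probability), a variance-ratio F, and
improved/worsened/unchanged counts.

The GRM uses the standardized (GEMMA-style) single-formula form over
polymorphic markers, missing entries mean-imputed to 2p (contributing
zero); frequencies come from the combined test+reference genotypes.

## The benchmark study

`benchmark.build_study(seed)` freezes one desk-scale configuration:
5,000 markers over 2 chromosomes, 615 reference samples across 6 breeds
plus crossbreds, assays as above, platform error 0.2%. Analyses that
correspond to the published single-breed-set comparisons use a
taurine-like test subset (breeds with ≥ 100 reference haplotypes), since
sparsely represented breeds are studied via the relatedness report
instead. The misplacement scan swaps a 30-marker block's genotype columns
with scattered distant markers and keeps the rest of the run clean
(densest assay, zero error, observed-genotype reference) so flagged
windows localize the corruption.

Problem sizes were chosen so the full battery (panel build, composite
construction, five density runs, two panel runs, two strategy runs, the
scan and the GRM) completes in about a minute on one CPU.

## What the synthetic study does and does not show

Passing the battery demonstrates the *mechanisms*: chance correction
collapsing inflated rare-variant concordance, composite panels helping
mixed-ancestry targets, one-round cross-imputed references helping rare
common-chip-exclusive markers, accuracy monotone in starting density, and
region scans localizing map errors. Absolute accuracy levels (mean IQS
≈ 0.83 from 50K-like density) sit well below what full-scale cattle
panels achieve, because a 5,000-marker genome concentrates
haplotype-boundary ambiguity: each founder switch costs roughly one
typed-interval of uncertainty, and those intervals are a ~5× larger
fraction of a desk-scale genome than of a real one. For the same reason
both panels remain unsaturated at common markers, so the
composite-over-breed gain appears across the MAF range rather than
concentrating below MAF 0.05 as it does when common-marker accuracy is
already at ceiling. Directions, not magnitudes, are the meaningful
desk-scale output.

Rare variants in this generator are perfectly tagged by their founder
haplotype (no mutations younger than the LD structure), which makes
rare-variant imputation intrinsically easier than in real data; the
platform-error-bearing truth restores part of the real rare-variant
penalty. Other absent features: genetic-map heterogeneity, strand/allele
harmonization issues, pedigree structure, sex chromosomes, multi-allelic
sites.

## Numerical and degenerate-input choices

Identical configuration and seed reproduce every output bit-exactly; a
single global seed expands into per-stage seeds by CRC-hashing stage
names, so stages can be re-run in isolation. Degenerate inputs fail
loudly: zero typed markers, fewer than two reference haplotypes, empty
assay overlap, all-missing markers, absent breeds, empty post-QC
matrices. Chromosomes with no typed markers fall back to the reference
allele frequency. PED/MAP files use an extended 6-column MAP (A1/A2) on
write so allele orientation round-trips exactly; on read without declared
alleles, the counted allele is inferred as the minor allele with
lexicographic tie-break.
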