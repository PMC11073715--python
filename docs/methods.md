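# Methods

This note documents the statistical model behind `lnct3d`, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the numerical decisions a maintainer would want spelled
out.

## The annotation model

The pipeline annotates nuclear lncRNAs with candidate target genes on
the premise that a chromatin-bound lncRNA acts within its spatial
neighbourhood. Four stages, each consuming plain TSV/BED/FASTA tables:

**Nuclear classification.** Promoter CAGE tag counts are normalised to
tags per million within each library; a gene's per-fraction expression
is the mean over that fraction's libraries of its summed promoter tpm.
The nuclear-to-cytoplasmic ratio is `nuc / (nuc + cyto)`; when the
nucleus was split further, `mean(chromatin, nucleoplasm)` replaces
`nuc`. Genes at ratio ≥ 0.5 (inclusive) are nuclear. A 0/0 ratio is an
explicit undefined sentinel and the gene is dropped from classification;
genes without fractionation data can inherit the unweighted mean of
their ratios in other cell types.

**Interaction calling.** RNA–DNA contacts whose RNA tag lies wholly
inside an intron of the source gene, or whose DNA tag falls inside the
source gene's span, are treated as nascent transcription and removed
(a tag spanning an exon–intron junction is kept). Remaining DNA tags are
binned at 10 kb. The background probability of bin *b* is

    p_b = (trans-binding mRNA reads in b) / (total trans mRNA reads),

i.e. mRNAs — overwhelmingly non-chromatin-associated — define how reads
distribute over bins when binding is non-specific. For each gene with
`n` remaining reads, a bin with `x` reads is scored with the exact
binomial upper tail `P[X ≥ x | n, p_b]`. Bins with `p_b = 0` have no
background support and are untestable rather than infinitely
significant. Benjamini–Hochberg correction is applied within the gene
across its currently tested bins; bins at FDR ≤ 0.01 are moved to the
significant set and their reads subtracted from `n`; the loop repeats
until an iteration adds nothing. Since decreasing `n` with `x` fixed can
only shrink an upper-tail binomial p-value, the significant set grows
monotonically and the loop terminates within one iteration per tested
bin (asserted in tests). The final set keeps bins with ≥ 3 reads; this
support floor is applied once, after convergence, not inside the loop.

**Target regions.** Significant Hi-C interactions (≥ 5 read pairs,
q ≤ 0.05, duplicates collapsed by summing pairs before filtering) form
an undirected graph over intra-chromosomal 10 kb bins. A/B compartment
labels come from 1 Mb eigenvalues; per chromosome, if the mean CAGE
expression of the negative-sign segments exceeds that of the positive
ones, all signs are flipped, then A = positive (the operation is
idempotent, and afterwards mean A expression ≥ mean B expression by
construction). The target region of a lncRNA is the set of bins within
k = 2 hops (breadth-first search) of its strongest-promoter bin,
restricted to the maximal run of same-label segments containing that
promoter, padded ±100 kb. The restriction applies to **every bin on the
path**, not only endpoints — otherwise a path could tunnel through
excluded territory; `constrain="endpoints"` exposes the alternative.
The reference bin itself is not a target (a gene is trivially near
itself). Strongest promoters and expressed enhancers (aggregate tag
count ≥ 5) overlapping target bins are the candidate targets; several
features in one bin each count once per feature.

**Enrichment batteries.** All contingency analyses use the exact Fisher
test with the sample odds ratio `(a·d)/(b·c)` reported alongside
(sentinels `0`/`+inf` on degenerate margins; no Haldane–Anscombe
correction — counts stay exact and the display layer may smooth).
Knockdown differential expression: a gene is DE when its FDR ≤ 0.1 in at
least one ASO (union over ASOs); per lncRNA the 2×2 is
{target, non-target} × {DE-in-direction, not}, lncRNAs with < 3 DE
targets are excluded from the headline summary, and Fisher's method
(−2Σln p ~ χ²₂ₘ) combines the rest. GO terms are tested one-sided
against a leave-one-out background (targets of all other lncRNAs minus
the lncRNA's own), BH per lncRNA, significant at FDR ≤ 0.1 with overlap
≥ 3. TFBS motifs are assigned to promoter/enhancer regions (±250 bp) by
summing posterior scores of overlapping predicted sites (assigned at
aggregate ≥ 0.1; motifs covering < 200 regions dropped); lncRNAs with
≥ 5 target regions get a per-motif battery plus a Fisher-combined p, and
each motif gets a cross-lncRNA chi-square of occurrence counts.
Correlation preference: Spearman ρ between a lncRNA and each target
across conditions, then a one-sample t-test of the ρ's against zero
(positive/negative only at p ≤ 0.05 with matching sign; constant
expression vectors are dropped and counted). RBP batteries: reliable
eCLIP targets are FDR ≤ 0.05 **and** log2FC > 0.5 (strict), RBPs with
< 15 lncRNA targets are dropped; knockdown-DE enrichment is restricted
to RBPs binding ≤ 500 lncRNAs; the promoter-occupancy battery demands
BH ≤ 0.1 with ≥ 3 occupied promoters; PPI expansion uses edges with
score > 0.4 (strict); and bound-vs-unbound nuclear ratios are compared
with a one-tailed Mann–Whitney U.

## Defaults

| Parameter | Default | Why |
|---|---|---|
| bin size | 10 kb | resolution of the contact and Hi-C tables |
| caller FDR / support | 0.01 / 3 reads | operating point of the interaction caller |
| Hi-C filter | ≥ 5 pairs, q ≤ 0.05 | significant-interaction definition |
| degrees of separation | 2 | spatial-neighbourhood radius on the Hi-C graph |
| compartment pad | ±100 kb | tolerance at compartment boundaries |
| N/C threshold | 0.5 | nuclear-enrichment definition (inclusive) |
| promoter floor | 0.5 tpm, 3 tags | strongest-promoter eligibility |
| enhancer floor | 5 aggregate tags | expressed-enhancer definition |
| TFBS | ±250 bp, score 0.1, 200 regions, 5 targets | assignment and battery floors |
| battery FDR | 0.1 (KD, GO, TFBS, RBP) | discovery-oriented threshold |
| eCLIP | FDR 0.05, log2FC > 0.5, 15 lncRNAs | reliable-target definition |
| PPI score | > 0.4 | medium-confidence interaction floor |

All boundary comparisons are inclusive (`≥`/`≤`) except the two strict
ones noted (eCLIP log2FC, PPI score).

## The synthetic world

`lnct3d.synthetic` emulates the statistical structure of each input, not
its biology: 2 chromosomes × 5 Mb at 10 kb bins and 1 Mb compartments,
200 mRNAs, 20 lncRNAs of which half are planted nuclear, 100 enhancers.
Each planted nuclear lncRNA receives 8 planted target bins inside its
own compartment segment (excluding bins overlapping its own gene span,
whose reads the nascent filter would legitimately remove), with one mRNA
promoter placed in each so target-gene recovery is scorable.

Contacts: every gene emits `Poisson(background_rate × n_bins)` contacts
uniform over the genome (default rate 2 reads/bin, emulating a deeply
sequenced assay); planted bins receive additional reads so their total
mean is `enrichment_fold × background_rate` (default fold 20), which
makes fold = 1 exactly background. A `nascent_frac` (0.2) share of each
gene's contacts gets a nascent signature. mRNA placement is balanced
across chromosomes: the trans-mRNA reads a bin receives come from genes
on *other* chromosomes, so an uneven split would make the shared
background model misspecified per chromosome by construction. At these
defaults the caller's planted-bin sensitivity is 1.0 with false
discovery well under 5% across seeds; the signal strength matters
because per-gene BH at FDR 0.01 over ~200 genes always yields a few
chance 6-read pile-ups, and the planted mean must sit far above that
detection floor.

Hi-C: a scaffold guarantees every planted bin within two hops of its
lncRNA's promoter bin (direct or via a hub bin) with passing statistics;
random intra-chromosomal edges are added at `p_neighbor`, a `q_noise`
share of them with failing counts/q-values. Knockdown DE, eCLIP, ChIP,
PPI, RBP-knockdown, TFBS-site and GO-set tables are generated with
analogous planted structure. One RNG stream per table, seeded by
(master seed, table name), so adding a table never perturbs the others;
a fixed seed reproduces every byte.

Not emulated: sequencing error, PCR duplicates, bridge adapters,
restriction-fragment structure, distance-decay of Hi-C contact
frequency, chromatin-state heterogeneity of the background, and real
gene-density variation. Passing tests therefore show the *procedures*
are correct and well-calibrated under a faithful null, not that the
thresholds are optimal for any particular real assay.

## Numerical choices

- Binomial tails via `scipy.stats.binom.sf(x-1, n, p)` — the exact
  upper tail, vectorised per gene; tests cross-check against direct
  log-space pmf summation.
- "One-sided" binomial and Fisher tests are upper-tail (enrichment)
  throughout; the knockdown battery reports signed log2 odds ratios so
  depletion is visible, and its sidedness is a parameter.
- BH is within-gene for the caller (the iteration's subtraction logic is
  per-gene) and within-lncRNA for the GO/TFBS batteries.
- Strongest-promoter ties break on the lexicographically smallest
  promoter id; deterministic outputs everywhere.
- Degenerate 2×2 margins yield odds-ratio sentinels and p = 1 instead of
  errors; chi-square tables with expected counts < 5 log a warning but
  still report the asymptotic p.
- Fisher combination clips p = 0 to the smallest positive float with a
  warning.
- Bin-to-compartment assignment uses the bin midpoint; promoter-to-bin
  uses the TSS coordinate.
- The sensitivity/specificity and enrichment universe is all bins on the
  lncRNA's chromosome carrying a Hi-C edge or an annotated feature,
  exposed as an argument (the right universe is assay-dependent).
- Motif matches count overlapping occurrences on the given strand
  (`overlap=False` available); bracket groups are single-position
  alternatives and other ambiguity codes are rejected.

## Problem sizes

The default synthetic study (two 5 Mb chromosomes, 220 genes, ~440k
contacts, ~1.3k Hi-C edges) runs the full pipeline in under ten seconds
on one core; the test suite's largest jobs are the exact-enumeration
oracle sweep (all 2×2 tables with n ≤ 30) and 1,000 random caller
fixtures. These sizes were chosen so the whole suite stays interactive
while every stage still sees non-trivial multiplicity.

## Known limitations

- The background model assumes bin accessibility is shared across RNAs;
  systematic per-RNA binding preferences would need a richer null.
- Per-gene BH does not control the across-gene FDR; at genome scale the
  paper-style within-gene correction is what is implemented, and the
  global planted-bin FDR is only empirically small, not guaranteed.
- Expression correlation across the synthetic "conditions" (CAGE
  libraries) is mechanically exercised but has little power at 4
  conditions; with real data one would feed a gene × cell-type matrix.
- `binom.sf` with very small `p_b` and large `n` is numerically safe,
  but `p_b` estimation error is ignored (a beta-binomial would
  propagate it).
- GWAS/heritability enrichment, differential Hi-C modelling, TAD/loop
  calling and eigenvector computation are out of scope; the pipeline
  consumes their outputs where relevant.
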