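# Methods

This document describes the statistical models implemented in `lnclact`,
the default parameters and why they were chosen, what the synthetic-data
generator does and does not capture, and the package's known limitations.

## 1. lncRNA identification

### Triage cascade

Assembled transcripts are filtered in a fixed order; the first matching rule
decides the fate, so each transcript gets exactly one reason:

1. **Known coding** — same-strand exonic overlap with a `protein_coding`
   reference transcript → removed.
2. **Small ncRNA** — exonic overlap (either strand) with a reference
   tRNA/rRNA/snoRNA/miRNA → removed. Strand-agnostic because small-RNA
   contamination of an assembly is a technical artifact, not a biological
   antisense relation.
3. **Known lncRNA** — same-strand exonic overlap with a reference `lncRNA`
   transcript → retained without further testing.
4. **Length / exon floors** — spliced length < 200 nt or fewer than 2 exons
   → removed (defaults `min_length=200`, `min_exons=2`; both are
   parameters).
5. Everything else is a **candidate** for coding-potential assessment.

### Coding potential

Candidates are scored by a CPAT-style logistic regression on four sequence
features:

- **ORF size** — length of the longest ATG…stop open reading frame across
  the three forward frames (ties broken by the leftmost start).
- **ORF coverage** — ORF length divided by transcript length.
- **Fickett TESTCODE score** — the classic position/content statistic
  computed from the published lookup tables.
- **Hexamer usage bias** — mean log-ratio of in-frame hexamer frequencies
  under a coding vs a noncoding background table, estimated from the
  labeled training FASTA files with add-one smoothing.

Features are z-scaled by the training means/SDs and fed to a logistic
model. A transcript is called *noncoding* when its coding probability
falls below the threshold (default **0.02**). The final accept decision is
the **intersection** of all available predictors (the built-in model plus
any external calls supplied as a TSV): a transcript is accepted as lncRNA
only if every predictor calls it noncoding. Intersection trades
sensitivity for precision, appropriate when downstream analyses assume the
accepted set is clean.

**Numerical choice — ridge-stabilized logistic fit.** Synthetic (and many
real) training sets are perfectly separable in these four features, where
unpenalized maximum likelihood diverges. The model is therefore fit with a
small L2 penalty (α = 1e-3 on z-scaled features). This bounds the
coefficients without visibly moving the decision boundary (training AUC
> 0.99 on default data).

### Positional classification

Accepted lncRNAs are classified against protein-coding annotation with a
fixed precedence:

1. same-strand exonic overlap → **sense_overlapping**
2. opposite-strand exonic overlap → **antisense**
3. transcript span fully inside a gene span without exonic overlap →
   **intronic** (either strand)
4. same-strand overlap with a gene *span* (straddling a gene boundary
   without touching an exon) → **sense_overlapping**
5. otherwise → **intergenic**

Rule 4 exists because a transcript that straddles a gene's boundary on the
same strand shares the locus sense context even when no exon is touched;
the same geometry on the opposite strand is *not* antisense (no exonic
overlap) and, lacking containment, falls through to intergenic. The
classifier is validated against an independent per-base set-arithmetic
oracle over randomized layouts.

## 2. Expression and differential expression

**FPKM**: `fpkm = count * 1e9 / (library_size * length)` with validation
that lengths and library sizes are positive.

**Fold change**: `log2((b + ε) / (a + ε))`. The pseudocount default is
**ε = 0.01**. The choice matters: lncRNAs typically sit at FPKM 0.1–10, and
a pseudocount of 1.0 would compress a 4-fold change at FPKM 0.37 → 0.88 to
an apparent 0.88 → 1.88 (log2FC 0.46 instead of 1.25), pushing true
low-expression effects below any |log2FC| > 1 threshold. ε = 0.01 is small
relative to the expression range of interest while still guarding against
division by zero; with the default generator it raises DE sensitivity from
≈ 0.68 (ε = 1) to ≈ 0.92 without inflating the null false-positive rate
(measured ≈ 0 on pure-null data).

**Test**: Welch's unequal-variance t-test on log2(FPKM + ε), per breed,
for consecutive stage pairs plus first-vs-last. P-values are adjusted per
comparison with Benjamini–Hochberg; a transcript is DE when FDR < 0.05 and
|log2FC| > 1. Degenerate rows are handled explicitly: identical groups give
p = 1; zero-variance but different groups give p = 0.

**Common DE sets**: per breed, the intersection of the DE sets across all
three comparisons, reported with per-stage mean FPKM.

## 3. Target inference and the panel network

**Cis targets**: for each lncRNA, the nearest protein-coding gene span
upstream and the nearest downstream within a window (default **100 kb**),
plus any overlapping spans at distance 0. Ties on distance are broken by
gene start, then gene id, so results are deterministic. Validated against
an all-pairs oracle on randomized layouts.

**Trans targets**: Spearman correlation between DE lncRNAs and DE coding
transcripts within a breed; an edge requires |ρ| ≥ 0.9 (default `r_min`)
and p < 0.05. For n ≤ 9 samples the two-sided p-value is computed by
**exact permutation enumeration** (all n! rank permutations); the t
approximation is used above that. With n = 9 samples per breed the exact
null matters: the t approximation misstates tail probabilities precisely
where |ρ| ≥ 0.9 decisions are made. Midranks handle ties, matching the
enumeration oracle to 1e-12.

**Panel network**: signed Pearson correlations between DE lncRNAs and a
curated milk-trait gene panel (default 20 genes: caseins, whey proteins,
lipid-synthesis and glucose-transport genes), with BH-FDR per breed and
edges kept at FDR < 0.05, labeled positive/negative.

**Numerical choice — correlations on the log scale.** The pipeline
computes the Pearson panel network on log2(FPKM + ε), not raw FPKM.
FPKM is approximately lognormal; on the linear scale a few high values
dominate the covariance and inverse (negative) relations between a
low-expressed lncRNA and a high-expressed gene are masked. On the default
synthetic data the linear scale missed half of the planted negative edges;
the log scale recovers all planted edges in both breeds at the same α.
Spearman-based trans targets are rank-based and unaffected by this choice.

## 4. Enrichment

Hypergeometric over-representation analysis of the union of cis and trans
target genes against a GMT gene-set collection, restricted to the coding
background. The upper-tail probability is computed with exact binomial
coefficients (validated against full enumeration for all configurations
with N ≤ 15). BH adjustment is applied within each set category
(BP/MF/CC/pathway); the significance call uses the raw p < α convention
common for ORA screens, with the FDR column reported alongside.

## 5. qPCR validation

Relative quantification uses 2^-ΔΔCt with **two reference genes**:
technical replicates are averaged per (sample, gene); ΔCt subtracts the
mean of the two reference Cts; ΔΔCt subtracts the calibrator sample's ΔCt;
RQ = 2^-ΔΔCt. Censored wells (no amplification by the cycle cap)
propagate an `unreliable` flag — a censored calibrator taints every
sample. Concordance between qPCR log2 fold changes and RNA-seq log2 fold
changes is summarized by Pearson r over matched (gene, breed) pairs.

## 6. The synthetic-data generator

The generator plants truth for every pipeline stage from a single seeded
`numpy` generator consumed in a fixed order, so a given
(config, seed) pair is byte-reproducible.

- **Annotation**: non-overlapping multi-exon coding genes across a few
  chromosomes; lncRNA loci constructed to satisfy their positional-class
  definition *by construction* (intergenic in gaps, intronic inside
  introns, antisense across an exon on the opposite strand,
  sense-overlapping straddling the gene start on the same strand); short
  single-exon small-ncRNA decoys; a configurable fraction of lncRNAs also
  appears in the reference as "known".
- **Sequences**: coding transcripts are UTR + ATG + codons drawn from a
  Dirichlet codon-usage model + stop + UTR; noncoding transcripts come
  from a first-order Markov chain with any ORF longer than 50 codons
  broken by an inserted stop. The same two composition models generate the
  labeled training FASTA files, so the coding-potential features are
  learnable but not trivially separable by length alone.
- **Expression**: baseline log2-FPKM is Normal (lncRNA mean below mRNA
  mean, SD 2), plus planted per-breed stage shifts of ±2 log2 units for a
  configurable fraction of transcripts, plus a shared latent stage-varying
  factor for the planted lncRNA–gene edges (so the edges are detectable by
  correlation but their members are excluded from the independent DE
  mechanism), plus replicate noise (SD 0.25 log2).
- **qPCR**: Ct = 30 − log2(FPKM × 8) plus noise (SD 0.2 cycles),
  triplicate wells, two stage-constant reference genes, censoring at the
  cycle cap for zero expression. Ct values are rounded to 6 decimals on
  output, so round-tripping through the TSV is exact.

**Realism and limits.** The generator reproduces the *decision structure*
of a real study — class geometry, feature separability, lognormal
expression with planted effects, reference-gene normalization — not the
biology. Simplifications: no sequencing-count noise model (FPKM is
generated directly, not from reads), no isoform complexity or shared exons
between genes, no batch effects or library-size artifacts, expression
noise is homoskedastic in log space, Ct noise is Gaussian and shared
across replicates' censoring status, and gene sets are random rather than
functionally coherent (only sets built from the actual target list are
expected to enrich).

## 7. Reproducibility and limitations

- All pipeline randomness is confined to the simulator; the analysis
  itself is deterministic, and two runs on identical inputs are
  byte-identical (verified in the test suite, including the run log, which
  deliberately contains no timestamps).
- **Power at n = 3**: with three replicates per group, Welch's test has
  limited power; true 4-fold effects near the FDR boundary are sometimes
  missed, so DE sensitivity varies by seed (measured 0.86–0.93 across
  seeds at the default effect size). This is a property of the design
  being modeled, not a defect of the implementation.
- The intersection consensus for coding potential is conservative by
  design; with a single built-in predictor it reduces to that predictor's
  call, and external predictor tables can only shrink the accepted set.
- Cis inference is proximity-only and does not use strand or regulatory
  annotation; trans and panel edges are correlational and carry no causal
  direction.
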