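# Methods

`promptseq` quantifies promoter-upstream transcripts (PROMPTs) from
stranded bulk RNA-seq and tests for their differential accumulation between
a knockout (KO) and a control group — the analysis used to characterize
transcriptome surveillance defects when a nuclear RNA-exosome ribonuclease
such as DIS3 is lost. This note describes the model behind each stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices.

## PROMPT reference construction

For every annotated gene the candidate PROMPT window is the interval from
3 kb upstream to 1 bp upstream of the transcription start site (TSS), on
the gene's own coordinate system: `[TSS − L, TSS − 1]` for `+` genes and
`[TSS + 1, TSS + L]` for `−` genes, with `L = 3000` bp by default. The TSS
is the gene-level 5′-most coordinate of the gene feature — one window per
gene, not per transcript isoform. Windows are clipped to chromosome bounds
(clipped windows are kept if at least 1 bp survives; their recorded length
lets users filter).

A window is retained only if it shares **zero** base pairs with any
annotated gene body, on either strand. This exclusion is what makes a read
in a retained window attributable to promoter-upstream transcription
rather than to an overlapping gene. The overlap test is against gene-level
spans, not exon structure: a conservative choice, since intronic
transcription under an upstream window would otherwise contaminate PROMPT
counts. Two retained windows may overlap *each other* (convergent gene
pairs); both are kept, and the counting stage's ambiguity rule arbitrates
fragments that fall in the shared region.

## Strand-aware counting

Input fragments are sequenced cDNA templates (one span per read pair,
merged via the template length; strand of read 1, flipped when the library
protocol is `reverse`, which is the default for strand-selecting kits).
A fragment is compatible with a feature when their overlap is at least
`min_overlap` (default 1 bp) and the strand rule of the counting mode
holds:

* `sense` — fragment strand equals the anchor gene's strand;
* `antisense` — opposite strand (the direction in which PROMPTs
  predominantly accumulate);
* `unstranded` — either strand.

A fragment compatible with more than one feature *under the mode's strand
rule* is ambiguous and counted to none; each fragment contributes at most
one count. This matches the default behaviour of featureCounts-style
tools. One consequence worth knowing: on overlapping opposite-strand
features, a fragment can be uniquely assigned in a stranded mode yet
ambiguous in unstranded mode, so unstranded counts are guaranteed to
dominate stranded counts only where features do not overlap. Gene counting
uses the union of a gene's exons; overlap is the total intersection with
that union, so intron-only fragments never count.

The interval index is an interval tree per chromosome; its only contract,
enforced by tests, is exact agreement with an all-pairs brute-force
enumerator.

## Normalization and the negative-binomial test

Size factors come from the median-of-ratios method: the reference for gene
*i* is its geometric mean across samples, and `s_j` is the median over
genes with a strictly positive reference of `counts_ij / reference_i`.
Size factors are **always computed from gene counts** and injected into
the PROMPT analyses. PROMPT regions are sparse and strongly perturbed in
the KO, so normalizing on them would absorb the signal under test; genes
provide the stable denominator.

Counts are modelled per feature as NB with `Var = μ + αμ²`. With
normalized counts `y_ij = counts_ij / s_j` and group means `q̂_g`:

* dispersion `α̂_i` is the method-of-moments estimate
  `max(0, (var_g − mean_g) / mean_g²)` averaged over the two groups, with
  a floor of 1e−8 (features with variance at or below the mean get
  near-Poisson treatment);
* the effect is `log2FC = log2((q̂_KO + c) / (q̂_ctrl + c))` with
  pseudocount `c = 0.5`, which stabilizes the estimate at low counts at
  the price of a small shrinkage toward zero for weakly expressed
  features;
* `Var(q̂_g) ≈ n_g⁻² Σ_j (μ_ij + α̂ μ_ij²) / s_j²` with `μ_ij = s_j q̂_g`,
  propagated to the log2 scale by the delta method;
* the Wald statistic `log2FC / SE` is referred to a **t distribution with
  `n_ctrl + n_KO − 2` degrees of freedom**, two-sided. The t reference is
  a deliberate small-sample correction: the variance entering the
  statistic is estimated from only a handful of replicates, and with a
  standard-normal reference the null rejection rate at nominal 0.05 is
  0.08–0.10 at 5 vs 5 replicates, while the t reference keeps it at
  0.045–0.06 across dispersions 0.05–0.2 (measured by the Monte-Carlo
  calibration test in the suite).

All-zero features report `log2FC = 0, p = 1`. Benjamini–Hochberg step-up
adjustment (each p multiplied by N, divided by its rank, with monotone
enforcement from the largest rank down and a cap at 1) is applied
separately per analysis — genes, and each PROMPT strand mode — since each
is its own feature family with its own null behaviour. Significance is
strict: `p_adj < 0.05` by default.

This is intentionally a transparent simplification of the DESeq2-style
workflow: no dispersion shrinkage across features, no outlier (Cook's)
filtering, no independent filtering. Published DE counts obtained with the
full machinery are therefore not comparable number-for-number.

## Biotype breakdown, correlation, qPCR helper

Significant features are tallied per `gene_biotype` (PROMPTs inherit their
anchor gene's biotype) split by fold-change sign. For the PROMPT–gene
relationship, each retained PROMPT is paired with its own downstream
anchor gene; pairs where **both** members reach `p_adj < 0.05` in their
respective analyses enter a Pearson correlation of log2 fold changes, with
a two-sided p-value from `r√((n−2)/(1−r²)) ~ t(n−2)` and `n ≥ 3` required.
The antisense mode is the headline (PROMPTs accumulate predominantly
antisense to their anchors) but all three modes are computed. The
`2^−ΔΔCt` helper converts qPCR Ct values to relative abundance against a
reference transcript (e.g. β-actin), with the control condition at 1 by
construction.

## Marker-gene filter

On a cells × genes matrix with cluster labels, a gene marks a cluster iff
(1) its in-cluster mean is ≥ 2.5 × its mean over all other cells pooled
(genes silent outside the cluster qualify whenever expressed inside);
(2) it is detected (expression strictly above a threshold, default 0) in
≥ 10% of the cluster's cells; and (3) its per-cluster mean is strictly
highest in that cluster, so a gene can mark at most one cluster. The
rank-sum testing that usually accompanies such a filter is out of scope;
the filter is the contract.

## Synthetic exosome-loss data

The generator emulates the study design end to end: two conditions × five
replicates of stranded bulk RNA-seq over a simulated annotation. Defaults,
all overridable in `SimConfig`:

| parameter | default | rationale |
|---|---|---|
| genes | 2000 (4 chromosomes) | desk-scale; 30 000 used for pair-rich correlation runs |
| intergenic gap | ≥ 4000 bp | exceeds the 3 kb window, so every PROMPT survives filtering |
| gene baseline | log-normal, median 500, σ(log) = 1 | depth of a 30–40 M-fragment library; leaves PROMPT channels (5% of anchor) with tens of counts, enough to estimate their fold changes |
| dispersion α | 0.05 | typical bulk tissue RNA-seq scale |
| DE genes | 15%, lfc ~ N(0, 1.5) | both directions, mostly moderate effects |
| PROMPT baseline | 5% of anchor mean per strand channel | PROMPTs are unstable, low-abundance transcripts |
| accumulating PROMPTs | 30%, lfc ~ U(1, 5) | 2–32× stabilization upon exosome loss |
| direction mix | 0.8 antisense / 0.1 sense / 0.1 both | the antisense-dominant asymmetry of PROMPT transcription |
| true size factors | log-normal, σ(log) = 0.1 | mild library-depth variation |
| coupling | off; when on, anchor lfc = PROMPT lfc + N(0, 0.1) | positive control for the correlation stage |

Counts are drawn as NB with mean `s_j · q_i · 2^(lfc_i · [j ∈ KO])`. The
unstranded channel is the sum of the sense and antisense draws of the same
region, mirroring how an unstranded recount of the same fragments behaves
when regions are well separated. A truth manifest (true lfc per channel,
baselines, dispersions, directions) accompanies every dataset; the
unstranded truth is `log2((μ_s 2^{lfc_s} + μ_a 2^{lfc_a})/(μ_s + μ_a))`.
One `numpy` Generator seeded by the caller drives everything, so all
outputs are byte-reproducible. The fragment-level generator places exactly
`k` fixed-length fragments uniformly and fully inside each feature, on the
channel-appropriate strand, for exact count round trips.

What the generator does **not** emulate: positional/GC bias, fragment
length variation, multimapping, transcript isoforms, intron structure
(simulated genes are single-exon), batch effects, and annotation errors.
Tests passing on this generator therefore validate the statistical and
interval logic, not robustness to alignment artefacts.

Under the independence default, significant-pair correlations are null; in
coupled mode the measured r is ≈ 0.92 rather than the theoretical 0.99
because PROMPT fold-change estimates carry sampling noise and a small
number of pairs enter through BH false positives — an inherent property of
double-significance pairing, visible in real analyses too.

## Problem sizes used in the checks

The shipped tests and `scripts/acceptance.py` run the default 2000-gene
study for recovery and direction-asymmetry checks, a 30 000-gene study
(the scale of a genome-wide retained-PROMPT set) for the independence
correlation so that several hundred pairs pass the double filter, 2000
null features at 5 vs 5 for calibration, and 100 random fixtures for the
counting oracle. The full suite completes in well under five minutes on a
single CPU.

## Known limitations

* Gene-level TSS ignores alternative promoters; a transcript-level mode
  would yield several windows per gene and requires a policy for merging.
* The exclusion filter uses gene bodies only; unannotated transcription
  (eRNAs, readthrough) inside a retained window is indistinguishable from
  PROMPT signal.
* No dispersion sharing across features: power at very low counts is below
  what DESeq2-style shrinkage achieves, and dispersion estimates at n = 5
  are noisy.
* BH is applied separately per strand mode; a joint adjustment across
  modes would be more conservative.
* The `unstranded ≥ max(sense, antisense)` relation holds only where
  features do not overlap (see the counting section).
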