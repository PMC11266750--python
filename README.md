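# promptseq

Promoter-upstream transcripts (PROMPTs) are short, unstable RNAs produced
within ~3 kb upstream of active transcription start sites, often antisense
to the downstream gene. They are normally degraded by the nuclear RNA
exosome; when exosome decay is lost (e.g. on inactivation of the DIS3
ribonuclease), PROMPTs accumulate genome-wide. `promptseq` is a toolkit
for quantifying that accumulation from stranded bulk RNA-seq: it builds a
filtered PROMPT reference from a genome annotation, counts fragments over
PROMPT regions in three strand modes and over genes, tests for
differential accumulation between knockout and control groups, and asks
whether PROMPT changes propagate to their downstream genes. It is aimed at
people analysing RNA-surveillance mutants who want a transparent,
fully-tested implementation of each step rather than a black box.

## What it computes

* **PROMPT reference** — per gene, the window `[TSS − 3 kb, TSS − 1 bp]`
  on the gene's strand, keeping only windows that share zero bp with any
  annotated gene body (strand-agnostic), so reads in a retained window
  cannot come from annotated genic transcription.
* **Strand-aware counts** — each cDNA fragment is assigned to at most one
  feature per mode: *sense* (fragment strand = anchor gene strand),
  *antisense* (opposite; the dominant PROMPT direction), *unstranded*
  (either). Genes are counted on their exon union.
* **Differential accumulation** — median-of-ratios size factors
  `s_j = median_i (k_ij / (∏_v k_iv)^{1/m})` computed from **gene** counts
  only; per feature a two-group negative-binomial Wald test with
  method-of-moments dispersion (`Var = μ + αμ²`),
  `log2FC = log2((q̂_KO + ½)/(q̂_ctrl + ½))`, delta-method standard error,
  and a t reference with `n − 2` df; Benjamini–Hochberg FDR per analysis.
* **Biotype breakdown** of significant features and the **Pearson
  correlation** of log2 fold changes between PROMPTs and their anchor
  genes, over pairs where both reach `p_adj < 0.05`.
* **Extras** — the three-criteria single-cell marker-gene filter
  (≥ 2.5-fold over the pooled rest, detected in ≥ 10% of cluster cells,
  highest per-cluster mean) and a `2^−ΔΔCt` qPCR helper.
* **Synthetic data** — a seeded generator emulating the control-vs-KO
  design (5 + 5 replicates, NB counts, antisense-dominant PROMPT
  accumulation, truth manifest) so the entire pipeline is testable without
  any download.

## Worked example

Simulate the default study (2000 genes, five replicates per condition,
30% of PROMPTs accumulating in the knockout, 80% of those antisense) and
run normalization, differential testing and correlation:

```python
import numpy as np
from promptseq import SimConfig, run_synthetic_study

study = run_synthetic_study(SimConfig(), seed=1)
t = study["de_tables"]
for mode in ("sense", "antisense", "unstranded"):
    tab = t[f"prompts_{mode}"]
    print(f"{mode:10s} significant PROMPTs: {(tab['p_adj'] < 0.05).sum()}")
pairs, res = study["correlation"]["antisense"]
print(f"antisense PROMPT/gene pairs: n={res.n}  r={res.r:.3f}  p={res.p:.2g}")
print("size factors:", np.round(study["size_factors"], 3))
```

prints

```
sense      significant PROMPTs: 114
antisense  significant PROMPTs: 534
unstranded significant PROMPTs: 584
antisense PROMPT/gene pairs: n=37  r=0.095  p=0.58
size factors: [1.018 0.962 0.964 0.782 1.188 1.142 0.974 1.101 1.039 0.967]
```

The ~4.7:1 antisense:sense asymmetry among significant PROMPTs reflects
the simulated direction mix — the hallmark of PROMPT stabilization — and
the near-zero correlation shows that, with gene and PROMPT effects drawn
independently, significant PROMPT accumulation says nothing about the
anchor gene's own fold change. The size factors recover each sample's
simulated library-depth factor from gene counts alone.

The same stages run from the shell on real files:

```bash
promptseq build-prompts --gtf annotation.gtf --upstream 3000 --out prompts.bed
promptseq count --features prompts.bed --mode antisense --strandedness reverse \
    --out prompt_counts.tsv sample1.bam sample2.bam ...
promptseq de --counts prompt_counts.tsv --gene-counts gene_counts.tsv \
    --conditions conditions.tsv --out de_prompts.tsv
promptseq correlate --prompt-de de_prompts.tsv --gene-de de_genes.tsv --mode antisense
promptseq run --config run.yaml        # all stages, with a manifest
```

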