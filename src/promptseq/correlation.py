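"""Correlation between PROMPT accumulation and downstream-gene expression.

Each retained PROMPT region has a single downstream (anchor) gene.  To ask
whether PROMPT accumulation after exosome loss propagates to the anchor
gene, PROMPTs and genes that are both significant (adjusted p < alpha in
their respective analyses) are paired and the Pearson correlation of their
log2 fold changes is computed, per PROMPT strand mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationResult", "pair_prompt_gene", "pearson_correlation"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    strand_mode: str = "antisense"


def pair_prompt_gene(
    de_prompts: pd.DataFrame,
    de_genes: pd.DataFrame,
    anchor_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    strand_mode: str = "antisense",
) -> pd.DataFrame:
    """Pair significant PROMPTs with their significant anchor genes.

    ``de_prompts`` and ``de_genes`` are tables from
    :func:`promptseq.diffexpr.nb_wald_test` (PROMPT table restricted to one
    strand mode).  The PROMPT -> anchor gene mapping is taken from an
    ``anchor_gene_id`` column if present, else from ``anchor_map``.  A pair
    is retained only if both members have p_adj < alpha; PROMPTs whose
    anchor is absent from the gene table are skipped.
    """
    if "anchor_gene_id" in de_prompts.columns:
        anchors = de_prompts["anchor_gene_id"]
    elif anchor_map is not None:
        anchors = pd.Series({fid: anchor_map.get(fid) for fid in de_prompts.index})
    else:
        raise ValueError("need an anchor_gene_id column or an anchor_map")

    rows = []
    for fid, prow in de_prompts.iterrows():
        if not prow["p_adj"] < alpha:
            continue
        anchor = anchors.loc[fid]
        if anchor is None or anchor not in de_genes.index:
            continue
        grow = de_genes.loc[anchor]
        if not grow["p_adj"] < alpha:
            continue
        rows.append(
            {
                "anchor_gene_id": anchor,
                "prompt_log2fc": prow["log2fc"],
                "gene_log2fc": grow["log2fc"],
                "prompt_p_adj": prow["p_adj"],
                "gene_p_adj": grow["p_adj"],
                "strand_mode": strand_mode,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "anchor_gene_id",
            "prompt_log2fc",
            "gene_log2fc",
            "prompt_p_adj",
            "gene_p_adj",
            "strand_mode",
        ],
    )


def pearson_correlation(pairs: pd.DataFrame, strand_mode: str | None = None) -> CorrelationResult:
    """Pearson r of (prompt_log2fc, gene_log2fc) with a two-sided t test.

    r is computed directly from the sample covariance and variances; the
    p-value refers r*sqrt((n-2)/(1-r^2)) to a t distribution with n-2
    degrees of freedom.
    """
    x = np.asarray(pairs["prompt_log2fc"], dtype=float)
    y = np.asarray(pairs["gene_log2fc"], dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("insufficient pairs: Pearson correlation needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite log2 fold changes")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance in one coordinate")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if strand_mode is None:
        modes = set(pairs.get("strand_mode", pd.Series(dtype=str)))
        strand_mode = modes.pop() if len(modes) == 1 else "mixed"
    return CorrelationResult(r=r, p=p, n=n, strand_mode=strand_mode)
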