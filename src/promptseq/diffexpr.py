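"""Normalization, negative-binomial differential testing and FDR control.

The workflow mirrors a standard bulk RNA-seq comparison of a knockout (KO)
against a control group:

* per-sample size factors by the median-of-ratios method, always computed
  from **gene** counts (PROMPT regions are sparse and strongly perturbed,
  so they never contribute to normalization);
* a transparent two-group negative-binomial Wald test.  Counts are modelled
  as NB with Var = mu + alpha*mu^2; the dispersion alpha is estimated per
  feature by method of moments on normalized counts within each group.  The
  reported effect is log2((q_ko + c)/(q_ctrl + c)) with a small pseudocount
  c for stability at low counts, its standard error comes from the delta
  method, and the Wald statistic is referred to a t distribution with
  n_ctrl + n_ko - 2 degrees of freedom.  The t reference (rather than a
  normal) accounts for the variance being estimated from few replicates;
  with 5 + 5 samples it keeps the null type-I error at the nominal level,
  where a normal reference is measurably anti-conservative.
* Benjamini-Hochberg step-up adjustment, applied separately per analysis
  (genes, and each PROMPT strand mode).

This is deliberately a self-contained simplification of the DESeq2-style
workflow: no dispersion shrinkage across features, no outlier filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .quantify import CountMatrix

__all__ = [
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "classify_biotypes",
    "ma_table",
    "ddct_relative_abundance",
]

DISPERSION_FLOOR = 1e-8


def size_factors(gene_counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors from a genes x samples count matrix.

    The reference for gene i is its geometric mean across samples; the size
    factor of sample j is the median over genes (with a strictly positive
    reference, i.e. no zero in any sample) of counts_ij / reference_i.
    """
    counts = gene_counts.counts if isinstance(gene_counts, CountMatrix) else np.asarray(gene_counts)
    counts = counts.astype(float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("size factors require a 2-D matrix with >= 2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("size factors undefined: no gene has nonzero counts in all samples")
    logc = np.log(counts[positive])
    log_ref = logc.mean(axis=1)
    sf = np.exp(np.median(logc - log_ref[:, None], axis=0))
    return sf


def _group_dispersion(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion from a group's normalized mean/variance."""
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (v - q) / q**2
    return np.where(q > 0, np.maximum(a, 0.0), 0.0)


def nb_wald_test(
    counts: CountMatrix | np.ndarray,
    sf: np.ndarray,
    condition: Sequence[str],
    pseudocount: float = 0.5,
    feature_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test of KO vs control, one row per feature.

    ``condition`` labels each sample ``"control"`` or ``"ko"`` (>= 2 samples
    per group).  Returns a DataFrame with columns ``base_mean`` (mean
    normalized count over all samples), ``log2fc`` (KO over control),
    ``se``, ``p``, ``p_adj`` (BH within this table) and ``dispersion``.
    All-zero features get log2fc 0 and p = 1.
    """
    if isinstance(counts, CountMatrix):
        if feature_ids is None:
            feature_ids = counts.feature_ids
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    sf = np.asarray(sf, dtype=float)
    condition = np.asarray(condition)
    bad = set(condition) - {"control", "ko"}
    if bad:
        raise ValueError(f"condition labels must be 'control' or 'ko'; got {sorted(bad)}")
    ko = condition == "ko"
    ctrl = condition == "control"
    if ko.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    if counts.shape[1] != len(condition) or len(sf) != len(condition):
        raise ValueError("counts, size factors and condition labels are misaligned")

    y = counts / sf  # normalized counts
    base_mean = y.mean(axis=1)
    q_ctrl = y[:, ctrl].mean(axis=1)
    q_ko = y[:, ko].mean(axis=1)
    v_ctrl = y[:, ctrl].var(axis=1, ddof=1)
    v_ko = y[:, ko].var(axis=1, ddof=1)
    n_ctrl, n_ko = int(ctrl.sum()), int(ko.sum())

    alpha_hat = np.maximum(
        0.5 * (_group_dispersion(q_ctrl, v_ctrl) + _group_dispersion(q_ko, v_ko)),
        DISPERSION_FLOOR,
    )

    c = pseudocount
    log2fc = np.log2((q_ko + c) / (q_ctrl + c))

    # Var(q_hat_g) ~= n_g^-2 sum_j (mu_ij + alpha mu_ij^2)/s_j^2, mu_ij = s_j q_g
    def var_qhat(q: np.ndarray, members: np.ndarray, n: int) -> np.ndarray:
        s = sf[members]
        mu = s[None, :] * q[:, None]
        return ((mu + alpha_hat[:, None] * mu**2) / s[None, :] ** 2).sum(axis=1) / n**2

    ln2_sq = np.log(2.0) ** 2
    var_lfc = var_qhat(q_ko, ko, n_ko) / ((q_ko + c) ** 2 * ln2_sq) + var_qhat(
        q_ctrl, ctrl, n_ctrl
    ) / ((q_ctrl + c) ** 2 * ln2_sq)
    se = np.sqrt(var_lfc)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=n_ctrl + n_ko - 2)
    all_zero = (q_ctrl == 0) & (q_ko == 0)
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)

    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(counts.shape[0])]
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "p_adj": bh_adjust(p),
            "dispersion": alpha_hat,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Each p-value is multiplied by N and divided by its ascending rank, then
    monotonicity is enforced from the largest rank down (adj_(k) = min over
    ranks >= k) and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj


def classify_biotypes(
    de: pd.DataFrame,
    annotation: GenomeAnnotation | Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tally significant features (p_adj < alpha) by biotype and fold-change sign.

    ``annotation`` may be a :class:`GenomeAnnotation` or a feature_id ->
    biotype mapping; features absent from it count as ``unknown``.  Returns
    a DataFrame indexed by biotype with columns ``n_up`` and ``n_down``.
    """
    if isinstance(annotation, GenomeAnnotation):
        biotype_of: Mapping[str, str] = {g.gene_id: g.biotype for g in annotation.genes}
    else:
        biotype_of = annotation
    sig = de[(de["p_adj"] < alpha) & (de["log2fc"] != 0)]
    rows: dict[str, list[int]] = {}
    for fid, lfc in zip(sig.index, sig["log2fc"]):
        bt = biotype_of.get(fid, "unknown")
        slot = rows.setdefault(bt, [0, 0])
        slot[0 if lfc > 0 else 1] += 1
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["n_up", "n_down"]).sort_index()
    out.index.name = "biotype"
    return out


def ma_table(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Project a DE table to (base_mean, log2fc, significant) for MA plotting."""
    return pd.DataFrame(
        {
            "base_mean": de["base_mean"],
            "log2fc": de["log2fc"],
            "significant": de["p_adj"] < alpha,
        },
        index=de.index,
    )


def ddct_relative_abundance(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative transcript abundance by the 2^-ddCt method.

    Ct values of the target are normalized to a reference transcript
    (e.g. beta-actin) within each of sample and control; the control's
    relative abundance is 1 by construction.
    """
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
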