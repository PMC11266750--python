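"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: counting enumerates
all fragment/feature pairs with plain arithmetic, BH follows the textbook
definition with an explicit double loop, Pearson r uses raw sums, and the
marker filter re-checks every gene with scalar Python.
"""

from __future__ import annotations

import math

import numpy as np

from promptseq.annotation import PromptRegion
from promptseq.quantify import Fragment


def brute_force_count(fragments, features, mode, min_overlap=1):
    """All-pairs overlap enumeration; returns (counts, ambiguous, unassigned)."""
    feat_strand = [getattr(f, "anchor_strand", None) or f.strand for f in features]
    counts = np.zeros(len(features), dtype=np.int64)
    ambiguous = unassigned = 0
    for fr in fragments:
        matched = []
        for i, ft in enumerate(features):
            if ft.chrom != fr.chrom:
                continue
            ov = min(ft.end, fr.end) - max(ft.start - 1, fr.start)
            if ov < min_overlap:
                continue
            if mode == "sense" and fr.strand != feat_strand[i]:
                continue
            if mode == "antisense" and fr.strand == feat_strand[i]:
                continue
            matched.append(i)
        if len(matched) == 1:
            counts[matched[0]] += 1
        elif matched:
            ambiguous += 1
        else:
            unassigned += 1
    return counts, ambiguous, unassigned


def brute_force_bh(pvalues):
    """Textbook step-up BH: raw_(k) = p_(k)*N/k, adj_(k) = min over ranks >= k."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])  # stable
    adj = [0.0] * n
    for pos, idx in enumerate(order):
        best = math.inf
        for pos2 in range(pos, n):
            raw = p[order[pos2]] * n / (pos2 + 1)
            best = min(best, raw)
        adj[idx] = min(best, 1.0)
    return adj


def brute_force_bh_allpairs(pvalues):
    """BH via the all-pairs definition: adj_(k) = min_{m >= k} p_(m)*N/m.

    Uses an explicit n x n comparison rather than a running minimum, so it
    stays independent of the suffix-accumulate implementation.
    """
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    raw = p[order] * n / np.arange(1, n + 1)
    ge = np.triu(np.ones((n, n), dtype=bool))  # m >= k
    tail_min = np.where(ge, raw[None, :], np.inf).min(axis=1)
    adj = np.empty(n)
    adj[order] = np.minimum(tail_min, 1.0)
    return adj


def brute_force_pearson(x, y):
    """Pearson r from raw sums, scalar arithmetic only."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def brute_force_markers(expr, clusters, gene_ids, target, fold=2.5, min_frac=0.10, thr=0.0):
    """Per-gene scalar re-check of the three marker criteria."""
    labels = sorted(set(clusters))
    out = []
    for j, gid in enumerate(gene_ids):
        in_vals = [expr[i][j] for i in range(len(clusters)) if clusters[i] == target]
        rest_vals = [expr[i][j] for i in range(len(clusters)) if clusters[i] != target]
        mean_in = sum(in_vals) / len(in_vals)
        mean_rest = sum(rest_vals) / len(rest_vals)
        if mean_rest > 0:
            if not mean_in >= fold * mean_rest:
                continue
        elif not mean_in > 0:
            continue
        if sum(1 for v in in_vals if v > thr) / len(in_vals) < min_frac:
            continue
        highest = True
        for lab in labels:
            if lab == target:
                continue
            vals = [expr[i][j] for i in range(len(clusters)) if clusters[i] == lab]
            if sum(vals) / len(vals) >= mean_in:
                highest = False
                break
        if highest:
            out.append(gid)
    return out


def random_counting_fixture(rng, n_frags, n_feats, n_chroms=2, span=50_000, disjoint=False):
    """Random fragments and features for counting-oracle comparisons.

    With ``disjoint=True`` features are placed on a fixed grid so no two
    overlap (the regime in which unstranded counts dominate stranded ones).
    """
    features = []
    if disjoint:
        slots = rng.permutation(span // 4000)[:n_feats]
    for i in range(n_feats):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        if disjoint:
            start = int(slots[i]) * 4000 + 1
            length = int(rng.integers(50, 3500))
        else:
            start = int(rng.integers(1, span))
            length = int(rng.integers(50, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(PromptRegion(f"feat_{i}", f"anchor_{i}", chrom, start, start + length - 1, strand))
    fragments = []
    for _ in range(n_frags):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(20, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        fragments.append(Fragment(chrom, start, start + length, strand))
    return fragments, features
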