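"""Brute-force reference implementations used to cross-check the package.

Everything here is deliberately naive (explicit loops, enumeration, closed
forms) and independent of the library code paths it verifies.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from ncboost.types import GeneModel, VariantRecord


def oracle_gene_labels(
    variant: VariantRecord,
    gene: GeneModel,
    splicing_threshold: int = 10,
    flank: int = 1000,
) -> Set[str]:
    """Base-level label enumeration for one (variant, gene) pair."""
    if variant.chrom != gene.chrom:
        return set()
    p = variant.pos
    labels: Set[str] = set()
    for tx in gene.transcripts:
        if not (tx.tx_start <= p <= tx.tx_end):
            continue
        exon_positions = set()
        for s, e in tx.exons:
            exon_positions.update(range(s, e + 1))
        junctions = []
        for i, (s, e) in enumerate(tx.exons):
            if i > 0:
                junctions.append(s)
            if i < len(tx.exons) - 1:
                junctions.append(e)
        if any(abs(p - j) <= splicing_threshold for j in junctions):
            labels.add("splicing")
        if p in exon_positions:
            if tx.cds_start is not None:
                if p < tx.cds_start:
                    labels.add("UTR5" if gene.strand == "+" else "UTR3")
                elif p > tx.cds_end:
                    labels.add("UTR3" if gene.strand == "+" else "UTR5")
                else:
                    labels.add("exonic")
            else:
                labels.add("exonic")
        else:
            labels.add("intronic")
    if not labels and gene.start <= p <= gene.end:
        labels.add("intronic")
    if not labels:
        left = gene.start - flank <= p < gene.start
        right = gene.end < p <= gene.end + flank
        if gene.strand == "+":
            if left:
                labels.add("upstream")
            if right:
                labels.add("downstream")
        else:
            if right:
                labels.add("upstream")
            if left:
                labels.add("downstream")
    if gene.biotype == "noncoding_rna":
        remap = {
            "exonic": "ncRNA_exonic",
            "intronic": "ncRNA_intronic",
            "splicing": "ncRNA_splicing",
            "upstream": "ncRNA_flank",
            "downstream": "ncRNA_flank",
        }
        labels = {remap[l] for l in labels}
    return labels


def oracle_window_mean(
    panel_frame,
    chrom: str,
    pos: int,
    column: str,
    window_bp: int = 1000,
) -> float:
    """Linear scan over every panel record."""
    half = window_bp // 2
    vals = []
    for row in panel_frame.itertuples(index=False):
        if row.chrom != chrom or row.pos == pos:
            continue
        if pos - half <= row.pos <= pos + half:
            v = getattr(row, column)
            if not np.isnan(v):
                vals.append(v)
    return float(np.mean(vals)) if vals else float("nan")


def oracle_window_het(panel_frame, chrom: str, pos: int, window_bp: int = 1000) -> float:
    half = window_bp // 2
    vals = []
    for row in panel_frame.itertuples(index=False):
        if row.chrom != chrom or row.pos == pos:
            continue
        if pos - half <= row.pos <= pos + half:
            vals.append(2.0 * row.maf * (1.0 - row.maf))
    return float(np.mean(vals)) if vals else float("nan")


def oracle_gc_cpg(seq: str, pos: int, halfwidth: int = 75) -> Tuple[float, float]:
    lo = max(1, pos - halfwidth)
    hi = min(len(seq), pos + halfwidth)
    window = seq[lo - 1 : hi].upper()
    n_valid = 0
    gc = 0
    for b in window:
        if b != "N":
            n_valid += 1
            if b in ("G", "C"):
                gc += 1
    if n_valid == 0:
        return float("nan"), float("nan")
    cg = 0
    for i in range(len(window) - 1):
        if window[i] == "C" and window[i + 1] == "G":
            cg += 1
    gc_pct = 100.0 * gc / n_valid
    cpg_pct = 100.0 * cg / (n_valid - 1) if n_valid > 1 else float("nan")
    return gc_pct, cpg_pct


def oracle_track_lookup(records: Sequence[Tuple[str, int, int, float]], chrom: str, pos: int) -> float:
    for c, s, e, v in records:
        if c == chrom and s <= pos <= e:
            return float(v)
    return float("nan")


def oracle_auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """All positive x negative pairs, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_competition_percentile(
    background: Sequence[float], spiked: float
) -> Tuple[int, float]:
    """Sort-based standard competition ("1224") ranking."""
    pool = sorted(list(background) + [spiked], reverse=True)
    rank = 1 + pool.index(spiked)  # first index of the tied value block
    n = len(pool)
    return rank, 100.0 * (n - rank + 1) / n


def oracle_fisher_greater(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """One-sided (greater) Fisher p by hypergeometric enumeration, plus the
    sample odds ratio."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        if col1 - x > n - row1:
            continue
        p += comb(row1, x) * comb(n - row1, col1 - x) / denom
    if b * c == 0:
        oddsr = float("inf") if a * d > 0 else float("nan")
    else:
        oddsr = (a * d) / (b * c)
    return oddsr, p


def oracle_ranksum_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments of
    the pooled (tie-free) values."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    w_obs = sum(ranks[v] for v in x)
    ws = [sum(pooled.index(v) + 1 for v in combo) for combo in combinations(pooled, n1)]
    ws = np.array(ws)
    mean_w = ws.mean()
    extreme = np.sum(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-9)
    return float(extreme / len(ws))
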