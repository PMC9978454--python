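"""Enhancer-to-gene target assignment.

Tiers are tried in sequence per enhancer, the first non-empty tier winning:

1. ``pchic`` — genes whose promoter fragment interacts with a fragment
   overlapping the enhancer;
2. ``h3k27ac_corr`` — promoters whose cross-tissue signal is significantly
   rank-correlated with the enhancer's (permutation-adjusted p < alpha);
3. ``chromhmm_corr`` — the same machinery on segmentation-derived scores;
4. ``nearest`` — the closest expressed gene.

All tiers are restricted to the TAD containing the enhancer's midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .io_formats import Interaction

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "TargetAssignment",
    "tad_of",
    "promoter_interval",
    "pchic_targets",
    "spearman_rho",
    "permutation_adjusted_p",
    "correlation_targets",
    "nearest_expressed_gene",
    "assign_targets",
]


@dataclass
class CorrelationResult:
    enhancer: str
    gene: str
    rho: float
    p_adj: float


@dataclass
class TargetAssignment:
    enhancer: str
    gene: str
    tier: str


def tad_of(
    interval: GenomicInterval, tads: Sequence[GenomicInterval]
) -> GenomicInterval | None:
    """The TAD containing the interval's midpoint, or None."""
    mid = interval.midpoint
    for tad in tads:
        if tad.contains_point(interval.chrom, mid):
            return tad
    return None


def promoter_interval(chrom: str, tss: int, flank: int = 2000) -> GenomicInterval:
    """Promoter region: +/- ``flank`` bp around the TSS."""
    return GenomicInterval(chrom, max(tss - flank, 0), tss + flank)


def _overlapping(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> list[int]:
    return [i for i, o in enumerate(others) if iv.overlaps(o)]


def pchic_targets(
    enhancer: GenomicInterval,
    fragments: Sequence[GenomicInterval],
    interactions: Sequence[Interaction],
    genes: pd.DataFrame,
    tads: Sequence[GenomicInterval],
    promoter_flank: int = 2000,
) -> list[str]:
    """Genes whose promoter fragment interacts with a fragment overlapping
    the enhancer, restricted to the enhancer's TAD."""
    tad = tad_of(enhancer, tads)
    if tad is None:
        return []
    enh_frag_idx = set(_overlapping(enhancer, list(fragments)))
    if not enh_frag_idx:
        return []
    enh_frags = [fragments[i] for i in enh_frag_idx]
    partner_frags: list[GenomicInterval] = []
    for x in interactions:
        for frag in enh_frags:
            if x.fragA.overlaps(frag):
                partner_frags.append(x.fragB)
            if x.fragB.overlaps(frag):
                partner_frags.append(x.fragA)
    out = []
    for row in genes.itertuples():
        if row.chrom != enhancer.chrom:
            continue
        if not tad.contains_point(row.chrom, row.tss):
            continue
        prom = promoter_interval(row.chrom, row.tss, promoter_flank)
        if any(prom.overlaps(pf) for pf in partner_frags):
            out.append(row.gene)
    return sorted(set(out))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties; NaN when a
    vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def _norm_ranks(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)
    r = r - r.mean()
    norm = np.sqrt((r**2).sum())
    return r / norm if norm > 0 else r


def permutation_adjusted_p(
    enhancer_matrix: pd.DataFrame,
    promoter_matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CorrelationResult]:
    """Permutation-calibrated Spearman correlation for enhancer-promoter pairs.

    For each pair, tissue labels are shuffled independently for the enhancer
    and the promoter row ``n_perm`` times;
    p_adj = (1 + #{|rho*| >= |rho_obs|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_t = enhancer_matrix.shape[1]
    if promoter_matrix.shape[1] != n_t:
        raise ValueError("matrices must share tissue columns")
    out: list[CorrelationResult] = []
    for enh_id, gene in pairs:
        re = _norm_ranks(enhancer_matrix.loc[enh_id].to_numpy(dtype=float))
        rp = _norm_ranks(promoter_matrix.loc[gene].to_numpy(dtype=float))
        rho_obs = float((re * rp).sum())
        perm_e = rng.permuted(np.tile(np.arange(n_t), (n_perm, 1)), axis=1)
        perm_p = rng.permuted(np.tile(np.arange(n_t), (n_perm, 1)), axis=1)
        rho_star = np.einsum("pt,pt->p", re[perm_e], rp[perm_p])
        exceed = int((np.abs(rho_star) >= abs(rho_obs) - 1e-12).sum())
        p_adj = (1 + exceed) / (n_perm + 1)
        out.append(CorrelationResult(enh_id, gene, rho_obs, p_adj))
    return out


def correlation_targets(
    enhancer_id: str,
    results: Sequence[CorrelationResult],
    active_promoters: set[str],
    alpha: float = 0.01,
) -> list[str]:
    """Genes with p_adj strictly below alpha whose promoter is active."""
    return sorted(
        {
            r.gene
            for r in results
            if r.enhancer == enhancer_id
            and r.p_adj < alpha
            and r.gene in active_promoters
        }
    )


def nearest_expressed_gene(
    enhancer: GenomicInterval,
    genes: pd.DataFrame,
    tad: GenomicInterval | None,
    tpm_cut: float = 1.0,
) -> str | None:
    """Gene with minimal |TSS - enhancer midpoint| among genes with
    TPM >= tpm_cut inside the TAD; ties broken toward the smaller TSS."""
    if tad is None:
        return None
    mid = enhancer.midpoint
    best: tuple[int, int, str] | None = None
    for row in genes.itertuples():
        if row.chrom != enhancer.chrom or row.tpm < tpm_cut:
            continue
        if not tad.contains_point(row.chrom, row.tss):
            continue
        key = (abs(row.tss - mid), row.tss, row.gene)
        if best is None or key < best:
            best = key
    if best is None:
        logger.info("%s: no expressed gene in TAD", enhancer.id)
        return None
    return best[2]


def assign_targets(
    enhancers: Sequence[GenomicInterval],
    tads: Sequence[GenomicInterval],
    genes: pd.DataFrame,
    fragments: Sequence[GenomicInterval] | None = None,
    interactions: Sequence[Interaction] | None = None,
    enh_h3k27ac: pd.DataFrame | None = None,
    prom_h3k27ac: pd.DataFrame | None = None,
    enh_chromhmm: pd.DataFrame | None = None,
    prom_chromhmm: pd.DataFrame | None = None,
    active_promoters: set[str] | None = None,
    alpha: float = 0.01,
    tpm_cut: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[TargetAssignment], dict[str, float]]:
    """Sequential tiered assignment; the first tier with any hit wins per
    enhancer.  Returns assignments plus a per-tier tally (fractions)."""
    if active_promoters is None:
        active_promoters = set(genes.gene)
    assignments: list[TargetAssignment] = []
    tally = {t: 0 for t in ("pchic", "h3k27ac_corr", "chromhmm_corr", "nearest", "unassigned")}

    corr_results: dict[str, list[CorrelationResult]] = {"h3k27ac_corr": [], "chromhmm_corr": []}
    for tier, (em, pm) in {
        "h3k27ac_corr": (enh_h3k27ac, prom_h3k27ac),
        "chromhmm_corr": (enh_chromhmm, prom_chromhmm),
    }.items():
        if em is None or pm is None:
            logger.warning("tier %s inputs missing; tier skipped", tier)
            continue
        pairs = []
        for enh in enhancers:
            if enh.id not in em.index:
                continue
            tad = tad_of(enh, tads)
            if tad is None:
                continue
            for row in genes.itertuples():
                if row.gene in pm.index and tad.contains_point(row.chrom, row.tss):
                    pairs.append((enh.id, row.gene))
        corr_results[tier] = permutation_adjusted_p(em, pm, pairs, n_perm=n_perm, seed=seed)

    for enh in enhancers:
        tad = tad_of(enh, tads)
        hit_genes: list[str] = []
        tier_used = "unassigned"
        if fragments is not None and interactions is not None:
            hit_genes = pchic_targets(enh, fragments, interactions, genes, tads)
            if hit_genes:
                tier_used = "pchic"
        if not hit_genes:
            for tier in ("h3k27ac_corr", "chromhmm_corr"):
                hit_genes = correlation_targets(
                    enh.id, corr_results[tier], active_promoters, alpha
                )
                if hit_genes:
                    tier_used = tier
                    break
        if not hit_genes:
            gene = nearest_expressed_gene(enh, genes, tad, tpm_cut)
            if gene is not None:
                hit_genes = [gene]
                tier_used = "nearest"
        tally[tier_used] += 1
        for gene in hit_genes:
            assignments.append(TargetAssignment(enh.id, gene, tier_used))

    n = max(len(enhancers), 1)
    fractions = {k: v / n for k, v in tally.items()}
    genes_per_enh = len(assignments) / n
    per_gene: dict[str, int] = {}
    for a in assignments:
        per_gene[a.gene] = per_gene.get(a.gene, 0) + 1
    fractions["genes_per_enhancer"] = genes_per_enh
    fractions["enhancers_per_gene"] = (
        float(np.mean(list(per_gene.values()))) if per_gene else 0.0
    )
    return assignments, fractions
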