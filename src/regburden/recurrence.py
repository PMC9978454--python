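"""Recurrently mutated enhancer clusters.

A cluster is the set of enhancers assigned to one gene.  Clusters with DNMs
from multiple unrelated probands are tested two ways: per cluster against
the trinucleotide-expected count (Poisson upper tail, BH-corrected), and
globally with a shuffle-based permutation test asking how often a
configuration with at least ``n_clusters_hit`` clusters carrying at least
``min_dnms`` DNMs arises by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden_enrichment import fdr_adjust
from .intervals import GenomicInterval, IntervalIndex, merge_intervals
from .io_formats import DNMRecord
from .mutability import (
    MutabilityTable,
    PoissonTestResult,
    expected_dnms,
    poisson_upper_tail,
    set_mutability,
)
from .target_assignment import TargetAssignment

__all__ = [
    "EnhancerCluster",
    "build_clusters",
    "recurrent_clusters",
    "cluster_poisson_test",
    "poisson_test_all_clusters",
    "configuration_permutation_test",
]


@dataclass
class EnhancerCluster:
    gene: str
    enhancers: list[GenomicInterval]
    n_dnms: int = 0
    probands: set[str] = field(default_factory=set)

    @property
    def merged(self) -> list[GenomicInterval]:
        return merge_intervals(self.enhancers)


def build_clusters(
    assignments: Sequence[TargetAssignment],
    enhancer_map: Mapping[str, GenomicInterval],
) -> list[EnhancerCluster]:
    """One cluster per gene; an enhancer assigned to two genes appears in
    both clusters.  Overlapping members are merged within a cluster."""
    by_gene: dict[str, list[GenomicInterval]] = {}
    for a in assignments:
        if a.enhancer not in enhancer_map:
            raise KeyError(f"assignment references unknown enhancer {a.enhancer}")
        by_gene.setdefault(a.gene, []).append(enhancer_map[a.enhancer])
    return [
        EnhancerCluster(gene=g, enhancers=merge_intervals(ivs))
        for g, ivs in sorted(by_gene.items())
        if ivs
    ]


def _count_cluster_dnms(cluster: EnhancerCluster, dnms: Sequence[DNMRecord]) -> None:
    index = IntervalIndex(cluster.enhancers)
    hits = [d for d in dnms if index.contains_point(d.chrom, d.pos0)]
    cluster.n_dnms = len(hits)
    cluster.probands = {d.proband for d in hits}


def recurrent_clusters(
    clusters: Sequence[EnhancerCluster],
    dnms: Sequence[DNMRecord],
    min_dnms: int = 2,
    require_unrelated: bool = True,
) -> list[EnhancerCluster]:
    """Clusters with >= min_dnms DNMs, from >= min_dnms distinct probands
    when ``require_unrelated``."""
    out = []
    for c in clusters:
        _count_cluster_dnms(c, dnms)
        if c.n_dnms < min_dnms:
            continue
        if require_unrelated and len(c.probands) < min_dnms:
            continue
        out.append(c)
    return out


def cluster_poisson_test(
    cluster: EnhancerCluster,
    genome: Mapping[str, str],
    rate_table: MutabilityTable,
    n_probands: int,
    scale: float = 2.0,
) -> PoissonTestResult:
    """Observed cluster DNM count against the trinucleotide-expected count.

    Expected counts use the cluster's merged intervals so overlapping
    enhancers are not double-counted.
    """
    rate = set_mutability(genome, cluster.merged, rate_table, cluster.gene)
    lam = expected_dnms(rate.total_rate, n_probands, scale)
    p = poisson_upper_tail(cluster.n_dnms, lam) if cluster.n_dnms else 1.0
    return PoissonTestResult(observed=cluster.n_dnms, expected=lam, p=p)


def poisson_test_all_clusters(
    clusters: Sequence[EnhancerCluster],
    dnms: Sequence[DNMRecord],
    genome: Mapping[str, str],
    rate_table: MutabilityTable,
    n_probands: int,
    scale: float = 2.0,
) -> pd.DataFrame:
    """Per-cluster Poisson tests with BH FDR across the tested clusters."""
    rows = []
    for c in clusters:
        _count_cluster_dnms(c, dnms)
        res = cluster_poisson_test(c, genome, rate_table, n_probands, scale)
        rows.append(
            {
                "gene": c.gene,
                "n_enhancers": len(c.enhancers),
                "n_dnms": c.n_dnms,
                "n_probands": len(c.probands),
                "expected": res.expected,
                "poisson_p": res.p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = fdr_adjust(df["poisson_p"].to_numpy())
    return df


def configuration_permutation_test(
    clusters: Sequence[EnhancerCluster],
    dnms: Sequence[DNMRecord],
    min_dnms: int = 2,
    n_clusters_hit: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "membership",
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict:
    """Shuffle-based p for observing >= ``n_clusters_hit`` clusters with
    >= ``min_dnms`` DNMs.

    ``mode="membership"`` permutes enhancer-to-cluster membership preserving
    the cluster-size multiset and each enhancer's observed DNM count, so the
    marginal burden is held fixed and only its concentration into clusters is
    tested.  ``mode="relocate"`` instead places each enhancer uniformly at
    random in the genome and recounts (requires ``chrom_lengths``).

    When ``n_clusters_hit`` is None, the observed statistic (number of
    clusters with >= min_dnms DNMs) is used as the threshold, giving a
    standard permutation p-value.  The reported p is floored at 1/n_perm;
    the raw success count is also returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    enh_all: list[GenomicInterval] = []
    sizes: list[int] = []
    for c in clusters:
        enh_all.extend(c.enhancers)
        sizes.append(len(c.enhancers))
    index_per_enh = [IntervalIndex([iv]) for iv in enh_all]
    enh_counts = np.array(
        [
            sum(1 for d in dnms if idx.contains_point(d.chrom, d.pos0))
            for idx in index_per_enh
        ],
        dtype=np.int64,
    )
    boundaries = np.cumsum(sizes)[:-1]

    def stat_from_counts(counts: np.ndarray) -> int:
        per_cluster = np.add.reduceat(counts, np.concatenate([[0], boundaries]))
        return int((per_cluster >= min_dnms).sum())

    observed_stat = stat_from_counts(enh_counts)
    threshold = n_clusters_hit if n_clusters_hit is not None else observed_stat

    n_enh = len(enh_all)
    if mode == "membership":
        perms = rng.permuted(np.tile(np.arange(n_enh), (n_perm, 1)), axis=1)
        shuffled = enh_counts[perms]  # (n_perm, n_enh)
        per_cluster = np.add.reduceat(shuffled, np.concatenate([[0], boundaries]), axis=1)
        successes = int(((per_cluster >= min_dnms).sum(axis=1) >= threshold).sum())
    elif mode == "relocate":
        if chrom_lengths is None:
            raise ValueError("relocate mode requires chrom_lengths")
        chroms = list(chrom_lengths)
        dnm_by_chrom = {
            c: np.sort(np.array([d.pos0 for d in dnms if d.chrom == c], dtype=np.int64))
            for c in chroms
        }
        successes = 0
        for _ in range(n_perm):
            counts = np.zeros(n_enh, dtype=np.int64)
            for i, iv in enumerate(enh_all):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(0, chrom_lengths[chrom] - iv.length))
                pos = dnm_by_chrom[chrom]
                counts[i] = int(
                    np.searchsorted(pos, start + iv.length, side="left")
                    - np.searchsorted(pos, start, side="left")
                )
            if stat_from_counts(counts) >= threshold:
                successes += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    p = max(successes, 1) / n_perm
    return {
        "statistic": observed_stat,
        "threshold": threshold,
        "min_dnms": min_dnms,
        "successes": successes,
        "n_perm": n_perm,
        "p": min(p, 1.0),
        "seed": seed,
        "mode": mode,
    }
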