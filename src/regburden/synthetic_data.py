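"""Self-contained synthetic study generator.

Produces a toy genome, per-tissue window-state segmentations with planted
tissue-specific and shared enhancers, open-chromatin peaks, case/control DNM
cohorts sampled under the trinucleotide model (with an optional burden
multiplier inside a chosen enhancer set), TADs, restriction fragments,
promoter-capture interactions, cross-tissue signal matrices, expression and
gene lists — together with the ground truth needed to score every
downstream module.

Everything is reproducible: a fixed seed yields byte-identical artifacts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .intervals import GenomicInterval, IntervalIndex, merge_intervals
from .io_formats import DNMRecord, Interaction
from .mutability import BASES, MutabilityTable, _encode as _encode_seq, site_rate_array

ENHANCER_STATES = ("6_EnhG", "7_Enh")
PROMOTER_STATE = "1_TssA"
QUIESCENT_STATE = "15_Quies"
TIERS = ("pchic", "h3k27ac_corr", "chromhmm_corr", "nearest")

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PlantedEnhancer",
    "SegmentationSet",
    "RegulatoryContext",
    "Study",
    "DnmSampler",
    "generate_genome",
    "generate_segmentations",
    "generate_dnms",
    "generate_regulatory_context",
    "simulate_study",
    "write_study",
]


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic study.  Defaults give a 2 x 2 Mb toy genome."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    window_bp: int = 200
    n_tissues: int = 10
    n_fetal: int = 2
    n_planted_specific: int = 14
    n_planted_shared: int = 26
    n_probands_case: int = 47
    n_probands_control: int = 40
    mean_dnms_per_proband: float = 60.0
    mean_dnms_control: float = 60.0
    burden_multiplier: float = 1.0
    tpm_expressed_fraction: float = 0.7
    enhancer_windows: int = 4
    n_noise_enhancers: int = 30
    noise_min_tissues: int = 3
    shared_tissue_fraction: float = 0.9
    n_signal_tissues: int = 20
    genes_per_chrom: int = 20
    tad_bp: int = 200_000
    fragment_bp: int = 4_000

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom}")
            if length % self.window_bp:
                raise ValueError(
                    f"{chrom} length {length} not divisible by window {self.window_bp}"
                )
        if self.burden_multiplier < 1:
            raise ValueError("burden multiplier must be >= 1")
        if not 1 <= self.n_fetal <= self.n_tissues:
            raise ValueError("n_fetal must be between 1 and n_tissues")

    @property
    def tissues(self) -> list[str]:
        fetal = [f"E08{i + 1}" for i in range(self.n_fetal)]
        adult = [f"A{j:02d}" for j in range(1, self.n_tissues - self.n_fetal + 1)]
        return fetal + adult

    @property
    def fetal_tissues(self) -> list[str]:
        return self.tissues[: self.n_fetal]


@dataclass
class PlantedEnhancer:
    interval: GenomicInterval
    gene: str | None = None
    tier: str | None = None


@dataclass
class GroundTruth:
    """Planted structure: what downstream modules should recover."""

    specific: list[PlantedEnhancer]
    shared: list[GenomicInterval]
    burden_set: list[GenomicInterval]
    links: list[tuple[str, str, str]]  # (enhancer id, gene, tier)
    fetal_tissues: list[str]


@dataclass
class SegmentationSet:
    tracks: dict[str, dict[str, np.ndarray]]  # tissue -> chrom -> per-window state
    window_bp: int
    peaks: list[GenomicInterval]
    ground_truth: GroundTruth


@dataclass
class RegulatoryContext:
    tads: list[GenomicInterval]
    fragments: list[GenomicInterval]
    interactions: list[Interaction]
    genes: pd.DataFrame  # gene, chrom, tss, strand, tpm, rpkm
    enh_h3k27ac: pd.DataFrame
    prom_h3k27ac: pd.DataFrame
    enh_chromhmm: pd.DataFrame
    prom_chromhmm: pd.DataFrame
    gene_lists: dict[str, set[str]]
    pli: dict[str, float]
    active_promoters: set[str]


@dataclass
class Study:
    config: SyntheticConfig
    genome: dict[str, str]
    segmentations: SegmentationSet
    dnms_case: list[DNMRecord]
    dnms_control: list[DNMRecord]
    context: RegulatoryContext
    rate_table: MutabilityTable


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_genome(config: SyntheticConfig) -> dict[str, str]:
    """Uniform i.i.d. A/C/G/T sequences of the declared lengths."""
    rng = _rng(config, 0)
    genome = {}
    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    for chrom, length in config.chrom_lengths.items():
        codes = rng.integers(0, 4, size=length)
        genome[chrom] = base_arr[codes].tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# deterministic gene / TAD layout (shared between segmentation and context)

def _gene_layout(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    w = config.window_bp
    for chrom, length in config.chrom_lengths.items():
        n = config.genes_per_chrom
        for i in range(n):
            tss = ((i + 1) * length // (n + 1)) // w * w
            rows.append({"gene": f"{chrom}g{i:03d}", "chrom": chrom, "tss": tss, "strand": "+"})
    return pd.DataFrame(rows)


def _tads(config: SyntheticConfig) -> list[GenomicInterval]:
    out = []
    for chrom, length in config.chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + config.tad_bp, length)
            out.append(GenomicInterval(chrom, start, end))
            start = end
    return out


def _tad_of_point(tads: Sequence[GenomicInterval], chrom: str, pos: int) -> GenomicInterval | None:
    for tad in tads:
        if tad.contains_point(chrom, pos):
            return tad
    return None


def _place_planted(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[PlantedEnhancer], list[GenomicInterval]]:
    """Place specific enhancers near their (distinct) target genes within the
    gene's TAD, then scatter shared enhancers over the remaining space."""
    w = config.window_bp
    enh_len = config.enhancer_windows * w
    genes = _gene_layout(config)
    tads = _tads(config)
    if config.n_planted_specific > len(genes):
        raise ValueError("more planted specific enhancers than genes available")

    order = rng.permutation(len(genes))
    occupied: list[GenomicInterval] = []
    for _, row in genes.iterrows():
        occupied.append(
            GenomicInterval(row.chrom, max(row.tss - 2000, 0), row.tss + 2000)
        )

    specific: list[PlantedEnhancer] = []
    for k in range(config.n_planted_specific):
        row = genes.iloc[order[k]]
        tad = _tad_of_point(tads, row.chrom, row.tss)
        assert tad is not None
        offset = (10_000 + (k % 4) * 4_000) // w * w
        start = row.tss + offset
        if start + enh_len > tad.end:
            start = row.tss - offset - enh_len
        if start < tad.start:
            raise ValueError("cannot place planted enhancer inside TAD; enlarge TADs")
        iv = GenomicInterval(row.chrom, start, start + enh_len)
        specific.append(
            PlantedEnhancer(interval=iv, gene=row.gene, tier=TIERS[k % len(TIERS)])
        )
        occupied.append(iv)

    # shared enhancers: rejection-sample window-aligned slots clear of
    # everything placed so far (1-window margin so merges stay exact)
    shared: list[GenomicInterval] = []
    grid = []
    for chrom, length in config.chrom_lengths.items():
        n_slots = length // w - config.enhancer_windows
        grid.extend((chrom, s) for s in range(1, n_slots))
    if config.n_planted_shared + config.n_planted_specific > len(grid):
        raise ValueError("planted count exceeds available windows")
    occ_index = IntervalIndex(
        [GenomicInterval(iv.chrom, max(iv.start - w, 0), iv.end + w) for iv in occupied]
    )
    tries = 0
    while len(shared) < config.n_planted_shared:
        tries += 1
        if tries > 100 * config.n_planted_shared + 1000:
            raise ValueError("could not place shared enhancers; genome too crowded")
        chrom, slot = grid[int(rng.integers(0, len(grid)))]
        start = slot * w
        iv = GenomicInterval(chrom, start, start + enh_len)
        if occ_index.overlaps_interval(chrom, max(start - w, 0), iv.end + w):
            continue
        shared.append(iv)
        occupied.append(iv)
        occ_index = IntervalIndex(
            [GenomicInterval(o.chrom, max(o.start - w, 0), o.end + w) for o in occupied]
        )
    return specific, shared


def generate_segmentations(
    genome: Mapping[str, str], config: SyntheticConfig
) -> SegmentationSet:
    """Per-tissue window-state tracks with planted enhancers, plus peaks.

    Planted specific enhancers carry enhancer states only in the fetal
    tissues; planted shared enhancers carry enhancer states in at least
    ``shared_tissue_fraction`` of tissues (fetal tissues included).  Open
    chromatin peaks cover the planted enhancers.
    """
    if config.n_tissues < 2:
        raise ValueError("specificity undefined with a single tissue")
    for chrom in config.chrom_lengths:
        if chrom not in genome:
            raise ValueError(f"genome missing chromosome {chrom}")
    rng = _rng(config, 1)
    w = config.window_bp
    tissues = config.tissues
    specific, shared = _place_planted(config, rng)
    genes = _gene_layout(config)

    tracks: dict[str, dict[str, np.ndarray]] = {}
    for tissue in tissues:
        tracks[tissue] = {
            chrom: np.full(length // w, QUIESCENT_STATE, dtype="<U16")
            for chrom, length in config.chrom_lengths.items()
        }

    # promoters active in every tissue
    for _, row in genes.iterrows():
        w0 = max(row.tss - 2 * w, 0) // w
        w1 = min(row.tss + 2 * w, config.chrom_lengths[row.chrom]) // w
        for tissue in tissues:
            tracks[tissue][row.chrom][w0:w1] = PROMOTER_STATE

    fetal = config.fetal_tissues
    for k, pe in enumerate(specific):
        state = ENHANCER_STATES[k % 2]
        iv = pe.interval
        for tissue in fetal:
            tracks[tissue][iv.chrom][iv.start // w : iv.end // w] = state

    n_shared_tissues = math.ceil(config.shared_tissue_fraction * len(tissues))
    adult = [t for t in tissues if t not in fetal]
    for k, iv in enumerate(shared):
        state = ENHANCER_STATES[k % 2]
        n_adult = max(n_shared_tissues - len(fetal), 0)
        chosen = list(fetal) + list(rng.choice(adult, size=n_adult, replace=False))
        for tissue in chosen:
            tracks[tissue][iv.chrom][iv.start // w : iv.end // w] = state

    # background noise: lone enhancer windows shared by a random subset of
    # >= noise_min_tissues tissues (so their specificity z stays below that
    # of planted specific enhancers), kept clear of planted intervals
    planted_index = IntervalIndex(
        [GenomicInterval(iv.chrom, max(iv.start - w, 0), iv.end + w)
         for iv in [pe.interval for pe in specific] + shared]
    )
    k_min = min(config.noise_min_tissues, len(tissues))
    for _ in range(config.n_noise_enhancers):
        chrom = list(config.chrom_lengths)[int(rng.integers(0, len(config.chrom_lengths)))]
        win = int(rng.integers(0, config.chrom_lengths[chrom] // w))
        if planted_index.overlaps_interval(chrom, win * w, (win + 1) * w):
            continue
        k = int(rng.integers(k_min, len(tissues) + 1))
        for tissue in rng.choice(tissues, size=k, replace=False):
            if tracks[tissue][chrom][win] == QUIESCENT_STATE:
                tracks[tissue][chrom][win] = "7_Enh"

    peaks = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.id)
        for iv in sorted(
            [pe.interval for pe in specific] + shared,
            key=lambda v: (v.chrom, v.start),
        )
    ]
    gt = GroundTruth(
        specific=specific,
        shared=shared,
        burden_set=[pe.interval for pe in specific],
        links=[(pe.interval.id, pe.gene, pe.tier) for pe in specific],
        fetal_tissues=list(fetal),
    )
    return SegmentationSet(tracks=tracks, window_bp=w, peaks=peaks, ground_truth=gt)


# ---------------------------------------------------------------------------
# DNM sampling under the trinucleotide model

class DnmSampler:
    """Draws DNM sites with probability proportional to trinucleotide context
    rate, multiplied by ``beta`` inside the burden set."""

    def __init__(
        self,
        genome: Mapping[str, str],
        table: MutabilityTable,
        burden_set: Sequence[GenomicInterval] | None = None,
        beta: float = 1.0,
    ):
        if beta < 1:
            raise ValueError("beta must be >= 1")
        self.genome = genome
        self.table = table
        self.chroms = list(genome.keys())
        if burden_set:
            for iv in burden_set:
                if iv.chrom not in genome or iv.end > len(genome[iv.chrom]):
                    raise ValueError(f"burden interval {iv.id} outside genome")
        burden = IntervalIndex(burden_set) if burden_set else None

        weights = []
        self.offsets = {}
        offset = 0
        self.baseline_total = 0.0
        self.burden_baseline = 0.0
        self._codes = {}
        for chrom in self.chroms:
            seq = genome[chrom]
            self._codes[chrom] = _encode_seq(seq)
            w = site_rate_array(seq, table)
            self.baseline_total += float(w.sum())
            if burden is not None:
                mask = burden.contains_points(chrom, np.arange(len(seq)))
                self.burden_baseline += float(w[mask].sum())
                w = np.where(mask, w * beta, w)
            weights.append(w)
            self.offsets[chrom] = offset
            offset += len(seq)
        flat = np.concatenate(weights)
        self.total_weight = float(flat.sum())
        self._cdf = np.cumsum(flat)
        self._bounds = np.cumsum([len(genome[c]) for c in self.chroms])
        self.beta = beta

    @property
    def burden_share(self) -> float:
        """Probability that a sampled DNM lands in the burden set."""
        num = self.beta * self.burden_baseline
        return num / (num + self.baseline_total - self.burden_baseline)

    def sample(
        self,
        n_probands: int,
        mean_dnms: float,
        rng: np.random.Generator,
        proband_prefix: str = "P",
        cohort: str = "",
    ) -> list[DNMRecord]:
        counts = rng.poisson(mean_dnms, size=n_probands) if n_probands else np.array([], int)
        total = int(counts.sum())
        if total == 0:
            return []
        u = rng.random(total) * self._cdf[-1]
        flat_pos = np.searchsorted(self._cdf, u, side="right")
        chrom_idx = np.searchsorted(self._bounds, flat_pos, side="right")
        offsets = np.concatenate([[0], self._bounds[:-1]])
        pos0 = flat_pos - offsets[chrom_idx]

        # vectorized alt draw proportional to per-alt rates at each context
        ctx_idx = np.empty(total, dtype=np.int64)
        for ci, chrom in enumerate(self.chroms):
            sel = chrom_idx == ci
            if not sel.any():
                continue
            codes = self._codes[chrom]
            p = pos0[sel]
            ctx_idx[sel] = (
                codes[p - 1].astype(np.int64) * 16 + codes[p] * 4 + codes[p + 1]
            )
        probs = self.table.alt_rates[ctx_idx]
        cum = np.cumsum(probs, axis=1)
        r = rng.random(total) * cum[:, -1]
        alt_j = (r[:, None] >= cum).sum(axis=1)
        alt_codes = self.table.alt_codes[ctx_idx, alt_j]

        records: list[DNMRecord] = []
        i = 0
        for p_i, c in enumerate(counts):
            pid = f"{proband_prefix}{p_i + 1:03d}"
            for j in range(i, i + c):
                chrom = self.chroms[int(chrom_idx[j])]
                site = int(pos0[j])
                records.append(
                    DNMRecord(
                        pid,
                        chrom,
                        site + 1,
                        self.genome[chrom][site],
                        BASES[alt_codes[j]],
                        cohort,
                    )
                )
            i += c
        return records


def generate_dnms(
    genome: Mapping[str, str],
    rate_table: MutabilityTable,
    burden_set: Sequence[GenomicInterval] | None,
    beta: float,
    n_probands: int,
    mean_dnms: float,
    rng: np.random.Generator,
    proband_prefix: str = "P",
    cohort: str = "",
) -> list[DNMRecord]:
    """Per-proband DNM counts ~ Poisson(mean_dnms); sites drawn under the
    trinucleotide model with rate multiplied by ``beta`` inside the burden
    set; the alt allele drawn proportional to per-alt rates."""
    sampler = DnmSampler(genome, rate_table, burden_set, beta)
    return sampler.sample(n_probands, mean_dnms, rng, proband_prefix, cohort)


# ---------------------------------------------------------------------------
# regulatory context

def generate_regulatory_context(
    config: SyntheticConfig, ground_truth: GroundTruth
) -> RegulatoryContext:
    """TADs, fragments, interactions, signal matrices, expression, gene lists.

    Each planted link is realized through the machinery of its assigned tier:
    pchic links get a BEDPE row joining the enhancer's and promoter's
    fragments; correlation links get matrix row pairs sharing a latent
    profile; nearest links rely on gene placement and expression alone.
    """
    rng = _rng(config, 2)
    tads = _tads(config)
    genes = _gene_layout(config)
    target_genes = {gene for _, gene, _ in ground_truth.links}

    # expression
    tpm = np.empty(len(genes))
    for i, row in genes.iterrows():
        if row.gene in target_genes:
            tpm[i] = rng.uniform(5, 50)
        elif rng.random() < config.tpm_expressed_fraction:
            tpm[i] = rng.uniform(1.5, 30)
        else:
            tpm[i] = rng.uniform(0.0, 0.9)
    genes = genes.assign(tpm=np.round(tpm, 4))
    genes = genes.assign(rpkm=np.round(tpm * 0.8, 4))

    # restriction fragments tile each chromosome
    fragments = []
    for chrom, length in config.chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + config.fragment_bp, length)
            fragments.append(GenomicInterval(chrom, start, end))
            start = end
    frag_index = {iv.chrom: [] for iv in fragments}
    for iv in fragments:
        frag_index[iv.chrom].append(iv)

    def fragment_at(chrom: str, pos: int) -> GenomicInterval:
        return frag_index[chrom][pos // config.fragment_bp]

    tss_of = dict(zip(genes.gene, genes.tss))
    chrom_of = dict(zip(genes.gene, genes.chrom))
    interactions = []
    for enh_id, gene, tier in ground_truth.links:
        if tier != "pchic":
            continue
        pe = next(p for p in ground_truth.specific if p.interval.id == enh_id)
        fa = fragment_at(pe.interval.chrom, pe.interval.midpoint)
        fb = fragment_at(chrom_of[gene], tss_of[gene])
        interactions.append(Interaction(fa, fb, score=5.0))

    # signal matrices across synthetic profiling tissues
    cols = [f"S{j:02d}" for j in range(config.n_signal_tissues)]
    enh_ids = [pe.interval.id for pe in ground_truth.specific]
    gene_ids = list(genes.gene)

    def make_pair_matrices(tier: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        enh_m = rng.normal(size=(len(enh_ids), len(cols)))
        prom_m = rng.normal(size=(len(gene_ids), len(cols)))
        for enh_id, gene, t in ground_truth.links:
            if t != tier:
                continue
            latent = rng.normal(size=len(cols))
            ei = enh_ids.index(enh_id)
            gi = gene_ids.index(gene)
            enh_m[ei] = latent + 0.15 * rng.normal(size=len(cols))
            prom_m[gi] = latent + 0.15 * rng.normal(size=len(cols))
        return (
            pd.DataFrame(np.round(enh_m, 5), index=enh_ids, columns=cols),
            pd.DataFrame(np.round(prom_m, 5), index=gene_ids, columns=cols),
        )

    enh_k27, prom_k27 = make_pair_matrices("h3k27ac_corr")
    enh_hmm, prom_hmm = make_pair_matrices("chromhmm_corr")

    # gene lists and pLI
    known = set()
    for i, (_, gene, _) in enumerate(ground_truth.links):
        if i % 2 == 0:
            known.add(gene)
    for gene in gene_ids:
        if gene not in target_genes and rng.random() < 0.1:
            known.add(gene)
    pli = {}
    for gene in gene_ids:
        if gene in target_genes:
            pli[gene] = round(float(rng.uniform(0.9, 1.0)), 4)
        else:
            pli[gene] = round(float(rng.uniform(0.0, 1.0)), 4)

    return RegulatoryContext(
        tads=tads,
        fragments=fragments,
        interactions=interactions,
        genes=genes,
        enh_h3k27ac=enh_k27,
        prom_h3k27ac=prom_k27,
        enh_chromhmm=enh_hmm,
        prom_chromhmm=prom_hmm,
        gene_lists={"known_disorder": known},
        pli=pli,
        active_promoters=set(gene_ids),
    )


# ---------------------------------------------------------------------------
# top level

def simulate_study(config: SyntheticConfig) -> Study:
    """Generate the full study in memory."""
    genome = generate_genome(config)
    seg = generate_segmentations(genome, config)
    table = MutabilityTable.default()
    dnms_case = generate_dnms(
        genome,
        table,
        seg.ground_truth.burden_set,
        config.burden_multiplier,
        config.n_probands_case,
        config.mean_dnms_per_proband,
        _rng(config, 3),
        proband_prefix="ID",
        cohort="case",
    )
    dnms_control = generate_dnms(
        genome,
        table,
        None,
        1.0,
        config.n_probands_control,
        config.mean_dnms_control,
        _rng(config, 4),
        proband_prefix="C",
        cohort="control",
    )
    context = generate_regulatory_context(config, seg.ground_truth)
    return Study(
        config=config,
        genome=genome,
        segmentations=seg,
        dnms_case=dnms_case,
        dnms_control=dnms_control,
        context=context,
        rate_table=table,
    )


def _states_to_bed(states: Mapping[str, np.ndarray], window_bp: int) -> list[GenomicInterval]:
    """Run-length compress a window-state track into dense BED records."""
    out = []
    for chrom in states:
        arr = states[chrom]
        change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(arr)]])
        for s, e in zip(starts, ends):
            out.append(
                GenomicInterval(chrom, int(s) * window_bp, int(e) * window_bp, name=str(arr[s]))
            )
    return out


def write_study(study: Study, outdir: str | Path) -> dict[str, str]:
    """Serialize every artifact as plain text; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(outdir / name)
        return outdir / name

    io_formats.write_fasta(_p("genome.fa"), study.genome)
    seg = study.segmentations
    for tissue, states in seg.tracks.items():
        io_formats.write_bed(
            _p(f"segmentation_{tissue}.bed"), _states_to_bed(states, seg.window_bp)
        )
    io_formats.write_bed(_p("dnase_peaks.bed"), seg.peaks)
    io_formats.write_dnms(_p("dnms_case.tsv"), study.dnms_case)
    io_formats.write_dnms(_p("dnms_control.tsv"), study.dnms_control)
    study.rate_table.to_tsv(_p("rates.tsv"))

    ctx = study.context
    io_formats.write_bed(_p("tads.bed"), ctx.tads)
    io_formats.write_bed(_p("fragments.bed"), ctx.fragments)
    io_formats.write_bedpe(_p("interactions.bedpe"), ctx.interactions)
    ctx.genes.to_csv(_p("genes.tsv"), sep="\t", index=False)
    io_formats.write_matrix(_p("enh_h3k27ac.tsv"), ctx.enh_h3k27ac)
    io_formats.write_matrix(_p("prom_h3k27ac.tsv"), ctx.prom_h3k27ac)
    io_formats.write_matrix(_p("enh_chromhmm.tsv"), ctx.enh_chromhmm)
    io_formats.write_matrix(_p("prom_chromhmm.tsv"), ctx.prom_chromhmm)
    with open(_p("known_disorder_genes.tsv"), "w") as fh:
        fh.write("gene\n")
        for g in sorted(ctx.gene_lists["known_disorder"]):
            fh.write(g + "\n")
    with open(_p("pli.tsv"), "w") as fh:
        fh.write("gene\tpli\n")
        for g in sorted(ctx.pli):
            fh.write(f"{g}\t{ctx.pli[g]}\n")

    gt = seg.ground_truth
    with open(_p("ground_truth.json"), "w") as fh:
        json.dump(
            {
                "specific": [
                    {"id": pe.interval.id, "gene": pe.gene, "tier": pe.tier}
                    for pe in gt.specific
                ],
                "shared": [iv.id for iv in gt.shared],
                "burden_set": [iv.id for iv in gt.burden_set],
                "fetal_tissues": gt.fetal_tissues,
            },
            fh,
            indent=2,
        )
    return paths
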