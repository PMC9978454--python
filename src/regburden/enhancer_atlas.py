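"""Tissue-specific enhancer atlas construction.

From per-tissue window-state segmentations: merge consecutive enhancer-state
windows into enhancers, count enhancer-state windows across every tissue,
compute a cross-tissue specificity Z-score per enhancer, select the
top-scoring fraction, intersect with open-chromatin peaks, and merge the
per-track selections into a final set.  The same machinery also identifies
tissue-specific genes from a cross-tissue expression matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex, merge_intervals
from .io_formats import read_bed

DEFAULT_ENHANCER_STATES = frozenset({"6_EnhG", "7_Enh"})

__all__ = [
    "EnhancerRecord",
    "load_segmentation",
    "merge_enhancer_windows",
    "score_across_tissues",
    "specificity_zscores",
    "select_top_fraction",
    "intersect_open_chromatin",
    "merge_tissue_sets",
    "tissue_specific_genes",
    "build_atlas",
]


@dataclass
class EnhancerRecord:
    """A merged enhancer interval with per-tissue window-count scores."""

    chrom: str
    start: int
    end: int
    score: int  # number of constituent windows in the source tissue
    source_tissue: str
    tissue_scores: np.ndarray | None = None  # per-tissue window counts
    z: float | None = None
    specific: bool = field(default=True)  # False when score vector has zero variance

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def load_segmentation(
    path: str, window_bp: int, chrom_lengths: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Expand a dense segmentation BED into per-window state arrays.

    Rows must be window-aligned and non-overlapping; gaps are left as empty
    strings and trigger an error if later queried.
    """
    intervals = read_bed(path)
    track: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for iv in intervals:
        if iv.start % window_bp or iv.end % window_bp:
            raise ValueError(f"{path}: {iv.id} not aligned to {window_bp}-bp windows")
        sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end)
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            sizes[chrom] = max(sizes.get(chrom, 0), length)
    for chrom, size in sizes.items():
        track[chrom] = np.full(size // window_bp, "", dtype="<U16")
    for iv in intervals:
        w0, w1 = iv.start // window_bp, iv.end // window_bp
        if np.any(track[iv.chrom][w0:w1] != ""):
            raise ValueError(f"{path}: overlapping windows at {iv.id}")
        track[iv.chrom][w0:w1] = iv.name or ""
    return track


def merge_enhancer_windows(
    track: Mapping[str, np.ndarray],
    window_bp: int,
    source_tissue: str,
    enhancer_states: Iterable[str] = DEFAULT_ENHANCER_STATES,
) -> list[EnhancerRecord]:
    """Merge maximal runs of consecutive enhancer-state windows.

    Adjacent windows (end == next start) in any enhancer state coalesce; the
    record score is the run length in windows.
    """
    states = frozenset(enhancer_states)
    out: list[EnhancerRecord] = []
    for chrom in sorted(track):
        arr = track[chrom]
        mask = np.isin(arr, list(states))
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            out.append(
                EnhancerRecord(
                    chrom=chrom,
                    start=int(s) * window_bp,
                    end=int(e) * window_bp,
                    score=int(e - s),
                    source_tissue=source_tissue,
                )
            )
    return out


def score_across_tissues(
    enhancers: Sequence[EnhancerRecord],
    tracks: Mapping[str, Mapping[str, np.ndarray]],
    window_bp: int,
    tissue_order: Sequence[str] | None = None,
    enhancer_states: Iterable[str] = DEFAULT_ENHANCER_STATES,
) -> list[EnhancerRecord]:
    """Fill ``tissue_scores``: per tissue, the number of windows inside each
    enhancer labelled with an enhancer state."""
    states = list(enhancer_states)
    tissues = list(tissue_order) if tissue_order is not None else list(tracks)
    for enh in enhancers:
        scores = np.zeros(len(tissues), dtype=np.int64)
        w0, w1 = enh.start // window_bp, enh.end // window_bp
        for t, tissue in enumerate(tissues):
            track = tracks[tissue]
            if enh.chrom not in track or len(track[enh.chrom]) < w1:
                raise ValueError(
                    f"tissue {tissue} track missing windows for {enh.id}"
                )
            window_states = track[enh.chrom][w0:w1]
            if np.any(window_states == ""):
                raise ValueError(f"tissue {tissue} track missing windows in {enh.id}")
            scores[t] = int(np.isin(window_states, states).sum())
        enh.tissue_scores = scores
        src = tissues.index(enh.source_tissue)
        if scores[src] != enh.score:
            raise ValueError(
                f"{enh.id}: source-tissue score {scores[src]} != run length {enh.score}"
            )
    return list(enhancers)


def specificity_zscores(
    enhancers: Sequence[EnhancerRecord], tissue_order: Sequence[str]
) -> list[EnhancerRecord]:
    """z = (source score - mean) / population SD of the per-tissue scores.

    Zero variance yields z = 0 with the record flagged non-specific.
    """
    if len(tissue_order) < 2:
        raise ValueError("need at least 2 tissues for specificity")
    for enh in enhancers:
        if enh.tissue_scores is None:
            raise ValueError("tissue_scores not filled; run score_across_tissues first")
        scores = enh.tissue_scores.astype(float)
        sd = float(scores.std())  # population SD (ddof=0), fixed for reproducibility
        if sd == 0:
            enh.z = 0.0
            enh.specific = False
        else:
            src = tissue_order.index(enh.source_tissue)
            enh.z = float((scores[src] - scores.mean()) / sd)
            enh.specific = True
    return list(enhancers)


def select_top_fraction(
    enhancers: Sequence[EnhancerRecord], fraction: float = 0.35
) -> list[EnhancerRecord]:
    """The ceil(fraction * n) highest-z enhancers, ties broken by position."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not enhancers:
        return []
    k = math.ceil(fraction * len(enhancers))
    ranked = sorted(enhancers, key=lambda e: (-(e.z or 0.0), e.chrom, e.start))
    return ranked[:k]


def intersect_open_chromatin(
    enhancers: Sequence[EnhancerRecord], peaks: Sequence[GenomicInterval]
) -> list[EnhancerRecord]:
    """Keep enhancers with >= 1 bp overlap with any peak (half-open)."""
    index = IntervalIndex(peaks) if peaks else None
    if index is None:
        return []
    return [
        e for e in enhancers if index.overlaps_interval(e.chrom, e.start, e.end)
    ]


def merge_tissue_sets(
    set_a: Sequence[EnhancerRecord],
    set_b: Sequence[EnhancerRecord],
    tracks: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    window_bp: int | None = None,
    tissue_order: Sequence[str] | None = None,
    enhancer_states: Iterable[str] = DEFAULT_ENHANCER_STATES,
) -> list[EnhancerRecord]:
    """Interval union of two selected sets; overlapping or abutting records
    coalesce.  Scores are recomputed over the merged span when tracks are
    supplied; z is dropped on merged records."""
    merged = merge_intervals(
        [e.interval for e in set_a] + [e.interval for e in set_b]
    )
    win = window_bp or 1
    out = [
        EnhancerRecord(
            chrom=iv.chrom,
            start=iv.start,
            end=iv.end,
            score=iv.length // win if window_bp else 0,
            source_tissue="merged",
            z=None,
        )
        for iv in merged
    ]
    if tracks is not None and window_bp is not None:
        states = list(enhancer_states)
        tissues = list(tissue_order) if tissue_order is not None else list(tracks)
        for enh in out:
            w0, w1 = enh.start // window_bp, enh.end // window_bp
            enh.tissue_scores = np.array(
                [
                    int(np.isin(tracks[t][enh.chrom][w0:w1], states).sum())
                    for t in tissues
                ],
                dtype=np.int64,
            )
    return out


def tissue_specific_genes(
    expression: pd.DataFrame, focal_tissue: str, z_cut: float = 2.0
) -> list[str]:
    """Genes whose focal-tissue expression Z-score across tissues exceeds
    ``z_cut`` (strict inequality).  Constant rows are excluded."""
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    values = expression.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1)  # population SD, matching specificity_zscores
    focal = expression[focal_tissue].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (focal - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return [g for g, zi in zip(expression.index, z) if zi > z_cut]


def build_atlas(
    tracks: Mapping[str, Mapping[str, np.ndarray]],
    source_tissues: Sequence[str],
    peaks: Sequence[GenomicInterval],
    window_bp: int,
    fraction: float = 0.35,
    enhancer_states: Iterable[str] = DEFAULT_ENHANCER_STATES,
) -> list[EnhancerRecord]:
    """Full per-track pipeline, then union across source tissues.

    Selection (top fraction by Z) is applied independently per source track,
    as are the open-chromatin intersections; the per-track selections are
    merged into the final set.
    """
    tissue_order = list(tracks)
    selected_per_track: list[list[EnhancerRecord]] = []
    for tissue in source_tissues:
        enhancers = merge_enhancer_windows(
            tracks[tissue], window_bp, tissue, enhancer_states
        )
        score_across_tissues(enhancers, tracks, window_bp, tissue_order, enhancer_states)
        specificity_zscores(enhancers, tissue_order)
        selected = select_top_fraction(enhancers, fraction)
        selected = intersect_open_chromatin(selected, peaks)
        selected_per_track.append(selected)
    final = selected_per_track[0]
    for other in selected_per_track[1:]:
        final = merge_tissue_sets(
            final, other, tracks, window_bp, tissue_order, enhancer_states
        )
    return final
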