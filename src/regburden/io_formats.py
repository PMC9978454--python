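"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are enforced here, exactly once: BED/BEDPE files are
0-based half-open; DNM tables carry 1-based positions in their ``pos`` column
and are converted on access via :attr:`DNMRecord.pos0`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval, sort_intervals

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

__all__ = [
    "DNMRecord",
    "Interaction",
    "normalize_chrom",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_dnms",
    "write_dnms",
    "read_fasta",
    "write_fasta",
    "read_matrix",
    "write_matrix",
]


@dataclass
class DNMRecord:
    """One de novo SNV.  ``pos`` is 1-based (VCF-style)."""

    proband: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"non-ACGT allele in DNM: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


@dataclass
class Interaction:
    """An undirected pair of restriction fragments (e.g., one PCHi-C contact)."""

    fragA: GenomicInterval
    fragB: GenomicInterval
    score: float | None = None

    def __post_init__(self) -> None:
        # canonical order so that swapped input yields the same interaction
        a, b = self.fragA, self.fragB
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            self.fragA, self.fragB = b, a


def normalize_chrom(chrom: str) -> str:
    """Enforce the ``chr`` prefix; both dialects are accepted on input."""
    return chrom if chrom.startswith("chr") else "chr" + chrom


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into sorted, validated intervals.

    Column 4 (if present) is the name, column 5 the score.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                iv = GenomicInterval(
                    normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if len(fields) > 3 and fields[3] != ".":
                iv.name = fields[3]
            if len(fields) > 4 and fields[4] != ".":
                iv.score = float(fields[4])
            out.append(iv)
    return sort_intervals(out)


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in sort_intervals(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score))
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path: str | Path) -> list[Interaction]:
    out: list[Interaction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: fewer than 6 columns")
            try:
                a = GenomicInterval(
                    normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
                )
                b = GenomicInterval(
                    normalize_chrom(fields[3]), int(fields[4]), int(fields[5])
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            score = None
            if len(fields) > 7 and fields[7] not in (".", ""):
                score = float(fields[7])
            out.append(Interaction(a, b, score))
    return out


def write_bedpe(path: str | Path, interactions: Iterable[Interaction]) -> None:
    with open(path, "w") as fh:
        for x in interactions:
            cols = [
                x.fragA.chrom, str(x.fragA.start), str(x.fragA.end),
                x.fragB.chrom, str(x.fragB.start), str(x.fragB.end),
                ".",
                repr(x.score) if x.score is not None else ".",
            ]
            fh.write("\t".join(cols) + "\n")


_DNM_COLUMNS = ["proband", "chrom", "pos", "ref", "alt"]


def read_dnms(
    path: str | Path,
    genome: Mapping[str, str] | None = None,
    cohort: str = "",
) -> list[DNMRecord]:
    """Read a DNM table (TSV with header, or minimal VCF by ``.vcf`` suffix).

    Positions stay 1-based.  When a genome is supplied, records whose ref
    allele mismatches the sequence are rejected and logged.  Duplicate
    (proband, chrom, pos) rows are de-duplicated with a warning.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        records = _read_dnms_vcf(path, cohort)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _DNM_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        records = [
            DNMRecord(
                proband=row.proband,
                chrom=normalize_chrom(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                cohort=cohort,
            )
            for row in df.itertuples()
        ]
    seen: set[tuple[str, str, int]] = set()
    out: list[DNMRecord] = []
    n_dup = n_mismatch = 0
    for rec in records:
        key = (rec.proband, rec.chrom, rec.pos)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        if genome is not None:
            seq = genome.get(rec.chrom)
            if seq is None or not (0 <= rec.pos0 < len(seq)):
                n_mismatch += 1
                continue
            if seq[rec.pos0].upper() != rec.ref:
                n_mismatch += 1
                continue
        out.append(rec)
    if n_dup:
        logger.warning("%s: dropped %d duplicate DNM rows", path, n_dup)
    if n_mismatch:
        logger.warning("%s: rejected %d DNMs with ref mismatch", path, n_mismatch)
    return out


def _read_dnms_vcf(path: Path, cohort: str) -> list[DNMRecord]:
    """Minimal VCF fallback: SNV records only, INFO ignored."""
    out: list[DNMRecord] = []
    sample = "."
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) > 9:
                    sample = fields[9]
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, pos, _, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
                continue  # SNVs only
            out.append(
                DNMRecord(sample, normalize_chrom(chrom), int(pos), ref, alt, cohort)
            )
    return out


def write_dnms(path: str | Path, dnms: Iterable[DNMRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DNM_COLUMNS) + "\n")
        for d in dnms:
            fh.write(f"{d.proband}\t{d.chrom}\t{d.pos}\t{d.ref}\t{d.alt}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA into a chrom -> uppercase sequence mapping."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {normalize_chrom(name): str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | Path, genome: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a signal/count matrix TSV: rows = elements, columns = tissues."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t")
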