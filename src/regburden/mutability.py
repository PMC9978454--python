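"""Trinucleotide-context mutation model.

A :class:`MutabilityTable` maps (3-mer context, alternate allele) to a
per-generation mutation probability.  Contexts are strand-collapsed: a
context and its reverse complement share a rate, and tables are keyed by the
32 pyrimidine-centered contexts x 3 alternate alleles.

Summing per-site totals over a region gives its null mutation rate;
summing region rates over a merged region set gives the set's rate, from
which expected cohort DNM counts and Poisson upper-tail p-values follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# byte -> base code (A=0, C=1, G=2, T=3, anything else 4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

__all__ = [
    "MutabilityTable",
    "RegionSetMutability",
    "PoissonTestResult",
    "revcomp",
    "site_mutability",
    "site_rate_array",
    "region_mutability",
    "set_mutability",
    "expected_dnms",
    "poisson_upper_tail",
]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def _collapse(context: str, alt: str) -> tuple[str, str]:
    """Map to the pyrimidine-centered (middle base C or T) representative."""
    if context[1] in "CT":
        return context, alt
    return revcomp(context), _COMPLEMENT[alt]


@dataclass
class RegionSetMutability:
    """Summed mutation probability of a merged region set."""

    set_name: str
    total_rate: float
    n_regions: int


@dataclass
class PoissonTestResult:
    observed: int
    expected: float
    p: float


class MutabilityTable:
    """Per-(trinucleotide, alt) per-generation mutation probabilities."""

    def __init__(self, entries: Mapping[tuple[str, str], float], provenance: str = ""):
        self.entries: dict[tuple[str, str], float] = {}
        for (ctx, alt), rate in entries.items():
            ctx = ctx.upper()
            alt = alt.upper()
            if len(ctx) != 3 or any(b not in BASES for b in ctx) or alt not in BASES:
                raise ValueError(f"bad table entry ({ctx}, {alt})")
            if ctx[1] == alt:
                raise ValueError(f"context middle base equals alt: ({ctx}, {alt})")
            if rate <= 0:
                raise ValueError(f"non-positive rate for ({ctx}, {alt})")
            key = _collapse(ctx, alt)
            prev = self.entries.get(key)
            if prev is not None and not np.isclose(prev, rate):
                raise ValueError(f"conflicting rates for strand pair of {key}")
            self.entries[key] = float(rate)
        self.provenance = provenance
        self._validate()
        self._build_arrays()

    def _validate(self) -> None:
        expected = {
            (a + m + b, alt)
            for m in "CT"
            for a in BASES
            for b in BASES
            for alt in BASES
            if alt != m
        }
        missing = expected - set(self.entries)
        if missing:
            raise ValueError(f"table incomplete: {len(missing)} missing entries")

    def _build_arrays(self) -> None:
        # per 64 raw contexts: total rate and per-alt rates in the fixed
        # order of the 3 non-ref bases (sorted), for vectorized sampling
        self.context_total = np.zeros(64)
        self.alt_rates = np.zeros((64, 3))
        self.alt_codes = np.zeros((64, 3), dtype=np.uint8)
        for i0 in range(4):
            for i1 in range(4):
                for i2 in range(4):
                    idx = i0 * 16 + i1 * 4 + i2
                    ctx = BASES[i0] + BASES[i1] + BASES[i2]
                    alts = [b for b in BASES if b != ctx[1]]
                    for j, alt in enumerate(alts):
                        r = self.rate(ctx, alt)
                        self.alt_rates[idx, j] = r
                        self.alt_codes[idx, j] = BASES.index(alt)
                    self.context_total[idx] = self.alt_rates[idx].sum()

    def rate(self, context: str, alt: str) -> float:
        return self.entries[_collapse(context.upper(), alt.upper())]

    def total(self, context: str) -> float:
        mid = context[1].upper()
        return sum(self.rate(context, alt) for alt in BASES if alt != mid)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutabilityTable":
        entries: dict[tuple[str, str], float] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["context", "alt", "rate"]:
                raise ValueError(f"{path}: expected header context/alt/rate")
            for line in fh:
                if not line.strip():
                    continue
                ctx, alt, rate = line.rstrip("\n").split("\t")[:3]
                entries[(ctx, alt)] = float(rate)
        return cls(entries, provenance=str(path))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("context\talt\trate\n")
            for (ctx, alt), rate in sorted(self.entries.items()):
                fh.write(f"{ctx}\t{alt}\t{rate:.6e}\n")

    @classmethod
    def default(cls) -> "MutabilityTable":
        """Packaged default table (plausible human-scale magnitudes)."""
        ref = resources.files("regburden.data").joinpath("default_rates.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def site_mutability(
    genome: Mapping[str, str],
    chrom: str,
    pos0: int,
    table: MutabilityTable,
) -> tuple[dict[str, float], float]:
    """Per-alt rates and total at a single 0-based position.

    Raises ``ValueError`` for terminal bases or contexts containing N; callers
    iterating over regions should use :func:`region_mutability`, which skips
    and logs such sites.
    """
    seq = genome[chrom]
    if pos0 < 1 or pos0 >= len(seq) - 1:
        raise ValueError(f"{chrom}:{pos0}: no flanking context")
    ctx = seq[pos0 - 1 : pos0 + 2].upper()
    if any(b not in BASES for b in ctx):
        raise ValueError(f"{chrom}:{pos0}: context {ctx} contains non-ACGT base")
    rates = {alt: table.rate(ctx, alt) for alt in BASES if alt != ctx[1]}
    return rates, sum(rates.values())


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def context_codes(seq: str) -> np.ndarray:
    """Per-site 3-mer context index in [0, 64), or -1 where undefined."""
    codes = _encode(seq)
    n = len(codes)
    idx = np.full(n, -1, dtype=np.int64)
    if n < 3:
        return idx
    c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4)
    inner = c0.astype(np.int64) * 16 + c1 * 4 + c2
    idx[1:-1][valid] = inner[valid]
    return idx


def site_rate_array(seq: str, table: MutabilityTable) -> np.ndarray:
    """Vector of per-site total mutation rates (0 at ends and N contexts)."""
    idx = context_codes(seq)
    out = np.zeros(len(seq))
    valid = idx >= 0
    out[valid] = table.context_total[idx[valid]]
    return out


def region_mutability(
    genome: Mapping[str, str],
    interval: GenomicInterval | tuple[str, int, int],
    table: MutabilityTable,
) -> float:
    """Sum of per-site total rates over all valid positions in the interval.

    Accepts a ``(chrom, start, end)`` tuple as well; an empty span yields 0.
    """
    if isinstance(interval, tuple):
        chrom, start, end = interval
        if start == end:
            return 0.0
        interval = GenomicInterval(chrom, start, end)
    seq = genome[interval.chrom]
    if interval.end > len(seq):
        raise ValueError(f"{interval.id} extends past chromosome end")
    lo = max(interval.start - 1, 0)
    hi = min(interval.end + 1, len(seq))
    rates = site_rate_array(seq[lo:hi], table)
    a = interval.start - lo
    b = a + interval.length
    sub = rates[a:b]
    n_skipped = int((sub == 0).sum())
    if n_skipped:
        logger.info("%s: %d sites skipped (N or chromosome end)", interval.id, n_skipped)
    return float(sub.sum())


def set_mutability(
    genome: Mapping[str, str],
    regions: Iterable[GenomicInterval],
    table: MutabilityTable,
    set_name: str = "",
) -> RegionSetMutability:
    """Summed mutation probability over a set of non-overlapping regions.

    Overlapping input is an error: callers must merge first so that shared
    bases are not double-counted.
    """
    regions = list(regions)
    if len(merge_intervals(regions, merge_abutting=False)) != len(regions):
        raise ValueError(f"region set {set_name!r} contains overlapping intervals; merge first")
    total = sum(region_mutability(genome, iv, table) for iv in regions)
    return RegionSetMutability(set_name=set_name, total_rate=total, n_regions=len(regions))


def expected_dnms(set_rate: float, n_probands: int, scale: float = 2.0) -> float:
    """Expected cohort DNM count: lambda = set_rate * n_probands * scale.

    The default scale of 2 counts two haploid genomes per proband; it is
    surfaced as a parameter because different cohorts calibrate differently.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return set_rate * n_probands * scale


def poisson_upper_tail(observed: int, lam: float) -> float:
    """Upper-tail probability Pr[X >= observed] for X ~ Poisson(lam)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))
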