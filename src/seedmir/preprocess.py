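"""Raw FASTQ -> collapsed, length-filtered unique small-RNA tags.

The cleaning cascade mirrors the standard small-RNA workflow: drop
low-quality reads, trim adapters, drop N-containing reads, keep 18-25 nt
inserts, then collapse identical sequences into tags with per-library
counts. Summary tables report per-length totals and the <18 / in-range / >25
partition with half-up rounded percentages (1 decimal for length tallies,
2 decimals for class tallies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import normalize
from .io import ReadRecord


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero, the convention of printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total, half-up rounded; 0 when total is 0."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, decimals)


@dataclass
class SmallRNATag:
    """A distinct 18-25 nt sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    tag_class: str = "unassigned"
    families: list[str] = field(default_factory=list)
    matched_ids: list[str] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class LengthSummary:
    """Partition of a library's reads by insert length (printed-table style)."""

    total: int
    below: int
    in_range: int
    above: int
    lo: int = 18
    hi: int = 25

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("Total reads", self.total, percent(self.total, self.total)),
            (f"{self.lo}–{self.hi} nt", self.in_range,
             percent(self.in_range, self.total)),
            (f"<{self.lo} nt", self.below, percent(self.below, self.total)),
            (f">{self.hi} nt", self.above, percent(self.above, self.total)),
        ]
        return pd.DataFrame(rows, columns=["reads", "count", "percent"])


def quality_filter(reads: Iterable[ReadRecord], qmin: int = 13,
                   rule: str = "mean") -> list[ReadRecord]:
    """Keep reads whose mean (or, with rule="min", minimum) Phred >= qmin."""
    if qmin < 0:
        raise ValueError("qmin must be >= 0")
    if rule == "mean":
        return [r for r in reads if r.mean_quality >= qmin]
    if rule == "min":
        return [r for r in reads if r.qualities and min(r.qualities) >= qmin]
    raise ValueError(f"unknown quality rule {rule!r}")


def _trim3(seq: str, adapter: str, min_overlap: int) -> int:
    """Index at which the 3' adapter starts, or len(seq) if absent.

    The leftmost exact occurrence of an adapter prefix (>= min_overlap)
    extending to the read end, or of the full adapter anywhere, wins.
    """
    full = seq.find(adapter)
    if full != -1:
        return full
    n = len(seq)
    best = n
    for k in range(len(adapter), min_overlap - 1, -1):
        idx = n - k
        if idx >= 0 and seq.startswith(adapter[:k], idx):
            best = min(best, idx)
    return best


def trim_adapters(reads: Iterable[ReadRecord], adapter3: str,
                  adapter5: str | None = None,
                  min_overlap: int = 8) -> list[ReadRecord]:
    """Remove 3' (and optionally 5') adapter sequence, exact matching only."""
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    adapter3 = normalize(adapter3)
    adapter5 = normalize(adapter5) if adapter5 else None
    out = []
    for r in reads:
        seq = normalize(r.sequence)
        qual = list(r.qualities)
        cut = _trim3(seq, adapter3, min_overlap)
        seq, qual = seq[:cut], qual[:cut]
        if adapter5:
            # symmetric rule: longest adapter suffix matching the read start
            start = 0
            if (idx := seq.find(adapter5)) != -1 and idx == 0:
                start = len(adapter5)
            else:
                for k in range(len(adapter5) - 1, min_overlap - 1, -1):
                    if seq.startswith(adapter5[-k:]):
                        start = k
                        break
            seq, qual = seq[start:], qual[start:]
        out.append(ReadRecord(id=r.id, sequence=seq, qualities=qual))
    return out


def drop_ambiguous(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Remove reads containing N (any case)."""
    return [r for r in reads if "N" not in r.sequence.upper()]


def length_filter(reads: Sequence[ReadRecord], lo: int = 18, hi: int = 25,
                  ) -> tuple[list[ReadRecord], LengthSummary]:
    """Keep lo <= length <= hi; tally the <lo / in-range / >hi partition."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    kept, below, above = [], 0, 0
    for r in reads:
        n = len(r.sequence)
        if n < lo:
            below += 1
        elif n > hi:
            above += 1
        else:
            kept.append(r)
    return kept, LengthSummary(total=len(reads), below=below,
                               in_range=len(kept), above=above, lo=lo, hi=hi)


def collapse_tags(libraries: Mapping[str, Sequence[ReadRecord]],
                  ) -> list[SmallRNATag]:
    """One tag per distinct sequence with per-library counts (U -> T)."""
    tags: dict[str, SmallRNATag] = {}
    for lib, reads in libraries.items():
        for r in reads:
            seq = normalize(r.sequence)
            tag = tags.get(seq)
            if tag is None:
                tag = tags[seq] = SmallRNATag(sequence=seq)
            tag.counts[lib] = tag.counts.get(lib, 0) + 1
    return sorted(tags.values(), key=lambda t: (-t.total_count, t.sequence))


def length_distribution(tags: Iterable[SmallRNATag], lo: int = 18,
                        hi: int = 25) -> pd.DataFrame:
    """Per-length total reads and distinct tag counts (Figure-1-style data)."""
    idx = range(lo, hi + 1)
    totals = {n: 0 for n in idx}
    distinct = {n: 0 for n in idx}
    for tag in tags:
        n = len(tag.sequence)
        if lo <= n <= hi:
            totals[n] += tag.total_count
            distinct[n] += 1
    return pd.DataFrame({"length": list(idx),
                         "total_reads": [totals[n] for n in idx],
                         "distinct_tags": [distinct[n] for n in idx]})


@dataclass
class CascadeResult:
    """Cleaned reads plus the per-stage removal ledger of one library."""

    reads: list[ReadRecord]
    n_input: int
    n_low_quality: int
    n_ambiguous: int
    summary: LengthSummary


def clean_library(reads: Sequence[ReadRecord], adapter3: str,
                  adapter5: str | None = None, qmin: int = 13,
                  lo: int = 18, hi: int = 25, min_overlap: int = 8,
                  quality_rule: str = "mean") -> CascadeResult:
    """Full cascade: quality -> adapter trim -> drop N -> length filter."""
    n_input = len(reads)
    hq = quality_filter(reads, qmin, rule=quality_rule)
    trimmed = trim_adapters(hq, adapter3, adapter5, min_overlap)
    no_n = drop_ambiguous(trimmed)
    kept, summary = length_filter(no_n, lo, hi)
    return CascadeResult(reads=kept, n_input=n_input,
                         n_low_quality=n_input - len(hq),
                         n_ambiguous=len(trimmed) - len(no_n),
                         summary=summary)


def write_tags_fasta(path, tags: Sequence[SmallRNATag],
                     libraries: Sequence[str]) -> None:
    """Collapsed tags as FASTA: ``tag{serial}|{lib}:{count}|...``."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            counts = "|".join(f"{lib}:{tag.counts.get(lib, 0)}"
                              for lib in libraries)
            fh.write(f">tag{i}|{counts}\n{tag.sequence}\n")
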