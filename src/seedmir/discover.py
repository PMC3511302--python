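"""Pre-miRNA discovery on transcript contigs.

Tags are mapped exactly onto contigs; contigs carrying one or two tight
blocks of same-strand reads totalling at least ``min_reads`` are folded and
validated as hairpins (MFEI magnitude, mature-arm pairing to the opposite
arm, terminal-loop exclusion). Validated candidates yield per-arm mature /
star / isomiR calls and are classed as known-in-Bna, known-in-plants or
novel; novel families additionally require the mature in every library or a
detectable star.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp, to_rna
from .folding import fold, pair_table, terminal_loop
from .preprocess import SmallRNATag


@dataclass
class ContigHit:
    """Exact full-length occurrence of a tag on a contig (+ strand coords)."""

    tag: SmallRNATag
    contig_id: str
    start: int
    end: int
    strand: str


@dataclass
class AnchorBlock:
    """A stack of chain-overlapping hits: the footprint of one product."""

    contig_id: str
    start: int
    end: int
    strand: str
    hits: list[ContigHit] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(h.tag.total_count for h in self.hits)

    @property
    def distinct_tags(self) -> int:
        return len({h.tag.sequence for h in self.hits})


@dataclass
class BlockResult:
    contig_id: str
    strand: str
    blocks: list[AnchorBlock]
    passed: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(b.total_reads for b in self.blocks)


@dataclass
class MatureLocus:
    """Dominant product of one hairpin arm with its star and isomiRs."""

    precursor_id: str
    arm: str  # "5p" | "3p"
    sequence: str
    interval: tuple[int, int]  # window coordinates
    counts: dict[str, int]
    star_sequence: str | None = None
    isomirs: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def first_nucleotide(self) -> str:
        return to_rna(self.sequence[0])


@dataclass
class PrecursorCandidate:
    id: str
    contig_id: str
    interval: tuple[int, int]  # 0-based half-open, + strand of contig
    strand: str
    sequence: str  # oriented along the anchored strand
    dot_bracket: str = ""
    mfe: float = 0.0
    amfe: float = 0.0
    mfei: float = 0.0
    gc: float = 0.0
    blocks: list[AnchorBlock] = field(default_factory=list)
    loci: list[MatureLocus] = field(default_factory=list)
    category: str = "novel"
    status: str = "full_length"
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)
    mfe_band_warning: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def dominant_locus(self) -> MatureLocus | None:
        if not self.loci:
            return None
        return max(self.loci, key=lambda l: (l.total_count, l.sequence))

    def to_contig_coords(self, window_interval: tuple[int, int]) -> tuple[int, int]:
        """Map a window-coordinate interval back onto the + strand contig."""
        s, e = window_interval
        w0, w1 = self.interval
        if self.strand == "+":
            return (w0 + s, w0 + e)
        return (w1 - e, w1 - s)


# ---------------------------------------------------------------------------
# mapping and anchoring

def map_tags(tags: Iterable[SmallRNATag], contigs: Mapping[str, str],
             ) -> list[ContigHit]:
    """All exact full-length occurrences of tags on both contig strands."""
    by_seq = {t.sequence: t for t in tags}
    lengths = sorted({len(s) for s in by_seq})
    hits: list[ContigHit] = []
    for contig_id, contig in contigs.items():
        rc = revcomp(contig)
        n = len(contig)
        for strand, seq in (("+", contig), ("-", rc)):
            for k in lengths:
                for i in range(len(seq) - k + 1):
                    tag = by_seq.get(seq[i:i + k])
                    if tag is None:
                        continue
                    if strand == "+":
                        start, end = i, i + k
                    else:
                        start, end = n - (i + k), n - i
                    hits.append(ContigHit(tag, contig_id, start, end, strand))
    return hits


def _chain(hits: list[ContigHit], chain_gap: int) -> list[AnchorBlock]:
    blocks: list[AnchorBlock] = []
    for hit in sorted(hits, key=lambda h: (h.start, h.end)):
        if blocks:
            b = blocks[-1]
            last_start = b.hits[-1].start
            if hit.start < b.end or hit.start - last_start <= chain_gap:
                b.end = max(b.end, hit.end)
                b.hits.append(hit)
                continue
        blocks.append(AnchorBlock(hit.contig_id, hit.start, hit.end,
                                  hit.strand, [hit]))
    return blocks


def find_blocks(hits: Sequence[ContigHit], min_reads: int = 11,
                max_blocks: int = 2, chain_gap: int = 3,
                ) -> dict[str, BlockResult]:
    """Chain hits into anchor blocks per contig and apply the gate:
    one or two same-strand blocks carrying >= min_reads summed reads."""
    per_contig: dict[str, list[ContigHit]] = {}
    for h in hits:
        per_contig.setdefault(h.contig_id, []).append(h)
    results: dict[str, BlockResult] = {}
    for contig_id, contig_hits in per_contig.items():
        strands = {h.strand for h in contig_hits}
        if len(strands) > 1:
            results[contig_id] = BlockResult(
                contig_id, ".", [], False, ["hits on both strands"])
            continue
        strand = strands.pop()
        blocks = _chain(contig_hits, chain_gap)
        reasons = []
        if not 1 <= len(blocks) <= max_blocks:
            reasons.append(f"{len(blocks)} blocks (max {max_blocks})")
        total = sum(b.total_reads for b in blocks)
        if total < min_reads:
            reasons.append(f"{total} reads (min {min_reads})")
        results[contig_id] = BlockResult(contig_id, strand, blocks,
                                         not reasons, reasons)
    return results


def extract_window(contig: str, blocks: Sequence[AnchorBlock],
                   flank: int = 20, max_window: int = 300,
                   ) -> tuple[str, tuple[int, int]]:
    """Candidate window around the anchor blocks, clipped to the contig.

    Contigs no longer than ``max_window`` are used whole. Minus-strand
    blocks yield the reverse-complemented sequence; the interval stays on
    the + strand.
    """
    if not blocks:
        raise ValueError("no blocks to extract a window around")
    if len(contig) <= max_window:
        start, end = 0, len(contig)
    else:
        start = max(0, min(b.start for b in blocks) - flank)
        end = min(len(contig), max(b.end for b in blocks) + flank)
    seq = contig[start:end]
    if blocks[0].strand == "-":
        seq = revcomp(seq)
    return seq, (start, end)


# ---------------------------------------------------------------------------
# hairpin metrics and validation

def hairpin_metrics(mfe: float, sequence: str) -> tuple[float, float, float]:
    """(AMFE, MFEI, GC%): AMFE = MFE/L*100, MFEI = AMFE/GC."""
    length = len(sequence)
    if length <= 0:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = 100.0 * (s.count("G") + s.count("C")) / length
    amfe = mfe / length * 100.0
    if gc == 0.0:
        raise ValueError("GC content is zero; MFEI undefined")
    return amfe, amfe / gc, gc


def validate_hairpin(candidate: PrecursorCandidate,
                     mature_interval: tuple[int, int],
                     min_mfei: float = 0.85,
                     min_paired_frac: float = 0.75,
                     max_loop_overlap: int = 3) -> tuple[bool, list[str]]:
    """Check that the dominant product sits on one hairpin arm.

    Pass iff |MFEI| >= min_mfei, >= min_paired_frac of the mature bases pair
    with bases outside the mature footprint (the opposite arm), and at most
    max_loop_overlap mature bases fall inside the terminal loop.
    """
    reasons = []
    if abs(candidate.mfei) < min_mfei:
        reasons.append(f"|MFEI| {abs(candidate.mfei):.2f} < {min_mfei}")
    s, e = mature_interval
    pt = pair_table(candidate.dot_bracket)
    paired_opposite = sum(1 for i in range(s, e)
                          if pt[i] != -1 and not s <= pt[i] < e)
    if paired_opposite < min_paired_frac * (e - s):
        reasons.append(
            f"{paired_opposite}/{e - s} mature bases paired to opposite arm")
    loop = terminal_loop(candidate.dot_bracket)
    if loop is None:
        reasons.append("no hairpin loop")
    else:
        overlap = max(0, min(e, loop[1]) - max(s, loop[0]))
        if overlap > max_loop_overlap:
            reasons.append(f"{overlap} mature bases in terminal loop")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# mature / star / isomiR calling

def _window_hits(candidate: PrecursorCandidate, hits: Sequence[ContigHit],
                 ) -> list[tuple[SmallRNATag, int, int]]:
    """Hits of the candidate's strand mapped into window coordinates."""
    w0, w1 = candidate.interval
    out = []
    for h in hits:
        if h.strand != candidate.strand or not (w0 <= h.start and h.end <= w1):
            continue
        if candidate.strand == "+":
            out.append((h.tag, h.start - w0, h.end - w0))
        else:
            out.append((h.tag, w1 - h.end, w1 - h.start))
    return out


def call_mature_star_isomirs(candidate: PrecursorCandidate,
                             hits: Sequence[ContigHit],
                             isomir_window: int = 3) -> list[MatureLocus]:
    """Per-arm dominant tag, isomiR set and the opposite-arm star.

    Arms are split at the terminal loop; a tag belongs to the arm holding
    its midpoint. Ties on counts break to the lexicographically smallest
    sequence. isomiRs are same-arm tags within ``isomir_window`` nt of the
    dominant at both ends.
    """
    loop = terminal_loop(candidate.dot_bracket)
    if loop is None:
        return []
    whits = _window_hits(candidate, hits)
    arms: dict[str, list[tuple[SmallRNATag, int, int]]] = {"5p": [], "3p": []}
    for tag, s, e in whits:
        mid = (s + e) / 2
        arms["5p" if mid < (loop[0] + loop[1]) / 2 else "3p"].append((tag, s, e))
    loci: dict[str, MatureLocus] = {}
    for arm, members in arms.items():
        if not members:
            continue
        tag, s, e = min(members,
                        key=lambda m: (-m[0].total_count, m[0].sequence))
        isomirs = []
        for other, os_, oe in members:
            if other.sequence == tag.sequence:
                continue
            d5, d3 = os_ - s, oe - e
            if abs(d5) <= isomir_window and abs(d3) <= isomir_window:
                isomirs.append((other.sequence, d5, d3))
        loci[arm] = MatureLocus(
            precursor_id=candidate.id, arm=arm, sequence=tag.sequence,
            interval=(s, e), counts=dict(tag.counts),
            isomirs=sorted(isomirs))
    if "5p" in loci and "3p" in loci:
        loci["5p"].star_sequence = loci["3p"].sequence
        loci["3p"].star_sequence = loci["5p"].sequence
    return [loci[a] for a in ("5p", "3p") if a in loci]


def classify_precursor(candidate: PrecursorCandidate,
                       bna_matures: Mapping[str, str],
                       plant_matures: Mapping[str, str]) -> str:
    """known_bna / known_plant / novel by exact identity of the dominant
    mature to a packaged reference mature (zero mismatches)."""
    dom = candidate.dominant_locus
    if dom is None:
        return "novel"
    seq = dom.sequence
    norm = lambda refs: {v.upper().replace("U", "T") for v in refs.values()}
    if seq in norm(bna_matures):
        return "known_bna"
    if seq in norm(plant_matures):
        return "known_plant"
    return "novel"


def novel_family_filter(mature_counts: Mapping[str, int],
                        star_present: bool) -> bool:
    """Novel families need the mature in every library, or a star in any."""
    in_all = bool(mature_counts) and all(c > 0 for c in mature_counts.values())
    return in_all or star_present


def first_nucleotide_profile(loci: Iterable[MatureLocus]) -> dict[str, int]:
    """Counts of A/C/G/U at position 1 of the dominant matures."""
    profile = {"A": 0, "C": 0, "G": 0, "U": 0}
    for locus in loci:
        nt = locus.first_nucleotide
        if nt in profile:
            profile[nt] += 1
    return profile


# ---------------------------------------------------------------------------
# end-to-end discovery

@dataclass
class DiscoveryParams:
    min_reads: int = 11
    max_blocks: int = 2
    chain_gap: int = 3
    flank: int = 20
    max_window: int = 300
    min_mfei: float = 0.85
    min_paired_frac: float = 0.75
    max_loop_overlap: int = 3
    isomir_window: int = 3
    mfe_band: tuple[float, float] = (40.0, 100.0)


def discover_precursors(tags: Iterable[SmallRNATag],
                        contigs: Mapping[str, str],
                        bna_matures: Mapping[str, str],
                        plant_matures: Mapping[str, str],
                        params: DiscoveryParams | None = None,
                        libraries: Sequence[str] | None = None,
                        ) -> list[PrecursorCandidate]:
    """Full discovery pipeline; returns all candidates with ``accepted`` set.

    Tags classed as an ncRNA contaminant are excluded up front; miRNA-class
    and unassigned tags go into mapping.
    """
    params = params or DiscoveryParams()
    eligible = [t for t in tags if t.tag_class in ("miRNA", "unassigned")]
    hits = map_tags(eligible, contigs)
    hits_by_contig: dict[str, list[ContigHit]] = {}
    for h in hits:
        hits_by_contig.setdefault(h.contig_id, []).append(h)
    block_results = find_blocks(hits, params.min_reads, params.max_blocks,
                                params.chain_gap)
    candidates: list[PrecursorCandidate] = []
    serial = 0
    for contig_id in sorted(block_results):
        result = block_results[contig_id]
        if not result.passed:
            continue
        serial += 1
        seq, interval = extract_window(contigs[contig_id], result.blocks,
                                       params.flank, params.max_window)
        cand = PrecursorCandidate(
            id=f"cand{serial:03d}", contig_id=contig_id, interval=interval,
            strand=result.strand, sequence=seq, blocks=result.blocks)
        cand.dot_bracket, cand.mfe = fold(seq)
        cand.amfe, cand.mfei, cand.gc = hairpin_metrics(cand.mfe, seq)
        cand.mfe_band_warning = not (
            params.mfe_band[0] <= abs(cand.mfe) <= params.mfe_band[1])
        cand.loci = call_mature_star_isomirs(cand, hits_by_contig[contig_id],
                                             params.isomir_window)
        dom = cand.dominant_locus
        if dom is None:
            cand.reasons.append("no mature locus on an arm")
            candidates.append(cand)
            continue
        ok, reasons = validate_hairpin(cand, dom.interval, params.min_mfei,
                                       params.min_paired_frac,
                                       params.max_loop_overlap)
        cand.reasons.extend(reasons)
        cand.category = classify_precursor(cand, bna_matures, plant_matures)
        if ok:
            cand.status = "full_length"
            cand.accepted = True
            if cand.category == "novel":
                libs = libraries or sorted(
                    {lib for t in eligible for lib in t.counts})
                counts = {lib: dom.counts.get(lib, 0) for lib in libs}
                if not novel_family_filter(counts,
                                           dom.star_sequence is not None):
                    cand.accepted = False
                    cand.reasons.append(
                        "novel mature absent from a library and no star")
        elif cand.category == "known_bna":
            # partials are kept only when the mature is a known Bna sequence
            cand.status = "partial"
            cand.accepted = True
        candidates.append(cand)
    return candidates
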