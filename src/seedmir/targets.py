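"""miRNA target-site scanning with a complementarity expectation score.

Each candidate site on a transcript contig is aligned antiparallel to the
miRNA and scored with the classical plant-target penalty scheme: 0 for a
Watson-Crick pair, 0.5 for G:U wobble, 1 for a mismatch and 2 for a
gap/bulge, all doubled at miRNA positions 2-13 (the core region, counted
from the 5' end). Lower E means better complementarity; sites with
E <= e_max (default 4) are reported. At most one gap per duplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from ._seq import normalize, revcomp, check_nucleotides

#: complement including G:U wobble pairing on the opposite strand (DNA rep.)
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

CORE = (2, 13)  # 1-based inclusive miRNA positions with doubled penalties


@dataclass
class PenaltyScheme:
    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0
    core_multiplier: float = 2.0


DEFAULT_SCHEME = PenaltyScheme()


@dataclass
class TargetHit:
    mirna_id: str
    mirna_seq: str
    contig_id: str
    start: int  # 0-based half-open on the + strand of the contig
    end: int
    strand: str
    expectation: float
    mismatches: int
    gu_pairs: int
    gaps: int
    alignment: tuple[str, str, str] = ("", "", "")  # miRNA 3'->5', pairs, target 5'->3'


def _core_mult(pos1: int, scheme: PenaltyScheme) -> float:
    return scheme.core_multiplier if CORE[0] <= pos1 <= CORE[1] else 1.0


def _align(mirna: str, rsite: str, skip_site: int | None,
           skip_mirna: int | None, scheme: PenaltyScheme,
           e_max: float = float("inf")):
    """Score miRNA (5'->3') against a site read 3'->5' (``rsite``).

    ``skip_site`` bulges one site base out (gap in the miRNA row);
    ``skip_mirna`` leaves one miRNA base unpaired (gap in the target row).
    Returns (E, mismatches, gu, gaps, mirna_row, pair_row, site_row) or None
    once E exceeds e_max.
    """
    e, mm, gu, gaps = 0.0, 0, 0, 0
    m_row, p_row, s_row = [], [], []
    i = j = 0
    m, n = len(mirna), len(rsite)
    while i < m or j < n:
        if skip_site is not None and j == skip_site:
            pos1 = min(max(i, 1), m)  # gap sits between miRNA bases i and i+1
            e += scheme.gap * _core_mult(pos1, scheme)
            gaps += 1
            m_row.append("-")
            p_row.append(" ")
            s_row.append(rsite[j])
            j += 1
        elif skip_mirna is not None and i == skip_mirna:
            e += scheme.gap * _core_mult(i + 1, scheme)
            gaps += 1
            m_row.append(mirna[i])
            p_row.append(" ")
            s_row.append("-")
            i += 1
        elif i < m and j < n:
            pair = (mirna[i], rsite[j])
            mult = _core_mult(i + 1, scheme)
            if pair in _WC:
                p_row.append("|")
            elif pair in _WOBBLE:
                e += scheme.wobble * mult
                gu += 1
                p_row.append("o")
            else:
                e += scheme.mismatch * mult
                mm += 1
                p_row.append(" ")
            m_row.append(mirna[i])
            s_row.append(rsite[j])
            i += 1
            j += 1
        else:  # ragged end without a declared skip: treat as gap
            return None
        if e > e_max:
            return None
    return e, mm, gu, gaps, "".join(m_row), "".join(p_row), "".join(s_row)


def score_duplex(mirna: str, site: str,
                 scheme: PenaltyScheme = DEFAULT_SCHEME,
                 e_max: float = float("inf")):
    """Best-scoring duplex of a miRNA against one candidate site (5'->3').

    The site may be one base shorter or longer than the miRNA (a single
    bulge). Returns a dict with E and the alignment triple, or None when
    every alignment exceeds e_max.
    """
    mirna = normalize(mirna)
    site = normalize(site)
    check_nucleotides(mirna, allow_n=False)
    check_nucleotides(site, allow_n=False)
    m, n = len(mirna), len(site)
    rsite = site[::-1]
    results = []
    if n == m:
        results.append(_align(mirna, rsite, None, None, scheme, e_max))
    elif n == m + 1:
        for b in range(n):
            results.append(_align(mirna, rsite, b, None, scheme, e_max))
    elif n == m - 1:
        for g in range(m):
            results.append(_align(mirna, rsite, None, g, scheme, e_max))
    else:
        raise ValueError("site length must be within 1 nt of the miRNA")
    results = [r for r in results if r is not None]
    if not results:
        return None
    e, mm, gu, gaps, m_row, p_row, s_row = min(results, key=lambda r: r[0])
    return {
        "expectation": e, "mismatches": mm, "gu_pairs": gu, "gaps": gaps,
        # rows were built miRNA 5'->3' / site 3'->5'; reverse all three so
        # the miRNA prints 3'->5' over the target printed 5'->3'
        "alignment": (m_row[::-1], p_row[::-1], s_row[::-1]),
    }


def scan_targets(mirnas: Mapping[str, str], contigs: Mapping[str, str],
                 e_max: float = 4.0,
                 scheme: PenaltyScheme = DEFAULT_SCHEME) -> list[TargetHit]:
    """Score every candidate window (ungapped and single-gap) on both
    strands of every contig; emit hits with E <= e_max sorted by
    (E, contig, start)."""
    hits: list[TargetHit] = []
    for contig_id, contig in contigs.items():
        contig = normalize(contig)
        L = len(contig)
        for strand in "+-":
            seq = contig if strand == "+" else revcomp(contig)
            for mirna_id, mirna in mirnas.items():
                mseq = normalize(mirna)
                m = len(mseq)
                for wlen in (m - 1, m, m + 1):
                    if wlen < 1:
                        continue
                    for start in range(0, L - wlen + 1):
                        site = seq[start:start + wlen]
                        res = score_duplex(mseq, site, scheme, e_max)
                        if res is None:
                            continue
                        if strand == "+":
                            s, e = start, start + wlen
                        else:
                            s, e = L - (start + wlen), L - start
                        hits.append(TargetHit(
                            mirna_id=mirna_id, mirna_seq=mseq,
                            contig_id=contig_id, start=s, end=e,
                            strand=strand, expectation=res["expectation"],
                            mismatches=res["mismatches"],
                            gu_pairs=res["gu_pairs"], gaps=res["gaps"],
                            alignment=res["alignment"]))
    hits.sort(key=lambda h: (h.expectation, h.contig_id, h.start, h.end,
                             h.strand, h.mirna_id))
    return hits


def hits_per_mirna(hits: list[TargetHit]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.mirna_id] = counts.get(h.mirna_id, 0) + 1
    return counts
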