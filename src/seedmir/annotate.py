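"""Tag classification against ncRNA references and conserved-miRNA matching.

Non-miRNA classes (rRNA, tRNA, snRNA, snoRNA, mtRNA, cpRNA) are assigned by
zero-mismatch full-length substring containment in a class reference, on
either strand. Conserved miRNAs require exact full-length identity to a
known plant mature miRNA. Class precedence when a tag hits several
references: miRNA > rRNA > tRNA > snRNA > snoRNA > mtRNA > cpRNA, so a
conserved miRNA is never swallowed by the contaminant exclusion set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import normalize, revcomp
from .preprocess import SmallRNATag, percent

NCRNA_PRECEDENCE = ("rRNA", "tRNA", "snRNA", "snoRNA", "mtRNA", "cpRNA")
CLASS_ORDER = ("miRNA",) + NCRNA_PRECEDENCE + ("other sRNA",)

#: families grouped due to shared evolutionary origin
FAMILY_MERGES = {
    "MIR156": "MIR156/157", "MIR157": "MIR156/157",
    "MIR165": "MIR165/166", "MIR166": "MIR165/166",
    "MIR170": "MIR170/171", "MIR171": "MIR170/171",
}

_FAMILY_RE = re.compile(r"(?:^[a-z]{2,5}-)?miR-?(\d+)", re.IGNORECASE)


def family_from_id(ref_id: str) -> str:
    """``ath-miR156a-5p`` -> ``MIR156`` (species prefix, letter suffix and
    arm label stripped)."""
    m = _FAMILY_RE.search(ref_id)
    if not m:
        return ref_id.upper()
    return f"MIR{m.group(1)}"


def merged_family(family: str) -> str:
    return FAMILY_MERGES.get(family, family)


@dataclass
class FamilyAssignment:
    tag: SmallRNATag
    matched_ids: list[str]
    family: str

    @property
    def counts(self) -> dict[str, int]:
        return self.tag.counts


class SubstringIndex:
    """All substrings of the reference set at tag lengths, both strands."""

    def __init__(self, sequences: Iterable[str], lo: int = 18, hi: int = 25):
        self.lo, self.hi = lo, hi
        self._kmers: set[str] = set()
        for seq in sequences:
            for s in (normalize(seq), revcomp(seq)):
                for k in range(lo, hi + 1):
                    for i in range(len(s) - k + 1):
                        self._kmers.add(s[i:i + k])

    def __contains__(self, tag_seq: str) -> bool:
        return tag_seq in self._kmers


def classify_ncrna(tags: Iterable[SmallRNATag],
                   references: Mapping[str, Mapping[str, str]],
                   ) -> list[SmallRNATag]:
    """Set tag_class for tags fully contained in an ncRNA-class reference.

    ``references`` maps class -> {id: sequence}. Tags already classed as
    miRNA are left untouched; otherwise the first matching class in
    precedence order wins.
    """
    indexes = {cls: SubstringIndex(references[cls].values())
               for cls in NCRNA_PRECEDENCE if cls in references}
    tags = list(tags)
    for tag in tags:
        if tag.tag_class == "miRNA":
            continue
        for cls in NCRNA_PRECEDENCE:
            if cls in indexes and tag.sequence in indexes[cls]:
                tag.tag_class = cls
                break
    return tags


def match_conserved(tags: Iterable[SmallRNATag],
                    mature_refs: Mapping[str, str],
                    ) -> list[FamilyAssignment]:
    """Exact full-length identity against known mature miRNAs (0 mismatches).

    Matched tags get class miRNA; the family is parsed from the reference id
    (all matching ids are retained, one assignment per tag).
    """
    by_seq: dict[str, list[str]] = {}
    for ref_id, seq in mature_refs.items():
        by_seq.setdefault(normalize(seq), []).append(ref_id)
    assignments = []
    for tag in tags:
        ids = by_seq.get(tag.sequence)
        if not ids:
            continue
        tag.tag_class = "miRNA"
        family = merged_family(family_from_id(ids[0]))
        tag.families = sorted({merged_family(family_from_id(i)) for i in ids})
        tag.matched_ids = sorted(ids)
        assignments.append(FamilyAssignment(tag=tag, matched_ids=sorted(ids),
                                            family=family))
    return assignments


def merge_families(assignments: Sequence[FamilyAssignment]) -> pd.DataFrame:
    """Family table after merge rules: member numbers and read counts.

    Members = distinct tag sequences per merged family.
    """
    rows: dict[str, dict] = {}
    for a in assignments:
        fam = merged_family(a.family)
        row = rows.setdefault(fam, {"family": fam, "members": set(),
                                    "reads": 0, "counts": {}})
        row["members"].add(a.tag.sequence)
        row["reads"] += a.tag.total_count
        for lib, c in a.tag.counts.items():
            row["counts"][lib] = row["counts"].get(lib, 0) + c
    libs = sorted({lib for r in rows.values() for lib in r["counts"]})
    table = pd.DataFrame(
        [{"family": r["family"], "members": len(r["members"]),
          "reads": r["reads"],
          **{f"reads_{lib}": r["counts"].get(lib, 0) for lib in libs}}
         for r in rows.values()])
    if table.empty:
        return pd.DataFrame(columns=["family", "members", "reads"])
    return (table.sort_values(["members", "reads"], ascending=False)
            .reset_index(drop=True))


def class_tally(class_counts: Mapping[str, int]) -> pd.DataFrame:
    """Class tally with 2-decimal half-up percentages of the given totals.

    Pure table arithmetic: feed it read counts per class (the in-range
    total is their sum) and it reproduces the printed-table percentages.
    """
    total = sum(class_counts.values())
    rows = [(cls, class_counts.get(cls, 0),
             percent(class_counts.get(cls, 0), total, decimals=2))
            for cls in CLASS_ORDER]
    rows.append(("Total", total, percent(total, total, decimals=2)))
    return pd.DataFrame(rows, columns=["class", "reads", "percent"])


def categorize(tags: Iterable[SmallRNATag],
               library: str | None = None) -> pd.DataFrame:
    """Tally 18-25 nt reads by class (one library, or all when None)."""
    counts = {cls: 0 for cls in CLASS_ORDER}
    for tag in tags:
        n = tag.counts.get(library, 0) if library else tag.total_count
        cls = tag.tag_class if tag.tag_class in counts else "other sRNA"
        counts[cls] += n
    return class_tally(counts)
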