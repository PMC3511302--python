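"""Pipeline orchestration and summary tables.

Runs the stages in their canonical order (preprocess -> ncRNA/conserved
annotation -> precursor discovery -> quantification -> differential
abundance -> target scan -> report) and emits the study-style summary
artifacts: length tallies, class tallies, the five-category identification
table, per-family member counts and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import annotate, destats, discover, preprocess, targets
from ._seq import to_rna
from .io import read_fasta, read_fastq, write_fasta
from .preprocess import SmallRNATag

SIZE_CLASSES = tuple(range(18, 25))

IDENT_ROWS = (
    "new_known_in_plants_without_precursor",
    "known_bna_without_precursor",
    "new_in_known_bna_families_with_precursor",
    "new_known_in_plants_with_precursor",
    "new_unknown_with_precursor",
)


def identification_table(rows: Mapping[str, Mapping]) -> pd.DataFrame:
    """Five-category identification tally with column-sum grand totals.

    Each row provides per-size miRNA counts (keys 18..24), ``precursors``
    and ``families``; the miRNA total is the sum over size classes.
    """
    records = []
    for label in IDENT_ROWS:
        row = rows.get(label, {})
        sizes = {n: int(row.get(n, 0)) for n in SIZE_CLASSES}
        records.append({"class": label, **sizes,
                        "total_mirnas": sum(sizes.values()),
                        "precursors": int(row.get("precursors", 0)),
                        "families": int(row.get("families", 0))})
    totals = {"class": "Total"}
    for col in list(SIZE_CLASSES) + ["total_mirnas", "precursors", "families"]:
        totals[col] = sum(r[col] for r in records)
    records.append(totals)
    return pd.DataFrame(records)


def summarize_identification(candidates: Sequence[discover.PrecursorCandidate],
                             conserved: Sequence[annotate.FamilyAssignment],
                             bna_matures: Mapping[str, str],
                             ) -> pd.DataFrame:
    """Build the identification table from pipeline objects.

    Conserved tags split into known-in-Bna vs new-in-Bna (without
    precursor, excluding matures sitting on a discovered precursor);
    accepted candidates split by category, with novel families grouped by
    identical dominant mature sequence.
    """
    bna_seqs = {s.upper().replace("U", "T") for s in bna_matures.values()}
    accepted = [c for c in candidates if c.accepted]
    on_precursor = {c.dominant_locus.sequence for c in accepted
                    if c.dominant_locus}

    def size_counts(seqs):
        d = {n: 0 for n in SIZE_CLASSES}
        for s in seqs:
            if len(s) in d:
                d[len(s)] += 1
        return d

    cons_bna = {a.tag.sequence: a for a in conserved
                if a.tag.sequence in bna_seqs
                and a.tag.sequence not in on_precursor}
    cons_new = {a.tag.sequence: a for a in conserved
                if a.tag.sequence not in bna_seqs
                and a.tag.sequence not in on_precursor}
    rows = {
        IDENT_ROWS[0]: {**size_counts(cons_new), "precursors": 0,
                        "families": len({a.family for a in cons_new.values()})},
        IDENT_ROWS[1]: {**size_counts(cons_bna), "precursors": 0,
                        "families": len({a.family for a in cons_bna.values()})},
    }
    groups = {
        IDENT_ROWS[2]: [c for c in accepted if c.category == "known_bna"],
        IDENT_ROWS[3]: [c for c in accepted if c.category == "known_plant"],
        IDENT_ROWS[4]: [c for c in accepted if c.category == "novel"],
    }
    for label, cands in groups.items():
        matures = {c.dominant_locus.sequence for c in cands if c.dominant_locus}
        if label == IDENT_ROWS[2]:
            # new members of known Bna families: the known sequences are
            # already tallied above
            matures = {m for m in matures if m not in bna_seqs}
            families = 0
        elif label == IDENT_ROWS[3]:
            # families already counted in the conserved rows stay there;
            # only never-seen families count here
            seen = {a.family for a in list(cons_new.values())
                    + list(cons_bna.values())}
            fams = {a.family for a in conserved if a.tag.sequence in matures}
            families = len(fams - seen)
        else:
            families = len(matures)  # one novel family per distinct mature
        rows[label] = {**size_counts(matures), "precursors": len(cands),
                       "families": families}
    return identification_table(rows)


def summarize_families(assignments: Sequence[annotate.FamilyAssignment],
                       ) -> pd.DataFrame:
    """Per-family member counts, sorted descending, singletons flagged."""
    table = annotate.merge_families(assignments)
    if table.empty:
        return table.assign(singleton=pd.Series(dtype=bool))
    table["singleton"] = table["members"] == 1
    return table


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration

@dataclass
class PipelineConfig:
    """Paths and stage parameters of one end-to-end run."""

    libraries: dict[str, str]          # name -> FASTQ path
    contigs: str                       # FASTA path
    ncrna_refs: dict[str, str]         # class -> FASTA path
    plant_matures: str                 # FASTA path
    bna_matures: str                   # FASTA path
    output_dir: str = "seedmir_out"
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str | None = None
    qmin: int = 13
    lo: int = 18
    hi: int = 25
    min_overlap: int = 8
    quality_rule: str = "mean"
    discovery: discover.DiscoveryParams = field(
        default_factory=discover.DiscoveryParams)
    dispersion: float = 0.1
    alpha: float = 0.001
    min_fold: float = 2.0
    e_max: float = 4.0
    target_max_contig: int = 2000
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "discovery" in data and isinstance(data["discovery"], dict):
            disc = data["discovery"]
            if isinstance(disc.get("mfe_band"), list):
                disc["mfe_band"] = tuple(disc["mfe_band"])
            data["discovery"] = discover.DiscoveryParams(**disc)
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    config: PipelineConfig
    tags: list[SmallRNATag]
    conserved: list[annotate.FamilyAssignment]
    candidates: list[discover.PrecursorCandidate]
    counts: pd.DataFrame
    de_table: pd.DataFrame
    target_hits: list[targets.TargetHit]
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; write artifacts and a run manifest to output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [],
                      "inputs": {}, "parameters": asdict(config)}
    input_paths = {**config.libraries, "contigs": config.contigs,
                   "plant_matures": config.plant_matures,
                   "bna_matures": config.bna_matures,
                   **{f"ncrna_{k}": v for k, v in config.ncrna_refs.items()}}
    for name, path in input_paths.items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"input '{name}' missing: {path}")
        manifest["inputs"][name] = _sha256(path)

    # stage 1: preprocess
    cleaned: dict[str, list] = {}
    stage = {"name": "preprocess", "libraries": {}}
    for lib, path in config.libraries.items():
        reads = read_fastq(path)
        result = preprocess.clean_library(
            reads, config.adapter3, config.adapter5, config.qmin,
            config.lo, config.hi, config.min_overlap, config.quality_rule)
        cleaned[lib] = result.reads
        result.summary.as_frame().to_csv(
            out / f"length_summary_{lib}.tsv", sep="\t", index=False)
        stage["libraries"][lib] = {
            "input_reads": result.n_input,
            "low_quality": result.n_low_quality,
            "ambiguous": result.n_ambiguous,
            "below": result.summary.below, "above": result.summary.above,
            "retained": len(result.reads)}
    tags = preprocess.collapse_tags(cleaned)
    libs = list(config.libraries)
    preprocess.write_tags_fasta(out / "tags.fa", tags, libs)
    preprocess.length_distribution(tags, config.lo, config.hi).to_csv(
        out / "length_distribution.tsv", sep="\t", index=False)
    stage["distinct_tags"] = len(tags)
    manifest["stages"].append(stage)

    # stage 2: annotation
    ncrna = {cls: read_fasta(path) for cls, path in config.ncrna_refs.items()}
    plant = read_fasta(config.plant_matures)
    bna = read_fasta(config.bna_matures)
    conserved = annotate.match_conserved(tags, plant)
    annotate.classify_ncrna(tags, ncrna)
    for lib in libs:
        annotate.categorize(tags, lib).to_csv(
            out / f"class_tally_{lib}.tsv", sep="\t", index=False)
    fam_table = summarize_families(conserved)
    fam_table.to_csv(out / "families.tsv", sep="\t", index=False)
    manifest["stages"].append({"name": "annotation",
                               "conserved_tags": len(conserved),
                               "families": int(len(fam_table))})

    # stage 3: discovery
    contigs = read_fasta(config.contigs)
    candidates = discover.discover_precursors(
        tags, contigs, bna, plant, config.discovery, libs)
    accepted = [c for c in candidates if c.accepted]
    _write_discovery(out, accepted)
    manifest["stages"].append({"name": "discovery",
                               "candidates": len(candidates),
                               "accepted": len(accepted)})

    # stage 4: quantification
    loci = destats.loci_from_candidates(accepted)
    counts = destats.count_abundance(tags, loci, libs,
                                     config.discovery.isomir_window)
    counts.to_csv(out / "counts.tsv", sep="\t")
    manifest["stages"].append({"name": "quantification", "loci": len(loci)})

    # stage 5: differential abundance
    lib_sizes = {lib: float(len(cleaned[lib])) for lib in libs}
    if len(libs) == 2 and len(counts):
        de_table = destats.call_de(counts, lib_sizes, config.dispersion,
                                   config.alpha, config.min_fold)
    else:
        de_table = pd.DataFrame()
    de_table.to_csv(out / "de.tsv", sep="\t")
    manifest["stages"].append({
        "name": "differential_abundance",
        "tested": int(len(de_table)),
        "de": int(de_table["is_de"].sum()) if len(de_table) else 0})

    # stage 6: target prediction
    mature_seqs = {f"{c.id}-{c.dominant_locus.arm}": c.dominant_locus.sequence
                   for c in accepted if c.dominant_locus}
    scan_contigs = {k: v for k, v in contigs.items()
                    if len(v) <= config.target_max_contig}
    target_hits = targets.scan_targets(mature_seqs, scan_contigs,
                                       config.e_max)
    _write_targets(out / "targets.tsv", target_hits)
    manifest["stages"].append({"name": "target_prediction",
                               "mirnas": len(mature_seqs),
                               "hits": len(target_hits)})

    # stage 7: report
    ident = summarize_identification(candidates, conserved, bna)
    ident.to_csv(out / "identification.tsv", sep="\t", index=False)
    profile = discover.first_nucleotide_profile(
        [c.dominant_locus for c in accepted if c.dominant_locus])
    pd.Series(profile, name="count").rename_axis("nucleotide").to_csv(
        out / "first_nucleotide.tsv", sep="\t")
    manifest["stages"].append({"name": "report",
                               "total_mirnas": int(ident.iloc[-1]["total_mirnas"])})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return PipelineResult(config, tags, conserved, candidates, counts,
                          de_table, target_hits, manifest)


def _write_discovery(out: Path, accepted) -> None:
    write_fasta(out / "precursors.fa",
                [(c.id, c.sequence) for c in accepted])
    with open(out / "precursors.str", "w") as fh:
        for c in accepted:
            fh.write(f">{c.id}\n{to_rna(c.sequence)}\n"
                     f"{c.dot_bracket} ({c.mfe:.2f})\n")
    with open(out / "precursors.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for c in accepted:
            s, e = c.interval
            fh.write(f"{c.contig_id}\tseedmir\tprecursor\t{s + 1}\t{e}\t."
                     f"\t{c.strand}\t.\tID={c.id};category={c.category};"
                     f"status={c.status}\n")
            for locus in c.loci:
                cs, ce = c.to_contig_coords(locus.interval)
                kind = ("miRNA" if (c.dominant_locus
                                    and locus.arm == c.dominant_locus.arm)
                        else "miRNA_star")
                fh.write(f"{c.contig_id}\tseedmir\t{kind}\t{cs + 1}\t{ce}\t."
                         f"\t{c.strand}\t.\tID={c.id}-{locus.arm};"
                         f"arm={locus.arm}\n")
    rows = [{"id": c.id, "contig": c.contig_id, "length": c.length,
             "mfe": c.mfe, "amfe": round(c.amfe, 2),
             "mfei": round(c.mfei, 4), "gc": round(c.gc, 2),
             "category": c.category, "status": c.status,
             "mfe_band_warning": c.mfe_band_warning}
            for c in accepted]
    pd.DataFrame(rows).to_csv(out / "precursor_metrics.tsv", sep="\t",
                              index=False)


def _write_targets(path, hits: Sequence[targets.TargetHit]) -> None:
    rows = [{"mirna": h.mirna_id, "contig": h.contig_id, "start": h.start,
             "end": h.end, "strand": h.strand, "E": h.expectation,
             "mismatches": h.mismatches, "gu": h.gu_pairs, "gaps": h.gaps}
            for h in hits]
    pd.DataFrame(rows, columns=["mirna", "contig", "start", "end", "strand",
                                "E", "mismatches", "gu", "gaps"]
                 ).to_csv(path, sep="\t", index=False)
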