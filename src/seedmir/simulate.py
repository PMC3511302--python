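"""Seeded generator of ground-truthed inputs for the seed small-RNA pipeline.

Emulates what two-condition plant seed small-RNA libraries look like after
Illumina sequencing: hairpin precursors embedded in transcript contigs, each
shedding mature / star / isomiR reads, plus ncRNA contaminant reads and
unassignable background, all with a 3' adapter appended. Every downstream
stage (preprocessing, annotation, discovery, quantification, target scans)
can be exercised against the planted truth with no external data.

Design notes
------------
* Per-locus read counts are Poisson around ``abundance x fold_change``
  (negative binomial when ``dispersion > 0``), the simplest count models
  consistent with two-library exact-test DE.
* isomiRs take uniform offsets in {-2,-1,+1,+2} on a uniformly chosen end,
  at a configurable per-read rate (default 0.2).
* A single 3' adapter is appended full-length; qualities are constant
  Phred 30 except for a configurable low-quality read fraction (Phred 2)
  that exercises the quality filter.
* Mature arms start with U with probability ``u_start_bias`` (plant Dicer
  products are strongly U-biased at position 1).
* Background/contaminant insert lengths peak at 24 nt while planted matures
  default to 21 nt, reproducing the 21/24 bimodal length profile of plant
  seed libraries.

All randomness flows through ``numpy.random.Generator`` objects derived from
a single seed; a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import revcomp
from .io import ReadRecord

BASES = np.array(list("ACGT"))

#: bases on the opposite strand that pair (Watson-Crick or G:U wobble)
_PAIRS = {"A": "T", "C": "G", "G": "CT", "T": "AG"}

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

_NCRNA_PLAN = {
    # class -> (n sequences, length)
    "rRNA": (2, 1200),
    "tRNA": (5, 75),
    "snRNA": (3, 150),
    "snoRNA": (3, 110),
    "mtRNA": (2, 600),
    "cpRNA": (2, 600),
}

# synthetic miRBase-style reference ids; families chosen so that the
# MIR156/157, MIR165/166 and MIR170/171 merge rules are exercised
_PLANT_REF_IDS = [
    "ath-miR156a", "ath-miR157a", "bra-miR156b", "ath-miR159a", "bna-miR159a",
    "ath-miR160a", "ath-miR162a", "ath-miR164a", "ath-miR165a", "ath-miR166a",
    "osa-miR166b", "ath-miR167a", "bna-miR167a", "ath-miR168a", "ath-miR169a",
    "ath-miR170a", "ath-miR171a", "ath-miR172a", "ath-miR319a", "ath-miR390a",
    "ath-miR393a", "ath-miR394a", "ath-miR395a", "ath-miR396a", "ath-miR398a",
    "ath-miR399a", "bna-miR824a", "ath-miR403a", "ath-miR408a", "bna-miR1140a",
]


@dataclass
class LibraryProfile:
    """Sequencing depth and abundance model of one small-RNA library."""

    name: str
    total_reads: int = 30_000
    per_locus_abundance: float | Mapping[str, float] = 300.0
    fold_change_map: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")

    def expected_count(self, precursor_id: str) -> float:
        if isinstance(self.per_locus_abundance, Mapping):
            base = float(self.per_locus_abundance[precursor_id])
        else:
            base = float(self.per_locus_abundance)
        fc = float(self.fold_change_map.get(precursor_id, 1.0))
        if base <= 0 or fc <= 0:
            raise ValueError("abundances and fold changes must be positive")
        return base * fc


def _default_libraries() -> list[LibraryProfile]:
    return [LibraryProfile("mature_seed"), LibraryProfile("developing_seed")]


@dataclass
class SimConfig:
    """Parameters of one simulated study (two-condition seed sRNA-seq)."""

    seed: int = 0
    n_precursors: int = 24
    n_decoy_contigs: int = 30
    arm_len: int = 21
    loop_range: tuple[int, int] = (8, 15)
    gc_target: float = 0.45
    star_mismatches: int = 2
    libraries: list[LibraryProfile] = field(default_factory=_default_libraries)
    adapter3: str = DEFAULT_ADAPTER3
    contaminant_fraction: float = 0.10
    star_rate: float = 0.10
    isomir_rate: float = 0.20
    u_start_bias: float = 0.8
    low_quality_fraction: float = 0.02
    ambiguous_fraction: float = 0.01
    quality: int = 30
    low_quality: int = 2
    n_known_bna: int = 3
    n_known_plant: int = 3
    stem_ext: int = 15  # lower-stem extension flanking the mature:star duplex
    pad_to_total: bool = True  # fill with background reads up to total_reads
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if not 18 <= self.arm_len <= 25:
            raise ValueError("arm_len must lie in [18, 25]")
        for name in ("contaminant_fraction", "star_rate", "isomir_rate",
                     "u_start_bias", "low_quality_fraction",
                     "ambiguous_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Hairpin:
    """A simulated stem-loop: 5' arm + loop + 3' arm (near-revcomp of 5')."""

    sequence: str
    arm5p: str
    arm3p: str
    loop: str
    mature_arm: str  # "5p" or "3p": the arm shedding the dominant product

    @property
    def arm5p_interval(self) -> tuple[int, int]:
        return (0, len(self.arm5p))

    @property
    def arm3p_interval(self) -> tuple[int, int]:
        start = len(self.arm5p) + len(self.loop)
        return (start, start + len(self.arm3p))

    @property
    def mature_seq(self) -> str:
        return self.arm5p if self.mature_arm == "5p" else self.arm3p

    @property
    def star_seq(self) -> str:
        return self.arm3p if self.mature_arm == "5p" else self.arm5p


@dataclass
class PlantedTruth:
    """Ground truth for one planted precursor on one contig."""

    precursor_id: str
    contig_id: str
    interval: tuple[int, int]  # 0-based half-open on the contig
    mature5p: str
    mature5p_interval: tuple[int, int]
    mature3p: str
    mature3p_interval: tuple[int, int]
    mature_arm: str
    category: str  # known_bna | known_plant | novel
    expected_counts: dict[str, float] = field(default_factory=dict)

    @property
    def mature_seq(self) -> str:
        return self.mature5p if self.mature_arm == "5p" else self.mature3p

    @property
    def mature_interval(self) -> tuple[int, int]:
        return (self.mature5p_interval if self.mature_arm == "5p"
                else self.mature3p_interval)

    @property
    def star_seq(self) -> str:
        return self.mature3p if self.mature_arm == "5p" else self.mature5p

    @property
    def star_interval(self) -> tuple[int, int]:
        return (self.mature3p_interval if self.mature_arm == "5p"
                else self.mature5p_interval)


@dataclass
class ReferenceSet:
    """Synthetic stand-ins for public reference sets (all sequences random)."""

    ncrna: dict[str, dict[str, str]]      # class -> {id: seq}
    plant_matures: dict[str, str]          # miRBase-style id -> seq (DNA)
    bna_matures: dict[str, str]            # subset: B. napus entries


@dataclass
class SimulatedStudy:
    config: SimConfig
    references: ReferenceSet
    contigs: dict[str, str]
    truths: list[PlantedTruth]
    reads: dict[str, list[ReadRecord]]
    realized_counts: dict[str, dict[str, int]]  # lib -> precursor_id -> mature reads


# ---------------------------------------------------------------------------
# sequence construction

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _random_arm(rng: np.random.Generator, arm_len: int, gc_target: float,
                first_base: str | None) -> str:
    """Arm with round(arm_len*gc_target) G/C bases, optionally fixed base 1."""
    n_gc = int(round(arm_len * gc_target))
    arm = [""] * arm_len
    free = list(range(arm_len))
    if first_base is not None:
        arm[0] = first_base
        free = free[1:]
        if first_base in "GC":
            n_gc -= 1
    n_gc = max(0, min(n_gc, len(free)))
    gc_pos = rng.choice(len(free), size=n_gc, replace=False)
    gc_set = {free[i] for i in gc_pos}
    for i in free:
        pool = "GC" if i in gc_set else "AT"
        arm[i] = pool[rng.integers(0, 2)]
    return "".join(arm)


def _break_pairs(rng: np.random.Generator, arm5p: str, arm3p: str,
                 n_mismatches: int) -> str:
    """Substitute n bases of arm3p so they can no longer pair their partner."""
    arm3p = list(arm3p)
    n = len(arm3p)
    # avoid the two terminal positions of the stem so the duplex stays anchored
    candidates = list(range(1, n - 1)) if n > 2 + n_mismatches else list(range(n))
    pos = rng.choice(len(candidates), size=n_mismatches, replace=False)
    for p in pos:
        j = candidates[p]
        partner = arm5p[n - 1 - j]
        forbidden = set(_PAIRS[partner]) | {arm3p[j]}
        pool = [b for b in "ACGT" if b not in forbidden]
        arm3p[j] = pool[rng.integers(0, len(pool))]
    return "".join(arm3p)


def simulate_hairpin(seed: int | np.random.Generator, arm_len: int = 21,
                     loop_len: int = 8, gc_target: float = 0.45,
                     star_mismatches: int = 2, *, mature_arm: str = "5p",
                     mature_seq: str | None = None,
                     first_base: str | None = None) -> Hairpin:
    """Construct a stem-loop whose 3' arm is the reverse complement of the
    5' arm with exactly ``star_mismatches`` pair-breaking substitutions.

    ``mature_seq`` (length ``arm_len``) pins the mature arm to a given
    sequence, used when planting precursors of known miRNAs.
    """
    if arm_len < 18:
        raise ValueError("arm_len must be >= 18")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if not 0 <= star_mismatches <= arm_len - 4:
        raise ValueError("star_mismatches out of range")
    if mature_arm not in ("5p", "3p"):
        raise ValueError("mature_arm must be '5p' or '3p'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if mature_seq is not None:
        if len(mature_seq) != arm_len:
            raise ValueError("mature_seq length must equal arm_len")
        mature = mature_seq.upper().replace("U", "T")
    else:
        mature = _random_arm(rng, arm_len, gc_target, first_base)
    # arm5p[i] pairs arm3p[n-1-i]; by symmetry the same construction yields a
    # valid star whether the mature sits on the 5' or the 3' arm
    star = _break_pairs(rng, mature, revcomp(mature), star_mismatches)
    if mature_arm == "5p":
        arm5p, arm3p = mature, star
    else:
        arm5p, arm3p = star, mature
    # loop drawn from {A,C} only: keeps the terminal loop unstructured
    loop = "".join("AC"[i] for i in rng.integers(0, 2, size=loop_len))
    return Hairpin(arm5p + loop + arm3p, arm5p, arm3p, loop, mature_arm)


# ---------------------------------------------------------------------------
# references

def make_references(rng: np.random.Generator, arm_len: int = 21,
                    u_start_bias: float = 0.8) -> ReferenceSet:
    """Synthetic ncRNA-class and plant mature-miRNA reference sets."""
    ncrna = {
        cls: {f"{cls}_{i + 1}": _random_seq(rng, length)
              for i in range(n)}
        for cls, (n, length) in _NCRNA_PLAN.items()
    }
    plant: dict[str, str] = {}
    for ref_id in _PLANT_REF_IDS:
        first = "T" if rng.random() < u_start_bias else None
        plant[ref_id] = _random_arm(rng, arm_len, 0.45, first)
    bna = {k: v for k, v in plant.items() if k.startswith("bna-")}
    return ReferenceSet(ncrna=ncrna, plant_matures=plant, bna_matures=bna)


# ---------------------------------------------------------------------------
# planting

def plant_precursors(config: SimConfig, *, rng: np.random.Generator | None = None,
                     references: ReferenceSet | None = None,
                     ) -> tuple[dict[str, str], list[PlantedTruth], ReferenceSet]:
    """Embed hairpin precursors in random contigs with >= 20 nt flanks.

    Returns (contigs, truth records, references); decoy contigs are pure
    random sequence with no planted hairpin.
    """
    if config.n_decoy_contigs < 0:
        raise ValueError("n_decoy_contigs must be >= 0")
    rng = rng or np.random.default_rng(config.seed)
    references = references or make_references(rng, config.arm_len,
                                               config.u_start_bias)

    non_bna = [k for k in references.plant_matures if not k.startswith("bna-")]
    bna_ids = list(references.bna_matures)
    categories = (["known_bna"] * min(config.n_known_bna, len(bna_ids))
                  + ["known_plant"] * min(config.n_known_plant, len(non_bna)))
    categories = categories[:config.n_precursors]
    categories += ["novel"] * (config.n_precursors - len(categories))

    contigs: dict[str, str] = {}
    truths: list[PlantedTruth] = []
    bna_pool = [bna_ids[i] for i in rng.permutation(len(bna_ids))]
    plant_pool = [non_bna[i] for i in rng.permutation(len(non_bna))]
    n_digits = len(str(config.n_precursors + config.n_decoy_contigs))
    for i, category in enumerate(categories):
        mature_seq = None
        if category == "known_bna":
            mature_seq = references.plant_matures[bna_pool.pop(0)]
        elif category == "known_plant":
            mature_seq = references.plant_matures[plant_pool.pop(0)]
        first = "T" if rng.random() < config.u_start_bias else None
        loop_len = int(rng.integers(config.loop_range[0],
                                    config.loop_range[1] + 1))
        hp = simulate_hairpin(
            rng, config.arm_len, loop_len, config.gc_target,
            config.star_mismatches,
            mature_arm="5p" if rng.random() < 0.5 else "3p",
            mature_seq=mature_seq, first_base=first)
        # real pre-miRNA stems extend below the mature:star duplex; pair an
        # extension on both sides (one broken pair when long enough)
        ext5 = _random_arm(rng, config.stem_ext, config.gc_target, None) \
            if config.stem_ext else ""
        ext3 = _break_pairs(rng, ext5, revcomp(ext5),
                            1 if config.stem_ext >= 6 else 0) if ext5 else ""
        precursor = ext5 + hp.sequence + ext3
        left = int(rng.integers(130, 250))
        right = int(rng.integers(130, 250))
        contig_id = f"contig{i + 1:0{n_digits}d}"
        seq = _random_seq(rng, left) + precursor + _random_seq(rng, right)
        contigs[contig_id] = seq
        p_start, p_end = left, left + len(precursor)
        shift = len(ext5)
        a5 = (hp.arm5p_interval[0] + shift, hp.arm5p_interval[1] + shift)
        a3 = (hp.arm3p_interval[0] + shift, hp.arm3p_interval[1] + shift)
        truths.append(PlantedTruth(
            precursor_id=f"prec{i + 1:03d}",
            contig_id=contig_id,
            interval=(p_start, p_end),
            mature5p=hp.arm5p,
            mature5p_interval=(p_start + a5[0], p_start + a5[1]),
            mature3p=hp.arm3p,
            mature3p_interval=(p_start + a3[0], p_start + a3[1]),
            mature_arm=hp.mature_arm,
            category=category,
        ))
    for j in range(config.n_decoy_contigs):
        contig_id = f"contig{config.n_precursors + j + 1:0{n_digits}d}"
        contigs[contig_id] = _random_seq(rng, int(rng.integers(150, 400)))
    return contigs, truths, references


# ---------------------------------------------------------------------------
# reads

_BG_LENGTHS = np.arange(20, 26)
# insert-length distribution of non-miRNA small RNAs: peaked at 24 nt
_BG_WEIGHTS = np.array([0.05, 0.06, 0.08, 0.12, 0.55, 0.14])


def _locus_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion > 0:
        # NB as gamma-Poisson; dispersion = 1/size (edgeR parameterization)
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean / shape)
        return int(rng.poisson(lam))
    return int(rng.poisson(mean))


def _isomir_interval(rng: np.random.Generator, start: int, end: int,
                     contig_len: int) -> tuple[int, int]:
    offset = int(rng.choice([-2, -1, 1, 2]))
    if rng.random() < 0.5:
        start = start + offset
    else:
        end = end + offset
    start, end = max(0, start), min(contig_len, end)
    return start, end


def simulate_reads(truths: Sequence[PlantedTruth], contigs: Mapping[str, str],
                   profiles: Sequence[LibraryProfile],
                   references: ReferenceSet, config: SimConfig,
                   seed: int | None = None,
                   ) -> tuple[dict[str, list[ReadRecord]], dict[str, dict[str, int]]]:
    """One read list per library; exactly ``total_reads`` reads each.

    Reads are mature (exact), star (at ``star_rate`` of the mature count),
    isomiR (offset variants at ``isomir_rate``), ncRNA contaminant and random
    background, each with the 3' adapter appended and constant Phred
    qualities (low-quality and N-containing fractions per config).
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if not truths:
        raise ValueError("truths must be non-empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    contaminant_seqs = [s for cls in references.ncrna.values()
                        for s in cls.values()]
    reads: dict[str, list[ReadRecord]] = {}
    realized: dict[str, dict[str, int]] = {}
    for profile in profiles:
        lib_rng = np.random.default_rng(rng.integers(0, 2**31))
        inserts: list[str] = []
        lib_counts: dict[str, int] = {}
        for truth in truths:
            contig = contigs[truth.contig_id]
            mean = profile.expected_count(truth.precursor_id)
            truth.expected_counts[profile.name] = mean
            n_mat = _locus_count(lib_rng, mean, config.dispersion)
            lib_counts[truth.precursor_id] = n_mat
            m_start, m_end = truth.mature_interval
            for _ in range(n_mat):
                if config.isomir_rate and lib_rng.random() < config.isomir_rate:
                    s, e = _isomir_interval(lib_rng, m_start, m_end, len(contig))
                    inserts.append(contig[s:e])
                else:
                    inserts.append(truth.mature_seq)
            n_star = _locus_count(lib_rng, config.star_rate * mean, 0.0)
            inserts.extend([truth.star_seq] * n_star)
        n_planted = len(inserts)
        if n_planted > profile.total_reads:
            raise ValueError(
                f"library {profile.name}: planted reads ({n_planted}) exceed "
                f"total_reads ({profile.total_reads}); raise total_reads")
        n_contam = int(round(config.contaminant_fraction * profile.total_reads))
        n_contam = min(n_contam, profile.total_reads - n_planted)
        for _ in range(n_contam):
            src = contaminant_seqs[lib_rng.integers(0, len(contaminant_seqs))]
            length = int(lib_rng.choice(_BG_LENGTHS, p=_BG_WEIGHTS))
            start = int(lib_rng.integers(0, len(src) - length + 1))
            frag = src[start:start + length]
            if lib_rng.random() < 0.5:
                frag = revcomp(frag)
            inserts.append(frag)
        if config.pad_to_total:
            while len(inserts) < profile.total_reads:
                length = int(lib_rng.choice(_BG_LENGTHS, p=_BG_WEIGHTS))
                inserts.append(_random_seq(lib_rng, length))
        order = lib_rng.permutation(len(inserts))
        lib_reads: list[ReadRecord] = []
        for serial, idx in enumerate(order):
            insert = inserts[idx]
            if config.ambiguous_fraction and lib_rng.random() < config.ambiguous_fraction:
                pos = int(lib_rng.integers(0, len(insert)))
                insert = insert[:pos] + "N" + insert[pos + 1:]
            seq = insert + config.adapter3
            qual = config.quality
            if (config.low_quality_fraction
                    and lib_rng.random() < config.low_quality_fraction):
                qual = config.low_quality
            lib_reads.append(ReadRecord(
                id=f"{profile.name}_{serial + 1}",
                sequence=seq,
                qualities=[qual] * len(seq),
            ))
        reads[profile.name] = lib_reads
        realized[profile.name] = lib_counts
    return reads, realized


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the full generator: references, contigs+truth, per-library reads."""
    rng = np.random.default_rng(config.seed)
    references = make_references(rng, config.arm_len, config.u_start_bias)
    contigs, truths, references = plant_precursors(
        config, rng=rng, references=references)
    reads, realized = simulate_reads(
        truths, contigs, config.libraries, references, config,
        seed=int(rng.integers(0, 2**31)))
    return SimulatedStudy(config, references, contigs, truths, reads, realized)


# ---------------------------------------------------------------------------
# emission

def write_truth_gff(path, truths: Sequence[PlantedTruth]) -> None:
    """GFF3-like truth table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truths:
            rows = [
                ("precursor", t.interval, f"ID={t.precursor_id};category={t.category}"),
                ("mature", t.mature5p_interval,
                 f"ID={t.precursor_id}-5p;arm=5p;dominant={t.mature_arm == '5p'}"),
                ("mature", t.mature3p_interval,
                 f"ID={t.precursor_id}-3p;arm=3p;dominant={t.mature_arm == '3p'}"),
            ]
            for kind, (s, e), attrs in rows:
                fh.write(f"{t.contig_id}\tseedmir_sim\t{kind}\t{s + 1}\t{e}\t."
                         f"\t+\t.\t{attrs}\n")


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write all generated inputs (FASTQ, FASTA, truth tables) to a directory.

    Returns the path map needed to assemble a pipeline configuration. All
    sequences are synthetic; mature references are written in RNA letters.
    """
    from pathlib import Path

    from ._seq import to_rna
    from .io import write_fasta, write_fastq

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for lib, reads in study.reads.items():
        p = out / f"reads_{lib}.fastq"
        write_fastq(p, reads)
        paths[f"library:{lib}"] = str(p)
    write_fasta(out / "contigs.fa", study.contigs.items())
    paths["contigs"] = str(out / "contigs.fa")
    for cls, refs in study.references.ncrna.items():
        p = out / f"ncrna_{cls}.fa"
        write_fasta(p, refs.items())
        paths[f"ncrna:{cls}"] = str(p)
    write_fasta(out / "plant_matures.fa",
                [(k, to_rna(v)) for k, v in study.references.plant_matures.items()])
    paths["plant_matures"] = str(out / "plant_matures.fa")
    write_fasta(out / "bna_matures.fa",
                [(k, to_rna(v)) for k, v in study.references.bna_matures.items()])
    paths["bna_matures"] = str(out / "bna_matures.fa")
    write_truth_gff(out / "truth.gff3", study.truths)
    write_truth_counts(out / "truth_counts.tsv", study.truths,
                       study.realized_counts)
    return paths


def write_truth_counts(path, truths: Sequence[PlantedTruth],
                       realized: Mapping[str, Mapping[str, int]]) -> None:
    libs = list(realized)
    with open(path, "w") as fh:
        header = ["precursor_id", "category", "mature_arm"]
        header += [f"expected_{l}" for l in libs] + [f"reads_{l}" for l in libs]
        fh.write("\t".join(header) + "\n")
        for t in truths:
            row = [t.precursor_id, t.category, t.mature_arm]
            row += [f"{t.expected_counts.get(l, 0):.1f}" for l in libs]
            row += [str(realized[l].get(t.precursor_id, 0)) for l in libs]
            fh.write("\t".join(row) + "\n")
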