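"""Self-contained toy communities for testing and demonstration.

Generates small reference communities with i.i.d. uniform-base genomes,
plants exact bait targets (and optional near-homologous off-target copies
with a chosen mismatch count) at recorded loci, and writes the matching
FASTA / abundance TSV / bait TSV / SAM files so the whole pipeline runs
with no external data. Fixed seeds give byte-identical fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io_align import Bait, ReferenceGenome, revcomp

_BASES = np.array(list("ACGT"))

# decade-structured genomic abundances (%) of a log-distributed mock
# community standard: each organism is 10x (or equal to) the next
ZYMO_LOG_ABUNDANCES = {
    "Lmonocytogenes": 89.1,
    "Paeruginosa": 8.9,
    "Bsubtilis": 0.89,
    "Scerevisiae": 0.89,
    "Ecoli": 0.089,
    "Senterica": 0.089,
    "Lfermentum": 0.0089,
    "Efaecalis": 0.00089,
    "Cneoformans": 0.00089,
    "Saureus": 0.000089,
}
# organisms never targeted by the bait panel (no resistance genes)
ZYMO_UNTARGETED = ("Scerevisiae", "Lfermentum", "Cneoformans")


@dataclass(frozen=True)
class ToyCommunitySpec:
    """Recipe for a synthetic toy community."""

    n_genomes: int = 3
    genome_lengths: tuple[int, ...] = (30000, 20000, 10000)
    abundances: tuple[float, ...] = (0.70, 0.25, 0.05)
    n_baits: int = 6
    bait_length: int = 120
    targets_per_genome: int | tuple[int, ...] = 2
    offtargets_per_bait: int = 0
    offtarget_mismatches: int = 5
    reverse_fraction: float = 0.25
    seed: int = 0
    genome_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.genome_lengths) != self.n_genomes:
            raise ValueError("genome_lengths must have n_genomes entries")
        if len(self.abundances) != self.n_genomes:
            raise ValueError("abundances must have n_genomes entries")
        if abs(sum(self.abundances) - 1.0) > 1e-6:
            raise ValueError("abundances must sum to 1")
        if self.bait_length < 2:
            raise ValueError("bait_length must be >= 2")
        if self.genome_ids and len(self.genome_ids) != self.n_genomes:
            raise ValueError("genome_ids must have n_genomes entries")

    @property
    def targets(self) -> tuple[int, ...]:
        t = self.targets_per_genome
        return tuple(t) if isinstance(t, (tuple, list)) else (t,) * self.n_genomes

    @property
    def ids(self) -> tuple[str, ...]:
        if self.genome_ids:
            return self.genome_ids
        return tuple(f"g{i + 1:02d}" for i in range(self.n_genomes))


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record of one planted bait-binding locus."""

    bait_id: str
    genome_id: str
    start: int
    end: int
    strand: str  # "forward" / "reverse"
    mismatches: int
    secondary: bool


@dataclass
class ToyCommunity:
    """A generated fixture: file paths, truth record, in-memory objects."""

    fasta_path: Path
    abundance_path: Path
    baits_path: Path
    sam_path: Path
    truth: list[PlantedSite]
    genomes: list[ReferenceGenome]
    baits: list[Bait]


def zymo_like_spec(seed: int = 0, genome_length: int = 20000) -> ToyCommunitySpec:
    """Preset mirroring a log-distributed 10-organism mock community at
    reduced genome sizes: decade-spaced abundances, three organisms left
    untargeted by the panel."""
    names = tuple(ZYMO_LOG_ABUNDANCES)
    raw = np.array([ZYMO_LOG_ABUNDANCES[n] for n in names])
    ab = tuple(float(x) for x in raw / raw.sum())
    targets = tuple(0 if n in ZYMO_UNTARGETED else 2 for n in names)
    return ToyCommunitySpec(
        n_genomes=len(names),
        genome_lengths=(genome_length,) * len(names),
        abundances=ab,
        n_baits=sum(targets),
        targets_per_genome=targets,
        seed=seed,
        genome_ids=names,
    )


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly k distinct positions with a different base."""
    if k == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=k, replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _place(
    glen: int, width: int, occupied: list[tuple[int, int]], rng: np.random.Generator
) -> int:
    """Uniform start for a width-sized planting that overlaps no prior one."""
    if glen < width:
        raise ValueError(f"genome too short ({glen}) for a {width}-base planting")
    for _ in range(200):
        s = int(rng.integers(0, glen - width + 1))
        if all(s + width <= a or s >= b for a, b in occupied):
            occupied.append((s, s + width))
            return s
    raise ValueError("could not place a target without overlap; genome too crowded")


def make_toy_community(spec: ToyCommunitySpec, out_dir: str | Path) -> ToyCommunity:
    """Generate a toy community and write its FASTA/TSV/SAM fixture files.

    Exact bait copies are planted at recorded loci (a fraction on the
    reverse strand); optional off-target copies carry exactly
    ``offtarget_mismatches`` substitutions. The SAM lists every planted
    site with correct position, CIGAR and edit distance; additional sites
    of a bait beyond its first are flagged secondary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ids = spec.ids

    sequences = {gid: list(_random_seq(n, rng)) for gid, n in zip(ids, spec.genome_lengths)}
    baits = [
        Bait(id=f"b{i + 1:02d}", sequence=_random_seq(spec.bait_length, rng))
        for i in range(spec.n_baits)
    ]

    truth: list[PlantedSite] = []
    occupied: dict[str, list[tuple[int, int]]] = {gid: [] for gid in ids}
    sites_per_bait: dict[str, int] = {b.id: 0 for b in baits}
    targeted = [gid for gid, t in zip(ids, spec.targets) if t > 0]

    def plant(bait: Bait, gid: str, mismatches: int) -> None:
        start = _place(len(sequences[gid]), spec.bait_length, occupied[gid], rng)
        reverse = bool(rng.random() < spec.reverse_fraction)
        copy = _mutate(bait.sequence, mismatches, rng)
        planted = revcomp(copy) if reverse else copy
        sequences[gid][start : start + spec.bait_length] = list(planted)
        truth.append(
            PlantedSite(
                bait_id=bait.id,
                genome_id=gid,
                start=start,
                end=start + spec.bait_length,
                strand="reverse" if reverse else "forward",
                mismatches=mismatches,
                secondary=sites_per_bait[bait.id] > 0,
            )
        )
        sites_per_bait[bait.id] += 1

    cursor = 0
    for gid, n_targets in zip(ids, spec.targets):
        for _ in range(n_targets):
            plant(baits[cursor % spec.n_baits], gid, mismatches=0)
            cursor += 1
    for bait in baits:
        for _ in range(spec.offtargets_per_bait):
            gid = targeted[int(rng.integers(0, len(targeted)))]
            plant(bait, gid, mismatches=spec.offtarget_mismatches)

    genome_strings = {gid: "".join(chars) for gid, chars in sequences.items()}
    genomes = [
        ReferenceGenome(id=gid, records={gid: genome_strings[gid]}, abundance=a)
        for gid, a in zip(ids, spec.abundances)
    ]

    fasta_path = out / "refs.fa"
    with open(fasta_path, "w") as fh:
        for gid in ids:
            fh.write(f">{gid}\n{genome_strings[gid]}\n")
    abundance_path = out / "abundances.tsv"
    abundance_path.write_text(
        "".join(f"{gid}\t{a:.10g}\n" for gid, a in zip(ids, spec.abundances))
    )
    baits_path = out / "baits.tsv"
    baits_path.write_text(
        "".join(f"{b.id}\t{b.sequence}\t{b.concentration:.10g}\n" for b in baits)
    )

    sam_path = out / "candidates.sam"
    _write_truth_sam(sam_path, truth, {b.id: b for b in baits}, genome_strings, ids)
    return ToyCommunity(
        fasta_path=fasta_path,
        abundance_path=abundance_path,
        baits_path=baits_path,
        sam_path=sam_path,
        truth=truth,
        genomes=genomes,
        baits=baits,
    )


def _write_truth_sam(
    sam_path: Path,
    truth: Sequence[PlantedSite],
    baits: dict[str, Bait],
    genome_strings: dict[str, str],
    order: Sequence[str],
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": gid, "LN": len(genome_strings[gid])} for gid in order],
    }
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        for site in truth:
            bait = baits[site.bait_id]
            a = pysam.AlignedSegment(sam.header)
            a.query_name = site.bait_id
            a.flag = (16 if site.strand == "reverse" else 0) | (
                256 if site.secondary else 0
            )
            a.reference_id = list(order).index(site.genome_id)
            a.reference_start = site.start
            a.mapping_quality = 42
            a.cigarstring = f"{len(bait.sequence)}M"
            # SEQ is the query in reference-forward orientation
            a.query_sequence = (
                revcomp(bait.sequence) if site.strand == "reverse" else bait.sequence
            )
            a.set_tag("NM", site.mismatches)
            sam.write(a)


def make_mismatch_series_sam(
    out_dir: str | Path,
    max_mismatch: int = 60,
    bait_length: int = 100,
    genome_length: int = 10000,
    seed: int = 0,
) -> ToyCommunity:
    """A filter-stress fixture: one genome, one all-match SAM record per
    mismatch count 0..max_mismatch, plus indel-containing records.

    Bait ``mm<k>`` differs from its reference window by exactly k
    substitutions and aligns with an all-M CIGAR; two extra records carry
    an insertion and a deletion. With the default mismatch cap of 40 the
    candidate-site parser retains exactly counts 0..40 and neither indel
    record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    gid = "g01"
    genome = _random_seq(genome_length, rng)
    window_start = 100
    window = genome[window_start : window_start + bait_length]

    baits = [
        Bait(id=f"mm{k:02d}", sequence=_mutate(window, k, rng))
        for k in range(max_mismatch + 1)
    ]
    ins_bait = Bait(id="has_insertion", sequence=_random_seq(bait_length, rng))
    del_bait = Bait(id="has_deletion", sequence=_random_seq(bait_length, rng))

    fasta_path = out / "refs.fa"
    fasta_path.write_text(f">{gid}\n{genome}\n")
    abundance_path = out / "abundances.tsv"
    abundance_path.write_text(f"{gid}\t1.0\n")
    baits_path = out / "baits.tsv"
    baits_path.write_text(
        "".join(f"{b.id}\t{b.sequence}\t1\n" for b in baits + [ins_bait, del_bait])
    )

    sam_path = out / "candidates.sam"
    header = {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": gid, "LN": genome_length}]}
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        for b in baits:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = b.id
            a.flag = 0
            a.reference_id = 0
            a.reference_start = window_start
            a.mapping_quality = 42
            a.cigarstring = f"{bait_length}M"
            a.query_sequence = b.sequence
            sam.write(a)
        for b, cigar in (
            (ins_bait, f"40M1I{bait_length - 41}M"),
            (del_bait, f"50M1D{bait_length - 50}M"),
        ):
            a = pysam.AlignedSegment(sam.header)
            a.query_name = b.id
            a.flag = 0
            a.reference_id = 0
            a.reference_start = window_start
            a.mapping_quality = 42
            a.cigarstring = cigar
            a.query_sequence = b.sequence
            sam.write(a)

    genomes = [ReferenceGenome(id=gid, records={gid: genome}, abundance=1.0)]
    return ToyCommunity(
        fasta_path=fasta_path,
        abundance_path=abundance_path,
        baits_path=baits_path,
        sam_path=sam_path,
        truth=[],
        genomes=genomes,
        baits=baits + [ins_bait, del_bait],
    )
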