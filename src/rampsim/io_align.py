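"""Input/output and alignment parsing.

Reads reference communities (FASTA + abundance table) and bait panels
(TSV), converts SAM bait-to-target alignments into filtered candidate
hybridization sites, and writes/reads sampled fragments as FASTA.

Coordinates are 0-based half-open throughout; SAM's 1-based positions are
converted on read (pysam already does this).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger("rampsim")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")

FORWARD = "forward"
REVERSE = "reverse"


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """One organism of the community.

    An organism may span several FASTA records (chromosomes, plasmids); all
    records share the organism's single relative genomic abundance ``a_g``.
    """

    id: str
    records: dict[str, str]  # record id -> sequence, insertion-ordered
    abundance: float

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"genome {self.id!r} has no sequence records")
        for rid, seq in self.records.items():
            if len(seq) < 1:
                raise ValueError(f"record {rid!r} of genome {self.id!r} is empty")
        if not 0.0 < self.abundance <= 1.0:
            raise ValueError(
                f"genome {self.id!r}: abundance must be in (0, 1], got {self.abundance}"
            )

    @property
    def length(self) -> int:
        """Total length across all records."""
        return sum(len(s) for s in self.records.values())

    @property
    def sequence(self) -> str:
        """Sequence of a single-record genome (error on multi-record ones)."""
        if len(self.records) != 1:
            raise ValueError(
                f"genome {self.id!r} has {len(self.records)} records; "
                "address them individually via .records"
            )
        return next(iter(self.records.values()))


@dataclass(frozen=True)
class Bait:
    """An oligonucleotide probe with relative concentration ``c_p``."""

    id: str
    sequence: str
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(f"bait {self.id!r}: sequence shorter than 2 bases")
        if self.concentration <= 0:
            raise ValueError(f"bait {self.id!r}: concentration must be > 0")


@dataclass
class HybridizationSite:
    """One candidate bait-binding locus on a reference record.

    ``match_mask`` is indexed along the reference interval [start, end) and
    is true where the strand-oriented bait base Watson-Crick pairs the
    reference base. ``energy`` (kcal/mol) is filled by the thermodynamic
    model after parsing.
    """

    bait_id: str
    genome_id: str
    record_id: str
    start: int
    end: int
    strand: str  # FORWARD or REVERSE
    match_mask: np.ndarray
    mismatch_count: int
    site_sequence: str = ""  # strand-oriented reference subsequence
    bait_sequence: str = ""  # aligned bait bases, same orientation
    energy: float = float("nan")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


def _read_two_column_tsv(path: str | Path, what: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{what} {path}: line {lineno} has <2 columns")
        out[fields[0]] = fields[1]
    return out


def read_community(
    fasta_path: str | Path,
    abundance_table: str | Path | Mapping[str, float],
    record_to_genome: Mapping[str, str] | None = None,
) -> list[ReferenceGenome]:
    """Load reference genomes with normalized relative abundances.

    ``abundance_table`` maps genome id to a (possibly unnormalized) abundance;
    it may be a TSV path (``genome_id<TAB>abundance``) or a mapping.
    ``record_to_genome`` optionally groups FASTA records (chromosomes,
    plasmids) under an organism id sharing one abundance; by default each
    record is its own genome.
    """
    if isinstance(abundance_table, (str, Path)):
        raw = _read_two_column_tsv(abundance_table, "abundance table")
        abundances = {k: float(v) for k, v in raw.items()}
    else:
        abundances = {k: float(v) for k, v in abundance_table.items()}

    grouped: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {rec.id!r}: non-ACGTN characters {sorted(bad)}"
            )
        gid = (record_to_genome or {}).get(rec.id, rec.id)
        if gid not in abundances:
            raise ValueError(f"no abundance entry for record/genome {gid!r}")
        grouped.setdefault(gid, {})[rec.id] = seq

    total = sum(abundances[g] for g in grouped)
    if total <= 0:
        raise ValueError("abundances sum to zero")
    return [
        ReferenceGenome(id=g, records=recs, abundance=abundances[g] / total)
        for g, recs in grouped.items()
    ]


def read_baits(path: str | Path) -> list[Bait]:
    """Read a bait panel TSV: ``bait_id<TAB>sequence[<TAB>concentration]``.

    Missing concentration columns default to 1.0 (a uniform panel).
    """
    baits: list[Bait] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"bait table {path}: line {lineno} has <2 columns")
        conc = float(fields[2]) if len(fields) > 2 else 1.0
        baits.append(Bait(id=fields[0], sequence=fields[1].upper(), concentration=conc))
    return baits


_INDEL_OPS = {1, 2, 3}  # I, D, N
_MATCH_OPS = {0, 7, 8}  # M, =, X
_CLIP_OPS = {4, 5}  # S, H


def parse_candidate_sites(
    sam_path: str | Path,
    baits: Sequence[Bait],
    genomes: Sequence[ReferenceGenome],
    max_mismatches: int = 40,
) -> list[HybridizationSite]:
    """Parse a SAM file of bait-to-reference alignments into candidate sites.

    All mapped records are retained equally (primary, secondary,
    supplementary — secondaries carry off-target sites), except records with
    any CIGAR insertion/deletion and records exceeding ``max_mismatches``.
    Soft/hard-clipped bait ends are excluded from the site span. The match
    mask is recomputed by comparing the strand-oriented bait sequence (from
    the bait table, not the SAM SEQ field, which secondaries may omit)
    against the reference subsequence; an N on either side counts as a
    mismatch.
    """
    bait_by_id = {b.id: b for b in baits}
    record_lookup: dict[str, tuple[str, str]] = {}
    for g in genomes:
        for rid, seq in g.records.items():
            record_lookup[rid] = (g.id, seq)

    sites: list[HybridizationSite] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            bait = bait_by_id.get(aln.query_name)
            if bait is None:
                raise ValueError(
                    f"SAM query {aln.query_name!r} not present in the bait table"
                )
            if aln.reference_name not in record_lookup:
                raise ValueError(
                    f"SAM reference {aln.reference_name!r} absent from the FASTA"
                )
            cig = aln.cigartuples or []
            if any(op in _INDEL_OPS for op, _ in cig):
                continue
            if any(op not in _MATCH_OPS | _CLIP_OPS for op, _ in cig):
                raise ValueError(
                    f"unsupported CIGAR {aln.cigarstring!r} for {aln.query_name!r}"
                )
            span = sum(n for op, n in cig if op in _MATCH_OPS)
            if span == 0:
                continue
            clip_left = 0
            i = 0
            while i < len(cig) and cig[i][0] in _CLIP_OPS:
                clip_left += cig[i][1]
                i += 1
            clip_right = 0
            j = len(cig) - 1
            while j >= 0 and cig[j][0] in _CLIP_OPS:
                clip_right += cig[j][1]
                j -= 1

            genome_id, ref_seq = record_lookup[aln.reference_name]
            start = aln.reference_start
            end = start + span
            if not (0 <= start < end <= len(ref_seq)):
                raise ValueError(
                    f"alignment of {aln.query_name!r} at [{start},{end}) exceeds "
                    f"reference {aln.reference_name!r} (length {len(ref_seq)})"
                )
            strand = REVERSE if aln.is_reverse else FORWARD
            oriented = revcomp(bait.sequence) if aln.is_reverse else bait.sequence
            aligned_bait = oriented[clip_left : len(oriented) - clip_right]
            if len(aligned_bait) != span:
                raise ValueError(
                    f"CIGAR span {span} of {aln.query_name!r} does not match the "
                    f"bait length {len(bait.sequence)} after clipping"
                )
            ref_sub = ref_seq[start:end]
            mask = np.fromiter(
                (
                    a == b and a != "N"
                    for a, b in zip(aligned_bait, ref_sub)
                ),
                dtype=bool,
                count=span,
            )
            mismatches = int(span - mask.sum())
            if mismatches > max_mismatches:
                continue
            sites.append(
                HybridizationSite(
                    bait_id=bait.id,
                    genome_id=genome_id,
                    record_id=aln.reference_name,
                    start=start,
                    end=end,
                    strand=strand,
                    match_mask=mask,
                    mismatch_count=mismatches,
                    site_sequence=ref_sub,
                    bait_sequence=aligned_bait,
                )
            )
    return sites


# --- fragment FASTA ---------------------------------------------------------

_ORIGINS = ("capture", "background")


def write_fragments_fasta(
    fragments: Iterable,
    genomes: Sequence[ReferenceGenome],
    out_path: str | Path,
) -> None:
    """Write sampled fragments as FASTA.

    The header is machine-parseable: ``>frag<i> genome=<id> record=<id>
    start=<s> end=<e> origin=<capture|background> bait=<id|.> site=<n|.>``.
    Sequences are forward-strand reference subsequences (fragments are
    double-stranded; strand is a sequencing-level concern).
    """
    record_lookup = {
        rid: seq for g in genomes for rid, seq in g.records.items()
    }
    with open(out_path, "w") as fh:
        for i, frag in enumerate(fragments):
            seq = record_lookup[frag.record_id]
            if not (0 <= frag.start < frag.end <= len(seq)):
                raise ValueError(
                    f"fragment [{frag.start},{frag.end}) out of bounds on "
                    f"record {frag.record_id!r}"
                )
            bait = frag.bait_id if frag.bait_id is not None else "."
            site = frag.site_index if frag.site_index is not None else "."
            fh.write(
                f">frag{i} genome={frag.genome_id} record={frag.record_id} "
                f"start={frag.start} end={frag.end} origin={frag.origin} "
                f"bait={bait} site={site}\n"
            )
            fh.write(seq[frag.start : frag.end] + "\n")


def read_fragments_fasta(path: str | Path) -> list:
    """Parse a fragment FASTA written by :func:`write_fragments_fasta`."""
    from .sampler import FragmentRecord

    fragments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = dict(part.split("=", 1) for part in rec.description.split()[1:])
        origin = kv["origin"]
        if origin not in _ORIGINS:
            raise ValueError(f"unknown fragment origin {origin!r}")
        fragments.append(
            FragmentRecord(
                genome_id=kv["genome"],
                record_id=kv["record"],
                start=int(kv["start"]),
                end=int(kv["end"]),
                origin=origin,
                bait_id=None if kv["bait"] == "." else kv["bait"],
                site_index=None if kv["site"] == "." else int(kv["site"]),
            )
        )
    return fragments
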