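"""Candidate read-pair extraction and quality filters.

The detection method only realigns reads the primary aligner could not place
consistently: pairs whose mates mapped to different chromosomes
("discordant") and pairs with one or both mates unmapped.  This module pulls
those pairs out of a coordinate- or name-sorted SAM/BAM, estimates the
library's insert-size distribution and mean summed base quality (both used
as downstream thresholds), and applies the per-read model-alignment filters:
keep a read only if its summed Phred exceeds the library mean and more than
half of its bases are aligned according to the CIGAR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .refmodel import reverse_complement

__all__ = [
    "ReadPairRecord",
    "LibraryStats",
    "compute_library_stats",
    "extract_candidates",
    "write_candidate_fastq",
    "filter_model_alignments",
    "summed_phred",
    "cigar_matched_fraction",
]

logger = logging.getLogger(__name__)


@dataclass
class MateInfo:
    mapped: bool
    chrom: str | None
    pos: int | None          # 1-based leftmost, None if unmapped
    mapq: int
    cigar: str | None
    seq: str                 # original read orientation
    qual: str


@dataclass
class ReadPairRecord:
    """One candidate paired-end observation in original read orientation."""

    read_id: str
    mate1: MateInfo
    mate2: MateInfo
    insert_size: int | None  # signed template length when both mates mapped together

    @property
    def is_discordant(self) -> bool:
        return (
            self.mate1.mapped
            and self.mate2.mapped
            and self.mate1.chrom != self.mate2.chrom
        )

    @property
    def any_unmapped(self) -> bool:
        return not (self.mate1.mapped and self.mate2.mapped)


@dataclass
class LibraryStats:
    """Insert-size moments and mean summed Phred of the sequencing library."""

    mean_insert: float
    sd_insert: float
    mean_summed_phred: float
    n_pairs_sampled: int = 0
    n_reads_sampled: int = 0

    def __post_init__(self) -> None:
        if self.sd_insert < 0 or self.mean_summed_phred < 0:
            raise ValueError("library statistics must be non-negative")

    def to_dict(self) -> dict:
        return {
            "mean_insert": self.mean_insert,
            "sd_insert": self.sd_insert,
            "mean_summed_phred": self.mean_summed_phred,
            "n_pairs_sampled": self.n_pairs_sampled,
            "n_reads_sampled": self.n_reads_sampled,
        }


def summed_phred(record_or_quals) -> int:
    """Sum of base quality scores of one read."""
    quals = getattr(record_or_quals, "query_qualities", record_or_quals)
    if quals is None:
        return 0
    return int(sum(quals))


def cigar_matched_fraction(record: "pysam.AlignedSegment") -> float:
    """Fraction of read bases aligned (CIGAR M/=/X) over full read length."""
    if record.cigartuples is None:
        return 0.0
    matched = sum(ln for op, ln in record.cigartuples if op in (0, 7, 8))
    read_len = record.infer_read_length() or record.query_length
    if not read_len:
        return 0.0
    return matched / read_len


def _is_primary_paired(rec: "pysam.AlignedSegment") -> bool:
    return rec.is_paired and not rec.is_secondary and not rec.is_supplementary


def compute_library_stats(
    bam_path, sample_size: int = 1_000_000, seed: int = 0
) -> LibraryStats:
    """Insert mean/sd and mean summed Phred over properly-paired primary reads.

    Reads are reservoir-sampled (seeded) up to ``sample_size`` so the result
    is deterministic and bounded in memory at any input scale.  Insert sizes
    use the absolute SAM template length, counted once per pair.
    """
    rng = np.random.default_rng(seed)
    inserts: list[int] = []
    phreds: list[int] = []
    n_insert_seen = 0
    n_read_seen = 0
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as fh:
        for rec in fh:
            if not (_is_primary_paired(rec) and rec.is_proper_pair and not rec.is_unmapped):
                continue
            n_read_seen += 1
            sp = summed_phred(rec)
            if len(phreds) < sample_size:
                phreds.append(sp)
            else:
                j = int(rng.integers(n_read_seen))
                if j < sample_size:
                    phreds[j] = sp
            if rec.template_length > 0:
                n_insert_seen += 1
                if len(inserts) < sample_size:
                    inserts.append(rec.template_length)
                else:
                    j = int(rng.integers(n_insert_seen))
                    if j < sample_size:
                        inserts[j] = rec.template_length
    if not inserts:
        raise ValueError(f"{bam_path}: no properly-paired primary alignments")
    arr = np.abs(np.asarray(inserts, dtype=float))
    return LibraryStats(
        mean_insert=float(arr.mean()),
        sd_insert=float(arr.std(ddof=0)),
        mean_summed_phred=float(np.mean(phreds)),
        n_pairs_sampled=len(inserts),
        n_reads_sampled=len(phreds),
    )


def _mate_info(rec: "pysam.AlignedSegment") -> MateInfo:
    seq = rec.query_sequence or ""
    qual = (
        "".join(chr(q + 33) for q in rec.query_qualities)
        if rec.query_qualities is not None
        else "I" * len(seq)
    )
    if not rec.is_unmapped and rec.is_reverse:
        # restore the orientation in which the read was sequenced
        seq = reverse_complement(seq)
        qual = qual[::-1]
    return MateInfo(
        mapped=not rec.is_unmapped,
        chrom=rec.reference_name if not rec.is_unmapped else None,
        pos=rec.reference_start + 1 if not rec.is_unmapped else None,
        mapq=rec.mapping_quality,
        cigar=rec.cigarstring,
        seq=seq,
        qual=qual,
    )


def extract_candidates(bam_path) -> list[ReadPairRecord]:
    """Pairs whose mates mapped to different chromosomes or are (half-)unmapped.

    Secondary and supplementary records are ignored for the pairing decision;
    orphaned mates (only one primary record present) are logged and skipped.
    """
    pending: dict[str, "pysam.AlignedSegment"] = {}
    out: list[ReadPairRecord] = []
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as fh:
        for rec in fh:
            if not _is_primary_paired(rec):
                continue
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = rec
                continue
            first, second = (other, rec) if other.is_read1 else (rec, other)
            m1, m2 = _mate_info(first), _mate_info(second)
            if not ((m1.mapped and m2.mapped and m1.chrom != m2.chrom) or not (m1.mapped and m2.mapped)):
                continue  # concordant same-chromosome pair
            insert = None
            if m1.mapped and m2.mapped and m1.chrom == m2.chrom:
                insert = first.template_length
            out.append(ReadPairRecord(rec.query_name, m1, m2, insert))
    if pending:
        logger.warning("skipped %d orphaned mates without a pair member", len(pending))
    return out


def write_candidate_fastq(records, prefix) -> tuple[str, str, str]:
    """Write candidate pairs as a FASTQ pair plus a provenance TSV."""
    fq1, fq2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
    prov = f"{prefix}_provenance.tsv"
    with open(fq1, "w") as f1, open(fq2, "w") as f2, open(prov, "w") as pv:
        pv.write("read_id\tchrom1\tpos1\tmapq1\tchrom2\tpos2\tmapq2\tclass\n")
        for rec in records:
            f1.write(f"@{rec.read_id}/1\n{rec.mate1.seq}\n+\n{rec.mate1.qual}\n")
            f2.write(f"@{rec.read_id}/2\n{rec.mate2.seq}\n+\n{rec.mate2.qual}\n")
            klass = "discordant" if rec.is_discordant else "unmapped"
            pv.write(
                f"{rec.read_id}\t{rec.mate1.chrom or '.'}\t{rec.mate1.pos or 0}\t{rec.mate1.mapq}\t"
                f"{rec.mate2.chrom or '.'}\t{rec.mate2.pos or 0}\t{rec.mate2.mapq}\t{klass}\n"
            )
    return fq1, fq2, prov


def filter_model_alignments(records, stats: LibraryStats) -> list:
    """Quality filter for alignments against a model reference.

    Keeps records whose summed Phred strictly exceeds the library mean and
    whose CIGAR-matched fraction strictly exceeds 0.5 (a read with 50% or
    less of its bases aligned is discarded).  Mapped records without a CIGAR
    are dropped with a warning.  The filter is idempotent.
    """
    kept = []
    n_no_cigar = 0
    for rec in records:
        if rec.is_unmapped:
            continue
        if rec.cigartuples is None:
            n_no_cigar += 1
            continue
        if summed_phred(rec) <= stats.mean_summed_phred:
            continue
        if cigar_matched_fraction(rec) <= 0.5:
            continue
        kept.append(rec)
    if n_no_cigar:
        logger.warning("dropped %d mapped records lacking a CIGAR", n_no_cigar)
    return kept
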