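import numpy as np
import pysam
import pytest

from silicosv.karyoband import BandTable, BreakpointFrequencyTable, CytoBand


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_table():
    """Two 30 kb chromosomes with three 10 kb bands each."""
    bands = []
    for chrom in ("1", "2"):
        for i, name in enumerate(("p11", "q11", "q12")):
            bands.append(CytoBand(chrom, i * 10_000 + 1, (i + 1) * 10_000, name))
    return BandTable(bands, genome_label="test")


@pytest.fixture
def small_genome(small_table, rng):
    return {
        chrom: "".join("ACGT"[b] for b in rng.integers(0, 4, 30_000))
        for chrom in ("1", "2")
    }


@pytest.fixture
def uniform_freqs(small_table):
    return BreakpointFrequencyTable({}, small_table.labels, pseudocount=1.0)


def make_sam(path, references, records):
    """Write a small SAM from dict-style record specs.

    Each record: dict with qname and optional keys chrom, pos (1-based),
    cigar, mapq, seq, qual (int or str), flags (read1, reverse, proper,
    unmapped, mate_*), tlen.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": name, "LN": length} for name, length in references],
        }
    )
    tid = {name: i for i, (name, _) in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for spec in records:
            rec = pysam.AlignedSegment(header)
            rec.query_name = spec["qname"]
            seq = spec.get("seq", "A" * 100)
            rec.query_sequence = seq
            qual = spec.get("qual", 30)
            if isinstance(qual, int):
                rec.query_qualities = [qual] * len(seq)
            else:
                rec.query_qualities = pysam.qualitystring_to_array(qual)
            rec.is_paired = spec.get("paired", True)
            rec.is_read1 = spec.get("read1", True)
            rec.is_read2 = not rec.is_read1 if rec.is_paired else False
            if spec.get("unmapped"):
                rec.is_unmapped = True
            else:
                rec.reference_id = tid[spec.get("chrom", references[0][0])]
                rec.reference_start = spec.get("pos", 1) - 1
                rec.cigarstring = spec.get("cigar", f"{len(seq)}M")
                rec.mapping_quality = spec.get("mapq", 60)
                rec.is_reverse = spec.get("reverse", False)
            rec.is_proper_pair = spec.get("proper", False)
            rec.is_secondary = spec.get("secondary", False)
            if spec.get("mate_unmapped"):
                rec.mate_is_unmapped = True
            elif "mate_chrom" in spec:
                rec.next_reference_id = tid[spec["mate_chrom"]]
                rec.next_reference_start = spec.get("mate_pos", 1) - 1
            rec.template_length = spec.get("tlen", 0)
            out.write(rec)
    return str(path)
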