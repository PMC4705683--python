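"""In silico model references: two-band fusion sequences with junction metadata.

A model reference concatenates the sequence of two cytogenetic bands from
different chromosomes, simulating the product of a recombination event such
as a translocation.  Reads that truly derive from a breakpoint between the
two bands align to such a reference as an ordinary pair whose mates fall on
either side of the junction, which is what the downstream scoring measures.

The junction offset is the 1-based position of the last base contributed by
the first band; e.g. joining 16q13 (56700001-57400000, 700 kb) to 8q24
places the junction at exactly 700,000 bp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .karyoband import CytoBand

__all__ = ["InSilicoReference", "build_reference", "write_reference_set", "read_manifest"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ORIENTATIONS = ("ff", "fr", "rf", "rr")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceBuildError(ValueError):
    pass


@dataclass
class InSilicoReference:
    """A two-band concatenated model sequence with its junction offset."""

    name: str
    band_a: CytoBand
    band_b: CytoBand
    sequence: str
    junction_offset: int
    segment_lengths: tuple[int, int]
    n_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.junction_offset != self.segment_lengths[0]:
            raise ReferenceBuildError("junction offset must equal first segment length")
        if len(self.sequence) != sum(self.segment_lengths):
            raise ReferenceBuildError("sequence length must equal summed segment lengths")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def band_pair(self) -> frozenset[str]:
        return frozenset((self.band_a.label, self.band_b.label))

    @property
    def fasta_description(self) -> str:
        return (
            f"junction={self.junction_offset} bands={self.band_a.label},{self.band_b.label} "
            f"lengths={self.segment_lengths[0]},{self.segment_lengths[1]}"
        )


def default_name(band_a: CytoBand, band_b: CytoBand) -> str:
    """Translocation-style name, e.g. ``t(16;8)(q13;q24)``."""
    return f"t({band_a.chrom};{band_b.chrom})({band_a.name};{band_b.name})"


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start..end] (1-based inclusive) from a dict of
    strings or a pyfaidx.Fasta-like mapping."""
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise ReferenceBuildError(f"chromosome {chrom!r} absent from genome") from exc
    if end > len(record):
        raise ReferenceBuildError(
            f"band interval {chrom}:{start}-{end} exceeds chromosome length {len(record)}"
        )
    return str(record[start - 1 : end]).upper()


def build_reference(
    genome,
    band_a: CytoBand,
    band_b: CytoBand,
    orientation: str = "ff",
    name: str | None = None,
) -> InSilicoReference:
    """Concatenate band A and band B sequence into one model reference.

    ``orientation`` selects the strand of each segment (``"ff"`` joins
    forward-strand A end-to-start to forward-strand B, the default; ``"fr"``,
    ``"rf"``, ``"rr"`` reverse-complement the corresponding segment).  Only
    inter-chromosomal models are supported.
    """
    if orientation not in ORIENTATIONS:
        raise ReferenceBuildError(f"orientation must be one of {ORIENTATIONS}")
    if band_a.chrom == band_b.chrom:
        raise ReferenceBuildError(
            "intra-chromosomal models are out of scope: both bands on "
            f"chromosome {band_a.chrom}"
        )
    seg_a = _fetch(genome, band_a.chrom, band_a.start, band_a.end)
    seg_b = _fetch(genome, band_b.chrom, band_b.start, band_b.end)
    if not seg_a or not seg_b:
        raise ReferenceBuildError("zero-length band segment")
    if orientation[0] == "r":
        seg_a = reverse_complement(seg_a)
    if orientation[1] == "r":
        seg_b = reverse_complement(seg_b)
    sequence = seg_a + seg_b
    n_fraction = (sequence.count("N") + sequence.count("n")) / len(sequence)
    return InSilicoReference(
        name=name or default_name(band_a, band_b),
        band_a=band_a,
        band_b=band_b,
        sequence=sequence,
        junction_offset=len(seg_a),
        segment_lengths=(len(seg_a), len(seg_b)),
        n_fraction=n_fraction,
    )


def _safe_filename(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def write_reference_set(refs, out_dir, n_flag_threshold: float = 0.5) -> str:
    """Write one FASTA per reference plus a manifest TSV; returns manifest path.

    N-heavy references (fraction of N above ``n_flag_threshold``, e.g.
    centromeres) are flagged in the manifest but kept: centromeric models are
    legitimate candidates and are scored like any other.
    """
    refs = list(refs)
    names = [r.name for r in refs]
    if len(set(names)) != len(names):
        raise ReferenceBuildError("duplicate reference names in set")
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as man:
        man.write(
            "name\tfasta\tband_a\tband_b\tjunction_offset\tlen_a\tlen_b\tn_fraction\tn_heavy\n"
        )
        for ref in refs:
            fasta = _safe_filename(ref.name) + ".fa"
            with open(os.path.join(out_dir, fasta), "w") as fh:
                fh.write(f">{ref.name} {ref.fasta_description}\n")
                seq = ref.sequence
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
            man.write(
                f"{ref.name}\t{fasta}\t{ref.band_a.label}\t{ref.band_b.label}\t"
                f"{ref.junction_offset}\t{ref.segment_lengths[0]}\t{ref.segment_lengths[1]}\t"
                f"{ref.n_fraction:.6f}\t{int(ref.n_fraction > n_flag_threshold)}\n"
            )
    return manifest_path


def read_manifest(manifest_path) -> list[dict]:
    """Load the reference-set manifest written by :func:`write_reference_set`."""
    rows: list[dict] = []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            row["junction_offset"] = int(row["junction_offset"])
            row["len_a"] = int(row["len_a"])
            row["len_b"] = int(row["len_b"])
            row["n_fraction"] = float(row["n_fraction"])
            row["n_heavy"] = bool(int(row["n_heavy"]))
            rows.append(row)
    return rows
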