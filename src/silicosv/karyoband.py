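"""Cytogenetic band tables and per-band breakpoint frequencies.

The human ideogram at major-band resolution has 320 bands (e.g. ``16q13``);
every band has been reported in at least one cancer karyotype, so any pair of
bands is a candidate recombination to model.  This module loads and validates
band definitions (UCSC ``cytoBand``-style TSV or this package's 1-based
dialect), collapses sub-bands (``q13.2``) to their major band, enumerates the
candidate band pairs, and turns observed per-band breakpoint counts into
smoothed probabilities used by the reference-selection optimizer.

Coordinates are stored 1-based inclusive throughout; UCSC input (0-based,
half-open) is converted on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

__all__ = [
    "CytoBand",
    "BandTable",
    "BreakpointFrequencyTable",
    "load_band_table",
    "packaged_band_table",
    "enumerate_band_pairs",
    "band_probability",
]

PACKAGE_DIALECT_HEADER = "#coords=1-based-inclusive"

# chromosome arm + band grammar: arm letter, major band number, optional
# sub-band suffix (".1", ".12", ...)
_BAND_NAME_RE = re.compile(r"^(?P<arm>[pq])(?P<major>\d+)(?P<sub>\.\d+)?$")

# chromosomes eligible for band enumeration: autosomes + sex chromosomes.
_CANONICAL_CHROM_RE = re.compile(r"^(\d{1,2}|X|Y)$")


class BandValidationError(ValueError):
    """Raised when a band table or frequency table violates its invariants."""


@dataclass(frozen=True, order=True)
class CytoBand:
    """One cytogenetic band, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    name: str
    stain: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise BandValidationError(f"band {self.label}: start {self.start} < 1")
        if self.end < self.start:
            raise BandValidationError(
                f"band {self.label}: end {self.end} < start {self.start}"
            )
        if _BAND_NAME_RE.match(self.name) is None:
            raise BandValidationError(f"invalid band name {self.name!r}")

    @property
    def label(self) -> str:
        """Full band label, e.g. ``16q13``."""
        return f"{self.chrom}{self.name}"

    @property
    def arm(self) -> str:
        return self.name[0]

    @property
    def major_name(self) -> str:
        """Band name truncated to major resolution (``q13.2`` -> ``q13``)."""
        return self.name.split(".")[0]

    @property
    def is_major(self) -> bool:
        return "." not in self.name

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix; keep the bare chromosome token."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class BandTable:
    """Ordered, validated collection of cytogenetic bands for one assembly."""

    def __init__(self, bands: Iterable[CytoBand], genome_label: str = "unknown"):
        self.bands: list[CytoBand] = sorted(
            bands, key=lambda b: (_chrom_sort_key(b.chrom), b.start)
        )
        self.genome_label = genome_label
        self._by_label: dict[str, CytoBand] = {}
        for band in self.bands:
            if band.label in self._by_label:
                raise BandValidationError(f"duplicate band label {band.label}")
            self._by_label[band.label] = band
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        prev: CytoBand | None = None
        for band in self.bands:
            if prev is not None and band.chrom == prev.chrom and band.start <= prev.end:
                raise BandValidationError(
                    f"overlapping bands on chromosome {band.chrom}: "
                    f"{prev.label} and {band.label}"
                )
            prev = band

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self) -> Iterator[CytoBand]:
        return iter(self.bands)

    def __getitem__(self, label: str) -> CytoBand:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    @property
    def major_count(self) -> int:
        """Number of major-resolution bands in the table."""
        return sum(1 for b in self.bands if b.is_major)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.bands:
            seen.setdefault(b.chrom, None)
        return list(seen)

    def collapse_to_major(self) -> "BandTable":
        """Merge sub-bands into their major band spanning min(start)..max(end)."""
        merged: dict[tuple[str, str], list[CytoBand]] = {}
        for band in self.bands:
            merged.setdefault((band.chrom, band.major_name), []).append(band)
        out = []
        for (chrom, major), group in merged.items():
            stains = {g.stain for g in group if g.stain is not None}
            out.append(
                CytoBand(
                    chrom=chrom,
                    start=min(g.start for g in group),
                    end=max(g.end for g in group),
                    name=major,
                    stain=stains.pop() if len(stains) == 1 else None,
                )
            )
        return BandTable(out, genome_label=self.genome_label)

    def to_tsv(self, path) -> None:
        """Serialize in the package dialect (1-based inclusive, with header)."""
        with open(path, "w") as fh:
            fh.write(PACKAGE_DIALECT_HEADER + "\n")
            for b in self.bands:
                stain = b.stain if b.stain is not None else ""
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}\t{stain}\n")


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    if chrom.isdigit():
        return (int(chrom), "")
    return (100 + {"X": 0, "Y": 1}.get(chrom, 9), chrom)


def load_band_table(path, collapse: bool = True, genome_label: str | None = None) -> BandTable:
    """Load a band TSV in either the UCSC cytoBand dialect or the package dialect.

    UCSC rows are ``chrom  start0  end  name  stain`` with 0-based half-open
    coordinates; the package dialect declares itself with a
    ``#coords=1-based-inclusive`` header line and stores 1-based inclusive
    coordinates.  Mitochondrial and unplaced contigs are skipped.  With
    ``collapse=True`` (the default) sub-bands are merged into major bands.
    """
    bands: list[CytoBand] = []
    one_based = False
    label = genome_label or "unknown"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.strip() == PACKAGE_DIALECT_HEADER:
                    one_based = True
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BandValidationError(f"{path}:{lineno}: expected >= 4 columns")
            chrom = normalize_chrom(fields[0])
            if not _CANONICAL_CHROM_RE.match(chrom):
                if chrom.startswith(("M", "Un")) or "_" in fields[0]:
                    continue  # mitochondrial / unplaced: excluded by design
                raise BandValidationError(f"{path}:{lineno}: unknown chromosome {fields[0]!r}")
            start, end = int(fields[1]), int(fields[2])
            if not one_based:
                start += 1  # 0-based half-open -> 1-based inclusive
            stain = fields[4] if len(fields) > 4 and fields[4] else None
            bands.append(CytoBand(chrom, start, end, fields[3], stain))
    if not bands:
        raise BandValidationError(f"{path}: no usable band rows")
    table = BandTable(bands, genome_label=label)
    if collapse:
        table = table.collapse_to_major()
    return table


def packaged_band_table() -> BandTable:
    """The packaged GRCh37-like major-band table (320 major bands).

    The table is a synthetic stand-in for the UCSC cytoBand ideogram: real
    hg19 chromosome lengths and standard major-band names, proportional
    band coordinates, with 16q13 and 8q24 placed at their published
    positions.  See ``data/grch37_major_bands.synthetic.tsv``.
    """
    ref = resources.files("silicosv.data").joinpath("grch37_major_bands.synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_band_table(path, collapse=True, genome_label="GRCh37-synthetic")


def enumerate_band_pairs(table: BandTable) -> list[tuple[CytoBand, CytoBand]]:
    """All unordered pairs of distinct bands; n bands yield n(n-1)/2 pairs."""
    if len(table) < 2:
        raise BandValidationError("band pair enumeration requires >= 2 bands")
    bands = table.bands
    return [(bands[i], bands[j]) for i in range(len(bands)) for j in range(i + 1, len(bands))]


def inter_chromosomal_pairs(table: BandTable) -> list[tuple[CytoBand, CytoBand]]:
    """Unordered band pairs restricted to different chromosomes."""
    return [(a, b) for a, b in enumerate_band_pairs(table) if a.chrom != b.chrom]


class BreakpointFrequencyTable:
    """Observed breakpoint counts per band, smoothed to probabilities.

    Counts come from karyotype databases tabulated upstream; bands absent
    from the count table receive a pseudocount (default 1) so that rarely
    reported bands keep nonzero selection probability.
    """

    def __init__(
        self,
        counts: Mapping[str, int],
        band_labels: Iterable[str],
        pseudocount: float = 1.0,
    ):
        self.band_labels = list(band_labels)
        universe = set(self.band_labels)
        for label, count in counts.items():
            if label not in universe:
                raise BandValidationError(f"frequency entry for unknown band {label!r}")
            if count < 0:
                raise BandValidationError(f"negative count for band {label!r}")
        self.counts = {label: int(counts.get(label, 0)) for label in self.band_labels}
        self.pseudocount = float(pseudocount)
        self.total = sum(self.counts.values())
        denom = self.total + self.pseudocount * len(self.band_labels)
        if denom <= 0:
            raise BandValidationError("frequency table has zero total and no pseudocount")
        self._denom = denom

    @classmethod
    def from_tsv(cls, path, table: BandTable, pseudocount: float = 1.0) -> "BreakpointFrequencyTable":
        """Read a two-column TSV: band label, observed breakpoint count."""
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, count = line.split("\t")[:2]
                counts[label] = counts.get(label, 0) + int(count)
        return cls(counts, table.labels, pseudocount=pseudocount)

    def probability(self, band: str) -> float:
        if band not in self.counts:
            raise BandValidationError(f"band {band!r} not in frequency table universe")
        return (self.counts[band] + self.pseudocount) / self._denom

    def probabilities(self) -> dict[str, float]:
        return {label: self.probability(label) for label in self.band_labels}


def band_probability(freqs: BreakpointFrequencyTable, band: str) -> float:
    """Smoothed probability that a breakpoint involves ``band``."""
    return freqs.probability(band)
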