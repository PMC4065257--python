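"""Genome and polymorphism-track input/output.

Coordinate conventions
----------------------
Externally (VCF, the TSV track dialect, reports) positions are 1-based
inclusive, following VCF: an Indel record anchors at the first reference
base shared between the two alleles.  Internally every computation uses
0-based half-open intervals.  :class:`IndelRecord` owns the conversion:
``ref_start``/``ref_end`` give the record's reference footprint (the
reference bases covered by the REF allele) as a 0-based half-open pair.

TSV track dialect
-----------------
A plain-text export of a genome-browser polymorphism track:

* tab-separated, exactly five columns: chrom, pos, ref, alt, id;
* ``pos`` is 1-based, VCF-anchored (first base of REF);
* lines starting with ``#`` are comments and are ignored;
* no quoting, no escaping, one record per line.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
#: Variant alleles are unambiguous nucleotides only.
VALID_ALLELE_BASES = frozenset("ACGT")

TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "id")


class TrackValidationError(ValueError):
    """A polymorphism record is inconsistent with the reference genome."""


class FastaParseError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class ReferenceGenome:
    """A reference assembly held fully in memory (uppercase A/C/G/T/N)."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FastaParseError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Reference slice over a 0-based half-open interval."""
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]


@dataclass(frozen=True)
class IndelRecord:
    """One biallelic polymorphism annotated against the reference.

    ``pos`` is the 1-based position of the first REF base (VCF anchor).
    SNPs are represented with single-base REF and ALT; Indels carry the
    shared anchor base, so a 17-bp deletion has an 18-bp REF and 1-bp ALT.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        for label, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele or set(allele) - VALID_ALLELE_BASES:
                raise ValueError(
                    f"{label} allele {allele!r} at {self.chrom}:{self.pos} "
                    "must be a non-empty A/C/G/T string"
                )

    @property
    def net_length(self) -> int:
        """Absolute allele-length difference in bp (0 for SNPs)."""
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def signed_net_length(self) -> int:
        """len(ALT) - len(REF): negative for deletions, positive for insertions."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return self.net_length >= 1

    @property
    def is_deletion(self) -> bool:
        return len(self.alt_allele) < len(self.ref_allele)

    @property
    def is_insertion(self) -> bool:
        return len(self.alt_allele) > len(self.ref_allele)

    @property
    def ref_start(self) -> int:
        """0-based start of the reference footprint."""
        return self.pos - 1

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the reference footprint."""
        return self.pos - 1 + len(self.ref_allele)

    def overlaps(self, start: int, end: int) -> bool:
        """True if the reference footprint intersects [start, end)."""
        return self.ref_start < end and start < self.ref_end

    def contained_in(self, start: int, end: int) -> bool:
        return start <= self.ref_start and self.ref_end <= end

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class PolymorphismTrack:
    """Sorted, deduplicated list of polymorphisms for one inbred vs the reference."""

    records: tuple[IndelRecord, ...]
    inbred_name: str = ""

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.records, key=IndelRecord.sort_key))
        seen: set[tuple] = set()
        for rec in ordered:
            key = (rec.chrom, rec.pos, rec.ref_allele, rec.alt_allele)
            if key in seen:
                raise TrackValidationError(f"duplicate record {key}")
            seen.add(key)
        object.__setattr__(self, "records", ordered)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IndelRecord]:
        return iter(self.records)

    def by_chrom(self) -> dict[str, list[IndelRecord]]:
        out: dict[str, list[IndelRecord]] = {}
        for chrom, group in itertools.groupby(self.records, key=lambda r: r.chrom):
            out[chrom] = list(group)
        return out

    def in_interval(self, chrom: str, start: int, end: int) -> list[IndelRecord]:
        """Records whose reference footprint intersects [start, end) (0-based)."""
        return [
            r for r in self.records if r.chrom == chrom and r.overlaps(start, end)
        ]

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Every REF allele must match the reference sequence at its footprint."""
        for rec in self.records:
            if rec.chrom not in genome.sequences:
                raise TrackValidationError(
                    f"record {rec.id} on unknown chromosome {rec.chrom!r}"
                )
            if rec.ref_end > genome.lengths[rec.chrom]:
                raise TrackValidationError(
                    f"record {rec.id} at {rec.chrom}:{rec.pos} extends past "
                    f"chromosome end ({genome.lengths[rec.chrom]} bp)"
                )
            expected = genome.fetch(rec.chrom, rec.ref_start, rec.ref_end)
            if expected != rec.ref_allele:
                raise TrackValidationError(
                    f"REF mismatch for record {rec.id} at {rec.chrom}:{rec.pos}: "
                    f"track says {rec.ref_allele!r}, genome has {expected!r}"
                )


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (multi-)FASTA into memory, uppercasing sequences."""
    path = Path(path)
    sequences: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueError subclasses
        raise FastaParseError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path} contains no FASTA records")
    for rec in records:
        if rec.id in sequences:
            raise FastaParseError(f"duplicate chromosome name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"chromosome {rec.id!r} has an empty sequence")
        sequences[rec.id] = seq
    return ReferenceGenome(sequences=sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _records_from_vcf(path: Path) -> Iterator[IndelRecord]:
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            if row.alts is None:
                continue
            # multi-allelic rows are split into biallelic records
            for alt in row.alts:
                if alt is None or set(alt.upper()) - VALID_ALLELE_BASES:
                    continue
                yield IndelRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    ref_allele=row.ref.upper(),
                    alt_allele=alt.upper(),
                    id=row.id or ".",
                )


def _records_from_tsv(path: Path) -> Iterator[IndelRecord]:
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=TSV_COLUMNS,
        dtype={"chrom": str, "pos": int, "ref": str, "alt": str, "id": str},
        header=None,
    )
    for row in frame.itertuples(index=False):
        yield IndelRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            ref_allele=row.ref.upper(),
            alt_allele=row.alt.upper(),
            id=str(row.id),
        )


def read_track(
    path: str | Path,
    dialect: str = "vcf",
    inbred_name: str = "",
    genome: ReferenceGenome | None = None,
) -> PolymorphismTrack:
    """Read a polymorphism track (VCF 4.x or the 5-column TSV dialect).

    Records are sorted by (chrom, pos); multi-allelic VCF rows are split
    into biallelic records.  SNPs are retained (primer placement needs
    them).  If ``genome`` is given, every REF allele is validated against
    it and a :class:`TrackValidationError` names the first offender.
    """
    path = Path(path)
    if dialect == "vcf":
        records = tuple(_records_from_vcf(path))
    elif dialect == "tsv":
        records = tuple(_records_from_tsv(path))
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")
    track = PolymorphismTrack(records=records, inbred_name=inbred_name)
    if genome is not None:
        track.validate_against(genome)
    return track


def write_track(
    track: PolymorphismTrack,
    path: str | Path,
    dialect: str = "vcf",
    genome: ReferenceGenome | None = None,
) -> None:
    """Write a track as VCF 4.2 or the TSV dialect (round-trip safe)."""
    path = Path(path)
    if dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if genome is not None:
                for name, length in genome.lengths.items():
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            else:
                for name in dict.fromkeys(r.chrom for r in track):
                    fh.write(f"##contig=<ID={name}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for rec in track:
                fh.write(
                    f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref_allele}\t"
                    f"{rec.alt_allele}\t.\t.\t.\n"
                )
    elif dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(TSV_COLUMNS) + "\n")
            for rec in track:
                fh.write(
                    f"{rec.chrom}\t{rec.pos}\t{rec.ref_allele}\t"
                    f"{rec.alt_allele}\t{rec.id}\n"
                )
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")


def write_bed(records: Iterable[IndelRecord], path: str | Path) -> None:
    """BED6 of reference footprints: score column carries the net length."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.ref_start}\t{rec.ref_end}\t{rec.id}\t"
                f"{rec.net_length}\t+\n"
            )


def filter_indels(
    track: PolymorphismTrack, min_net_length: int = 7
) -> PolymorphismTrack:
    """Keep Indels whose net allele-length difference is >= ``min_net_length``.

    The threshold is inclusive; SNPs (net length 0) are always removed.
    The default of 7 bp is the smallest size difference that genotypes
    reliably on a 4% agarose gel across the 80-300 bp product range.
    """
    if min_net_length < 1:
        raise ValueError("min_net_length must be >= 1")
    kept = tuple(r for r in track if r.net_length >= min_net_length)
    return PolymorphismTrack(records=kept, inbred_name=track.inbred_name)
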