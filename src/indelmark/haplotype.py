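"""Per-inbred haplotype construction over the reference coordinate system.

An inbred line is fully homozygous, so one variant track applied to the
reference defines its haplotype completely.  The haplotype is never
materialised chromosome-wide; any reference interval can be rendered or
sized on demand, which is all amplicon prediction needs.

Anchoring: a VCF-style Indel at position P shares its first base with the
reference, so the inserted/deleted bases sit immediately after P.
Containment and overlap tests use the record's reference footprint
(the bases covered by the REF allele).  An Indel whose footprint straddles
an interval boundary is an error, never a silent truncation — a truncated
Indel would corrupt every downstream size prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import IndelRecord, PolymorphismTrack, ReferenceGenome


class OverlappingVariantsError(ValueError):
    """Two variants in one track claim the same reference bases."""


class BoundaryStraddleError(ValueError):
    """An Indel's reference footprint crosses a requested interval edge."""


@dataclass(frozen=True)
class InbredHaplotype:
    """The genome of one inbred, expressed as reference + applied track."""

    genome: ReferenceGenome
    track: PolymorphismTrack

    @property
    def inbred_name(self) -> str:
        return self.track.inbred_name

    def __post_init__(self) -> None:
        self.track.validate_against(self.genome)
        for chrom, records in self.track.by_chrom().items():
            prev: IndelRecord | None = None
            for rec in records:
                if prev is not None and rec.ref_start < prev.ref_end:
                    raise OverlappingVariantsError(
                        f"variants {prev.id} ({chrom}:{prev.pos}) and "
                        f"{rec.id} ({chrom}:{rec.pos}) overlap on the reference"
                    )
                prev = rec

    def _contained_records(
        self, chrom: str, start: int, end: int
    ) -> list[IndelRecord]:
        """Records inside [start, end); straddling Indels raise."""
        out = []
        for rec in self.track.in_interval(chrom, start, end):
            if rec.contained_in(start, end):
                out.append(rec)
            elif rec.is_indel:
                raise BoundaryStraddleError(
                    f"Indel {rec.id} at {chrom}:{rec.pos} "
                    f"(footprint [{rec.ref_start}, {rec.ref_end})) straddles "
                    f"interval [{start}, {end})"
                )
            # a SNP can only straddle if the interval is degenerate; the
            # footprint is one base, so intersecting implies contained
        return out

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Haplotype sequence over a 0-based half-open reference interval."""
        parts: list[str] = []
        cursor = start
        for rec in self._contained_records(chrom, start, end):
            parts.append(self.genome.fetch(chrom, cursor, rec.ref_start))
            parts.append(rec.alt_allele)
            cursor = rec.ref_end
        parts.append(self.genome.fetch(chrom, cursor, end))
        return "".join(parts)

    def segment_size(self, chrom: str, start: int, end: int) -> int:
        """Haplotype length of a reference interval.

        Equals the interval length plus the signed net lengths of all
        contained Indels; raises on boundary-straddling Indels.
        """
        size = end - start
        for rec in self._contained_records(chrom, start, end):
            size += rec.signed_net_length
        return size

    def chrom_sequence(self, chrom: str) -> str:
        """Full haplotype chromosome (for small genomes / simulators)."""
        return self.sequence(chrom, 0, self.genome.lengths[chrom])


def build_haplotype(
    genome: ReferenceGenome, track: PolymorphismTrack
) -> InbredHaplotype:
    """Validate a track against the genome and wrap it as a haplotype."""
    return InbredHaplotype(genome=genome, track=track)
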