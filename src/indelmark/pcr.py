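"""In-silico PCR, amplicon prediction, gel resolvability and marker classification.

Specificity is established by deterministic primer-site scanning of the
whole genome rather than BLAST: every convergent pair of primer binding
sites within a maximum product size is reported, allowing a bounded
number of mismatches per primer but requiring the 3'-terminal bases to
match exactly (a mismatched 3' end aborts extension).  A pair is specific
when the designed locus is its only hit genome-wide.

Amplification in a non-reference inbred can fail three ways, mirroring
how sequence divergence defeats primers designed on the reference:

* ``PRIMER_SITE_VARIANT_3PRIME`` — any variant falls under a 3' clamp;
* ``PRIMER_SITE_DELETED`` — a deletion removes part of a primer footprint;
* ``PRIMER_SITE_DIVERGENCE`` — too many mismatches under a primer
  (SNPs beyond the allowed count, or an insertion splitting the site).

Sub-lethal mismatches do not block amplification but handicap the allele
when both templates compete in heterozygous/mixed DNA; a handicap
difference between alleles makes the marker dominant (the cleaner allele
— in practice the reference allele the primers were designed on —
preferentially amplifies).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from statistics import mean

from .haplotype import InbredHaplotype
from .io import IndelRecord, ReferenceGenome
from .primers import PrimerPair, reverse_complement


class FailureReason(str, enum.Enum):
    NONE = "NONE"
    PRIMER_SITE_VARIANT_3PRIME = "PRIMER_SITE_VARIANT_3PRIME"
    PRIMER_SITE_DIVERGENCE = "PRIMER_SITE_DIVERGENCE"
    PRIMER_SITE_DELETED = "PRIMER_SITE_DELETED"


class Verdict(str, enum.Enum):
    CO_DOMINANT = "CO_DOMINANT"
    DOMINANT = "DOMINANT"
    PAV = "PAV"
    NON_POLYMORPHIC = "NON_POLYMORPHIC"
    FAILED = "FAILED"


class AnnotationVerdict(str, enum.Enum):
    CONCORDANT = "CONCORDANT"
    WRONG_DIRECTION = "WRONG_DIRECTION"
    SAME_SIZE = "SAME_SIZE"
    NO_PRODUCT = "NO_PRODUCT"


@dataclass(frozen=True)
class PcrHit:
    """One predicted PCR product from a convergent pair of primer sites."""

    chrom: str
    product_interval: tuple[int, int]
    fwd_mismatches: int
    rev_mismatches: int
    #: which designed primer binds the plus strand here ("F" or "R")
    plus_primer: str

    @property
    def product_len(self) -> int:
        return self.product_interval[1] - self.product_interval[0]


@dataclass(frozen=True)
class AmpliconPrediction:
    """Predicted PCR outcome for one primer pair on one inbred haplotype."""

    inbred_name: str
    amplifies: bool
    product_len: int | None = None
    failure_reason: FailureReason = FailureReason.NONE
    #: sub-lethal primer-site mismatches (competition disadvantage)
    competition_handicap: int = 0

    def __post_init__(self) -> None:
        if self.amplifies and self.product_len is None:
            raise ValueError("amplifying prediction requires product_len")
        if not self.amplifies and self.failure_reason is FailureReason.NONE:
            raise ValueError("failed prediction requires a failure reason")


@dataclass(frozen=True)
class GelModel:
    """When are two product lengths distinguishable on a 4% agarose gel?

    Two bands resolve when their absolute difference exceeds both a floor
    (``min_abs_diff``) and a fraction of their mean length
    (``rel_diff_frac``) — larger products need larger differences, which
    is why small (<150 bp) products score small Indels best.
    ``heteroduplex_offset`` is the apparent extra size of the
    slow-migrating heteroduplex band in heterozygous reactions; only its
    presence is modelled quantitatively, not its mobility.
    """

    min_abs_diff: int = 4
    rel_diff_frac: float = 0.05
    heteroduplex_offset: int = 25

    def __post_init__(self) -> None:
        if self.min_abs_diff < 1:
            raise ValueError("min_abs_diff must be >= 1")
        if not (0.0 < self.rel_diff_frac < 1.0):
            raise ValueError("rel_diff_frac must be in (0, 1)")


@dataclass(frozen=True)
class MarkerClassification:
    """Pairwise marker verdict for two inbred haplotypes."""

    verdict: Verdict
    favored_allele: str | None = None
    resolvable: bool = False
    heteroduplex_expected: bool = False

    def __post_init__(self) -> None:
        favored_required = self.verdict in (Verdict.DOMINANT, Verdict.PAV)
        if favored_required != (self.favored_allele is not None):
            raise ValueError(
                f"favored_allele must be set iff verdict is DOMINANT or PAV, "
                f"got {self.verdict} / {self.favored_allele}"
            )


def _site_matches(
    seq: str,
    primer_plus: str,
    exact: tuple[int, int],
    max_mismatches: int,
) -> list[tuple[int, int]]:
    """All (start, mismatches) where ``primer_plus`` binds the plus strand.

    ``exact`` is the (start, end) slice of ``primer_plus`` that must match
    with zero mismatches (the 3' clamp, expressed in plus-strand
    orientation).  Candidate starts come from exact occurrences of that
    seed, so the scan is linear in practice.
    """
    m = len(primer_plus)
    seed = primer_plus[exact[0] : exact[1]]
    hits: list[tuple[int, int]] = []
    search_from = 0
    while True:
        idx = seq.find(seed, search_from)
        if idx == -1:
            break
        start = idx - exact[0]
        search_from = idx + 1
        if start < 0 or start + m > len(seq):
            continue
        site = seq[start : start + m]
        mismatches = sum(a != b for a, b in zip(site, primer_plus))
        if mismatches <= max_mismatches:
            hits.append((start, mismatches))
    return hits


def primer_sites(
    seq: str,
    primer: str,
    strand: str,
    max_mismatches: int,
    require_exact_3prime: int,
) -> list[tuple[int, int]]:
    """Binding sites of ``primer`` on one strand of a plus-strand sequence.

    Returns (plus-strand start, mismatches).  On the plus strand the
    primer reads left-to-right with its 3' end rightmost; on the minus
    strand its reverse complement appears on the plus strand with the
    3' end leftmost.
    """
    clamp = min(require_exact_3prime, len(primer))
    if strand == "+":
        return _site_matches(
            seq, primer, (len(primer) - clamp, len(primer)), max_mismatches
        )
    if strand == "-":
        return _site_matches(
            seq, reverse_complement(primer), (0, clamp), max_mismatches
        )
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def insilico_pcr(
    genome: ReferenceGenome,
    pair: PrimerPair,
    max_mismatches: int = 2,
    require_exact_3prime: int = 5,
    max_product_scan: int = 2000,
) -> list[PcrHit]:
    """All predicted products of ``pair`` anywhere in ``genome``.

    Considers both primers on both strands and reports every convergent
    site pair (plus-strand site upstream of a minus-strand site) whose
    product is at most ``max_product_scan`` bp.  The designed locus
    always appears as a zero-mismatch self-hit.
    """
    primers = {"F": pair.forward_seq, "R": pair.reverse_seq}
    hits: list[PcrHit] = []
    for chrom, seq in genome.sequences.items():
        plus = {
            name: primer_sites(seq, p, "+", max_mismatches, require_exact_3prime)
            for name, p in primers.items()
        }
        minus = {
            name: primer_sites(seq, p, "-", max_mismatches, require_exact_3prime)
            for name, p in primers.items()
        }
        for up_name, up_sites in plus.items():
            for down_name, down_sites in minus.items():
                for up_start, up_mm in up_sites:
                    for down_start, down_mm in down_sites:
                        end = down_start + len(primers[down_name])
                        if down_start <= up_start:
                            continue
                        if end - up_start > max_product_scan:
                            continue
                        fwd_mm = up_mm if up_name == "F" else down_mm
                        rev_mm = down_mm if down_name == "R" else up_mm
                        hits.append(
                            PcrHit(
                                chrom=chrom,
                                product_interval=(up_start, end),
                                fwd_mismatches=fwd_mm,
                                rev_mismatches=rev_mm,
                                plus_primer=up_name,
                            )
                        )
    hits.sort(key=lambda h: (h.chrom, h.product_interval, h.plus_primer))
    return hits


def is_specific(
    genome: ReferenceGenome,
    pair: PrimerPair,
    max_mismatches: int = 2,
    require_exact_3prime: int = 5,
    max_product_scan: int = 2000,
) -> bool:
    """True when the designed locus is the pair's only genome-wide product."""
    hits = insilico_pcr(
        genome, pair, max_mismatches, require_exact_3prime, max_product_scan
    )
    return len(hits) == 1


def predict_amplicon(
    pair: PrimerPair,
    haplotype: InbredHaplotype,
    max_mismatches: int = 2,
    require_exact_3prime: int = 5,
) -> AmpliconPrediction:
    """Predict whether and at what size ``pair`` amplifies one inbred.

    Checks, per primer: deletions removing primer bases (lethal), any
    variant under the 3' clamp (lethal), insertions splitting the site
    (lethal, counted as divergence), then SNP mismatches — lethal above
    ``max_mismatches``, otherwise summed into the competition handicap.
    """
    track = haplotype.track
    chrom = pair.chrom
    clamp_f, clamp_r = pair.clamp_intervals(require_exact_3prime)
    handicap = 0
    for footprint, clamp in (
        (pair.forward_interval, clamp_f),
        (pair.reverse_interval, clamp_r),
    ):
        under_primer = track.in_interval(chrom, *footprint)
        deletions = [r for r in under_primer if r.is_deletion]
        if deletions:
            return AmpliconPrediction(
                inbred_name=haplotype.inbred_name,
                amplifies=False,
                failure_reason=FailureReason.PRIMER_SITE_DELETED,
            )
        if any(r.overlaps(*clamp) for r in under_primer):
            return AmpliconPrediction(
                inbred_name=haplotype.inbred_name,
                amplifies=False,
                failure_reason=FailureReason.PRIMER_SITE_VARIANT_3PRIME,
            )
        insertions = [r for r in under_primer if r.is_insertion]
        snp_mismatches = sum(1 for r in under_primer if r.is_snp)
        if insertions or snp_mismatches > max_mismatches:
            return AmpliconPrediction(
                inbred_name=haplotype.inbred_name,
                amplifies=False,
                failure_reason=FailureReason.PRIMER_SITE_DIVERGENCE,
            )
        handicap += snp_mismatches
    product_len = haplotype.segment_size(chrom, *pair.amplicon_interval)
    return AmpliconPrediction(
        inbred_name=haplotype.inbred_name,
        amplifies=True,
        product_len=product_len,
        competition_handicap=handicap,
    )


def resolvable_on_gel(len_a: int, len_b: int, gel: GelModel | None = None) -> bool:
    """Can two homozygous products be told apart on the gel?

    True iff |len_a - len_b| >= max(min_abs_diff, rel_diff_frac x mean).
    Symmetric in its arguments.
    """
    gel = gel or GelModel()
    if len_a < 1 or len_b < 1:
        raise ValueError("product lengths must be >= 1 bp")
    diff = abs(len_a - len_b)
    threshold = max(gel.min_abs_diff, gel.rel_diff_frac * mean((len_a, len_b)))
    return diff >= threshold


def heteroduplex_apparent_size(len_a: int, len_b: int, gel: GelModel) -> int:
    """Apparent size of the slow heteroduplex band (larger allele + offset)."""
    return max(len_a, len_b) + gel.heteroduplex_offset


def classify_marker(
    pred_a: AmpliconPrediction,
    pred_b: AmpliconPrediction,
    gel: GelModel | None = None,
) -> MarkerClassification:
    """Classify one marker for an inbred pair from its two amplicon predictions.

    FAILED: neither allele amplifies.  PAV: exactly one amplifies.  When
    both amplify: DOMINANT if the competition handicaps differ (the
    cleaner allele wins the mixed-template reaction and masks the other);
    otherwise CO_DOMINANT when the sizes resolve on the gel, else
    NON_POLYMORPHIC.  A heteroduplex band is expected whenever two
    distinct-length products coamplify.
    """
    gel = gel or GelModel()
    if not pred_a.amplifies and not pred_b.amplifies:
        return MarkerClassification(verdict=Verdict.FAILED)
    if pred_a.amplifies != pred_b.amplifies:
        winner = pred_a if pred_a.amplifies else pred_b
        return MarkerClassification(
            verdict=Verdict.PAV, favored_allele=winner.inbred_name
        )
    assert pred_a.product_len is not None and pred_b.product_len is not None
    hetero = pred_a.product_len != pred_b.product_len
    resolvable = resolvable_on_gel(pred_a.product_len, pred_b.product_len, gel)
    if pred_a.competition_handicap != pred_b.competition_handicap:
        favored = (
            pred_a
            if pred_a.competition_handicap < pred_b.competition_handicap
            else pred_b
        )
        return MarkerClassification(
            verdict=Verdict.DOMINANT,
            favored_allele=favored.inbred_name,
            resolvable=resolvable,
            heteroduplex_expected=hetero,
        )
    if resolvable:
        return MarkerClassification(
            verdict=Verdict.CO_DOMINANT,
            resolvable=True,
            heteroduplex_expected=hetero,
        )
    return MarkerClassification(
        verdict=Verdict.NON_POLYMORPHIC,
        resolvable=False,
        heteroduplex_expected=hetero,
    )


def validate_annotation(
    expected: IndelRecord,
    observed_sizes: dict[str, int | None],
    reference_inbred: str,
    min_net_length: int = 7,
) -> AnnotationVerdict:
    """Audit an Indel annotation against observed product sizes.

    ``observed_sizes`` maps inbred name to product length (None = no
    product) and must contain the reference inbred plus exactly one
    other.  NO_PRODUCT: the non-reference allele fails to amplify.
    SAME_SIZE: the products are equal despite an annotated Indel of at
    least ``min_net_length``.  WRONG_DIRECTION: the sign of the observed
    size shift contradicts the annotation (a deletion that amplified a
    larger product, or an insertion a smaller one).  CONCORDANT: the
    shift agrees with the annotation in sign — gel scoring reads
    direction reliably but magnitude only approximately, so concordance
    is judged on direction.
    """
    if reference_inbred not in observed_sizes:
        raise ValueError(f"missing reference inbred {reference_inbred!r} size")
    ref_size = observed_sizes[reference_inbred]
    if ref_size is None:
        raise ValueError(f"reference inbred {reference_inbred!r} has no product")
    others = [k for k in observed_sizes if k != reference_inbred]
    if len(others) != 1:
        raise ValueError(
            f"expected exactly one non-reference inbred, got {sorted(others)}"
        )
    other_size = observed_sizes[others[0]]
    if other_size is None:
        return AnnotationVerdict.NO_PRODUCT
    observed_shift = other_size - ref_size
    annotated_shift = expected.signed_net_length
    if observed_shift == 0:
        if expected.net_length >= min_net_length:
            return AnnotationVerdict.SAME_SIZE
        return AnnotationVerdict.CONCORDANT
    if observed_shift * annotated_shift < 0:
        return AnnotationVerdict.WRONG_DIRECTION
    return AnnotationVerdict.CONCORDANT
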