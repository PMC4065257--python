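"""PCR primer design around a target Indel.

The design goal is an agarose-scorable fragment-length marker: a primer
pair whose reference amplicon is 80-300 bp and whose primers flank the
target Indel so the allele-length difference is carried entirely by the
product.  Primer length, Tm and GC windows are standard PCR practice and
fully configurable; product-size bounds are the binding constraint for
gel scoring.

Candidate primers are enumerated exhaustively over a search window on
each side of the Indel, filtered by hard constraints, scored by a
weighted soft penalty and paired.  There is no randomness anywhere:
identical inputs yield byte-identical ranked output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .io import IndelRecord, PolymorphismTrack, ReferenceGenome

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC content in percent."""
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def three_prime_complementarity(fwd: str, rev: str) -> int:
    """Longest 3'-terminal stretch of one primer complementary to the other's.

    A proxy for primer-dimer potential: length k such that the last k
    bases of ``fwd`` reverse-complement the last k bases of ``rev``.
    """
    k = 0
    limit = min(len(fwd), len(rev))
    while k < limit and fwd[-(k + 1)] == rev[-(k + 1)].translate(_COMPLEMENT):
        k += 1
    return k


@dataclass(frozen=True)
class DesignConfig:
    """Primer-design constraints and scoring weights.

    Thermodynamic conditions (monovalent salt, oligo concentrations) are
    fixed named defaults so every reported Tm is reproducible; they are
    echoed in report headers for provenance.
    """

    amplicon_min: int = 80
    amplicon_max: int = 300
    primer_len_min: int = 18
    primer_len_max: int = 27
    tm_min: float = 55.0
    tm_max: float = 63.0
    tm_pair_max_diff: float = 3.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_homopolymer: int = 5
    avoid_linked_polymorphisms: bool = True
    three_prime_clamp: int = 5
    #: how far (bp) from the Indel footprint primer 3' ends are tried
    search_radius: int = 150
    #: candidates kept per side before pairing (best by single-primer penalty)
    max_candidates_per_side: int = 40
    # thermodynamic conditions for nearest-neighbor Tm
    na_mM: float = 50.0
    oligo_nM: float = 250.0
    # soft-penalty weights
    w_tm_dev: float = 1.0
    w_tm_diff: float = 1.0
    w_gc_dev: float = 0.05
    w_homopolymer: float = 0.5
    w_three_prime_comp: float = 1.0

    def __post_init__(self) -> None:
        if self.amplicon_min >= self.amplicon_max:
            raise ValueError("amplicon_min must be < amplicon_max")
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("empty primer length range")
        if self.tm_min > self.tm_max or self.gc_min > self.gc_max:
            raise ValueError("empty Tm or GC range")

    @property
    def tm_mid(self) -> float:
        return (self.tm_min + self.tm_max) / 2.0

    @property
    def gc_mid(self) -> float:
        return (self.gc_min + self.gc_max) / 2.0


def melting_temperature(seq: str, cfg: DesignConfig | None = None) -> float:
    """Nearest-neighbor melting temperature in deg C.

    Uses the SantaLucia unified NN parameters with the configured
    monovalent-salt and oligo concentrations.  Deterministic; ambiguous
    bases are rejected.
    """
    cfg = cfg or DesignConfig()
    if len(seq) < 8:
        raise ValueError(f"sequence too short for NN Tm: {seq!r}")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous bases in {seq!r}")
    return _mt.Tm_NN(
        seq,
        Na=cfg.na_mM,
        dnac1=cfg.oligo_nM,
        dnac2=cfg.oligo_nM,
    )


@dataclass(frozen=True)
class PrimerPair:
    """Two oligos flanking a target Indel, with reference coordinates.

    Intervals are 0-based half-open on the reference top strand; the
    reverse primer sequence is the reverse complement of the top strand
    over ``reverse_interval``.  The reference amplicon spans from the
    forward primer's 5' end to the reverse primer's 5' end inclusive.
    """

    target_id: str
    chrom: str
    forward_seq: str
    reverse_seq: str
    forward_interval: tuple[int, int]
    reverse_interval: tuple[int, int]
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float

    @property
    def amplicon_interval(self) -> tuple[int, int]:
        return (self.forward_interval[0], self.reverse_interval[1])

    @property
    def ref_amplicon_len(self) -> int:
        return self.reverse_interval[1] - self.forward_interval[0]

    def clamp_intervals(self, clamp: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """Reference intervals of the two 3'-terminal clamps."""
        fs, fe = self.forward_interval
        rs, re = self.reverse_interval
        return ((fe - clamp, fe), (rs, rs + clamp))


def pair_from_intervals(
    genome: ReferenceGenome,
    chrom: str,
    forward_interval: tuple[int, int],
    reverse_interval: tuple[int, int],
    target_id: str = ".",
    cfg: DesignConfig | None = None,
) -> PrimerPair:
    """Construct a PrimerPair directly from reference coordinates."""
    cfg = cfg or DesignConfig()
    fs, fe = forward_interval
    rs, re = reverse_interval
    if not (fs < fe <= rs < re):
        raise ValueError("primer intervals must be disjoint and ordered")
    fwd = genome.fetch(chrom, fs, fe)
    rev = reverse_complement(genome.fetch(chrom, rs, re))
    return PrimerPair(
        target_id=target_id,
        chrom=chrom,
        forward_seq=fwd,
        reverse_seq=rev,
        forward_interval=(fs, fe),
        reverse_interval=(rs, re),
        tm_f=melting_temperature(fwd, cfg),
        tm_r=melting_temperature(rev, cfg),
        gc_f=gc_fraction(fwd),
        gc_r=gc_fraction(rev),
    )


def score_pair(pair: PrimerPair, cfg: DesignConfig) -> float:
    """Deterministic soft penalty for a constraint-satisfying pair (lower = better).

    Tm/GC terms vanish when both primers sit at the range midpoints, so
    the ranking is driven purely by structural terms in that case.
    """
    penalty = 0.0
    penalty += cfg.w_tm_dev * (
        abs(pair.tm_f - cfg.tm_mid) + abs(pair.tm_r - cfg.tm_mid)
    )
    penalty += cfg.w_tm_diff * abs(pair.tm_f - pair.tm_r)
    penalty += cfg.w_gc_dev * (
        abs(pair.gc_f - cfg.gc_mid) + abs(pair.gc_r - cfg.gc_mid)
    )
    penalty += cfg.w_homopolymer * (
        (max_homopolymer_run(pair.forward_seq) - 1)
        + (max_homopolymer_run(pair.reverse_seq) - 1)
    )
    penalty += cfg.w_three_prime_comp * three_prime_complementarity(
        pair.forward_seq, pair.reverse_seq
    )
    return penalty


@dataclass(frozen=True)
class _Candidate:
    seq: str
    interval: tuple[int, int]
    tm: float
    gc: float

    def single_penalty(self, cfg: DesignConfig) -> float:
        return (
            cfg.w_tm_dev * abs(self.tm - cfg.tm_mid)
            + cfg.w_gc_dev * abs(self.gc - cfg.gc_mid)
            + cfg.w_homopolymer * (max_homopolymer_run(self.seq) - 1)
        )


def _linked_records(
    linked_track: PolymorphismTrack | None,
    indel: IndelRecord,
    chrom: str,
    start: int,
    end: int,
) -> list[IndelRecord]:
    """Linked-track records near the locus, excluding the target itself."""
    if linked_track is None:
        return []
    return [
        r
        for r in linked_track.in_interval(chrom, start, end)
        if r.sort_key() != indel.sort_key()
    ]


def _candidates(
    genome: ReferenceGenome,
    chrom: str,
    indel: IndelRecord,
    linked: list[IndelRecord],
    cfg: DesignConfig,
    side: str,
) -> list[_Candidate]:
    """Enumerate single-primer candidates on one side of the Indel footprint.

    ``side='forward'``: top-strand primers with 3' end at or left of the
    footprint start.  ``side='reverse'``: bottom-strand primers whose
    reference footprint starts at or right of the footprint end.
    """
    chrom_len = genome.lengths[chrom]
    out: list[_Candidate] = []
    if side == "forward":
        ends = range(indel.ref_start, max(indel.ref_start - cfg.search_radius, 0) - 1, -1)
    else:
        ends = range(indel.ref_end, min(indel.ref_end + cfg.search_radius, chrom_len) + 1)
    for anchor in ends:
        for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            if side == "forward":
                start, end = anchor - length, anchor
            else:
                start, end = anchor, anchor + length
            if start < 0 or end > chrom_len:
                continue
            site = genome.fetch(chrom, start, end)
            if set(site) - set("ACGT"):
                continue
            seq = site if side == "forward" else reverse_complement(site)
            if max_homopolymer_run(seq) > cfg.max_homopolymer:
                continue
            gc = gc_fraction(seq)
            if not (cfg.gc_min <= gc <= cfg.gc_max):
                continue
            # 3' clamp is always polymorphism-free (target excluded by geometry)
            if side == "forward":
                clamp = (end - cfg.three_prime_clamp, end)
            else:
                clamp = (start, start + cfg.three_prime_clamp)
            if any(r.overlaps(*clamp) for r in linked):
                continue
            if cfg.avoid_linked_polymorphisms and any(
                r.overlaps(start, end) for r in linked
            ):
                continue
            tm = melting_temperature(seq, cfg)
            if not (cfg.tm_min <= tm <= cfg.tm_max):
                continue
            out.append(_Candidate(seq=seq, interval=(start, end), tm=tm, gc=gc))
    out.sort(key=lambda c: (c.single_penalty(cfg), c.interval))
    return out[: cfg.max_candidates_per_side]


def design_primers(
    genome: ReferenceGenome,
    indel: IndelRecord,
    linked_track: PolymorphismTrack | None = None,
    cfg: DesignConfig | None = None,
) -> list[PrimerPair]:
    """Enumerate and rank primer pairs flanking ``indel``.

    Every returned pair satisfies all hard constraints: amplicon within
    [amplicon_min, amplicon_max] on the reference, primer Tm/GC/length
    windows, pair Tm difference, homopolymer cap, polymorphism-free 3'
    clamps, and (when ``avoid_linked_polymorphisms``) primer footprints
    free of any linked-track record.  The target Indel footprint always
    lies strictly between the primer footprints.

    Ranking: soft penalty, then smaller reference amplicon (smaller
    products resolve small size differences better on agarose), then
    leftmost forward primer.  Returns an empty list when no design exists.
    """
    cfg = cfg or DesignConfig()
    chrom = indel.chrom
    window = (
        max(indel.ref_start - cfg.search_radius - cfg.primer_len_max, 0),
        min(
            indel.ref_end + cfg.search_radius + cfg.primer_len_max,
            genome.lengths[chrom],
        ),
    )
    linked = _linked_records(linked_track, indel, chrom, *window)
    fwd_cands = _candidates(genome, chrom, indel, linked, cfg, "forward")
    rev_cands = _candidates(genome, chrom, indel, linked, cfg, "reverse")
    if not fwd_cands or not rev_cands:
        logger.info(
            "no single-primer candidates for %s at %s:%d (fwd=%d rev=%d)",
            indel.id, chrom, indel.pos, len(fwd_cands), len(rev_cands),
        )
        return []

    scored: list[tuple[tuple, PrimerPair]] = []
    for f in fwd_cands:
        for r in rev_cands:
            amp_len = r.interval[1] - f.interval[0]
            if not (cfg.amplicon_min <= amp_len <= cfg.amplicon_max):
                continue
            if abs(f.tm - r.tm) > cfg.tm_pair_max_diff:
                continue
            pair = PrimerPair(
                target_id=indel.id,
                chrom=chrom,
                forward_seq=f.seq,
                reverse_seq=r.seq,
                forward_interval=f.interval,
                reverse_interval=r.interval,
                tm_f=f.tm,
                tm_r=r.tm,
                gc_f=f.gc,
                gc_r=r.gc,
            )
            key = (score_pair(pair, cfg), amp_len, f.interval[0], r.interval[1])
            scored.append((key, pair))
    scored.sort(key=lambda item: item[0])
    if not scored:
        logger.info(
            "no pairable candidates for %s at %s:%d", indel.id, chrom, indel.pos
        )
    return [pair for _, pair in scored]
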