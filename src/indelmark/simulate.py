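"""Synthetic genomes and inbred variant tracks with known ground truth.

Real marker design starts from a multi-gigabase assembly and a track of
millions of polymorphisms; neither is needed to exercise any part of the
pipeline.  This module generates scaled-down genomes with planted SNPs
and Indels whose positions and signed net lengths are recorded in a
manifest, so every downstream prediction can be checked exactly.  A
``duplication_fraction`` copies reference segments elsewhere in the
genome to exercise specificity rejection.

It also plants six small demonstration loci covering the behaviour
classes a marker can show between three inbreds (reference "B73" plus
"Mo17" and "W22" tracks): co-dominant fragment-length polymorphisms,
three-allele systems, presence-absence variants caused by a deleted
primer site, dominant markers caused by primer-site divergence in one
allele, and an annotation that disagrees with the actual haplotype.
All sequences are generated; only the size arithmetic of the scenarios
is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    IndelRecord,
    PolymorphismTrack,
    ReferenceGenome,
    write_fasta,
    write_track,
)
from .primers import PrimerPair, pair_from_intervals

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic genome + tracks draw.

    Rates are per reference bp.  The Indel net-length distribution is a
    discrete distribution over 1-50 bp, by default geometric-ish and
    weighted toward short events, matching the strong excess of short
    Indels in real inbred comparisons.  A seed is mandatory: there is no
    global randomness anywhere in the package.
    """

    rng_seed: int
    n_chroms: int = 2
    chrom_length: int = 150_000
    inbred_names: tuple[str, ...] = ("Mo17", "W22")
    snp_rate: float = 0.0015
    indel_rate: float = 0.0005
    indel_net_lengths: tuple[int, ...] = tuple(range(1, 51))
    indel_net_weights: tuple[float, ...] = tuple(0.8 ** n for n in range(1, 51))
    duplication_fraction: float = 0.0
    duplication_segment_len: int = 500

    def __post_init__(self) -> None:
        for name, rate in (("snp_rate", self.snp_rate), ("indel_rate", self.indel_rate)):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.indel_net_lengths) != len(self.indel_net_weights):
            raise ValueError("net-length values and weights differ in length")
        mean_net = float(
            np.average(self.indel_net_lengths, weights=self.indel_net_weights)
        )
        if self.snp_rate + self.indel_rate * (1 + mean_net) > 0.3:
            raise ValueError(
                "variant rates imply overlap saturation; lower snp_rate/indel_rate"
            )


@dataclass(frozen=True)
class Duplication:
    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int


@dataclass(frozen=True)
class SimResult:
    """A simulated reference, per-inbred tracks, and the ground-truth manifest."""

    genome: ReferenceGenome
    tracks: dict[str, PolymorphismTrack]
    manifest: pd.DataFrame
    duplications: tuple[Duplication, ...] = ()

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA + one VCF per inbred + manifest TSV; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {"genome": outdir / "genome.fa"}
        write_fasta(self.genome, paths["genome"])
        for name, track in self.tracks.items():
            paths[name] = outdir / f"{name}.vcf"
            write_track(track, paths[name], dialect="vcf", genome=self.genome)
        paths["manifest"] = outdir / "manifest.tsv"
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _apply_duplications(
    rng: np.random.Generator,
    seqs: dict[str, np.ndarray],
    cfg: SimConfig,
) -> tuple[Duplication, ...]:
    total = sum(len(s) for s in seqs.values())
    target_bp = int(cfg.duplication_fraction * total)
    if target_bp <= 0:
        return ()
    chroms = list(seqs)
    dups: list[Duplication] = []
    copied = 0
    while copied < target_bp:
        src = chroms[rng.integers(0, len(chroms))]
        dst = chroms[rng.integers(0, len(chroms))]
        seg = min(cfg.duplication_segment_len, target_bp - copied)
        if len(seqs[src]) <= seg or len(seqs[dst]) <= seg:
            break
        s0 = int(rng.integers(0, len(seqs[src]) - seg))
        d0 = int(rng.integers(0, len(seqs[dst]) - seg))
        if src == dst and abs(d0 - s0) < seg:
            continue  # avoid self-overlapping copy
        seqs[dst][d0 : d0 + seg] = seqs[src][s0 : s0 + seg]
        dups.append(Duplication(src, s0, s0 + seg, dst, d0))
        copied += seg
    return tuple(dups)


def _plant_track(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    cfg: SimConfig,
    inbred: str,
    rows: list[dict],
) -> PolymorphismTrack:
    weights = np.asarray(cfg.indel_net_weights, dtype=float)
    weights = weights / weights.sum()
    total_rate = cfg.snp_rate + cfg.indel_rate
    records: list[IndelRecord] = []
    counter = 0
    for chrom, seq in genome.sequences.items():
        length = len(seq)
        if total_rate <= 0:
            continue
        hits = np.flatnonzero(rng.random(length) < total_rate)
        is_snp = rng.random(hits.size) < (cfg.snp_rate / total_rate)
        nets = rng.choice(cfg.indel_net_lengths, size=hits.size, p=weights)
        is_del = rng.random(hits.size) < 0.5
        alt_draws = rng.integers(0, 4, size=(hits.size, 51))
        last_end = -1
        for j, anchor in enumerate(hits.tolist()):
            if anchor < last_end:
                continue
            ref_base = seq[anchor]
            counter += 1
            rec_id = f"{inbred}.{counter:06d}"
            if is_snp[j]:
                alt = _BASES[(list("ACGT").index(ref_base) + 1 + alt_draws[j, 0] % 3) % 4]
                rec = IndelRecord(chrom, anchor + 1, ref_base, str(alt), rec_id)
            elif is_del[j]:
                net = int(nets[j])
                if anchor + net + 1 > length:
                    continue
                ref = seq[anchor : anchor + net + 1]
                rec = IndelRecord(chrom, anchor + 1, ref, ref[0], rec_id)
            else:
                net = int(nets[j])
                ins = "".join(_BASES[alt_draws[j, 1 : net + 1]])
                rec = IndelRecord(chrom, anchor + 1, ref_base, ref_base + ins, rec_id)
            records.append(rec)
            last_end = rec.ref_end
            rows.append(
                {
                    "inbred": inbred,
                    "chrom": chrom,
                    "pos": rec.pos,
                    "ref": rec.ref_allele,
                    "alt": rec.alt_allele,
                    "id": rec.id,
                    "kind": "snp" if rec.is_snp else ("del" if rec.is_deletion else "ins"),
                    "net_length": rec.net_length,
                    "signed_net": rec.signed_net_length,
                }
            )
    return PolymorphismTrack(records=tuple(records), inbred_name=inbred)


def simulate(cfg: SimConfig) -> SimResult:
    """Draw a reference genome and per-inbred polymorphism tracks.

    Variants never overlap within a track; the manifest records every
    planted variant with its signed net length.  Identical configs
    (including seed) give byte-identical FASTA/VCF output.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    seqs = {
        f"chr{i + 1}": _random_sequence(rng, cfg.chrom_length)
        for i in range(cfg.n_chroms)
    }
    duplications = _apply_duplications(rng, seqs, cfg)
    genome = ReferenceGenome(
        sequences={name: "".join(arr) for name, arr in seqs.items()}
    )
    rows: list[dict] = []
    tracks = {
        inbred: _plant_track(rng, genome, cfg, inbred, rows)
        for inbred in cfg.inbred_names
    }
    columns = [
        "inbred", "chrom", "pos", "ref", "alt", "id", "kind",
        "net_length", "signed_net",
    ]
    manifest = pd.DataFrame(rows, columns=columns)
    return SimResult(
        genome=genome, tracks=tracks, manifest=manifest, duplications=duplications
    )


# ---------------------------------------------------------------------------
# Demonstration loci: the canonical behaviour classes of Indel markers
# ---------------------------------------------------------------------------

REFERENCE_INBRED = "B73"

@dataclass(frozen=True)
class DemoScenario:
    """One planted locus with its primer pair and annotation record."""

    name: str
    description: str
    chrom: str
    pair: PrimerPair
    #: the Indel annotation the marker was designed against (may disagree
    #: with the actual haplotype, as in the annotation-audit scenario)
    annotation: IndelRecord
    #: the inbred pair this scenario demonstrates
    highlight_pair: tuple[str, str]


@dataclass(frozen=True)
class DemoFixtures:
    genome: ReferenceGenome
    tracks: dict[str, PolymorphismTrack]
    scenarios: tuple[DemoScenario, ...]

    def scenario(self, name: str) -> DemoScenario:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise KeyError(name)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {"genome": outdir / "genome.fa"}
        write_fasta(self.genome, paths["genome"])
        for name, track in self.tracks.items():
            paths[name] = outdir / f"{name}.vcf"
            write_track(track, paths[name], dialect="vcf", genome=self.genome)
        primer_rows = []
        for s in self.scenarios:
            p = s.pair
            primer_rows.append(
                {
                    "target_id": p.target_id,
                    "chrom": p.chrom,
                    "fwd_start": p.forward_interval[0],
                    "fwd_end": p.forward_interval[1],
                    "rev_start": p.reverse_interval[0],
                    "rev_end": p.reverse_interval[1],
                    "fwd_seq": p.forward_seq,
                    "rev_seq": p.reverse_seq,
                    "ref_amplicon_len": p.ref_amplicon_len,
                    "pair_a": s.highlight_pair[0],
                    "pair_b": s.highlight_pair[1],
                }
            )
        paths["primers"] = outdir / "primers.tsv"
        pd.DataFrame(primer_rows).to_csv(paths["primers"], sep="\t", index=False)
        return paths


def _deletion(genome: ReferenceGenome, chrom: str, anchor0: int, net: int,
              rec_id: str) -> IndelRecord:
    ref = genome.fetch(chrom, anchor0, anchor0 + net + 1)
    return IndelRecord(chrom, anchor0 + 1, ref, ref[0], rec_id)


def _insertion(genome: ReferenceGenome, chrom: str, anchor0: int, net: int,
               rec_id: str, rng: np.random.Generator) -> IndelRecord:
    ref = genome.fetch(chrom, anchor0, anchor0 + 1)
    ins = "".join(_BASES[rng.integers(0, 4, size=net)])
    return IndelRecord(chrom, anchor0 + 1, ref, ref + ins, rec_id)


def _snp(genome: ReferenceGenome, chrom: str, anchor0: int, rec_id: str) -> IndelRecord:
    ref = genome.fetch(chrom, anchor0, anchor0 + 1)
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    return IndelRecord(chrom, anchor0 + 1, ref, alt, rec_id)


def plant_demo_loci(rng_seed: int = 11) -> DemoFixtures:
    """Six generated loci demonstrating every marker behaviour class.

    All loci share the layout: a 600-bp chromosome with a 20-bp forward
    primer at [100, 120) and the reverse primer closing a reference
    amplicon of the scenario's size.  Variants sit strictly between the
    primers unless the scenario is about a damaged primer site.

    * ``locusA`` — 154-bp product, 17-bp Mo17 deletion: the common
      co-dominant class, B73 and W22 sharing an allele.
    * ``locusB`` — 255-bp product, 19-bp Mo17 and 40-bp W22 deletions:
      three mutually resolvable co-dominant alleles.
    * ``locusC`` — 143-bp product, 13-bp Mo17 deletion; in W22 a
      deletion removes part of the reverse primer site, so W22 shows
      presence-absence against both other inbreds.
    * ``locusD`` — 168-bp product, 14-bp Mo17 insertion plus a SNP under
      the forward primer in Mo17: both alleles amplify alone, but the
      handicapped Mo17 allele loses the mixed-template reaction
      (dominant marker favoring B73).
    * ``locusE`` — 201-bp product, 11-bp deletion shared by Mo17 and
      W22, both carrying a primer-site SNP: dominant against B73,
      monomorphic between Mo17 and W22.
    * ``locusF`` — 192-bp product; the track annotates a 24-bp Mo17
      deletion that the actual haplotype does not carry, so all three
      inbreds amplify the same size (annotation-disagreement audit case).
    """
    rng = np.random.default_rng(rng_seed)
    amplicon_lens = {"locusA": 154, "locusB": 255, "locusC": 143,
                     "locusD": 168, "locusE": 201, "locusF": 192}
    genome = ReferenceGenome(
        sequences={
            name: "".join(_random_sequence(rng, 600)) for name in amplicon_lens
        }
    )

    def pair_for(chrom: str) -> PrimerPair:
        amp = amplicon_lens[chrom]
        return pair_from_intervals(
            genome, chrom, (100, 120), (100 + amp - 20, 100 + amp),
            target_id=chrom,
        )

    pairs = {name: pair_for(name) for name in amplicon_lens}

    mo17: list[IndelRecord] = []
    w22: list[IndelRecord] = []

    # locusA: 17-bp deletion in Mo17 only
    a_del = _deletion(genome, "locusA", 160, 17, "locusA.del17")
    mo17.append(a_del)
    # locusB: 19-bp Mo17 deletion, 40-bp W22 deletion at distinct positions
    b_del = _deletion(genome, "locusB", 170, 19, "locusB.del19")
    mo17.append(b_del)
    w22.append(_deletion(genome, "locusB", 200, 40, "locusB.del40"))
    # locusC: 13-bp Mo17 deletion; W22 deletion eats the reverse primer's
    # 5' half (not the 3' clamp at [223, 228))
    c_del = _deletion(genome, "locusC", 150, 13, "locusC.del13")
    mo17.append(c_del)
    w22.append(_deletion(genome, "locusC", 233, 30, "locusC.primerdel"))
    # locusD: 14-bp Mo17 insertion + sub-lethal SNP under the forward primer
    d_ins = _insertion(genome, "locusD", 180, 14, "locusD.ins14", rng)
    mo17.append(d_ins)
    mo17.append(_snp(genome, "locusD", 105, "locusD.primersnp"))
    # locusE: 11-bp deletion and primer-site SNP shared by Mo17 and W22
    e_del = _deletion(genome, "locusE", 170, 11, "locusE.del11")
    e_snp = _snp(genome, "locusE", 107, "locusE.primersnp")
    mo17.extend([e_del, e_snp])
    w22.extend([e_del, e_snp])
    # locusF: annotated 24-bp deletion absent from every haplotype
    f_phantom = _deletion(genome, "locusF", 150, 24, "locusF.phantom24")

    tracks = {
        REFERENCE_INBRED: PolymorphismTrack(records=(), inbred_name=REFERENCE_INBRED),
        "Mo17": PolymorphismTrack(records=tuple(mo17), inbred_name="Mo17"),
        "W22": PolymorphismTrack(records=tuple(w22), inbred_name="W22"),
    }
    scenarios = (
        DemoScenario(
            "locusA", "co-dominant, B73 and W22 share the reference allele",
            "locusA", pairs["locusA"], a_del, ("B73", "Mo17"),
        ),
        DemoScenario(
            "locusB", "three co-dominant alleles",
            "locusB", pairs["locusB"], b_del, ("B73", "Mo17"),
        ),
        DemoScenario(
            "locusC", "presence-absence: W22 reverse primer site deleted",
            "locusC", pairs["locusC"], c_del, ("B73", "W22"),
        ),
        DemoScenario(
            "locusD", "dominant: Mo17 insertion allele handicapped by primer SNP",
            "locusD", pairs["locusD"], d_ins, ("B73", "Mo17"),
        ),
        DemoScenario(
            "locusE", "dominant vs B73; Mo17 and W22 monomorphic",
            "locusE", pairs["locusE"], e_del, ("B73", "Mo17"),
        ),
        DemoScenario(
            "locusF", "annotation disagreement: planted deletion not in haplotype",
            "locusF", pairs["locusF"], f_phantom, ("B73", "Mo17"),
        ),
    )
    return DemoFixtures(genome=genome, tracks=tracks, scenarios=scenarios)
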