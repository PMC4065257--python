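# Methods

## Scope and model

`indelmark` models the design and behaviour of fragment-length PCR
markers built on Indel polymorphisms between fully homozygous inbred
lines. One inbred is the reference (its genome is the coordinate
system); every other inbred is represented as the reference plus a
variant track. Because inbreds are homozygous, a track fully determines
a haplotype; there is no phasing, no diploidy, and no allele frequency
anywhere in the model.

## Coordinates and the Indel size metric

Externally everything is VCF-convention 1-based: an Indel record anchors
at the first shared base, so a 17-bp deletion is an 18-bp REF with a
1-bp ALT. Internally all computations use 0-based half-open intervals;
`IndelRecord.ref_start/ref_end` are the single source of the conversion.
Containment and overlap tests use the record's *reference footprint*
(the REF-allele bases).

The size of an Indel is its **net allele-length difference**
|len(REF) − len(ALT)|, not a gapped-alignment length. For the simple
insertions/deletions that dominate inbred comparisons the two coincide;
for complex substitutions the net difference is what shifts an amplicon,
which is the quantity a gel measures. The 7-bp default filter threshold
is inclusive and SNPs are always removed by the filter.

Multi-allelic VCF rows are split into biallelic records on input: each
marker targets one alternate allele.

## Haplotype arithmetic

A haplotype sequence over a reference interval is the reference with
SNP substitutions and Indel splices applied; the segment size equals the
interval length plus the sum of signed net lengths of contained Indels.
An Indel whose footprint straddles a requested interval edge raises an
error instead of being truncated — a truncated splice would silently
corrupt every size prediction downstream, and the primer designer is
responsible for never placing amplicon edges over variants. Insertions
anchored on the last base of an interval are counted inside it.

## Primer design

Product-size bounds (80–300 bp reference amplicon) are the binding
constraint: they keep products inside the resolving range of a 4%
agarose gel. The remaining constraints are standard PCR practice and
configurable in `DesignConfig`:

| parameter | default | note |
|---|---|---|
| primer length | 18–27 nt | |
| Tm | 55–63 °C, pair Δ ≤ 3 °C | nearest-neighbor, see below |
| GC | 30–70 % | |
| homopolymer run | ≤ 5 nt | |
| 3′ clamp | last 5 nt polymorphism-free | enforced always |
| linked polymorphisms | avoided under the whole primer | `avoid_linked_polymorphisms=True` |
| search radius | 150 bp per side | candidate 3′-end positions |
| candidates per side | 40 | best by single-primer penalty, deterministic |

Avoiding linked polymorphisms under primers is the default because
primer-site divergence in the non-reference allele is the dominant cause
of one-allele (dominant/PAV) markers; turning it off reproduces that
failure mode deliberately.

Melting temperatures use the unified nearest-neighbor ΔH/ΔS parameters
(via Biopython's `Tm_NN`) at fixed, named conditions: 50 mM monovalent
salt, 250 nM each oligo. The implementation is cross-checked in the test
suite against an independent direct summation of the published ΔH/ΔS
table; the conditions are echoed in report headers.

Soft scoring is a weighted sum of |Tm − range midpoint| for both
primers, the pair Tm difference, |GC − midpoint|, homopolymer run
lengths, and the 3′-terminal cross-complementarity run (primer-dimer
proxy); Tm/GC terms vanish at the midpoints. Ranking is penalty, then
**smaller** reference amplicon (small products resolve small Indels
best), then leftmost forward primer — fully deterministic, no randomness
anywhere in design.

## In-silico PCR and specificity

Genome-wide specificity is established by direct primer-site scanning
rather than alignment-program heuristics: a site binds if it matches a
primer with at most 2 mismatches and an exact 3′-terminal pentamer
(mismatched 3′ ends abort extension); every convergent plus/minus site
pair within 2 kb is a predicted product, considering both primers in
both orientations. A pair is specific when its designed locus is the
only product. Scanning is seeded on exact 3′-pentamer occurrences, and
is verified in the tests against a naive all-positions scan.

## Amplification-failure model and dominance

For a non-reference haplotype, each primer footprint is audited against
the track, in this order:

1. any **deletion** overlapping the footprint → `PRIMER_SITE_DELETED`
   (the site no longer exists; this takes precedence even when the
   deletion also covers the clamp);
2. any variant under the **3′ clamp** → `PRIMER_SITE_VARIANT_3PRIME`;
3. an **insertion** splitting the site, or more than 2 SNP mismatches →
   `PRIMER_SITE_DIVERGENCE`.

Surviving SNP mismatches are sub-lethal: the allele amplifies, but the
mismatch count accumulates as a *competition handicap*. When both
alleles of a pair amplify alone but their handicaps differ, the marker
is classified `DOMINANT` with the cleaner allele favored — in practice
the reference allele, since primers are designed on the reference. This
handicap mechanism is a deliberate operationalization of PCR
competition, not a thermodynamic simulation; it reproduces the observed
direction of preferential amplification, and its magnitude should not be
over-interpreted.

## Gel model

Two homozygous products resolve when
|a − b| ≥ max(`min_abs_diff`, `rel_diff_frac` · mean(a, b)), defaults
4 bp and 5%. The constants are calibrated so that 11–19 bp differences
on 143–255 bp products resolve while a 7-bp difference on a ~300-bp
product does not; both are configurable. Heteroduplex bands are modelled
only as a presence flag (expected whenever two distinct-length products
coamplify) plus a nominal apparent-size offset (+25 bp on the larger
allele); their mobility is not simulated.

## Annotation audit

`validate_annotation` compares an annotated Indel with observed product
sizes for the reference and one other inbred: `NO_PRODUCT` (other allele
absent), `SAME_SIZE` (equal products despite an annotated Indel at or
above threshold), `WRONG_DIRECTION` (observed shift opposite in sign to
the annotation), else `CONCORDANT`. Concordance is judged on the
*direction* of the shift: gel electrophoresis reads direction reliably
but magnitude only approximately, so a same-direction magnitude
difference is scored as the annotation being confirmed.

## Spacing and interval refinement

Gap statistics are successive position differences within a chromosome;
chromosomes with fewer than two markers contribute no gaps. The
aggregate pools all within-chromosome gaps rather than averaging
per-chromosome means, giving a single genome-wide mean/median distance.

`select_evenly_spaced` places k interior anchors at
start + i·(end−start)/(k+1), i = 1..k — endpoints excluded, since
flanking markers are typically genotyped already — and assigns each
anchor its nearest unchosen candidate, ties to the lower coordinate.
`refine_interval` intersects half-lines implied by per-marker
left/right calls and errors on contradictions (a genotyping error
signal), so iterated refinement monotonically shrinks the interval.

## Synthetic data

The simulator emulates the statistical shape of an inbred-vs-reference
polymorphism track at desk scale: uniform random chromosomes, per-bp SNP
and Indel rates (defaults 1.5×10⁻³ and 5×10⁻⁴), Indel net lengths drawn
from a short-weighted discrete distribution over 1–50 bp (geometric-like,
ratio 0.8), deletions and insertions equiprobable, variants
non-overlapping within a track, and an optional duplication fraction
that copies segments elsewhere to exercise specificity rejection. Every
planted variant is recorded in a manifest with its signed net length.
A seed is mandatory and all outputs are byte-reproducible.

What it does **not** emulate: real nucleotide composition, linkage
disequilibrium, repeat and transposon structure, centromeric
polymorphism deserts, or annotation error. Passing tests therefore
demonstrate the correctness of the pipeline's arithmetic and logic, not
the empirical success rate of markers on real genomes — real-genome
rates are dominated by annotation quality and repeat content, which are
outside this model.

Six planted demonstration loci cover the behaviour classes end to end
(co-dominant, three-allele, PAV via primer-site deletion, dominant via
primer-site SNP handicap, shared non-reference allele, and an annotated
deletion absent from the haplotype for the audit path). Their sequences
are generated; only their size arithmetic and classification outcomes
are meaningful.

## Problem sizes and numerical choices

- End-to-end recovery runs on a 4 × 1 Mb genome with Indel rate 10⁻³,
  giving ~1000 target Indels ≥ 7 bp; every designed, genome-specific
  marker must recover its planted size shift exactly (the expected shift
  sums the signed net lengths of all planted Indels inside the amplicon,
  not just the target's).
- Percentages in summaries are rounded half-up to integers. Markers
  where neither allele amplifies are excluded from `n_tested` and
  reported separately as `n_failed`, keeping the count-sum invariant.
- All tie-breaks (candidate ordering, ranking, anchor assignment) are
  lexicographic on coordinates, making every output deterministic.
- Degenerate inputs fail loudly: empty FASTA, REF-mismatching records,
  overlapping variants in one track, boundary-straddling Indels,
  contradictory refinement calls, and tracks with no defined gaps all
  raise typed errors.

## Limitations

- Dominance prediction is a mismatch-count heuristic; it cannot capture
  template-specific amplification biases (one observed exception in
  practice — a non-reference allele amplifying preferentially — has no
  mechanism in this model and is not special-cased).
- In-silico PCR ignores primer thermodynamics at off-target sites
  (mismatch position within the non-clamp region is not weighted).
- The TSV track dialect carries no genotype or quality fields; tracks
  are assumed pre-filtered for confident homozygous calls.
- No liftover between assemblies; tracks must be annotated on the same
  reference they are applied to.
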