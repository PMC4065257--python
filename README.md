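# indelmark

Design agarose-scorable Indel markers for fine-mapping from a reference
genome and per-inbred polymorphism tracks.

## The problem

Positional cloning in maize (and any crop with a reference assembly and
resequenced parents) stalls at marker development: once a locus is mapped
to an interval, you need cheap PCR markers *inside* that interval,
scorable on a plain agarose gel, polymorphic between your two mapping
parents. Insertion–deletion (Indel) polymorphisms annotated against the
reference are ideal raw material — a primer pair flanking an Indel of
net size Δ amplifies products differing by Δ bp between the parents, and
a 4% agarose gel reads that difference directly.

`indelmark` turns a reference genome (FASTA) plus per-inbred variant
tracks (VCF, or a 5-column genome-browser TSV export) into PCR-ready
markers:

1. **filter** — keep Indels with net allele-length difference
   |len(REF) − len(ALT)| ≥ 7 bp (the smallest shift that genotypes
   reliably on 4% agarose across the 80–300 bp product range);
2. **design** — enumerate primer pairs flanking each Indel with the
   reference amplicon in [80, 300] bp, primers within standard length /
   Tm / GC windows, 3′ clamps free of polymorphisms, and (by default)
   whole primer footprints clear of linked SNPs and short Indels;
3. **specificity** — deterministic in-silico PCR over the whole genome
   (≤2 mismatches per primer, exact 3′ pentamer, products ≤2 kb); a pair
   is kept only if its designed locus is the single genome-wide product;
4. **predict & classify** — apply each inbred's track to the reference
   to get its haplotype, predict per-inbred product sizes and
   amplification failures, and classify every marker for an inbred pair:

   | verdict | meaning |
   |---|---|
   | `CO_DOMINANT` | both alleles amplify and their sizes resolve on the gel — heterozygotes scorable |
   | `DOMINANT` | both amplify alone, but one allele's primer sites carry sub-lethal mismatches and lose the mixed-template reaction |
   | `PAV` | presence–absence: one allele yields no product (3′-clamp variant, primer-site deletion, or divergence) |
   | `NON_POLYMORPHIC` | both amplify at indistinguishable sizes |
   | `FAILED` | neither amplifies |

5. **select / refine** — spacing statistics over a track, k evenly
   spaced candidate markers inside a mapping interval, and iterative
   interval refinement from recombinant genotypes.

Two product lengths resolve on the gel when
|a − b| ≥ max(4 bp, 0.05 · mean(a, b)) — which is why small products
(<150 bp) make small Indels easiest to score. A bundled generator
(`indelmark.simulate`) produces seeded synthetic genomes and tracks with
a ground-truth manifest, so the whole pipeline is testable offline.

## Worked example

```python
from indelmark import (PolymorphismTrack, SimConfig, simulate, filter_indels,
                       design_primers, build_haplotype, predict_amplicon,
                       classify_marker, is_specific)

sim = simulate(SimConfig(rng_seed=42, n_chroms=1, chrom_length=50_000))
track = sim.tracks["Mo17"]
targets = filter_indels(track, min_net_length=7)
print(f"{len(track)} polymorphisms, {len(targets)} Indels >= 7 bp")

b73 = build_haplotype(sim.genome, PolymorphismTrack(records=(), inbred_name="B73"))
mo17 = build_haplotype(sim.genome, track)
for indel in targets.records[:3]:
    pair = design_primers(sim.genome, indel, linked_track=track)[0]
    assert is_specific(sim.genome, pair)
    pa, pb = predict_amplicon(pair, b73), predict_amplicon(pair, mo17)
    cls = classify_marker(pa, pb)
    print(f"{indel.id}: B73 {pa.product_len} bp, Mo17 {pb.product_len} bp "
          f"-> {cls.verdict.value} (heteroduplex: {cls.heteroduplex_expected})")
```

prints

```
99 polymorphisms, 8 Indels >= 7 bp
Mo17.000003: B73 178 bp, Mo17 185 bp -> NON_POLYMORPHIC (heteroduplex: True)
Mo17.000013: B73 96 bp, Mo17 104 bp -> CO_DOMINANT (heteroduplex: True)
Mo17.000016: B73 167 bp, Mo17 176 bp -> CO_DOMINANT (heteroduplex: True)
```

The first marker carries a 7-bp shift on a 178-bp product: below the
5% relative threshold, so the homozygote bands co-migrate and the marker
is called non-polymorphic (the heteroduplex band would still betray a
heterozygote). The same-order shifts on 96- and 167-bp products resolve
and give co-dominant markers — the reason the designer prefers the
smallest legal amplicon.

The same pipeline is available from the shell:

```
indelmark simulate --seed 42 --out sim/
indelmark filter  --track sim/Mo17.vcf --min-net-length 7 --out sim/large.vcf
indelmark design  --genome sim/genome.fa --track sim/Mo17.vcf --out sim/primers.tsv
indelmark classify --genome sim/genome.fa --primers sim/primers.tsv \
    --track Mo17=sim/Mo17.vcf --pair B73/Mo17 --out sim/classes.tsv
indelmark select  --track sim/large.vcf --interval chr1:1-50000 -k 5
```

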