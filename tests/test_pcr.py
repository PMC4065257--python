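"""In-silico PCR scanning, amplicon prediction, gel model and classification."""

import numpy as np
import pytest

from indelmark import (
    AmpliconPrediction,
    GelModel,
    IndelRecord,
    PolymorphismTrack,
    ReferenceGenome,
    build_haplotype,
    classify_marker,
    insilico_pcr,
    is_specific,
    pair_from_intervals,
    predict_amplicon,
    resolvable_on_gel,
    validate_annotation,
)
from indelmark.pcr import AnnotationVerdict, FailureReason, Verdict
from indelmark.primers import reverse_complement


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def locus_genome():
    genome = ReferenceGenome(sequences={"chr1": _random_seq(1, 3000)})
    pair = pair_from_intervals(genome, "chr1", (1000, 1020), (1130, 1150), "m1")
    return genome, pair


class TestInsilicoPcr:
    def test_designed_locus_is_the_single_self_hit(self, locus_genome):
        genome, pair = locus_genome
        hits = insilico_pcr(genome, pair)
        assert len(hits) == 1
        (hit,) = hits
        assert hit.product_interval == (1000, 1150)
        assert hit.product_len == 150
        assert hit.fwd_mismatches == 0 and hit.rev_mismatches == 0
        assert is_specific(genome, pair)

    def test_verbatim_duplication_gives_two_hits(self, locus_genome):
        genome, pair = locus_genome
        dup = ReferenceGenome(
            sequences={
                "chr1": genome.sequences["chr1"],
                "chr2": _random_seq(2, 500)
                + genome.fetch("chr1", 950, 1200)
                + _random_seq(3, 500),
            }
        )
        hits = insilico_pcr(dup, pair)
        assert len(hits) == 2
        assert {h.chrom for h in hits} == {"chr1", "chr2"}
        assert all(h.product_len == 150 for h in hits)
        assert not is_specific(dup, pair)

    def test_reverse_strand_site_same_product_length(self, locus_genome):
        genome, pair = locus_genome
        flipped = ReferenceGenome(
            sequences={
                "chrR": _random_seq(4, 300)
                + reverse_complement(genome.fetch("chr1", 990, 1160))
                + _random_seq(5, 300)
            }
        )
        hits = insilico_pcr(flipped, pair)
        assert len(hits) == 1
        assert hits[0].product_len == 150
        # on the flipped copy the reverse primer binds the plus strand
        assert hits[0].plus_primer == "R"

    def test_mismatch_budget_is_monotone(self, locus_genome):
        genome, pair = locus_genome
        # plant a degenerate forward site (1 internal mismatch) next to a
        # clean reverse-complement reverse site
        seq = list(genome.sequences["chr1"])
        fwd = list(pair.forward_seq)
        fwd[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[fwd[3]]
        mutated = (
            "".join(seq[:2000])
            + "".join(fwd)
            + genome.fetch("chr1", 1020, 1130)
            + reverse_complement(pair.reverse_seq)
            + "".join(seq[2150:])
        )
        g2 = ReferenceGenome(sequences={"chr1": mutated})
        strict = insilico_pcr(g2, pair, max_mismatches=0)
        loose = insilico_pcr(g2, pair, max_mismatches=2)
        assert set(strict) <= set(loose)
        assert len(loose) > len(strict)

    def test_agrees_with_naive_sliding_scan(self, locus_genome):
        """Seeded scanning equals an exhaustive all-positions scan."""
        genome, pair = locus_genome
        seq = (
            genome.sequences["chr1"][:2500]
            + genome.fetch("chr1", 995, 1155)  # second copy of the locus
        )
        g2 = ReferenceGenome(sequences={"chr1": seq})
        max_mm, exact3, max_scan = 2, 5, 2000
        primers = {"F": pair.forward_seq, "R": pair.reverse_seq}

        def naive_sites(p):
            plus, minus = [], []
            rc = reverse_complement(p)
            for s in range(len(seq) - len(p) + 1):
                site = seq[s : s + len(p)]
                if (
                    site[-exact3:] == p[-exact3:]
                    and sum(a != b for a, b in zip(site, p)) <= max_mm
                ):
                    plus.append((s, sum(a != b for a, b in zip(site, p))))
                if (
                    site[:exact3] == rc[:exact3]
                    and sum(a != b for a, b in zip(site, rc)) <= max_mm
                ):
                    minus.append((s, sum(a != b for a, b in zip(site, rc))))
            return plus, minus

        expected = set()
        naive = {name: naive_sites(p) for name, p in primers.items()}
        for up_name, (plus, _) in naive.items():
            for down_name, (_, minus) in naive.items():
                for s, mm_up in plus:
                    for t, mm_down in minus:
                        end = t + len(primers[down_name])
                        if t > s and end - s <= max_scan:
                            fwd_mm = mm_up if up_name == "F" else mm_down
                            rev_mm = mm_down if down_name == "R" else mm_up
                            expected.add(("chr1", (s, end), fwd_mm, rev_mm, up_name))

        got = {
            (h.chrom, h.product_interval, h.fwd_mismatches, h.rev_mismatches,
             h.plus_primer)
            for h in insilico_pcr(g2, pair, max_mm, exact3, max_scan)
        }
        assert got == expected


# ---------------------------------------------------------------------------
# amplicon prediction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def predict_fixture():
    genome = ReferenceGenome(sequences={"chr1": _random_seq(8, 500)})
    # 154-bp reference amplicon: forward [100,120), reverse [234,254)
    pair = pair_from_intervals(genome, "chr1", (100, 120), (234, 254), "p1")
    return genome, pair


def _prediction(genome, pair, *records, name="Mo17"):
    track = PolymorphismTrack(records=records, inbred_name=name)
    return predict_amplicon(pair, build_haplotype(genome, track))


def _snp_at(genome, pos0):
    ref = genome.fetch("chr1", pos0, pos0 + 1)
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
    return IndelRecord("chr1", pos0 + 1, ref, alt, f"snp{pos0}")


class TestPredictAmplicon:
    def test_internal_deletion_shifts_product(self, predict_fixture):
        genome, pair = predict_fixture
        ref = genome.fetch("chr1", 160, 178)
        deletion = IndelRecord("chr1", 161, ref, ref[0], "del17")
        pred = _prediction(genome, pair, deletion)
        assert pred.amplifies and pred.product_len == 137
        assert pred.competition_handicap == 0

    def test_clean_site_amplifies_reference_size(self, predict_fixture):
        genome, pair = predict_fixture
        pred = _prediction(genome, pair, name="B73")
        assert pred.amplifies and pred.product_len == 154

    def test_snp_under_three_prime_clamp_kills_amplification(self, predict_fixture):
        genome, pair = predict_fixture
        pred = _prediction(genome, pair, _snp_at(genome, 119))  # fwd 3' base
        assert not pred.amplifies
        assert pred.failure_reason is FailureReason.PRIMER_SITE_VARIANT_3PRIME

    def test_internal_primer_snp_is_sublethal_handicap(self, predict_fixture):
        genome, pair = predict_fixture
        pred = _prediction(genome, pair, _snp_at(genome, 105))
        assert pred.amplifies and pred.product_len == 154
        assert pred.competition_handicap == 1

    def test_three_primer_snps_exceed_mismatch_budget(self, predict_fixture):
        genome, pair = predict_fixture
        snps = [_snp_at(genome, p) for p in (102, 106, 110)]
        pred = _prediction(genome, pair, *snps)
        assert not pred.amplifies
        assert pred.failure_reason is FailureReason.PRIMER_SITE_DIVERGENCE

    def test_deletion_removing_primer_bases_kills_amplification(
        self, predict_fixture
    ):
        genome, pair = predict_fixture
        ref = genome.fetch("chr1", 244, 275)  # eats reverse primer 5' half
        deletion = IndelRecord("chr1", 245, ref, ref[0], "primdel")
        pred = _prediction(genome, pair, deletion)
        assert not pred.amplifies
        assert pred.failure_reason is FailureReason.PRIMER_SITE_DELETED

    def test_insertion_splitting_primer_site_kills_amplification(
        self, predict_fixture
    ):
        genome, pair = predict_fixture
        ref = genome.fetch("chr1", 105, 106)
        ins = IndelRecord("chr1", 106, ref, ref + "ACGTA", "primins")
        pred = _prediction(genome, pair, ins)
        assert not pred.amplifies
        assert pred.failure_reason is FailureReason.PRIMER_SITE_DIVERGENCE


# ---------------------------------------------------------------------------
# gel model and classification
# ---------------------------------------------------------------------------


class TestResolvableOnGel:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (154, 137, True),   # 17-bp difference on a small product
            (150, 150, False),  # zero difference
            (300, 293, False),  # 7 bp at 296.5 bp mean: below 5% threshold
            (100, 93, True),    # same 7 bp resolves on a 96.5 bp mean product
        ],
    )
    def test_rule(self, a, b, expected):
        assert resolvable_on_gel(a, b) is expected
        assert resolvable_on_gel(b, a) is expected  # symmetry

    def test_relative_term_dominates_for_large_products(self):
        gel = GelModel(min_abs_diff=4, rel_diff_frac=0.05)
        assert resolvable_on_gel(100, 95, gel)       # 5 >= max(4, 4.875)
        assert not resolvable_on_gel(400, 395, gel)  # 5 < 19.875


def _pred(name, size=None, handicap=0, reason=FailureReason.NONE):
    return AmpliconPrediction(
        inbred_name=name,
        amplifies=size is not None,
        product_len=size,
        failure_reason=reason,
        competition_handicap=handicap,
    )


_FAIL = FailureReason.PRIMER_SITE_DIVERGENCE


class TestClassifyMarker:
    def test_resolvable_size_difference_is_co_dominant(self):
        cls = classify_marker(_pred("B73", 154), _pred("Mo17", 137))
        assert cls.verdict is Verdict.CO_DOMINANT
        assert cls.resolvable and cls.heteroduplex_expected
        assert cls.favored_allele is None

    def test_single_amplifying_allele_is_pav(self):
        cls = classify_marker(_pred("B73", 143), _pred("W22", None, reason=_FAIL))
        assert cls.verdict is Verdict.PAV
        assert cls.favored_allele == "B73"

    def test_handicap_difference_is_dominant(self):
        cls = classify_marker(_pred("B73", 201), _pred("Mo17", 190, handicap=1))
        assert cls.verdict is Verdict.DOMINANT
        assert cls.favored_allele == "B73"
        assert cls.heteroduplex_expected

    def test_identical_clean_products_are_non_polymorphic(self):
        cls = classify_marker(_pred("B73", 192), _pred("Mo17", 192))
        assert cls.verdict is Verdict.NON_POLYMORPHIC
        assert not cls.heteroduplex_expected

    def test_unresolvable_small_difference_is_non_polymorphic(self):
        cls = classify_marker(_pred("B73", 300), _pred("Mo17", 297))
        assert cls.verdict is Verdict.NON_POLYMORPHIC
        assert cls.heteroduplex_expected  # different sizes still heteroduplex

    def test_neither_allele_amplifying_is_failed(self):
        cls = classify_marker(
            _pred("A", None, reason=_FAIL), _pred("B", None, reason=_FAIL)
        )
        assert cls.verdict is Verdict.FAILED

    @pytest.mark.parametrize(
        "pa,pb",
        [
            (_pred("A", 154), _pred("B", 137)),
            (_pred("A", 143), _pred("B", None, reason=_FAIL)),
            (_pred("A", 201), _pred("B", 190, handicap=1)),
            (_pred("A", 192), _pred("B", 192)),
        ],
    )
    def test_symmetric_under_argument_swap(self, pa, pb):
        ab, ba = classify_marker(pa, pb), classify_marker(pb, pa)
        assert ab.verdict is ba.verdict
        assert ab.favored_allele == ba.favored_allele
        assert ab.resolvable == ba.resolvable
        assert ab.heteroduplex_expected == ba.heteroduplex_expected

    def test_size_structure_transitivity(self):
        """If A/B resolve and A and C share a size, B/C resolve identically."""
        a, b, c = _pred("A", 154), _pred("B", 137), _pred("C", 154)
        assert classify_marker(a, b).verdict is Verdict.CO_DOMINANT
        assert classify_marker(a, c).verdict is Verdict.NON_POLYMORPHIC
        assert classify_marker(b, c).verdict is Verdict.CO_DOMINANT


class TestValidateAnnotation:
    ANNOT = IndelRecord("chr1", 100, "A" + "C" * 17, "A", "del17")

    def test_expected_shift_is_concordant(self):
        verdict = validate_annotation(
            self.ANNOT, {"B73": 154, "Mo17": 137}, reference_inbred="B73"
        )
        assert verdict is AnnotationVerdict.CONCORDANT

    def test_equal_sizes_despite_annotated_indel(self):
        annot = IndelRecord("chr1", 100, "A" + "C" * 24, "A", "del24")
        verdict = validate_annotation(
            annot, {"B73": 192, "Mo17": 192}, reference_inbred="B73"
        )
        assert verdict is AnnotationVerdict.SAME_SIZE

    def test_deletion_amplifying_larger_product_is_wrong_direction(self):
        verdict = validate_annotation(
            self.ANNOT, {"B73": 154, "Mo17": 171}, reference_inbred="B73"
        )
        assert verdict is AnnotationVerdict.WRONG_DIRECTION

    def test_missing_product_reported(self):
        verdict = validate_annotation(
            self.ANNOT, {"B73": 154, "Mo17": None}, reference_inbred="B73"
        )
        assert verdict is AnnotationVerdict.NO_PRODUCT

    def test_missing_reference_size_errors(self):
        with pytest.raises(ValueError):
            validate_annotation(self.ANNOT, {"Mo17": 137}, reference_inbred="B73")
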