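"""Nucleotide/feature confusion counting, statistics, classification,
clique pairing and splice complexity."""

import math
import random

import pytest

from annodiff.compare import (
    CDS_MATCH,
    ConfusionCounts,
    EXON_MATCH,
    NON_MATCH,
    PERFECT_MATCH,
    UTR_MATCH,
    classify,
    compare_locus,
    compare_vectors,
    compute_stats,
    count_nucleotides,
    match_features,
    overall_identity,
    pair_cliques,
    splice_complexity,
    structural_aed,
)
from annodiff.model import GeneLocus, GenomicInterval, PREDICTION, REFERENCE
from annodiff.vectors import (
    ModelVector,
    TranscriptClique,
    encode_model_vector,
    model_vectors_for,
)

from conftest import make_gene, make_transcript


def raw_vector(symbols, locus_start=1, source=REFERENCE):
    locus = GenomicInterval("chr1", locus_start, locus_start + len(symbols) - 1)
    return ModelVector(locus, symbols, TranscriptClique((), source))


def clique_vector(transcripts, locus, source=REFERENCE):
    return encode_model_vector(TranscriptClique(tuple(transcripts), source), locus)


class TestCountNucleotides:
    def test_identity_case(self):
        s = "C" * 60 + "G" * 140
        c = count_nucleotides(raw_vector(s), raw_vector(s), "CDS")
        assert (c.tp, c.fp, c.fn, c.tn) == (60, 0, 0, 140)

    def test_positionwise_counting(self):
        c = count_nucleotides(raw_vector("CCCCGGGG"), raw_vector("CCGGGGCC"), "CDS")
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 2, 2)

    def test_all_G_gives_undefined_sn_sp(self):
        c = count_nucleotides(raw_vector("GGGG"), raw_vector("GGGG"), "CDS")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 4)
        p = compute_stats(c)
        assert p.sensitivity is None and p.specificity is None

    def test_utr_class_pools_F_and_T(self):
        c = count_nucleotides(raw_vector("FFTT"), raw_vector("TTFF"), "UTR")
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_nucleotides(raw_vector("CC"), raw_vector("C"), "CDS")

    def test_counts_sum_to_locus_length(self):
        rng = random.Random(0)
        for _ in range(20):
            n = rng.randint(1, 60)
            a = "".join(rng.choice("CFGIT") for _ in range(n))
            b = "".join(rng.choice("CFGIT") for _ in range(n))
            for cls in ("CDS", "UTR"):
                c = count_nucleotides(raw_vector(a), raw_vector(b), cls)
                assert c.total == n


class TestOverallIdentity:
    def test_identical(self):
        assert overall_identity(raw_vector("GFCIT"), raw_vector("GFCIT")) == 1.0

    def test_four_of_five(self):
        assert overall_identity(raw_vector("GFCIT"), raw_vector("GGCIT")) == 0.8

    def test_fully_disjoint(self):
        assert overall_identity(raw_vector("CCCC"), raw_vector("GGGG")) == 0.0

    def test_smc_on_cds_class_equals_collapsed_identity(self):
        """SMC for the CDS class is overall identity after collapsing the
        alphabet to {C, not-C}."""
        rng = random.Random(5)
        for _ in range(30):
            n = rng.randint(1, 80)
            a = "".join(rng.choice("CFGIT") for _ in range(n))
            b = "".join(rng.choice("CFGIT") for _ in range(n))
            smc = compute_stats(
                count_nucleotides(raw_vector(a), raw_vector(b), "CDS")
            ).smc
            collapsed_a = "".join("C" if x == "C" else "x" for x in a)
            collapsed_b = "".join("C" if x == "C" else "x" for x in b)
            ident = overall_identity(raw_vector(collapsed_a), raw_vector(collapsed_b))
            assert smc == pytest.approx(ident)


class TestMatchFeatures:
    def test_identical_structures(self):
        segs = [(11, 40), (61, 90), (120, 180)]
        c = match_features(segs, segs)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 0)

    def test_one_end_off(self):
        c = match_features([(11, 40), (61, 90)], [(11, 40), (61, 95)])
        assert (c.tp, c.fp, c.fn) == (1, 1, 1)

    def test_start_off_by_one_is_a_miss(self):
        c = match_features([(12, 40)], [(11, 40)])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_duplicate_reference_segments_consumed_once_each(self):
        c = match_features([(1, 10)], [(1, 10), (1, 10)])
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)


class TestComputeStats:
    def test_hand_derived_panel(self):
        p = compute_stats(ConfusionCounts(80, 10, 20, 90))
        assert p.sensitivity == pytest.approx(0.8)
        assert p.specificity == pytest.approx(0.8889, abs=1e-4)
        assert p.f1 == pytest.approx(0.8421, abs=1e-4)
        assert p.aed == pytest.approx(0.1556, abs=1e-4)
        assert p.smc == pytest.approx(0.85)
        assert p.cc == pytest.approx(0.7035, abs=1e-4)

    def test_perfect_agreement_limit(self):
        p = compute_stats(ConfusionCounts(42, 0, 0, 0))
        assert p.sensitivity == p.specificity == p.f1 == 1.0
        assert p.aed == 0.0

    def test_total_disagreement_limit(self):
        p = compute_stats(ConfusionCounts(0, 7, 9, 0))
        assert p.sensitivity == 0.0 and p.specificity == 0.0
        assert p.aed == 1.0

    def test_feature_level_has_no_smc_cc(self):
        p = compute_stats(ConfusionCounts(3, 1, 1, 0), "feature")
        assert p.smc is None and p.cc is None

    def test_values_in_range_on_random_counts(self):
        rng = random.Random(3)
        for _ in range(200):
            c = ConfusionCounts(*(rng.randint(0, 50) for _ in range(4)))
            p = compute_stats(c)
            for v in (p.sensitivity, p.specificity, p.f1, p.aed, p.smc):
                assert v is None or 0.0 <= v <= 1.0
            assert p.cc is None or -1.0 <= p.cc <= 1.0


LOCUS = GenomicInterval("chr1", 1, 200)


def t_ref():
    return make_transcript("r1", [(11, 40), (61, 90)], [(21, 40), (61, 80)])


class TestClassify:
    def test_identical_strings_perfect(self):
        a = clique_vector([t_ref()], LOCUS)
        b = clique_vector([t_ref()], LOCUS, PREDICTION)
        assert classify(a, b) == PERFECT_MATCH

    def test_longer_utr_same_cds_is_cds_match(self):
        a = clique_vector([t_ref()], LOCUS)
        b = clique_vector(
            [make_transcript("p1", [(1, 40), (61, 90)], [(21, 40), (61, 80)])],
            LOCUS, PREDICTION,
        )
        assert classify(a, b) == CDS_MATCH

    def test_shifted_cds_same_exons_is_exon_match(self):
        a = clique_vector([t_ref()], LOCUS)
        b = clique_vector(
            [make_transcript("p1", [(11, 40), (61, 90)], [(27, 40), (61, 80)])],
            LOCUS, PREDICTION,
        )
        assert classify(a, b) == EXON_MATCH

    def test_same_utrs_different_exons_is_utr_match(self):
        # internal exon boundary moved within the CDS: UTRs untouched
        a = clique_vector([t_ref()], LOCUS)
        b = clique_vector(
            [make_transcript("p1", [(11, 35), (61, 90)], [(21, 35), (61, 80)])],
            LOCUS, PREDICTION,
        )
        assert classify(a, b) == UTR_MATCH

    def test_everything_differs_is_non_match(self):
        a = clique_vector([t_ref()], LOCUS)
        b = clique_vector(
            [make_transcript("p1", [(5, 35), (61, 95)], [(25, 35), (61, 85)])],
            LOCUS, PREDICTION,
        )
        assert classify(a, b) == NON_MATCH

    def test_perfect_iff_identity_one(self):
        rng = random.Random(9)
        for _ in range(50):
            s = rng.randint(1, 120)
            ln = rng.randint(30, 60)
            a = clique_vector(
                [make_transcript("a", [(s, s + ln)], [(s + 5, s + ln - 5)])], LOCUS
            )
            s2 = s + rng.choice([0, 0, 3])
            b = clique_vector(
                [make_transcript("b", [(s2, s2 + ln)], [(s2 + 5, s2 + ln - 5)])],
                LOCUS, PREDICTION,
            )
            assert (classify(a, b) == PERFECT_MATCH) == (
                overall_identity(a, b) == 1.0
            )


def locus_for(ref_ts, pred_ts, interval=LOCUS):
    ref_genes = tuple(
        make_gene(f"rg{i}", [t], REFERENCE) for i, t in enumerate(ref_ts)
    )
    pred_genes = tuple(
        make_gene(f"pg{i}", [t], PREDICTION) for i, t in enumerate(pred_ts)
    )
    return GeneLocus(interval, ref_genes, pred_genes)


class TestPairCliques:
    def test_single_pair_no_unmatched(self):
        locus = locus_for([t_ref()], [t_ref()])
        lc = compare_locus(locus)
        assert len(lc.pairs) == 1
        assert lc.unmatched_ref == [] and lc.unmatched_pred == []

    def test_identity_outranks_imperfect_match(self):
        r1 = t_ref()
        r2 = make_transcript("r2", [(30, 90)], [(40, 80)])  # overlaps r1
        pred = make_transcript("p1", [(11, 40), (61, 90)], [(21, 40), (61, 80)])
        locus = locus_for([r1, r2], [pred])
        lc = compare_locus(locus)
        (pair,) = lc.pairs
        assert pair.classification == PERFECT_MATCH
        assert pair.ref_vector.clique.id == "r1"
        assert [c.id for c in lc.unmatched_ref] == ["r2"]

    def test_absent_prediction_compared_against_all_G(self):
        locus = locus_for([t_ref()], [])
        lc = compare_locus(locus)
        (pair,) = lc.pairs
        assert pair.classification == NON_MATCH
        assert pair.pred_vector.symbols == "G" * LOCUS.length
        assert pair.nuc_panel("CDS").sensitivity == 0.0
        # every reference C/F/T position is a false negative
        assert pair.nuc_counts["CDS"].fn == 40
        assert [c.id for c in lc.unmatched_ref] == ["r1"]
        assert lc.counted_pairs == []

    @pytest.mark.parametrize("seed", range(10))
    def test_no_clique_assigned_twice(self, seed):
        rng = random.Random(seed)

        def random_side(prefix):
            out = []
            for i in range(rng.randint(1, 5)):
                s = rng.randint(1, 150)
                ln = rng.randint(20, 50)
                out.append(
                    make_transcript(
                        f"{prefix}{i}", [(s, s + ln)], [(s + 4, s + ln - 4)]
                    )
                )
            return out

        locus = locus_for(random_side("r"), random_side("p"))
        lc = compare_locus(locus)
        ref_ids = [p.ref_vector.clique.id for p in lc.pairs]
        pred_ids = [p.pred_vector.clique.id for p in lc.pairs]
        assert len(set(ref_ids)) == len(ref_ids)
        assert len(set(pred_ids)) == len(pred_ids)
        n_ref = len(model_vectors_for(locus.transcripts(REFERENCE), LOCUS, REFERENCE))
        n_pred = len(model_vectors_for(locus.transcripts(PREDICTION), LOCUS, PREDICTION))
        assert len(lc.pairs) + len(lc.unmatched_ref) == n_ref
        assert len(lc.pairs) + len(lc.unmatched_pred) == n_pred


def random_structured_transcript(rng, name, lo=1, hi=150):
    s = rng.randint(lo, hi)
    n_ex = rng.randint(1, 3)
    exons = []
    pos = s
    for _ in range(n_ex):
        ln = rng.randint(20, 40)
        exons.append((pos, pos + ln - 1))
        pos += ln + rng.randint(10, 25)
    total = sum(e - x + 1 for x, e in exons)
    u5, u3 = rng.randint(2, 8), rng.randint(2, 8)
    cds = []
    idx = 0
    for x, e in exons:
        ln = e - x + 1
        a, b = max(u5, idx), min(total - u3, idx + ln)
        if a < b:
            cds.append((x + a - idx, x + b - idx - 1))
        idx += ln
    return make_transcript(name, exons, cds, strand=rng.choice("+-"))


class TestSymmetry:
    @pytest.mark.parametrize("seed", range(40))
    def test_swapping_roles_swaps_sn_sp_and_fp_fn(self, seed):
        """Reference/prediction are labels: swapping them exchanges
        Sn with Sp and FP with FN, and preserves F1, AED, SMC, CC,
        identity and the classification."""
        rng = random.Random(seed)
        big = GenomicInterval("chr1", 1, 400)
        a = clique_vector([random_structured_transcript(rng, "a")], big)
        b_t = random_structured_transcript(rng, "b")
        b = clique_vector([b_t], big, PREDICTION)
        fwd = compare_vectors(a, b)
        rev = compare_vectors(
            clique_vector([b_t], big, REFERENCE),
            ModelVector(big, a.symbols, TranscriptClique(a.clique.members, PREDICTION)),
        )
        for cls in ("CDS", "UTR"):
            f, r = fwd.nuc_counts[cls], rev.nuc_counts[cls]
            assert (f.tp, f.fp, f.fn, f.tn) == (r.tp, r.fn, r.fp, r.tn)
            fp_, rp = fwd.nuc_panel(cls), rev.nuc_panel(cls)
            assert fp_.sensitivity == rp.specificity
            assert fp_.specificity == rp.sensitivity
            for attr in ("f1", "aed", "smc", "cc"):
                x, y = getattr(fp_, attr), getattr(rp, attr)
                assert (x is None) == (y is None)
                if x is not None:
                    assert x == pytest.approx(y)
        assert fwd.identity == rev.identity
        assert fwd.classification == rev.classification


class TestSpliceComplexity:
    def test_single_transcript_is_zero(self):
        assert splice_complexity([t_ref()], LOCUS) == 0.0

    def test_identical_isoforms_are_zero(self):
        a = t_ref()
        b = make_transcript("r2", [(11, 40), (61, 90)], [(21, 40), (61, 80)])
        assert splice_complexity([a, b], LOCUS) == 0.0

    def test_two_isoforms_match_brute_force_aed(self):
        """One isoform skips a 20 bp internal piece of the second exon;
        the expected AED is recomputed here by direct position-wise
        confusion over the two single-transcript vectors."""
        a = t_ref()
        b = make_transcript("r2", [(11, 40), (81, 90)], [(21, 40), (81, 85)])
        va = clique_vector([a], LOCUS)
        vb = clique_vector([b], LOCUS)
        cls_of = {"C": "C", "F": "U", "T": "U", "I": "I", "G": None}
        tp = fp = fn = 0
        for x, y in zip(va.symbols, vb.symbols):
            cx, cy = cls_of[x], cls_of[y]
            if cx is not None and cx == cy:
                tp += 1
            else:
                fp += cy is not None
                fn += cx is not None
        expected = 1 - (tp / (tp + fn) + tp / (tp + fp)) / 2
        assert splice_complexity([a, b], LOCUS) == pytest.approx(expected)
        assert structural_aed(va, vb) == pytest.approx(expected)

    def test_mean_over_all_pairs(self):
        rng = random.Random(2)
        ts = [random_structured_transcript(rng, f"t{i}") for i in range(4)]
        big = GenomicInterval("chr1", 1, 400)
        vecs = [clique_vector([t], big) for t in ts]
        pairwise = [
            structural_aed(vecs[i], vecs[j])
            for i in range(4) for j in range(i + 1, 4)
        ]
        assert splice_complexity(ts, big) == pytest.approx(
            sum(pairwise) / len(pairwise)
        )


class TestPerfectMatchImplications:
    def test_perfect_match_panels_all_perfect(self):
        lc = compare_locus(locus_for([t_ref()], [t_ref()]))
        (pair,) = lc.pairs
        assert pair.classification == PERFECT_MATCH
        assert pair.identity == 1.0
        for cls in ("CDS", "UTR"):
            p = pair.nuc_panel(cls)
            for v, want in ((p.sensitivity, 1), (p.specificity, 1), (p.f1, 1),
                            (p.aed, 0), (p.smc, 1), (p.cc, 1)):
                if v is not None:
                    assert v == pytest.approx(want)
        for ft in ("exon", "cds_segment", "utr_segment"):
            p = pair.feat_panel(ft)
            if p.sensitivity is not None:
                assert p.sensitivity == p.specificity == 1.0
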