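"""Putative SNP detection thresholds, screening rules, summaries."""
import numpy as np
import pytest
from intervaltree import IntervalTree

from oracles import oracle_detect, oracle_screen
from poolsnp._seq import encode
from poolsnp.calling import (
    CallPolicy,
    DIRTY_FLANK,
    FILTERED_FAIL,
    FILTERED_PASS,
    IN_REPEAT,
    LOW_MAF,
    NOT_BIALLELIC,
    SnpCall,
    classify_substitution,
    detect_putative,
    screen_quality,
    summarize,
)
from poolsnp.mapping import PileupColumn

POLICY = CallPolicy()


def col(bases: str, quals=None, species=None, flank=None, pos=100,
        contig="c"):
    n = len(bases)
    quals = np.full(n, 35.0, dtype=np.float32) if quals is None \
        else np.asarray(quals, dtype=np.float32)
    flank = np.full(n, 30.0, dtype=np.float32) if flank is None \
        else np.asarray(flank, dtype=np.float32)
    species = np.zeros(n, dtype=np.uint8) if species is None \
        else np.asarray(species, dtype=np.uint8)
    return PileupColumn(contig, pos, encode(bases), quals, flank, species)


def snp(contig, pos, maf=0.3, n_alleles=2, ref="A", major="A", minor="G",
        status="putative"):
    counts = {major: 7, minor: 3}
    return SnpCall(
        contig=contig, position=pos, ref=ref, counts=counts,
        counts_channel=counts, counts_blue={}, depth=10, n_alleles=n_alleles,
        major=major, minor=minor, maf=maf,
        substitution_class=classify_substitution(major, minor), status=status,
    )


class TestDetectPutative:
    def test_minimal_depth_four_with_two_variant_reads(self):
        call = detect_putative(col("AAGG"), POLICY, "A")
        assert call is not None
        assert {call.major, call.minor} == {"A", "G"}
        assert call.maf == 0.5
        assert call.substitution_class == "transition"

    def test_depth_three_is_never_a_snp(self):
        assert detect_putative(col("AGG"), POLICY, "A") is None

    def test_single_variant_read_is_not_a_snp(self):
        assert detect_putative(col("A" * 19 + "G"), POLICY, "A") is None

    def test_unscorable_reference_base(self):
        assert detect_putative(col("AAGG"), POLICY, "N") is None

    def test_low_quality_observations_do_not_participate(self):
        # two G reads at Q24 fall below the central-quality gate
        call = detect_putative(
            col("AAAAGG", quals=[35, 35, 35, 35, 24, 24]), POLICY, "A"
        )
        assert call is None

    def test_poor_flank_quality_excludes_observation(self):
        call = detect_putative(
            col("AAAAGG", flank=[30, 30, 30, 30, 19, 19]), POLICY, "A"
        )
        assert call is None

    def test_n_observations_never_count(self):
        assert detect_putative(col("ANNN"), POLICY, "A") is None

    def test_maf_uses_qualified_depth_denominator(self):
        call = detect_putative(
            col("AAAAAAGGGG", quals=[35] * 8 + [10, 10]), POLICY, "A"
        )
        assert call.depth == 8
        assert call.maf == pytest.approx(2 / 8)

    def test_reference_absent_from_observations(self):
        call = detect_putative(col("GGGGTTTT"), POLICY, "A")
        assert call is not None
        assert {call.major, call.minor} == {"G", "T"}

    def test_deletion_allele_yields_indel_class(self):
        call = detect_putative(col("AAA--"), POLICY, "A")
        assert call is not None
        assert call.substitution_class == "indel"
        assert not call.is_snp


class TestClassifySubstitution:
    @pytest.mark.parametrize("pair,expected", [
        (("A", "G"), "transition"), (("C", "T"), "transition"),
        (("A", "C"), "transversion"), (("A", "T"), "transversion"),
        (("C", "G"), "transversion"), (("G", "T"), "transversion"),
    ])
    def test_all_unordered_pairs(self, pair, expected):
        assert classify_substitution(*pair) == expected
        assert classify_substitution(*pair[::-1]) == expected

    def test_two_transitions_four_transversions(self):
        from itertools import combinations

        classes = [classify_substitution(a, b)
                   for a, b in combinations("ACGT", 2)]
        assert classes.count("transition") == 2
        assert classes.count("transversion") == 4

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")


class TestScreenQuality:
    def test_maf_exactly_10pct_is_inclusive(self):
        calls = [snp("c", 100, maf=0.10)]
        out = screen_quality(calls, {"c": np.array([100])}, None, POLICY)
        assert out[0].status == FILTERED_PASS

    def test_maf_just_below_10pct_fails(self):
        calls = [snp("c", 100, maf=0.0999)]
        out = screen_quality(calls, {"c": np.array([100])}, None, POLICY)
        assert out[0].fail_reasons == (LOW_MAF,)

    def test_two_snps_10bp_apart_both_dirty(self):
        calls = [snp("c", 100), snp("c", 110)]
        nbrs = {"c": np.array([100, 110])}
        out = screen_quality(calls, nbrs, None, POLICY)
        assert [c.status for c in out] == [FILTERED_FAIL] * 2
        assert all(DIRTY_FLANK in c.fail_reasons for c in out)

    def test_snps_16bp_apart_are_clean(self):
        calls = [snp("c", 100), snp("c", 116)]
        nbrs = {"c": np.array([100, 116])}
        out = screen_quality(calls, nbrs, None, POLICY)
        assert [c.status for c in out] == [FILTERED_PASS] * 2

    def test_failed_neighbor_still_contaminates(self):
        # the neighbor at 110 is itself a fail (low maf) but still counts
        calls = [snp("c", 100), snp("c", 110, maf=0.05)]
        out = screen_quality(calls, {"c": np.array([100, 110])}, None, POLICY)
        assert DIRTY_FLANK in out[0].fail_reasons

    def test_indel_neighbor_contaminates(self):
        calls = [snp("c", 100)]
        out = screen_quality(calls, {"c": np.array([100, 108])}, None, POLICY)
        assert out[0].fail_reasons == (DIRTY_FLANK,)

    def test_triallelic_site_fails_biallelic_rule(self):
        calls = [snp("c", 100, maf=0.3, n_alleles=3)]
        out = screen_quality(calls, {"c": np.array([100])}, None, POLICY)
        assert out[0].fail_reasons == (NOT_BIALLELIC,)

    def test_repeat_mask_overrides_everything_else(self):
        mask = {"c": IntervalTree()}
        mask["c"].addi(90, 120)
        calls = [snp("c", 100)]
        out = screen_quality(calls, {"c": np.array([100])}, mask, POLICY)
        assert IN_REPEAT in out[0].fail_reasons

    def test_unsorted_input_is_a_hard_error(self):
        calls = [snp("c", 200), snp("c", 100)]
        with pytest.raises(ValueError, match="sorted"):
            screen_quality(calls, {}, None, POLICY)


class TestOracleAgreement:
    def test_random_columns_match_rule_transcription(self, rng):
        """200 random columns: detection identical to the plain transcription."""
        for _ in range(200):
            depth = int(rng.integers(1, 60))
            bases = "".join(
                rng.choice(list("ACGTN-"), size=depth,
                           p=[.55, .15, .15, .05, .05, .05])
            )
            quals = rng.integers(5, 41, size=depth)
            flank = rng.integers(10, 40, size=depth)
            species = rng.integers(0, 2, size=depth)
            ref = str(rng.choice(list("ACGTN")))
            c = col(bases, quals=quals, flank=flank, species=species)
            got = detect_putative(c, POLICY, ref)
            obs = [(b, int(q), int(f), int(s))
                   for b, q, f, s in zip(bases, quals, flank, species)]
            exp = oracle_detect(obs, ref)
            if exp is None:
                assert got is None
            else:
                major, minor, maf, n_alleles, is_indel = exp
                assert got is not None
                assert (got.major, got.minor) == (major, minor)
                assert got.maf == pytest.approx(maf)
                assert got.n_alleles == n_alleles
                assert (got.substitution_class == "indel") == is_indel

    def test_screening_matches_rule_transcription(self, rng):
        positions = np.sort(rng.choice(2000, size=40, replace=False))
        mask_iv = [(300, 400), (1200, 1300)]
        mask = {"c": IntervalTree()}
        for s, e in mask_iv:
            mask["c"].addi(s, e)
        calls = [
            snp("c", int(p), maf=float(rng.choice([0.05, 0.1, 0.3])),
                n_alleles=int(rng.choice([2, 3])))
            for p in positions
        ]
        out = screen_quality(calls, {"c": positions}, mask, POLICY)
        for c in out:
            expected = oracle_screen(
                dict(pos=c.position, maf=c.maf, n_alleles=c.n_alleles,
                     neighbors=positions.tolist(), mask=mask_iv)
            )
            assert sorted(c.fail_reasons) == sorted(expected)
            assert (c.status == FILTERED_PASS) == (not expected)


class TestMonotonicity:
    def test_raising_min_maf_never_gains_passes(self, rng):
        calls = [snp("c", int(p), maf=float(rng.uniform(0, 0.5)))
                 for p in np.sort(rng.choice(5000, size=60, replace=False))]
        passes = []
        for maf in (0.05, 0.10, 0.20):
            policy = CallPolicy(min_maf=maf)
            out = screen_quality(
                calls, {"c": np.array([c.position for c in calls])}, None,
                policy,
            )
            passes.append(sum(c.status == FILTERED_PASS for c in out))
        assert passes[0] >= passes[1] >= passes[2]

    def test_raising_min_depth_never_gains_putative_calls(self, rng):
        columns = []
        for _ in range(150):
            depth = int(rng.integers(1, 30))
            bases = "".join(rng.choice(list("ACGT"), size=depth,
                                       p=[.6, .2, .15, .05]))
            columns.append(col(bases, quals=rng.integers(15, 41, size=depth)))
        counts = []
        for d in (2, 4, 8):
            policy = CallPolicy(min_depth=d)
            counts.append(
                sum(detect_putative(c, policy, "A") is not None
                    for c in columns)
            )
        assert counts[0] >= counts[1] >= counts[2]


class TestSummarize:
    def test_empty_call_set(self):
        s = summarize([], {"c": "A" * 200})
        assert s.total_snps == 0 and s.transitions == 0
        assert s.snp_per_100bp == 0.0 and s.contigs_with_snps == 0

    def test_density_arithmetic(self):
        calls = [
            snp("c", 10, major="A", minor="G"),   # transition
            snp("c", 30, major="C", minor="T"),   # transition
            snp("c", 60, major="G", minor="A"),   # transition
            snp("c", 90, major="A", minor="C"),   # transversion
        ]
        s = summarize(calls, {"c": "A" * 200})
        assert s.total_snps == 4
        assert (s.transitions, s.transversions) == (3, 1)
        assert s.snp_per_100bp == pytest.approx(2.0)
        assert s.contigs_with_snps == 1

    def test_transitions_plus_transversions_equals_total(self, small_dataset):
        for view, calls in small_dataset.screened.items():
            s = summarize([c for c in calls if c.is_snp],
                          small_dataset.contigs)
            assert s.transitions + s.transversions == s.total_snps

    def test_maf_histogram_bins_are_005_wide(self):
        calls = [snp("c", 10 + 20 * i, maf=m) for i, m in
                 enumerate([0.04, 0.06, 0.12, 0.49])]
        s = summarize(calls, {"c": "A" * 1000})
        assert s.maf_hist == {0: 1, 1: 1, 2: 1, 9: 1}


class TestPolicyValidation:
    def test_variant_count_cannot_exceed_depth(self):
        with pytest.raises(ValueError):
            CallPolicy(min_depth=2, min_variant_count=3)

    def test_min_maf_range(self):
        with pytest.raises(ValueError):
            CallPolicy(min_maf=0.6)
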