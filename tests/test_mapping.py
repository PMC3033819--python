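"""Read placement: inclusion rule, exhaustive-DP agreement, pileups, SAM."""
import numpy as np
import pytest

from oracles import sw_best_score
from poolsnp._seq import revcomp, string_to_phred
from poolsnp.mapping import (
    AlignPolicy,
    ContigIndex,
    Pileup,
    build_pileup,
    import_sam,
    map_read,
    map_reads,
    write_sam,
)

POLICY = AlignPolicy()


@pytest.fixture(scope="module")
def contig_10kb():
    rng = np.random.default_rng(77)
    return "".join(rng.choice(list("ACGT"), size=10_000))


@pytest.fixture(scope="module")
def index_10kb(contig_10kb):
    return ContigIndex({"ref1": contig_10kb})


def mutate(seq: str, positions, rng=None):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestMapRead:
    def test_exact_substring_maps_with_full_similarity(self, contig_10kb,
                                                       index_10kb):
        read = contig_10kb[4000:4036]
        p = map_read("CH|r|0", read, index_10kb)
        assert p is not None
        assert (p.contig, p.start, p.strand) == ("ref1", 4000, "+")
        assert p.similarity == 1.0 and p.aligned_fraction == 1.0
        assert p.edit == [("=", 36)]

    def test_reverse_strand_read_is_placed(self, contig_10kb, index_10kb):
        read = revcomp(contig_10kb[2000:2050])
        p = map_read("BL|r|1", read, index_10kb)
        assert p is not None
        assert (p.start, p.strand) == (2000, "-")
        assert p.similarity == 1.0

    def test_21_of_100_mismatches_fails_80pct_similarity(self, contig_10kb,
                                                         index_10kb):
        # interior mismatches spaced 4 apart keep the full-length local
        # alignment optimal: similarity 79/100 = 0.79 < 0.80
        read = mutate(contig_10kb[1000:1100], [3 + 4 * k for k in range(21)])
        assert map_read("CH|r|2", read, index_10kb) is None

    def test_20_of_100_mismatches_passes_at_the_boundary(self, contig_10kb,
                                                         index_10kb):
        read = mutate(contig_10kb[1000:1100], [3 + 4 * k for k in range(20)])
        p = map_read("CH|r|3", read, index_10kb)
        assert p is not None
        assert p.similarity == pytest.approx(0.80)
        assert p.start == 1000

    def test_random_read_is_unmappable(self, index_10kb, rng):
        read = "".join(rng.choice(list("ACGT"), size=50))
        assert map_read("CH|r|4", read, index_10kb) is None

    def test_deletion_read_gets_gapped_placement(self, contig_10kb,
                                                 index_10kb):
        read = contig_10kb[3000:3030] + contig_10kb[3032:3052]
        p = map_read("CH|r|5", read, index_10kb)
        assert p is not None and p.start == 3000
        assert ("D", 2) in p.edit
        assert p.ref_span == 52
        assert p.similarity == pytest.approx(50 / 52)

    def test_insertion_read_gets_gapped_placement(self, contig_10kb,
                                                  index_10kb):
        read = contig_10kb[3000:3025] + "GG" + contig_10kb[3025:3048]
        p = map_read("CH|r|6", read, index_10kb)
        assert p is not None and p.start == 3000
        assert ("I", 2) in p.edit
        assert p.ref_span == 48

    def test_tie_breaks_to_lower_contig_then_start(self):
        block = "ATGCCGTTAGCATCCGATAACGGATTGCATTGCGAGCTAG"
        filler1 = "TGTAAGCCTAGCCTACAACG"
        filler2 = "GCATTAACATGGCGTATACT"
        contigs = {
            "b": filler1 + block + filler2,
            "a": filler2 + block + block + filler1,
        }
        index = ContigIndex(contigs)
        p = map_read("CH|r|7", block, index)
        assert (p.contig, p.start) == ("a", 20)

    def test_empty_read_returns_none(self, index_10kb):
        assert map_read("CH|r|8", "", index_10kb) is None


class TestSmithWatermanAgreement:
    def test_planted_reads_score_equal_to_exhaustive_dp(self, contig_10kb,
                                                        index_10kb, rng):
        """Placements match full Smith-Waterman over every contig position."""
        for i in range(60):
            start = int(rng.integers(0, len(contig_10kb) - 50))
            # mutations stay left of the last 14 bp so an exact k-mer seed
            # always survives (seed-and-extend needs one clean 12-mer)
            n_mut = int(rng.integers(0, 7))
            pos = rng.choice(36, size=n_mut, replace=False)
            read = mutate(contig_10kb[start : start + 50], pos)
            if rng.random() < 0.5:
                read = revcomp(read)
            p = map_read(f"CH|r|{i}", read, index_10kb)
            assert p is not None, f"read {i} (from {start}) not placed"
            fwd, _ = sw_best_score(read, contig_10kb)
            rev, _ = sw_best_score(revcomp(read), contig_10kb)
            assert p.score == max(fwd, rev)
            # the edit script must account for the score it claims
            m = sum(n for op, n in p.edit if op == "=")
            x = sum(n for op, n in p.edit if op == "X")
            ins = sum(n for op, n in p.edit if op == "I")
            dels = sum(n for op, n in p.edit if op == "D")
            assert p.score == m - 2 * x - 3 * (ins + dels)
            assert p.similarity == pytest.approx(m / (m + x + ins + dels))

    def test_random_reads_agree_with_dp_on_rejection(self, contig_10kb,
                                                     index_10kb, rng):
        """Random reads: a null placement implies no DP alignment both
        strong (score) and long enough to pass the inclusion rule."""
        for i in range(30):
            read = "".join(rng.choice(list("ACGT"), size=50))
            p = map_read(f"CH|q|{i}", read, index_10kb)
            if p is None:
                best, _ = sw_best_score(read, contig_10kb)
                rev, _ = sw_best_score(revcomp(read), contig_10kb)
                # passing needs >= 25 aligned bases at >= 80% similarity,
                # i.e. score >= 25*(1*0.8 - 2*0.2) = 10
                assert max(best, rev) < 50 * 0.8  # loose upper witness
            else:
                assert p.similarity >= 0.8 and p.aligned_fraction >= 0.5


class TestPileup:
    def test_single_exact_read_gives_depth_one_columns(self, contig_10kb,
                                                       index_10kb):
        read = contig_10kb[100:150]
        p = map_read("CH|p|0", read, index_10kb)
        store = {"CH|p|0": (read, np.full(50, 35))}
        pile = build_pileup([p], store, {"ref1": contig_10kb})
        cols = list(pile.columns("ref1"))
        assert len(cols) == 50
        assert all(c.depth_total == 1 for c in cols)
        assert [c.position for c in cols] == list(range(100, 150))

    def test_disagreeing_overlap_shows_both_bases(self, contig_10kb,
                                                  index_10kb):
        a = contig_10kb[200:250]
        b = mutate(contig_10kb[210:260], [15])  # disagrees at ref pos 225
        pa = map_read("CH|p|1", a, index_10kb)
        pb = map_read("BL|p|2", b, index_10kb)
        store = {"CH|p|1": (a, np.full(50, 35)), "BL|p|2": (b, np.full(50, 35))}
        pile = build_pileup([pa, pb], store, {"ref1": contig_10kb})
        col = pile.column("ref1", 225)
        assert col.depth_total == 2
        assert len({obs[0] for obs in col.observations}) == 2
        assert col.depth_per_species == (1, 1)

    def test_deletion_contributes_gap_observations(self, contig_10kb,
                                                   index_10kb):
        read = contig_10kb[3000:3030] + contig_10kb[3032:3052]
        p = map_read("CH|p|3", read, index_10kb)
        store = {"CH|p|3": (read, np.full(50, 35))}
        pile = build_pileup([p], store, {"ref1": contig_10kb})
        for pos in (3030, 3031):
            col = pile.column("ref1", pos)
            assert col.observations[0][0] == "-"

    def test_insertion_goes_to_side_channel_not_columns(self, contig_10kb,
                                                        index_10kb):
        read = contig_10kb[3000:3025] + "GG" + contig_10kb[3025:3048]
        p = map_read("CH|p|4", read, index_10kb)
        store = {"CH|p|4": (read, np.full(50, 35))}
        pile = build_pileup([p], store, {"ref1": contig_10kb})
        assert len(list(pile.columns("ref1"))) == 48  # no extra columns
        ins_pos, *_ = pile.insertion_arrays("ref1")
        assert list(ins_pos) == [3025]

    def test_depth_conservation_and_recount(self, small_dataset):
        """Sum of column depths equals total aligned reference span, and a
        brute-force interval recount reproduces every per-position depth."""
        ds = small_dataset
        total_span = sum(p.ref_span for p in ds.placements)
        assert ds.pileup.total_depth() == total_span
        contig = sorted(ds.contigs)[0]
        recount = np.zeros(len(ds.contigs[contig]), dtype=int)
        for p in ds.placements:
            if p.contig == contig:
                recount[p.start : p.end] += 1
        depths = np.zeros_like(recount)
        for col in ds.pileup.columns(contig):
            depths[col.position] = col.depth_total
        assert np.array_equal(depths, recount)

    def test_zero_error_placements_have_similarity_one(self):
        from conftest import make_dataset

        ds = make_dataset(
            n_contigs=2, rng_seed=21, base_error_rate=0.0, coverage_target=8,
            intra_snp_rate=0, intra_both_rate=0, inter_fixed_diff_rate=0,
            indel_rate=0, msat_tract_rate=0, repeat_tract_rate=0,
        )
        assert ds.placements and all(
            p.similarity == 1.0 for p in ds.placements
        )


class TestSamInterop:
    def test_round_trip_preserves_placements_and_pileup(self, tmp_path,
                                                        contig_10kb,
                                                        index_10kb, rng):
        contigs = {"ref1": contig_10kb}
        reads, store = [], {}
        for i in range(40):
            start = int(rng.integers(0, 9900))
            n_mut = int(rng.integers(0, 4))
            seq = mutate(contig_10kb[start : start + 60],
                         rng.choice(60, size=n_mut, replace=False))
            if rng.random() < 0.5:
                seq = revcomp(seq)
            name = f"{'CH' if i % 2 else 'BL'}|t|{i}"
            reads.append((name, seq, "J" * 60))
            store[name] = (seq, string_to_phred("J" * 60))
        placements, _ = map_reads(reads, index_10kb)
        sam = tmp_path / "t.sam"
        write_sam(placements, store, contigs, str(sam))
        back, back_reads = import_sam(str(sam), contigs)
        assert len(back) == len(placements)
        for a, b in zip(
            sorted(placements, key=lambda p: p.read_id),
            sorted(back, key=lambda p: p.read_id),
        ):
            assert (a.read_id, a.contig, a.start, a.strand) == \
                (b.read_id, b.contig, b.start, b.strand)
            assert a.edit == b.edit
            assert a.similarity == pytest.approx(b.similarity)
            assert a.species == b.species
        p1 = build_pileup(placements, store, contigs)
        p2 = build_pileup(back, back_reads, contigs)
        assert p1.total_depth() == p2.total_depth()
        for c1, c2 in zip(p1.columns("ref1"), p2.columns("ref1")):
            assert c1.position == c2.position
            assert sorted(c1.observations) == sorted(c2.observations)

    def test_unmapped_record_contributes_nothing(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:100\n"
            "CH|u|0\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTACGT\tJJJJJJJJJJJJ\n"
        )
        placements, reads = import_sam(str(sam), {"ref1": "A" * 100})
        assert placements == [] and reads == {}

    def test_exact_36bp_match_has_similarity_one(self, tmp_path, contig_10kb):
        seq = contig_10kb[50:86]
        sam = tmp_path / "e.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref1\tLN:10000\n"
            f"CH|e|0\t0\tref1\t51\t60\t36M\t*\t0\t0\t{seq}\t{'J' * 36}\n"
        )
        placements, _ = import_sam(str(sam), {"ref1": contig_10kb})
        assert len(placements) == 1
        assert placements[0].similarity == 1.0
        assert placements[0].start == 50


class TestPolicyValidation:
    def test_costs_must_be_positive(self):
        with pytest.raises(ValueError):
            AlignPolicy(mismatch_cost=0)

    def test_fractions_in_unit_interval(self):
        with pytest.raises(ValueError):
            AlignPolicy(min_similarity=1.5)
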