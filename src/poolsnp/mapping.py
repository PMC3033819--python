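"""Read placement onto transcript contigs and pileup construction.

The mapper reproduces a permissive local-alignment inclusion rule: reads
are scored with unit match reward, mismatch cost 2 and gap (insertion or
deletion) cost 3, and the highest-scoring placement is retained only when
it reaches >= 80% similarity over >= 50% of the read's length.  Similarity
is matches / (matches + mismatches + inserted + deleted bases) over the
aligned region; the length fraction is aligned read bases / read length.

Candidate loci are found with exact k-mer seeds (k = 12 by default) on both
strands and extended with a banded local Smith-Waterman (Biopython's
PairwiseAligner, C implementation) around each candidate diagonal.  Each
read receives at most one placement; score ties break deterministically by
(contig order, start, forward strand).

Pileups carry, for every observation, the base, its phred quality, the mean
quality of the same read's bases surrounding the site, and the species of
origin, which is everything the downstream SNP caller gates on.  Deletions
contribute '-' observations carrying the mean quality of the flanking read
bases; insertions go to a side channel keyed by reference position and do
not create columns.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio import Align

from ._seq import BASES, encode, revcomp
from .simulate import BLUE, CHANNEL

SPECIES_CODE = {CHANNEL: 0, BLUE: 1}
SPECIES_NAME = {0: CHANNEL, 1: BLUE}

DEFAULT_SEED_K = 12
_BAND = 12          # extension window slack around a candidate diagonal
_MAX_SEED_HITS = 64  # k-mers more frequent than this are not used as seeds
_MAX_CANDIDATES = 16


@dataclass(frozen=True)
class AlignPolicy:
    mismatch_cost: int = 2
    deletion_cost: int = 3
    insertion_cost: int = 3
    min_similarity: float = 0.80
    min_length_fraction: float = 0.50
    seed_k: int = DEFAULT_SEED_K

    def __post_init__(self):
        if min(self.mismatch_cost, self.deletion_cost, self.insertion_cost) < 1:
            raise ValueError("alignment costs must be positive integers")
        for f in (self.min_similarity, self.min_length_fraction):
            if not (0.0 < f <= 1.0):
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class Placement:
    """One retained read placement (0-based half-open on the contig)."""

    read_id: str
    contig: str
    start: int
    strand: str                      # '+' or '-'
    edit: list[tuple[str, int]]      # runs of '=', 'X', 'I', 'D'
    qstart: int                      # aligned span on the oriented read
    qend: int
    score: int
    similarity: float
    aligned_fraction: float
    species: str

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.edit if op in "=XD")

    @property
    def end(self) -> int:
        return self.start + self.ref_span


def species_from_name(read_id: str) -> str:
    if read_id.startswith("CH|"):
        return CHANNEL
    if read_id.startswith("BL|"):
        return BLUE
    raise ValueError(f"cannot infer species from read name {read_id!r}")


class ContigIndex:
    """Exact k-mer seed index over a contig set."""

    def __init__(self, contigs: dict[str, str], k: int = DEFAULT_SEED_K):
        self.k = k
        self.names = sorted(contigs)
        self.order = {n: i for i, n in enumerate(self.names)}
        self.seqs = {n: contigs[n].upper() for n in self.names}
        self.codes = {n: encode(self.seqs[n]) for n in self.names}
        self._index: dict[int, list[tuple[int, int]]] = {}
        for ci, name in enumerate(self.names):
            codes = self.codes[name]
            if len(codes) < k:
                continue
            packed = _pack_kmers(codes, k)
            for pos in range(len(packed)):
                key = packed[pos]
                if key < 0:  # window contains N
                    continue
                self._index.setdefault(key, []).append((ci, pos))

    def seed_hits(self, key: int) -> list[tuple[int, int]]:
        hits = self._index.get(key, ())
        return hits if len(hits) <= _MAX_SEED_HITS else ()

    def length(self, name: str) -> int:
        return len(self.seqs[name])


def _pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mers; -1 where the window contains an ambiguous base."""
    n = len(codes) - k + 1
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    isn = codes >= 4
    for i in range(k):
        vals = vals * 4 + c[i : i + n]
        bad |= isn[i : i + n]
    vals[bad] = -1
    return vals


def _make_aligner(policy: AlignPolicy) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -policy.mismatch_cost
    # linear gap penalties; insertion = extra read bases (gap in reference),
    # deletion = missing read bases (gap in read)
    try:
        aligner.open_internal_insertion_score = -policy.insertion_cost
        aligner.extend_internal_insertion_score = -policy.insertion_cost
        aligner.open_internal_deletion_score = -policy.deletion_cost
        aligner.extend_internal_deletion_score = -policy.deletion_cost
    except AttributeError:  # older Biopython naming
        aligner.target_internal_open_gap_score = -policy.insertion_cost
        aligner.target_internal_extend_gap_score = -policy.insertion_cost
        aligner.query_internal_open_gap_score = -policy.deletion_cost
        aligner.query_internal_extend_gap_score = -policy.deletion_cost
    return aligner


def _runs_from_mismatches(length: int, mm_idx) -> list[tuple[str, int]]:
    """'='/'X' run-length script for an ungapped segment of given length."""
    edit: list[tuple[str, int]] = []
    cursor = 0
    for p in mm_idx:
        p = int(p)
        if p > cursor:
            edit.append(("=", p - cursor))
        if edit and edit[-1][0] == "X":
            edit[-1] = ("X", edit[-1][1] + 1)
        else:
            edit.append(("X", 1))
        cursor = p + 1
    if cursor < length:
        edit.append(("=", length - cursor))
    return edit


def _edit_from_alignment(alignment, t_codes: np.ndarray, q_codes: np.ndarray):
    """Run-length edit script and match counts from a Bio.Align alignment."""
    t_blocks, q_blocks = alignment.aligned
    edit: list[tuple[str, int]] = []

    def push(op: str, n: int):
        if n <= 0:
            return
        if edit and edit[-1][0] == op:
            edit[-1] = (op, edit[-1][1] + n)
        else:
            edit.append((op, n))

    matches = mismatches = ins = dels = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            push("D", ts - prev_t)  # reference consumed, read missing bases
            push("I", qs - prev_q)  # read consumed, extra bases vs reference
            dels += ts - prev_t
            ins += qs - prev_q
        t = t_codes[ts:te]
        q = q_codes[qs:qe]
        neq = (t != q) | (t >= 4)
        mm = int(neq.sum())
        matches += len(t) - mm
        mismatches += mm
        for op, n in _runs_from_mismatches(len(t), np.flatnonzero(neq)):
            push(op, n)
        prev_t, prev_q = te, qe
    qstart = int(q_blocks[0][0])
    qend = int(q_blocks[-1][1])
    tstart = int(t_blocks[0][0])
    return edit, matches, mismatches, ins, dels, qstart, qend, tstart


#: ungapped fast path applies while the diagonal shows at most this many
#: mismatches; beyond it (or when the read overhangs the contig) the banded
#: Smith-Waterman extension decides
_MAX_FAST_MISMATCHES = 3


def _diagonal_candidate(codes, ref_codes, ci, diag, policy):
    """Exact/sparse-mismatch evaluation restricted to one diagonal.

    Returns the best local segment on the diagonal (a prefix-sum scan, so
    optimal for gap-free alignments), or None when the mismatch load
    suggests an indel or the read overhangs the contig.
    """
    L = len(codes)
    if diag < 0 or diag + L > len(ref_codes):
        return None
    window = ref_codes[diag : diag + L]
    neq = (window != codes) | (codes >= 4) | (window >= 4)
    n_mm = int(neq.sum())
    if n_mm == 0:
        return (L, ci, diag, [("=", L)], 0, L, 1.0, 1.0)
    if n_mm > _MAX_FAST_MISMATCHES:
        return None
    per = np.where(neq, -policy.mismatch_cost, 1)
    prefix = np.concatenate(([0], np.cumsum(per)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    j = int(np.argmax(gains))          # inclusive segment end
    score = int(gains[j])
    i = int(np.argmin(prefix[: j + 1]))  # segment start
    mm_idx = np.flatnonzero(neq[i : j + 1])
    seg_len = j + 1 - i
    m = seg_len - len(mm_idx)
    return (
        score, ci, diag + i,
        _runs_from_mismatches(seg_len, mm_idx),
        i, j + 1, m / seg_len, seg_len / L,
    )


def _evaluate_candidate(
    read: str, codes: np.ndarray, index: ContigIndex, ci: int, diag: int,
    policy: AlignPolicy, aligner: Align.PairwiseAligner,
):
    """Best local alignment of the read near one candidate diagonal."""
    name = index.names[ci]
    ref_codes = index.codes[name]
    L = len(read)
    fast = _diagonal_candidate(codes, ref_codes, ci, diag, policy)
    if fast is not None:
        return fast
    ws = max(0, diag - _BAND)
    we = min(len(ref_codes), diag + L + _BAND)
    if we - ws < policy.seed_k:
        return None
    window = index.seqs[name][ws:we]
    alns = aligner.align(window, read)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    edit, m, mm, ins, dels, qstart, qend, tstart = _edit_from_alignment(
        aln, ref_codes[ws:we], codes
    )
    denom = m + mm + ins + dels
    if denom == 0:
        return None
    sim = m / denom
    frac = (qend - qstart) / L
    score = m - policy.mismatch_cost * mm - policy.insertion_cost * ins \
        - policy.deletion_cost * dels
    return (score, ci, ws + tstart, edit, qstart, qend, sim, frac)


def _seed_candidates(
    read_codes: np.ndarray, index: ContigIndex, k: int, exhaustive: bool
) -> list[tuple[int, int]]:
    """Candidate (contig index, diagonal start) pairs, most-voted first."""
    L = len(read_codes)
    if L < k:
        return []
    packed = _pack_kmers(read_codes, k)
    offsets = (
        range(len(packed))
        if exhaustive
        else range(0, len(packed), max(1, (L - k) // 8 or 1))
    )
    votes: dict[tuple[int, int], int] = {}
    for off in offsets:
        key = packed[off]
        if key < 0:
            continue
        for ci, pos in index.seed_hits(key):
            d = (ci, pos - off)
            votes[d] = votes.get(d, 0) + 1
    # cluster nearby diagonals (indels shift them); the cluster is
    # represented by its most-voted exact diagonal so that unmutated reads
    # hit the exact-match fast path
    groups: list[tuple[int, int, int]] = []  # (votes, ci, rep_diag)
    prev_ci = prev_d = None
    for ci, d in sorted(votes):
        if ci != prev_ci or prev_d is None or d - prev_d > _BAND:
            groups.append((votes[(ci, d)], ci, d))
        else:
            gv, gci, gd = groups[-1]
            v = votes[(ci, d)]
            groups[-1] = (gv + v, gci, d if v > votes[(gci, gd)] else gd)
        prev_ci, prev_d = ci, d
    groups.sort(key=lambda g: (-g[0], g[1], g[2]))
    return [(ci, d) for _, ci, d in groups[:_MAX_CANDIDATES]]


def map_read(
    read_id: str,
    seq: str,
    index: ContigIndex,
    policy: AlignPolicy = AlignPolicy(),
    aligner: Align.PairwiseAligner | None = None,
    species: str | None = None,
) -> Placement | None:
    """Best placement of one read, or None when no placement passes.

    Ties on score break by (contig order, start, forward strand).
    """
    if not seq:
        return None
    if aligner is None:
        aligner = _make_aligner(policy)
    seq = seq.upper()
    oriented = {"+": seq, "-": revcomp(seq)}
    codes = {s: encode(oriented[s]) for s in "+-"}
    best = None
    best_key = None
    for exhaustive in (False, True):
        for strand in "+-":
            if strand == "-" and best is not None and best[0][0] == len(seq):
                break  # a full-length exact match cannot be outscored
            for ci, diag in _seed_candidates(
                codes[strand], index, policy.seed_k, exhaustive
            ):
                res = _evaluate_candidate(
                    oriented[strand], codes[strand], index, ci, diag, policy,
                    aligner,
                )
                if res is None:
                    continue
                score, ci_, start, _, _, _, sim, frac = res
                if sim < policy.min_similarity or \
                        frac < policy.min_length_fraction:
                    continue
                key = (-score, ci_, start, 0 if strand == "+" else 1)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (res, strand)
        if best is not None:
            break
    if best is None:
        return None
    (score, ci, start, edit, qstart, qend, sim, frac), strand = best
    return Placement(
        read_id=read_id,
        contig=index.names[ci],
        start=start,
        strand=strand,
        edit=edit,
        qstart=qstart,
        qend=qend,
        score=score,
        similarity=sim,
        aligned_fraction=frac,
        species=species or species_from_name(read_id),
    )


def map_reads(
    reads: Iterable[tuple[str, str, str]],
    index: ContigIndex,
    policy: AlignPolicy = AlignPolicy(),
    species: str | None = None,
) -> tuple[list[Placement], list[tuple[str, str, str]]]:
    """Map a read stream; returns (placements, unmapped reads)."""
    aligner = _make_aligner(policy)
    placements, unmapped = [], []
    for name, seq, qual in reads:
        p = map_read(name, seq, index, policy, aligner, species=species)
        if p is None:
            unmapped.append((name, seq, qual))
        else:
            placements.append(p)
    return placements, unmapped


# ---------------------------------------------------------------------------
# pileups


@dataclass
class PileupColumn:
    """All read observations over one reference position."""

    contig: str
    position: int
    bases: np.ndarray        # uint8 codes (A,C,G,T,N,-)
    quals: np.ndarray        # phred of the observation itself
    flank_quals: np.ndarray  # mean phred of surrounding bases in the read
    species: np.ndarray      # 0 = channel, 1 = blue

    @property
    def depth_total(self) -> int:
        return len(self.bases)

    @property
    def depth_per_species(self) -> tuple[int, int]:
        ch = int((self.species == 0).sum())
        return ch, len(self.species) - ch

    @property
    def observations(self) -> list[tuple[str, int, str]]:
        return [
            (BASES[b], int(q), SPECIES_NAME[s])
            for b, q, s in zip(self.bases, self.quals, self.species)
        ]


class Pileup:
    """Column-addressable observation store for a contig set."""

    def __init__(self, contigs: dict[str, str], flank_window: int = 5):
        self.contigs = {n: contigs[n].upper() for n in contigs}
        self.flank_window = flank_window
        self._chunks: dict[str, list] = {n: [] for n in self.contigs}
        self._ins_chunks: dict[str, list] = {n: [] for n in self.contigs}
        self._arrays: dict[str, tuple] = {}
        self._ins_arrays: dict[str, tuple] = {}
        self._final = False

    # -- construction -----------------------------------------------------
    def add_placement(self, p: Placement, seq: str, qual_phred: np.ndarray):
        if self._final:
            raise RuntimeError("pileup already finalized")
        if p.end > len(self.contigs[p.contig]):
            raise ValueError(
                f"placement of {p.read_id} extends past the end of {p.contig}"
            )
        oriented = seq.upper() if p.strand == "+" else revcomp(seq.upper())
        quals = qual_phred if p.strand == "+" else qual_phred[::-1]
        codes = encode(oriented)
        flank = _flank_means(quals, self.flank_window)
        pos_l, base_l, qual_l, flank_l = [], [], [], []
        rpos, tpos = p.qstart, p.start
        for op, n in p.edit:
            if op in "=X":
                pos_l.append(np.arange(tpos, tpos + n, dtype=np.int32))
                base_l.append(codes[rpos : rpos + n])
                qual_l.append(quals[rpos : rpos + n])
                flank_l.append(flank[rpos : rpos + n])
                rpos += n
                tpos += n
            elif op == "I":
                q = float(np.mean(quals[rpos : rpos + n]))
                fq = float(flank[min(rpos, len(flank) - 1)])
                self._ins_chunks[p.contig].append(
                    (tpos, q, fq, SPECIES_CODE[p.species])
                )
                rpos += n
            elif op == "D":
                lo = max(rpos - 1, 0)
                hi = min(rpos + 1, len(quals))
                q = float(np.mean(quals[lo:hi]))
                fq = float(flank[min(rpos, len(flank) - 1)])
                pos_l.append(np.arange(tpos, tpos + n, dtype=np.int32))
                base_l.append(np.full(n, 5, dtype=np.uint8))  # '-'
                qual_l.append(np.full(n, q, dtype=np.float32))
                flank_l.append(np.full(n, fq, dtype=np.float32))
                tpos += n
        if pos_l:
            self._chunks[p.contig].append(
                (
                    np.concatenate(pos_l),
                    np.concatenate(base_l),
                    np.concatenate(qual_l).astype(np.float32),
                    np.concatenate(flank_l).astype(np.float32),
                    SPECIES_CODE[p.species],
                )
            )

    def finalize(self) -> "Pileup":
        for name, chunks in self._chunks.items():
            if not chunks:
                self._arrays[name] = (
                    np.empty(0, np.int32), np.empty(0, np.uint8),
                    np.empty(0, np.float32), np.empty(0, np.float32),
                    np.empty(0, np.uint8),
                )
                continue
            pos = np.concatenate([c[0] for c in chunks])
            base = np.concatenate([c[1] for c in chunks])
            qual = np.concatenate([c[2] for c in chunks])
            flank = np.concatenate([c[3] for c in chunks])
            spec = np.concatenate(
                [np.full(len(c[0]), c[4], dtype=np.uint8) for c in chunks]
            )
            order = np.argsort(pos, kind="stable")
            self._arrays[name] = (
                pos[order], base[order], qual[order], flank[order], spec[order]
            )
        for name, chunks in self._ins_chunks.items():
            if not chunks:
                self._ins_arrays[name] = (
                    np.empty(0, np.int32), np.empty(0, np.float32),
                    np.empty(0, np.float32), np.empty(0, np.uint8),
                )
                continue
            arr = np.array(chunks, dtype=np.float64)
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            self._ins_arrays[name] = (
                arr[:, 0].astype(np.int32), arr[:, 1].astype(np.float32),
                arr[:, 2].astype(np.float32), arr[:, 3].astype(np.uint8),
            )
        self._chunks = self._ins_chunks = None
        self._final = True
        return self

    # -- access -----------------------------------------------------------
    def arrays(self, contig: str):
        """(pos, base, qual, flank_qual, species) sorted by position."""
        if not self._final:
            raise RuntimeError("finalize() the pileup first")
        return self._arrays[contig]

    def insertion_arrays(self, contig: str):
        if not self._final:
            raise RuntimeError("finalize() the pileup first")
        return self._ins_arrays[contig]

    def column(self, contig: str, position: int) -> PileupColumn | None:
        pos, base, qual, flank, spec = self.arrays(contig)
        lo = np.searchsorted(pos, position, "left")
        hi = np.searchsorted(pos, position, "right")
        if lo == hi:
            return None
        return PileupColumn(
            contig, position, base[lo:hi], qual[lo:hi], flank[lo:hi], spec[lo:hi]
        )

    def columns(self, contig: str) -> Iterator[PileupColumn]:
        pos, base, qual, flank, spec = self.arrays(contig)
        if len(pos) == 0:
            return
        bounds = np.flatnonzero(np.diff(pos)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(pos)]))
        for lo, hi in zip(starts, ends):
            yield PileupColumn(
                contig, int(pos[lo]), base[lo:hi], qual[lo:hi],
                flank[lo:hi], spec[lo:hi],
            )

    def total_depth(self) -> int:
        return sum(len(self._arrays[n][0]) for n in self._arrays)


def _flank_means(quals: np.ndarray, w: int) -> np.ndarray:
    """Mean quality of bases within w positions of each site, site excluded."""
    q = np.asarray(quals, dtype=np.float64)
    n = len(q)
    cum = np.concatenate(([0.0], np.cumsum(q)))
    lo = np.maximum(np.arange(n) - w, 0)
    hi = np.minimum(np.arange(n) + w + 1, n)
    tot = cum[hi] - cum[lo] - q
    cnt = hi - lo - 1
    return (tot / np.maximum(cnt, 1)).astype(np.float32)


def build_pileup(
    placements: Iterable[Placement],
    reads: dict[str, tuple[str, np.ndarray]],
    contigs: dict[str, str],
    flank_window: int = 5,
) -> Pileup:
    """Assemble a finalized pileup from placements and their reads.

    ``reads`` maps read id -> (sequence, phred array) as sequenced (the
    pileup re-orients reverse-strand placements itself).
    """
    pileup = Pileup(contigs, flank_window=flank_window)
    for p in placements:
        seq, qual = reads[p.read_id]
        pileup.add_placement(p, seq, np.asarray(qual))
    return pileup.finalize()


# ---------------------------------------------------------------------------
# SAM interop (pysam-backed)

_CIGAR_CODE = {"=": 7, "X": 8, "I": 1, "D": 2, "S": 4}


def write_sam(
    placements: Iterable[Placement],
    reads: dict[str, tuple[str, np.ndarray]],
    contigs: dict[str, str],
    path: str,
) -> None:
    import pysam

    names = sorted(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(contigs[n])} for n in names],
        "RG": [{"ID": "channel", "SM": "channel"}, {"ID": "blue", "SM": "blue"}],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for p in placements:
            seq, qual = reads[p.read_id]
            oriented = seq if p.strand == "+" else revcomp(seq)
            q = np.asarray(qual)
            if p.strand == "-":
                q = q[::-1]
            a = pysam.AlignedSegment(out.header)
            a.query_name = p.read_id
            a.query_sequence = oriented
            a.query_qualities = [int(x) for x in q]
            a.flag = 0 if p.strand == "+" else 16
            a.reference_id = tid[p.contig]
            a.reference_start = p.start
            a.mapping_quality = 60
            cig = []
            if p.qstart:
                cig.append((_CIGAR_CODE["S"], p.qstart))
            cig += [(_CIGAR_CODE[op], n) for op, n in p.edit]
            tail = len(seq) - p.qend
            if tail:
                cig.append((_CIGAR_CODE["S"], tail))
            a.cigartuples = cig
            a.set_tag("RG", p.species)
            out.write(a)


def import_sam(
    path: str,
    contigs: dict[str, str],
    policy: AlignPolicy = AlignPolicy(),
    logger=None,
) -> tuple[list[Placement], dict[str, tuple[str, np.ndarray]]]:
    """Convert mapped primary SAM records into retained placements.

    Similarity and aligned fraction are recomputed against the supplied
    contigs and the inclusion thresholds re-applied, so external alignments
    pass through exactly the same filter as internal ones.  Returns
    (placements, reads) with reads re-oriented to sequencing direction.
    """
    import pysam

    placements: list[Placement] = []
    reads: dict[str, tuple[str, np.ndarray]] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary \
                    or rec.is_duplicate:
                continue
            if rec.query_sequence is None or rec.cigartuples is None:
                continue
            name = rec.reference_name
            if name not in contigs:
                if logger:
                    logger.warning("SAM record on unknown contig %s", name)
                continue
            consumed = sum(
                n for code, n in rec.cigartuples if code in (0, 1, 4, 7, 8)
            )
            if consumed != len(rec.query_sequence):
                if logger:
                    logger.warning(
                        "CIGAR/sequence length mismatch for %s; skipped",
                        rec.query_name,
                    )
                continue
            ref = contigs[name].upper()
            if rec.reference_end is None or rec.reference_end > len(ref):
                if logger:
                    logger.warning(
                        "%s extends past end of %s; skipped", rec.query_name, name
                    )
                continue
            oriented = rec.query_sequence.upper()
            edit: list[tuple[str, int]] = []
            m = mm = ins = dels = 0
            rpos = tpos = 0
            qstart = qend = None
            start = rec.reference_start

            def push(op, n):
                if n <= 0:
                    return
                if edit and edit[-1][0] == op:
                    edit[-1] = (op, edit[-1][1] + n)
                else:
                    edit.append((op, n))

            for code, n in rec.cigartuples:
                if code in (4, 5):  # clip
                    if code == 4:
                        rpos += n
                    continue
                if qstart is None and code in (0, 1, 7, 8):
                    qstart = rpos
                if code in (0, 7, 8):  # aligned pair run
                    for i in range(n):
                        if oriented[rpos + i] == ref[start + tpos + i] and \
                                oriented[rpos + i] in "ACGT":
                            push("=", 1)
                            m += 1
                        else:
                            push("X", 1)
                            mm += 1
                    rpos += n
                    tpos += n
                    qend = rpos
                elif code == 1:
                    push("I", n)
                    ins += n
                    rpos += n
                    qend = rpos
                elif code == 2 or code == 3:
                    push("D", n)
                    dels += n
                    tpos += n
            if qstart is None or m + mm + ins + dels == 0:
                continue
            sim = m / (m + mm + ins + dels)
            frac = (qend - qstart) / len(oriented)
            if sim < policy.min_similarity or frac < policy.min_length_fraction:
                continue
            try:
                spec = (
                    rec.get_tag("RG")
                    if rec.has_tag("RG") and rec.get_tag("RG") in SPECIES_CODE
                    else species_from_name(rec.query_name)
                )
            except ValueError:
                if logger:
                    logger.warning("no species for %s; skipped", rec.query_name)
                continue
            score = m - policy.mismatch_cost * mm \
                - policy.insertion_cost * ins - policy.deletion_cost * dels
            strand = "-" if rec.is_reverse else "+"
            quals = np.array(rec.query_qualities, dtype=np.int16)
            seq_fwd = oriented if strand == "+" else revcomp(oriented)
            q_fwd = quals if strand == "+" else quals[::-1]
            reads[rec.query_name] = (seq_fwd, q_fwd)
            placements.append(
                Placement(
                    read_id=rec.query_name, contig=name, start=start,
                    strand=strand, edit=edit, qstart=qstart, qend=qend,
                    score=score, similarity=sim, aligned_fraction=frac,
                    species=spec,
                )
            )
    return placements, reads


def write_unmapped_fasta(unmapped: list[tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq, _ in unmapped:
            fh.write(f">{name}\n{seq}\n")
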