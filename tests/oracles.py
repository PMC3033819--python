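"""Independent brute-force reference implementations used as test oracles.

These transcribe the written rules directly (plain loops, regex, textbook
dynamic programming) and deliberately share no code with the package.
"""
from __future__ import annotations

import re

import numpy as np

# --------------------------------------------------------------------------
# Smith-Waterman over every position (linear gap penalties)


def sw_best_score(read: str, ref: str, mismatch: int = 2, gap: int = 3):
    """Optimal local-alignment score and the set of optimal end columns.

    Row-wise DP; the in-row horizontal dependency is resolved exactly with
    a running-maximum scan (valid for linear gap penalties).
    """
    m = len(ref)
    rr = np.frombuffer(ref.encode(), dtype=np.uint8)
    acgt = np.isin(rr, np.frombuffer(b"ACGT", dtype=np.uint8))
    h_prev = np.zeros(m + 1)
    best = 0.0
    best_ends: set[int] = set()
    idx = np.arange(m)
    for ch in read:
        sub = np.where((rr == ord(ch)) & acgt & (ch in "ACGT"), 1.0,
                       -float(mismatch))
        stacked = np.maximum(h_prev[:-1] + sub, h_prev[1:] - gap)
        col = np.maximum(stacked, 0.0)
        h = np.maximum.accumulate(col + gap * idx) - gap * idx
        row_best = h.max()
        if row_best > best:
            best = row_best
            best_ends = set(np.flatnonzero(h == row_best))
        elif row_best == best and best > 0:
            best_ends |= set(np.flatnonzero(h == row_best))
        h_prev = np.concatenate(([0.0], h))
    return best, best_ends


# --------------------------------------------------------------------------
# putative SNP rule on one column


def oracle_detect(observations, ref_base, *, min_depth=4, min_variant=2,
                  min_q=25, min_flank_q=20):
    """(major, minor, maf, n_alleles, is_indel) or None, by plain transcription.

    ``observations`` is a list of (base, quality, flank_quality, species).
    """
    if ref_base not in "ACGT":
        return None
    qualified = [
        (b, q, f, s) for b, q, f, s in observations
        if q >= min_q and f >= min_flank_q and b != "N"
    ]
    depth = len(qualified)
    if depth < min_depth:
        return None
    counts = {a: 0 for a in "ACGT-"}
    for b, *_ in qualified:
        counts[b] += 1
    nonref = {a: c for a, c in counts.items() if a != ref_base and c > 0}
    if not nonref or max(nonref.values()) < min_variant:
        return None
    order = "ACGTN-"
    ranked = sorted(
        (a for a in counts if counts[a] > 0),
        key=lambda a: (-counts[a], order.index(a)),
    )
    major = ranked[0]
    minor = ranked[1] if len(ranked) > 1 else ref_base
    maf = (counts[minor] if minor != major else 0) / depth
    n_alleles = sum(c >= min_variant for c in counts.values())
    return major, minor, maf, n_alleles, ("-" in (major, minor))


def oracle_screen(site, *, min_maf=0.10, clean_flank=15):
    """Fail-reason list for one putative SNP given its context.

    ``site`` carries maf, n_alleles, neighbor positions (all putative
    variants of the view), own position and mask intervals.
    """
    reasons = []
    if site["maf"] < min_maf:
        reasons.append("low_maf")
    if any(
        p != site["pos"] and abs(p - site["pos"]) <= clean_flank
        for p in site["neighbors"]
    ):
        reasons.append("dirty_flank")
    if any(s <= site["pos"] < e for s, e in site["mask"]):
        reasons.append("in_repeat")
    if site["n_alleles"] != 2:
        reasons.append("not_biallelic")
    return reasons


# --------------------------------------------------------------------------
# six-category site classification


def oracle_category(ch_counts, bl_counts, pooled_variant, *, min_depth=4,
                    min_variant=2, purity=0.0):
    """Direct transcription of the six category definitions.

    A species "has a SNP" when its second-most-frequent allele reaches the
    variant-count threshold at adequate depth; "sequence differed" compares
    the within-species consensus alleles.
    """
    def depth(c):
        return sum(c.values())

    def poly(c):
        top = sorted(c.values(), reverse=True)
        return depth(c) >= min_depth and len(top) > 1 and top[1] >= min_variant

    def consensus(c):
        present = {a: n for a, n in c.items() if n > 0}
        if not present:
            return None
        return max(present, key=lambda a: (present[a], a))

    ch_d, bl_d = depth(ch_counts), depth(bl_counts)
    ch_snp, bl_snp = poly(ch_counts), poly(bl_counts)
    if ch_snp and bl_snp:
        return 3
    if ch_snp:
        return 1 if bl_d >= min_depth else 5
    if bl_snp:
        return 2 if ch_d >= min_depth else 6
    ca, ba = consensus(ch_counts), consensus(bl_counts)
    if (
        pooled_variant and ch_d >= min_depth and bl_d >= min_depth
        and ca is not None and ba is not None and ca != ba
        and ch_counts[ca] >= purity * ch_d and bl_counts[ba] >= purity * bl_d
    ):
        return 4
    return "unclassifiable"


# --------------------------------------------------------------------------
# microsatellites (regex-backed exhaustive scanner)

_THRESH = {2: 8, 3: 5, 4: 5, 5: 5, 6: 5}


def naive_msats(seq: str):
    """(motif_length, n_repeats, start, end) tuples of qualifying tracts."""
    seq = seq.upper()
    cands = []
    for p, min_rep in _THRESH.items():
        for m in re.finditer(rf"([ACGT]{{{p}}})\1{{{min_rep - 1},}}", seq):
            motif = m.group(1)
            if any(
                p % d == 0 and motif == motif[:d] * (p // d)
                for d in range(1, p)
            ):
                continue
            n = (m.end() - m.start()) // p
            cands.append((p, -(n * p), m.start(), motif, n))
    cands.sort()
    kept = []
    for p, neg, start, motif, n in cands:
        end = start + n * p
        if any(start < e and s < end for _, _, s, e in kept):
            continue
        kept.append((p, n, start, end))
    return sorted(kept, key=lambda k: k[2])
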