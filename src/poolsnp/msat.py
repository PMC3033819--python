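"""Perfect microsatellite (SSR) detection in transcript contigs.

A microsatellite is a perfect tandem repeat of a primitive 2-6 bp motif.
Tracts qualify when they reach eight repeats for di-nucleotide motifs or
five repeats for tri- through hexa-nucleotide motifs.  A tract is considered
usable as a genotyping marker only when at least 50 bp of unambiguous
sequence flank it on both sides (enough to design PCR primers).

Mononucleotide runs are not reported (they are handled by the repeat-mask
fallback in the SNP caller instead), tracts are perfect only, and motifs are
reported on the given strand.  Overlapping descriptions of the same tract
under rotated or non-primitive motifs are collapsed to the shortest
primitive motif with maximal extent; the tract phase is chosen so that the
reported motif is the lexicographically smallest rotation compatible with
the maximal repeat count.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import encode

#: minimum repeat counts per motif length (di=8, tri..hexa=5)
REPEAT_THRESHOLDS = {2: 8, 3: 5, 4: 5, 5: 5, 6: 5}
MIN_FLANK = 50

MOTIF_CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class MicrosatelliteHit:
    """One perfect tandem-repeat locus (0-based half-open coordinates)."""

    contig: str
    start: int
    end: int
    motif: str
    n_repeats: int
    left_flank: int
    right_flank: int

    @property
    def flank_sufficient(self) -> bool:
        return self.left_flank >= MIN_FLANK and self.right_flank >= MIN_FLANK

    @property
    def motif_class(self) -> str:
        return MOTIF_CLASS_NAMES[len(self.motif)]


def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def _segment_candidates(seq: str, seg_start: int, seg_end: int) -> list[tuple]:
    """Maximal perfect tandem repeats within an N-free segment.

    Returns (motif_len, -tract_len, start, motif, n_repeats) sort keys.
    """
    out = []
    s = seq[seg_start:seg_end]
    n = len(s)
    arr = encode(s)
    for p, min_rep in REPEAT_THRESHOLDS.items():
        if n < p * min_rep:
            continue
        eq = arr[p:] == arr[:-p]
        # maximal runs of consecutive equalities
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for run_start, run_end in zip(idx[::2], idx[1::2]):
            tract_len = (run_end - run_start) + p
            n_rep = tract_len // p
            if n_rep < min_rep:
                continue
            # phase choice: any offset keeping n_rep full repeats inside the
            # maximal extent; pick the lexicographically smallest motif
            max_off = tract_len - n_rep * p
            best_off = min(
                range(max_off + 1), key=lambda o: s[run_start + o : run_start + o + p]
            )
            start = run_start + best_off
            motif = s[start : start + p]
            if not _is_primitive(motif):
                continue  # same tract is reported at its true (shorter) period
            out.append((p, -n_rep * p, seg_start + start, motif, n_rep))
    return out


def find_msats(contig: str, seq: str) -> list[MicrosatelliteHit]:
    """All qualifying perfect microsatellite tracts in one contig.

    Tracts containing N are split at the N; flanks count contiguous non-N
    bases adjacent to the tract.
    """
    seq = seq.upper()
    n_len = len(seq)
    candidates: list[tuple] = []
    seg_start = 0
    for i, ch in enumerate(seq + "N"):  # sentinel N terminates last segment
        if ch == "N":
            if i - seg_start >= min(p * r for p, r in REPEAT_THRESHOLDS.items()):
                candidates.extend(_segment_candidates(seq, seg_start, i))
            seg_start = i + 1
    # collapse overlaps: shortest primitive motif first, then maximal extent
    candidates.sort()
    kept: list[tuple] = []
    for p, neg_len, start, motif, n_rep in candidates:
        end = start + n_rep * p
        if any(start < k_end and k_start < end for _, _, k_start, k_end in kept):
            continue
        kept.append((motif, n_rep, start, end))
    hits = []
    for motif, n_rep, start, end in sorted(kept, key=lambda k: k[2]):
        left = start - (seq.rfind("N", 0, start) + 1)
        next_n = seq.find("N", end)
        right = (next_n if next_n != -1 else n_len) - end
        hits.append(
            MicrosatelliteHit(contig, int(start), int(end), motif, int(n_rep),
                              int(left), int(right))
        )
    return hits


def find_msats_all(contigs: dict[str, str]) -> list[MicrosatelliteHit]:
    hits: list[MicrosatelliteHit] = []
    for name in contigs:
        hits.extend(find_msats(name, contigs[name]))
    return hits


@dataclass
class MsatSummary:
    """Motif-class breakdown of detected microsatellites."""

    total: int = 0
    by_class: dict = field(default_factory=dict)
    n_flank_sufficient: int = 0
    n_contigs_with_hits: int = 0
    n_contigs_with_sufficient: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("total_microsatellites", self.total)]
        rows += [
            (f"{MOTIF_CLASS_NAMES[p]}_nucleotide_repeats", self.by_class.get(p, 0))
            for p in sorted(MOTIF_CLASS_NAMES)
        ]
        rows += [
            ("with_sufficient_flanks", self.n_flank_sufficient),
            ("contigs_with_microsatellites", self.n_contigs_with_hits),
            ("contigs_with_sufficient_flanks", self.n_contigs_with_sufficient),
        ]
        return pd.DataFrame(rows, columns=["statistic", "count"])


def summarize_msats(hits: Iterable[MicrosatelliteHit]) -> MsatSummary:
    hits = list(hits)
    by_class: dict[int, int] = {}
    for h in hits:
        by_class[len(h.motif)] = by_class.get(len(h.motif), 0) + 1
    return MsatSummary(
        total=len(hits),
        by_class=by_class,
        n_flank_sufficient=sum(h.flank_sufficient for h in hits),
        n_contigs_with_hits=len({h.contig for h in hits}),
        n_contigs_with_sufficient=len({h.contig for h in hits if h.flank_sufficient}),
    )


def hits_to_frame(hits: Iterable[MicrosatelliteHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.contig, h.start, h.end, h.motif, h.n_repeats, h.left_flank,
             h.right_flank, h.flank_sufficient)
            for h in hits
        ],
        columns=["contig", "start0", "end0", "motif", "n_repeats", "left_flank",
                 "right_flank", "flank_sufficient"],
    )


def hits_to_bed(hits: Iterable[MicrosatelliteHit]) -> str:
    """BED (0-based half-open) of tracts, usable as a repeat mask."""
    return "".join(
        f"{h.contig}\t{h.start}\t{h.end}\t{h.motif}x{h.n_repeats}\n" for h in hits
    )
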