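"""Threshold-based SNP detection and quality screening on pileups.

Detection reproduces a two-stage rule set used for pooled-transcriptome
marker discovery:

* putative stage — an observation participates only when its own phred
  quality is >= 25 and the mean quality of the same read's surrounding
  bases (5 bp each side) is >= 20; a site is a putative variant when the
  qualified depth reaches 4 and the most frequent non-reference allele has
  a qualified count of at least 2;
* screening stage — a putative SNP is kept ("filtered"/quality SNP) only
  when its minor allele represents no less than 10% of the qualified reads,
  no other putative SNP or indel lies within 15 bp on either side, the site
  is outside repetitive regions, and exactly two alleles are observed.

The minor allele frequency denominator is the qualified depth (observations
passing the quality gates), matching frequency estimation from reads
aligned at the polymorphic locus.  Deletion alleles are detected under the
same depth/count thresholds but only ever serve the clean-flank
neighborhood rule; they are not reported as SNPs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._seq import BASES
from .mapping import Pileup, PileupColumn, SPECIES_CODE

PURINES = {"A", "G"}
TRANSITION = "transition"
TRANSVERSION = "transversion"
INDEL = "indel"
MULTIALLELIC = "multiallelic"

PUTATIVE = "putative"
FILTERED_PASS = "filtered_pass"
FILTERED_FAIL = "filtered_fail"

LOW_MAF = "low_maf"
DIRTY_FLANK = "dirty_flank"
IN_REPEAT = "in_repeat"
NOT_BIALLELIC = "not_biallelic"

#: allele codes eligible to be counted (A, C, G, T, '-'); N never counts
_ALLELE_CODES = (0, 1, 2, 3, 5)


@dataclass(frozen=True)
class CallPolicy:
    min_depth: int = 4
    min_variant_count: int = 2
    min_central_quality: float = 25.0
    min_flank_mean_quality: float = 20.0
    flank_window: int = 5
    min_maf: float = 0.10
    clean_flank: int = 15
    biallelic_only: bool = True

    def __post_init__(self):
        if self.min_variant_count > self.min_depth:
            raise ValueError("min_variant_count must not exceed min_depth")
        if not (0.0 < self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in (0, 0.5]")


@dataclass
class SnpCall:
    """A detected variant site with allele accounting and filter state."""

    contig: str
    position: int
    ref: str
    counts: dict[str, int]
    counts_channel: dict[str, int]
    counts_blue: dict[str, int]
    depth: int
    n_alleles: int
    major: str
    minor: str
    maf: float
    substitution_class: str
    status: str = PUTATIVE
    fail_reasons: tuple[str, ...] = ()

    @property
    def is_snp(self) -> bool:
        """True for substitution calls (indel-allele calls excluded)."""
        return self.substitution_class != INDEL

    @property
    def depth_per_species(self) -> tuple[int, int]:
        return sum(self.counts_channel.values()), sum(self.counts_blue.values())


def classify_substitution(major: str, minor: str) -> str:
    """Transition (purine<->purine / pyrimidine<->pyrimidine) or transversion."""
    if major == minor:
        raise ValueError("substitution requires two distinct bases")
    return (
        TRANSITION
        if (major in PURINES) == (minor in PURINES)
        else TRANSVERSION
    )


def qualified_mask(column: PileupColumn, policy: CallPolicy) -> np.ndarray:
    """Observations passing the per-read quality gates (N never qualifies)."""
    return (
        (column.quals >= policy.min_central_quality)
        & (column.flank_quals >= policy.min_flank_mean_quality)
        & (column.bases != 4)
    )


def qualified_counts(
    column: PileupColumn, policy: CallPolicy, species: str | None = None
) -> tuple[int, dict[str, int]]:
    """(qualified depth, per-allele qualified counts), optionally one species."""
    keep = qualified_mask(column, policy)
    if species is not None:
        keep = keep & (column.species == SPECIES_CODE[species])
    bases = column.bases[keep]
    counts = {
        BASES[c]: int((bases == c).sum()) for c in _ALLELE_CODES
    }
    return int(keep.sum()), counts


def detect_putative(
    column: PileupColumn,
    policy: CallPolicy,
    ref_base: str,
    species: str | None = None,
) -> SnpCall | None:
    """Apply the putative-variant rule to one pileup column.

    ``ref_base`` is the base the observations are compared against: the
    contig base for the pooled view, or the species consensus when the
    column is restricted to one species (which emulates calling each
    species against its own assembly).  Returns None for unscorable
    reference bases (not A/C/G/T) and for columns failing the depth or
    variant-count thresholds.
    """
    ref_base = ref_base.upper()
    if ref_base not in "ACGT":
        return None
    depth, counts = qualified_counts(column, policy, species)
    if depth < policy.min_depth:
        return None
    nonref = {a: c for a, c in counts.items() if a != ref_base and c > 0}
    if not nonref:
        return None
    top_alt = max(nonref, key=lambda a: (nonref[a], -BASES.index(a)))
    if nonref[top_alt] < policy.min_variant_count:
        return None
    present = [a for a in counts if counts[a] > 0]
    ordered = sorted(present, key=lambda a: (-counts[a], BASES.index(a)))
    major = ordered[0]
    minor = ordered[1] if len(ordered) > 1 else ref_base
    minor_count = counts.get(minor, 0) if minor != major else 0
    maf = minor_count / depth
    # an allele exists only when it reaches the variant-count threshold;
    # singleton observations are sequencing noise, not alleles
    n_alleles = sum(c >= policy.min_variant_count for c in counts.values())
    if "-" in (major, minor):
        sub_class = INDEL
    elif n_alleles > 2:
        sub_class = MULTIALLELIC
    else:
        sub_class = classify_substitution(major, minor)
    _, ch_counts = qualified_counts(column, policy, "channel")
    _, bl_counts = qualified_counts(column, policy, "blue")
    return SnpCall(
        contig=column.contig,
        position=column.position,
        ref=ref_base,
        counts=counts,
        counts_channel=ch_counts,
        counts_blue=bl_counts,
        depth=depth,
        n_alleles=n_alleles,
        major=major,
        minor=minor,
        maf=maf,
        substitution_class=sub_class,
    )


def detect_insertion_sites(
    pileup: Pileup,
    contig: str,
    policy: CallPolicy,
    species: str | None = None,
) -> list[int]:
    """Positions where inserted sequence passes the depth/count thresholds.

    Insertions live in the pileup's side channel (keyed by the reference
    position they precede); they are neighbors for the clean-flank rule,
    never SNPs.
    """
    pos, qual, flank, spec = pileup.insertion_arrays(contig)
    keep = (qual >= policy.min_central_quality) & (
        flank >= policy.min_flank_mean_quality
    )
    if species is not None:
        keep &= spec == SPECIES_CODE[species]
    pos = pos[keep]
    if len(pos) == 0:
        return []
    uniq, counts = np.unique(pos, return_counts=True)
    out = []
    for p, c in zip(uniq, counts):
        if c < policy.min_variant_count:
            continue
        col = pileup.column(contig, int(p))
        if col is None:
            continue
        depth, _ = qualified_counts(col, policy, species)
        if depth >= policy.min_depth:
            out.append(int(p))
    return out


# ---------------------------------------------------------------------------
# repeat masks


def mask_from_bed(path: str) -> dict[str, IntervalTree]:
    """Repeat mask from a BED file (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            contig, start, end = f[0], int(f[1]), int(f[2])
            if end > start:
                trees.setdefault(contig, IntervalTree()).addi(start, end)
    return trees


def fallback_mask(contigs: dict[str, str]) -> dict[str, IntervalTree]:
    """Built-in repeat mask: homopolymers >= 10 bp plus microsatellite tracts.

    Used when no external repeat annotation (e.g. a RepeatMasker BED) is
    supplied.
    """
    from .msat import find_msats

    trees: dict[str, IntervalTree] = {}
    for name, seq in contigs.items():
        tree = IntervalTree()
        seq = seq.upper()
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if seq[i] != "N" and j - i >= 10:
                tree.addi(i, j)
            i = j
        for hit in find_msats(name, seq):
            tree.addi(hit.start, hit.end)
        if tree:
            tree.merge_overlaps()
            trees[name] = tree
    return trees


def in_mask(mask: dict[str, IntervalTree] | None, contig: str, pos: int) -> bool:
    return bool(mask and contig in mask and mask[contig].overlaps(pos))


# ---------------------------------------------------------------------------
# screening


def screen_quality(
    calls: Sequence[SnpCall],
    neighbor_positions: dict[str, np.ndarray],
    repeat_mask: dict[str, IntervalTree] | None,
    policy: CallPolicy,
) -> list[SnpCall]:
    """Mark each putative substitution call filtered_pass / filtered_fail.

    ``neighbor_positions`` maps contig -> sorted positions of *all* putative
    variants in the same view (SNPs whether or not they later fail, plus
    indels); any neighbor within ``clean_flank`` bp contaminates the site.
    Input must be sorted by (contig, position).
    """
    key = [(c.contig, c.position) for c in calls]
    if key != sorted(key):
        raise ValueError("calls must be sorted by (contig, position)")
    out = []
    for call in calls:
        reasons = []
        if call.maf < policy.min_maf:
            reasons.append(LOW_MAF)
        nbrs = neighbor_positions.get(call.contig)
        if nbrs is not None and len(nbrs):
            lo = np.searchsorted(nbrs, call.position - policy.clean_flank, "left")
            hi = np.searchsorted(nbrs, call.position + policy.clean_flank, "right")
            n_in_window = hi - lo
            n_self = np.searchsorted(nbrs, call.position, "right") - \
                np.searchsorted(nbrs, call.position, "left")
            if n_in_window - n_self > 0:
                reasons.append(DIRTY_FLANK)
        if in_mask(repeat_mask, call.contig, call.position):
            reasons.append(IN_REPEAT)
        if policy.biallelic_only and call.n_alleles != 2:
            reasons.append(NOT_BIALLELIC)
        out.append(
            replace(
                call,
                status=FILTERED_PASS if not reasons else FILTERED_FAIL,
                fail_reasons=tuple(reasons),
            )
        )
    return out


# ---------------------------------------------------------------------------
# summaries


@dataclass
class SnpSummary:
    """Marker-panel style summary of a finalized call set."""

    total_snps: int = 0
    transitions: int = 0
    transversions: int = 0
    multiallelic: int = 0
    indel_sites: int = 0
    snp_per_100bp: float = 0.0
    total_contig_bases: int = 0
    contigs_with_snps: int = 0
    snps_per_contig: dict = field(default_factory=dict)
    maf_hist: dict = field(default_factory=dict)
    maf_mean: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_biallelic_snps", self.total_snps),
            ("transitions", self.transitions),
            ("transversions", self.transversions),
            ("multiallelic_sites", self.multiallelic),
            ("indel_sites", self.indel_sites),
            ("snp_per_100bp", round(self.snp_per_100bp, 4)),
            ("total_contig_bases", self.total_contig_bases),
            ("contigs_with_snps", self.contigs_with_snps),
            ("mean_maf", round(self.maf_mean, 4) if self.total_snps else ""),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize(calls: Iterable[SnpCall], contigs: dict[str, str]) -> SnpSummary:
    """Totals, Ts/Tv, SNP density and MAF spectrum over finalized calls.

    Only substitution calls are SNPs; transition + transversion always
    equals the bi-allelic total.  The MAF histogram uses 0.05-wide bins.
    """
    summary = SnpSummary(total_contig_bases=sum(map(len, contigs.values())))
    per_contig: dict[str, int] = {}
    mafs = []
    for call in calls:
        if call.substitution_class == INDEL:
            summary.indel_sites += 1
            continue
        if call.substitution_class == MULTIALLELIC:
            summary.multiallelic += 1
            continue
        if call.substitution_class == TRANSITION:
            summary.transitions += 1
        else:
            summary.transversions += 1
        per_contig[call.contig] = per_contig.get(call.contig, 0) + 1
        mafs.append(call.maf)
        b = min(int(call.maf / 0.05), 9)
        summary.maf_hist[b] = summary.maf_hist.get(b, 0) + 1
    summary.total_snps = summary.transitions + summary.transversions
    if summary.total_contig_bases:
        summary.snp_per_100bp = 100.0 * summary.total_snps / summary.total_contig_bases
    summary.contigs_with_snps = len(per_contig)
    summary.snps_per_contig = per_contig
    if mafs:
        summary.maf_mean = float(np.mean(mafs))
    return summary


# ---------------------------------------------------------------------------
# whole-contig calling used by the pipeline


def species_consensus(
    pileup: Pileup, contig: str, policy: CallPolicy, species: str
) -> np.ndarray:
    """Per-position consensus base code for one species (qualified obs only).

    Positions with no qualified observation keep the contig base.  The
    consensus stands in for the species' own assembly when the two species
    are called against a shared contig set, so that a fixed inter-specific
    difference is not mistaken for an intra-specific SNP.
    """
    from ._seq import encode

    ref_codes = encode(pileup.contigs[contig]).copy()
    pos, base, qual, flank, spec = pileup.arrays(contig)
    keep = (
        (qual >= policy.min_central_quality)
        & (flank >= policy.min_flank_mean_quality)
        & (base != 4)
        & (spec == SPECIES_CODE[species])
    )
    pos, base = pos[keep], base[keep]
    counts = np.zeros((len(ref_codes), 6), dtype=np.int32)
    np.add.at(counts, (pos, base), 1)
    covered = counts.sum(axis=1) > 0
    consensus = counts.argmax(axis=1).astype(np.uint8)  # ties -> lower code
    out = ref_codes
    out[covered] = consensus[covered]
    return out


def call_view(
    pileup: Pileup,
    contig: str,
    policy: CallPolicy,
    species: str | None = None,
    use_consensus_ref: bool = False,
) -> list[SnpCall]:
    """All putative variant calls on one contig for one view.

    A vectorized prescreen finds candidate positions (qualified depth >=
    min_depth with a qualifying non-reference allele); each candidate is
    then confirmed through :func:`detect_putative` on its column.
    """
    from ._seq import encode

    pos, base, qual, flank, spec = pileup.arrays(contig)
    keep = (
        (qual >= policy.min_central_quality)
        & (flank >= policy.min_flank_mean_quality)
        & (base != 4)
    )
    if species is not None:
        keep = keep & (spec == SPECIES_CODE[species])
    pos_q, base_q = pos[keep], base[keep]
    n = len(pileup.contigs[contig])
    counts = np.zeros((n, 6), dtype=np.int32)
    np.add.at(counts, (pos_q, base_q), 1)
    depth = counts.sum(axis=1)
    if use_consensus_ref and species is not None:
        ref_codes = species_consensus(pileup, contig, policy, species)
    else:
        ref_codes = encode(pileup.contigs[contig])
    safe_ref = np.minimum(ref_codes, 5)
    ref_count = counts[np.arange(n), safe_ref]
    ref_count = np.where(ref_codes <= 3, ref_count, 0)
    alt_top = np.where(
        (np.arange(6)[None, :] == safe_ref[:, None]), 0, counts
    ).max(axis=1)
    cand = np.flatnonzero(
        (depth >= policy.min_depth)
        & (alt_top >= policy.min_variant_count)
        & (ref_codes <= 3)
    )
    calls = []
    for p in cand:
        col = pileup.column(contig, int(p))
        call = detect_putative(col, policy, BASES[ref_codes[p]], species)
        if call is not None:
            calls.append(call)
    return calls
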