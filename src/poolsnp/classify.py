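"""Six-category intra-/inter-specific classification of variant sites.

Candidate sites from the two species-restricted call sets and the pooled
call set are compared position by position on the shared contig
coordinates and assigned one of six categories:

1. polymorphic within channel only (blue adequately covered, monomorphic);
2. polymorphic within blue only (channel adequately covered, monomorphic);
3. polymorphic within both species at the same position;
4. inter-specific: monomorphic within each species but the two species
   carry different (fixed) alleles;
5. polymorphic within channel, blue coverage below the minimum (4 reads);
6. polymorphic within blue, channel coverage below the minimum.

From the category counts the derived totals follow by identity:
intra-channel = c1 + c3 + c5, intra-blue = c2 + c3 + c6, shared = c3,
inter-specific = c4.  Sites with inadequate coverage in both species are
"unclassifiable"; categories 5/6 deliberately expose the coverage-driven
underestimation of shared and inter-specific counts rather than correcting
for it.

Category 4 requires adequate depth in both species and within-species
allele purity of at least 90%, which implements "no variation within either
species" while tolerating stray sequencing errors.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .calling import CallPolicy, FILTERED_PASS, SnpCall, qualified_counts
from .mapping import Pileup
from .simulate import BLUE, CHANNEL

UNCLASSIFIABLE = "unclassifiable"
DEFAULT_MIN_SPECIES_DEPTH = 4
DEFAULT_PURITY = 0.9

CATEGORIES = (1, 2, 3, 4, 5, 6)


@dataclass
class SpeciesSiteEvidence:
    depth: int
    counts: dict[str, int]
    has_intra_snp: bool

    @property
    def major_allele(self) -> str | None:
        present = {a: c for a, c in self.counts.items() if c > 0}
        if not present:
            return None
        return max(present, key=lambda a: (present[a], a))

    @property
    def purity(self) -> float:
        if self.depth == 0:
            return 0.0
        return self.counts.get(self.major_allele, 0) / self.depth


@dataclass
class SiteEvidence:
    """Joint two-species evidence at one candidate position."""

    contig: str
    position: int
    channel: SpeciesSiteEvidence
    blue: SpeciesSiteEvidence
    pooled_variant: bool
    min_species_depth: int = DEFAULT_MIN_SPECIES_DEPTH
    purity_threshold: float = DEFAULT_PURITY


def classify_site(ev: SiteEvidence) -> int | str:
    """Category 1-6 (or "unclassifiable") for one site."""
    m = ev.min_species_depth
    ch_snp = ev.channel.has_intra_snp and ev.channel.depth >= m
    bl_snp = ev.blue.has_intra_snp and ev.blue.depth >= m
    if ch_snp and bl_snp:
        return 3
    if ch_snp:
        return 1 if ev.blue.depth >= m else 5
    if bl_snp:
        return 2 if ev.channel.depth >= m else 6
    if (
        ev.pooled_variant
        and ev.channel.depth >= m
        and ev.blue.depth >= m
        and ev.channel.major_allele is not None
        and ev.blue.major_allele is not None
        and ev.channel.major_allele != ev.blue.major_allele
        and ev.channel.purity >= ev.purity_threshold
        and ev.blue.purity >= ev.purity_threshold
    ):
        return 4
    return UNCLASSIFIABLE


@dataclass
class ClassifiedSite:
    contig: str
    position: int
    category: int | str
    evidence: SiteEvidence
    pooled_only: bool = False


@dataclass
class CategoryReport:
    """Category counts plus the identity-derived intra/inter totals."""

    counts: dict = field(default_factory=dict)
    contig_counts: dict = field(default_factory=dict)
    n_unclassifiable: int = 0

    def __getitem__(self, cat: int) -> int:
        return self.counts.get(cat, 0)

    @property
    def intra_channel(self) -> int:
        return self[1] + self[3] + self[5]

    @property
    def intra_blue(self) -> int:
        return self[2] + self[3] + self[6]

    @property
    def shared(self) -> int:
        return self[3]

    @property
    def inter_specific(self) -> int:
        return self[4]

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(f"category_{c}", self[c]) for c in CATEGORIES]
        rows += [
            ("unclassifiable", self.n_unclassifiable),
            ("intra_specific_channel", self.intra_channel),
            ("intra_specific_blue", self.intra_blue),
            ("intra_specific_shared", self.shared),
            ("inter_specific", self.inter_specific),
        ]
        rows += [
            (f"contigs_with_category_{c}", len(self.contig_counts.get(c, ())))
            for c in CATEGORIES
        ]
        return pd.DataFrame(rows, columns=["statistic", "count"])


def tally_categories(sites: Iterable[ClassifiedSite]) -> CategoryReport:
    report = CategoryReport()
    for site in sites:
        if site.category == UNCLASSIFIABLE:
            report.n_unclassifiable += 1
            continue
        report.counts[site.category] = report.counts.get(site.category, 0) + 1
        report.contig_counts.setdefault(site.category, set()).add(site.contig)
    return report


# ---------------------------------------------------------------------------
# pipeline glue: evidence assembly from screened call sets and the pileup


def _passing_positions(calls: Iterable[SnpCall], snps_only: bool = True):
    out: dict[str, set[int]] = {}
    for c in calls:
        if snps_only and not c.is_snp:
            continue
        if c.status == FILTERED_PASS:
            out.setdefault(c.contig, set()).add(c.position)
    return out


def classify_calls(
    pileup: Pileup,
    policy: CallPolicy,
    channel_calls: list[SnpCall],
    blue_calls: list[SnpCall],
    pooled_calls: list[SnpCall],
    min_species_depth: int = DEFAULT_MIN_SPECIES_DEPTH,
    purity_threshold: float = DEFAULT_PURITY,
) -> list[ClassifiedSite]:
    """Classify the union of screened call positions across the three views.

    The per-species lists must have been called against the species'
    consensus (so they contain only within-species polymorphisms) and all
    three lists must already be quality-screened; classification considers
    their passing sites, reproducing the three-list comparison design.
    """
    ch_pos = _passing_positions(channel_calls)
    bl_pos = _passing_positions(blue_calls)
    po_pos = _passing_positions(pooled_calls)
    contigs = sorted(set(ch_pos) | set(bl_pos) | set(po_pos))
    out: list[ClassifiedSite] = []
    for contig in contigs:
        sites = sorted(
            ch_pos.get(contig, set())
            | bl_pos.get(contig, set())
            | po_pos.get(contig, set())
        )
        for pos in sites:
            col = pileup.column(contig, pos)
            if col is None:
                continue
            ch_depth, ch_counts = qualified_counts(col, policy, CHANNEL)
            bl_depth, bl_counts = qualified_counts(col, policy, BLUE)
            ev = SiteEvidence(
                contig=contig,
                position=pos,
                channel=SpeciesSiteEvidence(
                    ch_depth, ch_counts, pos in ch_pos.get(contig, ())
                ),
                blue=SpeciesSiteEvidence(
                    bl_depth, bl_counts, pos in bl_pos.get(contig, ())
                ),
                pooled_variant=pos in po_pos.get(contig, ()),
                min_species_depth=min_species_depth,
                purity_threshold=purity_threshold,
            )
            out.append(
                ClassifiedSite(
                    contig=contig,
                    position=pos,
                    category=classify_site(ev),
                    evidence=ev,
                    pooled_only=(
                        pos not in ch_pos.get(contig, ())
                        and pos not in bl_pos.get(contig, ())
                    ),
                )
            )
    return out


def sites_to_frame(sites: Iterable[ClassifiedSite]) -> pd.DataFrame:
    def fmt(counts: dict[str, int]) -> str:
        return ";".join(f"{a}={c}" for a, c in sorted(counts.items()) if c)

    rows = []
    for s in sites:
        rows.append(
            (
                s.contig, s.position, s.category,
                s.evidence.channel.depth, fmt(s.evidence.channel.counts),
                s.evidence.blue.depth, fmt(s.evidence.blue.counts),
                int(s.pooled_only),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos0", "category", "depth_channel", "counts_channel",
            "depth_blue", "counts_blue", "pooled_only",
        ],
    )
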