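"""Scoring pipeline output against a synthetic-data truth ledger.

Used by validation experiments: which planted variants were recovered as
quality (filtered_pass) SNPs with the correct intra-/inter-specific
category, how many passing calls have no planted variant behind them, and
how well read-derived minor allele frequencies track the realized
(haplotype-sampled) frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import FILTERED_PASS, SnpCall
from .classify import ClassifiedSite
from .simulate import (
    BLUE,
    CHANNEL,
    INTER_FIXED,
    INTRA_BLUE,
    INTRA_BOTH,
    INTRA_CHANNEL,
    SimTruth,
    TruthRecord,
)

#: categories consistent with each planted variant kind (coverage of the
#: other species decides between e.g. 1 and 5, so sets are allowed)
EXPECTED_CATEGORIES = {
    INTRA_CHANNEL: {1, 3, 5},
    INTRA_BLUE: {2, 3, 6},
    INTRA_BOTH: {3},
    INTER_FIXED: {4},
}

INTRA_CATEGORIES = {1, 2, 3, 5, 6}


@dataclass
class RecoveryReport:
    n_eligible: int = 0
    n_recovered: int = 0
    n_missed: int = 0
    n_wrong_category: int = 0
    n_false_pass: int = 0
    total_bases: int = 0
    n_inter_leaked_as_intra: int = 0
    missed: list = field(default_factory=list)

    @property
    def recovery_pct(self) -> float:
        if self.n_eligible == 0:
            return float("nan")
        return 100.0 * self.n_recovered / self.n_eligible

    @property
    def false_pass_per_100kb(self) -> float:
        if self.total_bases == 0:
            return float("nan")
        return 1e5 * self.n_false_pass / self.total_bases


def score_recovery(
    truth: SimTruth,
    screened: dict[str, list[SnpCall]],
    sites: list[ClassifiedSite],
    total_bases: int,
    min_realized_maf: float = 0.15,
    clean_flank: int = 15,
) -> RecoveryReport:
    """Recovery and false-positive accounting for one synthetic run.

    Eligible truth records (bi-allelic, realized minor frequency at or
    above the cut, clean planted flanks, outside planted repeat tracts)
    are recovered when a classified site exists at their position with a
    category consistent with the planted kind.  A false pass is a
    filtered_pass SNP, in any view, at a position with no planted variant.
    """
    by_site = {(s.contig, s.position): s.category for s in sites}
    eligible = truth.eligible_snps(
        min_realized_maf=min_realized_maf, clean_flank=clean_flank
    )
    report = RecoveryReport(
        n_eligible=len(eligible), total_bases=total_bases
    )
    for rec in eligible:
        cat = by_site.get((rec.contig, rec.pos0))
        if cat is None:
            report.n_missed += 1
            report.missed.append(rec)
        elif cat in EXPECTED_CATEGORIES[rec.kind]:
            report.n_recovered += 1
        else:
            report.n_wrong_category += 1
            report.missed.append(rec)
    planted = {(r.contig, r.pos0) for r in truth}
    false_sites = set()
    for calls in screened.values():
        for c in calls:
            if c.is_snp and c.status == FILTERED_PASS \
                    and (c.contig, c.position) not in planted:
                false_sites.add((c.contig, c.position))
    report.n_false_pass = len(false_sites)
    inter_pos = {
        (r.contig, r.pos0) for r in truth.of_kind(INTER_FIXED)
    }
    report.n_inter_leaked_as_intra = sum(
        1 for s in sites
        if s.category in INTRA_CATEGORIES
        and (s.contig, s.position) in inter_pos
    )
    return report


def maf_recovery_error(
    truth: SimTruth, screened: dict[str, list[SnpCall]]
) -> tuple[float, int]:
    """(|mean called MAF - mean realized MAF|, n matched sites).

    Matches per-species filtered_pass calls to planted intra-specific
    records and compares the mean read-derived minor allele frequency
    against the mean realized haplotype frequency over the same sites.
    """
    called, realized = [], []
    for species, view, attr in (
        (CHANNEL, CHANNEL, "realized_freq_channel"),
        (BLUE, BLUE, "realized_freq_blue"),
    ):
        kinds = {INTRA_BOTH, INTRA_CHANNEL if species == CHANNEL else INTRA_BLUE}
        by_pos: dict[tuple[str, int], TruthRecord] = {
            (r.contig, r.pos0): r for r in truth if r.kind in kinds
        }
        for c in screened.get(view, ()):
            if not (c.is_snp and c.status == FILTERED_PASS):
                continue
            rec = by_pos.get((c.contig, c.position))
            if rec is None:
                continue
            f = getattr(rec, attr) or 0.0
            called.append(c.maf)
            realized.append(min(f, 1.0 - f))
    if not called:
        return float("nan"), 0
    return abs(float(np.mean(called)) - float(np.mean(realized))), len(called)
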