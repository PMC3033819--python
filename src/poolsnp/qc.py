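"""Read cleaning for pooled transcriptome libraries.

Each read is processed in a fixed order: (1) the longest 3' overlap with an
adaptor prefix is clipped, (2) trailing ambiguous bases (N) are stripped,
(3) the read is discarded when its mean phred quality falls below a
threshold (default 20), (4) the read is discarded when shorter than a
minimum length (default 15 bp).  Internal Ns are retained and simply count
as mismatches during mapping.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from ._seq import string_to_phred

KEPT = "kept"
LOW_QUALITY = "low_quality"
TOO_SHORT = "too_short"

MIN_ADAPTOR_OVERLAP = 8


@dataclass(frozen=True)
class TrimPolicy:
    adaptors: tuple[str, ...] = ()
    min_mean_quality: float = 20.0
    min_length: int = 15
    trim_trailing_n: bool = True

    def __post_init__(self):
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        object.__setattr__(self, "adaptors", tuple(a.upper() for a in self.adaptors))


@dataclass
class TrimStats:
    reads_before: int = 0
    reads_after: int = 0
    bases_before: int = 0
    bases_after: int = 0
    discarded: dict = field(default_factory=lambda: {LOW_QUALITY: 0, TOO_SHORT: 0})

    def to_tsv(self) -> str:
        lines = [
            ("reads_before", self.reads_before),
            ("reads_after", self.reads_after),
            ("bases_before", self.bases_before),
            ("bases_after", self.bases_after),
            ("discarded_low_quality", self.discarded[LOW_QUALITY]),
            ("discarded_too_short", self.discarded[TOO_SHORT]),
        ]
        return "".join(f"{k}\t{v}\n" for k, v in lines)


def _clip_adaptor(seq: str, policy: TrimPolicy) -> int:
    """Length to keep after clipping the longest adaptor prefix-overlap at 3'."""
    keep = len(seq)
    for adaptor in policy.adaptors:
        # complete adaptor occurrence: clip from its first occurrence
        hit = seq.find(adaptor)
        if hit != -1:
            keep = min(keep, hit)
            continue
        max_l = min(len(seq), len(adaptor))
        for l in range(max_l, MIN_ADAPTOR_OVERLAP - 1, -1):
            if seq.endswith(adaptor[:l]):
                keep = min(keep, len(seq) - l)
                break
    return keep


def trim_read(
    seq: str, qual: str | np.ndarray, policy: TrimPolicy
) -> tuple[bool, tuple[str, str] | None, str]:
    """Clean one read; returns (kept, (seq, qual) or None, reason code).

    Raises ValueError when sequence and quality lengths differ.
    """
    phred = string_to_phred(qual) if isinstance(qual, str) else np.asarray(qual)
    qstr = qual if isinstance(qual, str) else None
    if len(seq) != len(phred):
        raise ValueError("sequence and quality strings differ in length")
    seq = seq.upper()
    # clip adaptors and trailing Ns to a fixed point so trimming a trimmed
    # read changes nothing (clipping can expose a new adaptor overlap)
    keep = len(seq)
    while True:
        new = _clip_adaptor(seq[:keep], policy) if policy.adaptors else keep
        if policy.trim_trailing_n:
            while new > 0 and seq[new - 1] == "N":
                new -= 1
        if new == keep:
            break
        keep = new
    if keep == 0:
        return False, None, TOO_SHORT
    if float(np.mean(phred[:keep])) < policy.min_mean_quality:
        return False, None, LOW_QUALITY
    if keep < policy.min_length:
        return False, None, TOO_SHORT
    if qstr is None:
        from ._seq import phred_to_string

        qstr = phred_to_string(phred)
    return True, (seq[:keep], qstr[:keep]), KEPT


def trim_fastq(
    records: Iterable[tuple[str, str, str]],
    policy: TrimPolicy,
    stats: TrimStats | None = None,
) -> Iterator[tuple[str, str, str]]:
    """Stream (name, seq, qual) records through trim_read, preserving order.

    Pass a TrimStats to collect before/after counters (filled as the
    iterator is consumed).
    """
    if stats is None:
        stats = TrimStats()
    for i, (name, seq, qual) in enumerate(records):
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record #{i} ({name}): length mismatch")
        stats.reads_before += 1
        stats.bases_before += len(seq)
        kept, trimmed, reason = trim_read(seq, qual, policy)
        if kept:
            stats.reads_after += 1
            stats.bases_after += len(trimmed[0])
            yield name, trimmed[0], trimmed[1]
        else:
            stats.discarded[reason] += 1
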