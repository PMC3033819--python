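"""Synthetic two-species pooled transcriptome data with a ground-truth ledger.

The generator emulates the study design the package targets: RNA pooled
from many individuals of each of two closely related species (called
"channel" and "blue" throughout), sequenced as short quality-scored reads
against a shared set of transcript contigs.  Planted features:

* intra-specific SNPs — bi-allelic sites segregating within one species at
  a configured minor allele frequency (Hardy-Weinberg, unrelated diploids);
* shared intra-specific SNPs — the same site segregating in both species;
* inter-specific fixed differences — sites where every haplotype of one
  species carries an alternative allele and the other species is fixed for
  the reference allele;
* short indels (1-3 bp) segregating within one species;
* microsatellite tracts and low-complexity (homopolymer) tracts written
  into the reference itself.

Every planted feature is recorded in a :class:`SimTruth` ledger which is
updated with the *realized* (sampled) haplotype allele frequencies when the
pools are drawn, so downstream recovery can be scored against what was
actually present in the pool rather than the nominal frequency.

Haplotypes are unrelated and unlinked between sites: each of the 2N
haplotypes of an N-individual pool carries the alternative allele
independently with probability equal to the site's configured frequency.
Reads are drawn uniformly along each contig (no expression skew), with
independent per-base substitution errors and phred qualities sampled
around a per-position mean profile.  Species of origin is carried in the
read name prefix ("CH|" / "BL|").
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import decode, encode, phred_to_string, revcomp_codes

CHANNEL = "channel"
BLUE = "blue"
SPECIES = (CHANNEL, BLUE)
NAME_PREFIX = {CHANNEL: "CH", BLUE: "BL"}

# truth record kinds
INTRA_CHANNEL = "intra_channel"
INTRA_BLUE = "intra_blue"
INTRA_BOTH = "intra_both"
INTER_FIXED = "inter_fixed"
INDEL = "indel"
MSAT = "msat"
REPEAT_TRACT = "repeat_tract"

SNP_KINDS = (INTRA_CHANNEL, INTRA_BLUE, INTRA_BOTH, INTER_FIXED)
TRACT_KINDS = (MSAT, REPEAT_TRACT)

_EDGE_PAD = 10  # variants are not planted within this many bp of contig ends

TRUTH_COLUMNS = [
    "contig", "pos0", "kind", "ref", "alt", "freq_channel", "freq_blue",
    "motif", "nrepeats", "realized_freq_channel", "realized_freq_blue",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic two-species experiment."""

    n_contigs: int = 20
    contig_length_range: tuple[int, int] = (800, 1200)
    n_individuals_per_species: tuple[int, int] = (47, 19)
    intra_snp_rate: float = 2.0          # SNPs / kb / species
    intra_both_rate: float = 0.2         # shared polymorphic sites / kb
    inter_fixed_diff_rate: float = 1.0   # fixed differences / kb
    maf_distribution: tuple[tuple[float, float], ...] = tuple(
        (round(0.10 + 0.05 * i, 2), 1.0) for i in range(9)
    )
    indel_rate: float = 0.2              # events / kb
    transition_fraction: float = 2 / 3   # transition bias of substitutions
    msat_tract_rate: float = 0.3         # tracts / contig
    repeat_tract_rate: float = 0.3       # low-complexity tracts / contig
    read_length: int = 100
    coverage_target: float = 100.0
    base_error_rate: float = 0.001
    quality_profile: tuple[float, ...] | float = (38.0, 28.0)
    quality_sd: float = 6.0
    paired: bool = False
    fragment_length: int = 300
    adaptor_suffix: str | None = None
    adaptor_fraction: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.contig_length_range
        for r in (self.intra_snp_rate, self.intra_both_rate,
                  self.inter_fixed_diff_rate, self.indel_rate,
                  self.msat_tract_rate, self.repeat_tract_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.coverage_target <= 0:
            raise ValueError("coverage_target must be > 0")
        for f, w in self.maf_distribution:
            if not (0.0 < f <= 0.5):
                raise ValueError("allele frequencies must lie in (0, 0.5]")
            if w < 0:
                raise ValueError("maf weights must be >= 0")
        if not (0.0 <= self.transition_fraction <= 1.0):
            raise ValueError("transition_fraction must lie in [0, 1]")
        # longest plantable feature: hexa motif x 8 repeats, plus primer flanks
        if lo < 48 + 2 * 50:
            raise ValueError(
                "contig_length_range minimum too small to hold a planted "
                "tract with 50-bp flanks"
            )
        if hi < lo or lo < 1:
            raise ValueError("invalid contig_length_range")

    def mean_quality(self, read_length: int) -> np.ndarray:
        if isinstance(self.quality_profile, (int, float)):
            return np.full(read_length, float(self.quality_profile))
        prof = np.asarray(self.quality_profile, dtype=float)
        # stretch/interpolate the profile onto the read length
        x = np.linspace(0, 1, read_length)
        xp = np.linspace(0, 1, len(prof))
        return np.interp(x, xp, prof)


@dataclass
class TruthRecord:
    contig: str
    pos0: int
    kind: str
    ref: str
    alt: str
    freq_channel: float = 0.0
    freq_blue: float = 0.0
    motif: str = ""
    nrepeats: int = 0
    realized_freq_channel: float | None = None
    realized_freq_blue: float | None = None

    @property
    def end0(self) -> int:
        """End of the footprint on the reference (half-open)."""
        if self.kind in TRACT_KINDS:
            return self.pos0 + len(self.motif) * self.nrepeats
        return self.pos0 + max(len(self.ref), 1)


@dataclass
class SimTruth:
    """Ledger of every planted feature, keyed by (contig, position)."""

    records: list[TruthRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def of_kind(self, *kinds: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind in kinds]

    def validate(self, contigs: dict[str, str]) -> None:
        seen = set()
        for r in self.records:
            if r.contig not in contigs or not (0 <= r.pos0 < len(contigs[r.contig])):
                raise ValueError(f"truth record outside contig: {r}")
            if r.kind in SNP_KINDS:
                key = (r.contig, r.pos0)
                if key in seen:
                    raise ValueError(f"duplicate SNP truth record at {key}")
                seen.add(key)

    # -- recovery scoring -------------------------------------------------
    def tract_intervals(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for r in self.of_kind(*TRACT_KINDS):
            out.setdefault(r.contig, []).append((r.pos0, r.end0))
        return out

    def eligible_snps(
        self, min_realized_maf: float = 0.0, clean_flank: int = 15
    ) -> list[TruthRecord]:
        """Planted SNP sites a perfect caller is expected to recover.

        Eligible records are bi-allelic substitution sites whose realized
        minor-allele frequency reaches ``min_realized_maf`` in at least one
        species (fixed inter-specific differences qualify whenever realized
        as fixed), with no other planted feature within ``clean_flank`` bp
        and lying outside planted repeat/microsatellite tracts.
        """
        tracts = self.tract_intervals()
        by_contig: dict[str, list[TruthRecord]] = {}
        for r in self.records:
            by_contig.setdefault(r.contig, []).append(r)
        out = []
        for r in self.of_kind(*SNP_KINDS):
            rc = r.realized_freq_channel or 0.0
            rb = r.realized_freq_blue or 0.0
            if r.kind == INTER_FIXED:
                if sorted([rc, rb]) != [0.0, 1.0]:
                    continue
            else:
                maf = max(min(rc, 1 - rc), min(rb, 1 - rb))
                if maf < min_realized_maf:
                    continue
            if any(
                o is not r and o.end0 > r.pos0 - clean_flank
                and o.pos0 <= r.pos0 + clean_flank
                for o in by_contig[r.contig]
            ):
                continue
            if any(s <= r.pos0 < e for s, e in tracts.get(r.contig, [])):
                continue
            out.append(r)
        return out

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(TRUTH_COLUMNS) + "\n")
            for r in self.records:
                fh.write(
                    "\t".join(
                        [
                            r.contig, str(r.pos0), r.kind, r.ref, r.alt,
                            repr(r.freq_channel), repr(r.freq_blue),
                            r.motif, str(r.nrepeats),
                            "" if r.realized_freq_channel is None
                            else repr(r.realized_freq_channel),
                            "" if r.realized_freq_blue is None
                            else repr(r.realized_freq_blue),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != TRUTH_COLUMNS:
                raise ValueError("unrecognized truth ledger header")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                records.append(
                    TruthRecord(
                        contig=f[0], pos0=int(f[1]), kind=f[2], ref=f[3],
                        alt=f[4], freq_channel=float(f[5]),
                        freq_blue=float(f[6]), motif=f[7], nrepeats=int(f[8]),
                        realized_freq_channel=float(f[9]) if f[9] else None,
                        realized_freq_blue=float(f[10]) if f[10] else None,
                    )
                )
        return cls(records)


# ---------------------------------------------------------------------------
# reference simulation


def _plant_tracts(
    seq: np.ndarray, contig: str, config: SimConfig, rng: np.random.Generator
) -> list[TruthRecord]:
    """Overwrite microsatellite / homopolymer tracts into a contig."""
    records: list[TruthRecord] = []
    occupied: list[tuple[int, int]] = []
    n_msat = rng.poisson(config.msat_tract_rate)
    n_rep = rng.poisson(config.repeat_tract_rate)
    for kind in [MSAT] * n_msat + [REPEAT_TRACT] * n_rep:
        if kind == MSAT:
            p = int(rng.integers(2, 7))
            while True:  # primitive motif (not a repetition of a shorter one)
                motif = decode(rng.integers(0, 4, size=p).astype(np.uint8))
                if all(motif != motif[:d] * (p // d)
                       for d in range(1, p) if p % d == 0):
                    break
            n_rep_count = int(rng.integers(8, 13) if p == 2 else rng.integers(5, 9))
        else:
            motif = "ACGT"[rng.integers(0, 4)]
            p, n_rep_count = 1, int(rng.integers(10, 16))
        tract = encode(motif * n_rep_count)
        tlen = len(tract)
        for _ in range(100):  # rejection-sample a non-overlapping position
            start = int(rng.integers(50, len(seq) - 50 - tlen + 1))
            if all(start >= e + 1 or start + tlen <= s - 1 for s, e in occupied):
                break
        else:
            continue
        seq[start : start + tlen] = tract
        # keep the tract maximal: flanking bases must not extend the repeat
        first, last = tract[0], tract[-1]
        if seq[start - 1] == last:
            seq[start - 1] = (last + 1 + rng.integers(0, 3)) % 4
        if seq[start + tlen] == first:
            seq[start + tlen] = (first + 1 + rng.integers(0, 3)) % 4
        occupied.append((start, start + tlen))
        records.append(
            TruthRecord(contig, start, kind, ref="", alt="", motif=motif,
                        nrepeats=n_rep_count)
        )
    return records


def _draw_maf(config: SimConfig, rng: np.random.Generator) -> float:
    freqs = np.array([f for f, _ in config.maf_distribution])
    w = np.array([w for _, w in config.maf_distribution], dtype=float)
    return float(rng.choice(freqs, p=w / w.sum()))


def _plant_variants(
    seq: np.ndarray, contig: str, config: SimConfig, rng: np.random.Generator
) -> list[TruthRecord]:
    kb = len(seq) / 1000.0
    counts = {
        INTRA_CHANNEL: rng.poisson(config.intra_snp_rate * kb),
        INTRA_BLUE: rng.poisson(config.intra_snp_rate * kb),
        INTRA_BOTH: rng.poisson(config.intra_both_rate * kb),
        INTER_FIXED: rng.poisson(config.inter_fixed_diff_rate * kb),
        INDEL: rng.poisson(config.indel_rate * kb),
    }
    total = sum(counts.values())
    usable = np.arange(_EDGE_PAD, len(seq) - _EDGE_PAD)
    if total > len(usable):
        total = len(usable)
    positions = rng.choice(usable, size=total, replace=False)
    records: list[TruthRecord] = []
    i = 0
    for kind, n in counts.items():
        for _ in range(n):
            if i >= len(positions):
                break
            pos = int(positions[i])
            i += 1
            ref_code = int(seq[pos])
            ref = decode(np.array([ref_code], dtype=np.uint8))
            if kind == INDEL:
                if rng.random() < 0.5:  # deletion of 1-3 ref bases
                    dlen = int(rng.integers(1, 4))
                    dlen = min(dlen, len(seq) - _EDGE_PAD - pos)
                    ref_del = decode(seq[pos : pos + dlen])
                    rec = TruthRecord(contig, pos, INDEL, ref=ref_del, alt="")
                else:  # insertion of 1-3 bases after pos
                    ilen = int(rng.integers(1, 4))
                    ins = decode(rng.integers(0, 4, size=ilen).astype(np.uint8))
                    rec = TruthRecord(contig, pos, INDEL, ref="", alt=ins)
                f = _draw_maf(config, rng)
                if rng.random() < 0.5:
                    rec.freq_channel = f
                else:
                    rec.freq_blue = f
            else:
                # transition partner (A<->G, C<->T) with the configured
                # bias, otherwise one of the two transversions
                transition_partner = {0: 2, 1: 3, 2: 0, 3: 1}
                if rng.random() < config.transition_fraction:
                    alt_code = transition_partner[ref_code]
                else:
                    choices = [
                        b for b in range(4)
                        if b != ref_code and b != transition_partner[ref_code]
                    ]
                    alt_code = choices[int(rng.integers(0, 2))]
                alt = decode(np.array([alt_code], dtype=np.uint8))
                rec = TruthRecord(contig, pos, kind, ref=ref, alt=alt)
                if kind == INTRA_CHANNEL:
                    rec.freq_channel = _draw_maf(config, rng)
                elif kind == INTRA_BLUE:
                    rec.freq_blue = _draw_maf(config, rng)
                elif kind == INTRA_BOTH:
                    rec.freq_channel = _draw_maf(config, rng)
                    rec.freq_blue = _draw_maf(config, rng)
                else:  # fixed difference: one species fixed for the alt
                    if rng.random() < 0.5:
                        rec.freq_channel = 1.0
                    else:
                        rec.freq_blue = 1.0
            records.append(rec)
    return records


def simulate_references(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Random transcript contigs plus the ledger of planted features.

    The reference always carries the "ref" allele of every planted variant;
    alternative alleles exist only in the simulated pools.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 1])
    width = len(str(max(config.n_contigs - 1, 1)))
    contigs: dict[str, str] = {}
    truth = SimTruth()
    lo, hi = config.contig_length_range
    for c in range(config.n_contigs):
        name = f"contig{c:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.integers(0, 4, size=length).astype(np.uint8)
        truth.records.extend(_plant_tracts(seq, name, config, rng))
        truth.records.extend(_plant_variants(seq, name, config, rng))
        contigs[name] = decode(seq)
    truth.records.sort(key=lambda r: (r.contig, r.pos0))
    truth.validate(contigs)
    return contigs, truth


# ---------------------------------------------------------------------------
# pool simulation


def _haplotypes_for_contig(
    ref: str,
    variants: list[TruthRecord],
    species: str,
    n_hap: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Draw n_hap haplotypes, recording realized alt counts into the truth."""
    freq_attr = "freq_channel" if species == CHANNEL else "freq_blue"
    realized_attr = "realized_" + freq_attr
    carriers: list[tuple[TruthRecord, np.ndarray]] = []
    for rec in variants:
        f = getattr(rec, freq_attr)
        mask = (rng.random(n_hap) < f) if 0.0 < f < 1.0 else np.full(
            n_hap, bool(f)
        )
        setattr(rec, realized_attr, float(mask.sum()) / n_hap)
        carriers.append((rec, mask))
    ref_codes = encode(ref)
    haplotypes = []
    for h in range(n_hap):
        snps = [(r.pos0, r.alt) for r, m in carriers
                if m[h] and r.kind != INDEL]
        indels = [r for r, m in carriers if m[h] and r.kind == INDEL]
        if not indels:
            hap = ref_codes.copy()
            for pos, alt in snps:
                hap[pos] = encode(alt)[0]
            haplotypes.append(hap)
        else:
            hap = ref_codes.copy()
            for pos, alt in snps:
                hap[pos] = encode(alt)[0]
            pieces, cursor = [], 0
            for r in sorted(indels, key=lambda r: r.pos0):
                if r.pos0 < cursor:
                    continue  # swallowed by an overlapping upstream deletion
                if r.ref:  # deletion
                    pieces.append(hap[cursor : r.pos0])
                    cursor = r.pos0 + len(r.ref)
                else:  # insertion after pos0
                    pieces.append(hap[cursor : r.pos0 + 1])
                    pieces.append(encode(r.alt))
                    cursor = r.pos0 + 1
            pieces.append(hap[cursor:])
            haplotypes.append(np.concatenate(pieces))
    return haplotypes


def _emit_reads(
    haplotypes: list[np.ndarray],
    contig: str,
    species: str,
    config: SimConfig,
    rng: np.random.Generator,
    serial_start: int,
) -> list[tuple[str, str, str]]:
    rl = config.read_length
    length = len(haplotypes[0])
    n_units = int(round(config.coverage_target * length / rl))
    if config.paired:
        n_units = max(n_units // 2, 1)  # each fragment yields two mates
    mean_q = config.mean_quality(rl)
    prefix = NAME_PREFIX[species]
    reads = []
    hap_idx = rng.integers(0, len(haplotypes), size=n_units)
    strands = rng.random(n_units) < 0.5

    def finish(codes: np.ndarray, name: str, flip: bool):
        # orient the read first so qualities and errors live in read space
        codes = revcomp_codes(codes) if flip else codes.copy()
        quals = np.clip(
            np.rint(rng.normal(mean_q, config.quality_sd)), 2, 41
        ).astype(np.int16)
        if config.base_error_rate > 0:
            # phred scores are calibrated: errors fall on bases in proportion
            # to their nominal error probability 10^(-q/10), normalized so
            # the expected per-read error count is base_error_rate * length
            p = 10.0 ** (-quals / 10.0)
            p = np.minimum(p * (config.base_error_rate * rl / p.sum()), 1.0)
            err = rng.random(rl) < p
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                codes[err] = (codes[err] + shift) % 4
        seq = decode(codes)
        if config.adaptor_suffix and rng.random() < config.adaptor_fraction:
            a = config.adaptor_suffix
            alen = min(len(a), rl // 3)
            seq = seq[: rl - alen] + a[:alen]
        reads.append((name, seq, phred_to_string(quals)))

    for j in range(n_units):
        hap = haplotypes[hap_idx[j]]
        if len(hap) < rl:
            continue
        base = f"{prefix}|{contig}|{serial_start + j}"
        if not config.paired:
            start = int(rng.integers(0, len(hap) - rl + 1))
            finish(hap[start : start + rl], base, bool(strands[j]))
        else:
            flen = min(max(config.fragment_length, rl), len(hap))
            start = int(rng.integers(0, len(hap) - flen + 1))
            frag = hap[start : start + flen]
            # mate 1 forward from the fragment 5' end, mate 2 reverse from 3'
            finish(frag[:rl], base + "/1", bool(strands[j]))
            finish(frag[-rl:], base + "/2", not bool(strands[j]))
    return reads


def simulate_pools(
    contigs: dict[str, str], truth: SimTruth, config: SimConfig
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], SimTruth]:
    """Draw pooled reads for both species; updates truth in place.

    Returns (reads_channel, reads_blue, truth) where reads are
    (name, sequence, phred+33 quality) triples.
    """
    config.validate()
    truth.validate(contigs)
    rng = np.random.default_rng([config.rng_seed, 2])
    if config.coverage_target * min(map(len, contigs.values()), default=0) / max(
        config.read_length, 1
    ) < 1:
        warnings.warn("expected depth below 1x; pools will be mostly empty")
    by_contig: dict[str, list[TruthRecord]] = {}
    for rec in truth.of_kind(*SNP_KINDS, INDEL):
        by_contig.setdefault(rec.contig, []).append(rec)
    out = {CHANNEL: [], BLUE: []}
    for species, n_ind in zip(SPECIES, config.n_individuals_per_species):
        n_hap = 2 * n_ind
        serial = 0
        for name in contigs:
            haps = _haplotypes_for_contig(
                contigs[name], by_contig.get(name, []), species, n_hap, rng
            )
            reads = _emit_reads(haps, name, species, config, rng, serial)
            serial += len(reads)
            out[species].extend(reads)
    return out[CHANNEL], out[BLUE], truth


# ---------------------------------------------------------------------------
# plain-text writers/readers used by the CLI and tests


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for name, seq, qual in FastqGeneralIterator(fh):
            yield name.split()[0], seq.upper(), qual
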