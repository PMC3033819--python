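"""VCF 4.2 output for screened SNP calls (pysam-backed).

One record per putative substitution SNP; FILTER is PASS for calls that
survive quality screening, otherwise the semicolon-joined fail reasons.
Indel-allele detections are bookkeeping for the clean-flank rule and are
not written.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import pysam

from .calling import FILTERED_PASS, SnpCall

_INFO_LINES = [
    ('DP', '1', 'Integer', 'Qualified read depth at the site'),
    ('AD', 'R', 'Integer', 'Qualified read counts for REF and ALT alleles'),
    ('MAF', '1', 'Float', 'Minor allele frequency over qualified depth'),
    ('VC', '1', 'String', 'Variant class (transition/transversion/multiallelic)'),
    ('DPC', '1', 'Integer', 'Qualified depth, channel pool'),
    ('DPB', '1', 'Integer', 'Qualified depth, blue pool'),
    ('CAT', '1', 'String', 'Intra-/inter-specific category (1-6)'),
]
_FILTER_LINES = [
    ('low_maf', 'Minor allele below the minimum frequency'),
    ('dirty_flank', 'Another putative SNP or indel within the clean-flank window'),
    ('in_repeat', 'Site lies in a repetitive region'),
    ('not_biallelic', 'Not exactly two alleles observed'),
]


def write_vcf(
    calls: Iterable[SnpCall],
    contigs: dict[str, str],
    path: str,
    categories: Mapping[tuple[str, int], int | str] | None = None,
) -> int:
    """Write substitution calls as uncompressed VCF; returns records written."""
    header = pysam.VariantHeader()
    header.add_line('##source=poolsnp')
    for name in sorted(contigs):
        header.contigs.add(name, length=len(contigs[name]))
    for ident, number, typ, desc in _INFO_LINES:
        header.info.add(ident, number, typ, desc)
    for ident, desc in _FILTER_LINES:
        header.filters.add(ident, None, None, desc)
    n = 0
    with pysam.VariantFile(path, 'w', header=header) as out:
        for call in sorted(calls, key=lambda c: (c.contig, c.position)):
            if not call.is_snp:
                continue
            alts = sorted(
                (a for a, c in call.counts.items()
                 if c > 0 and a != call.ref and a != '-'),
                key=lambda a: (-call.counts[a], a),
            )
            if not alts:
                continue
            rec = out.new_record(
                contig=call.contig,
                start=call.position,
                stop=call.position + 1,
                alleles=tuple([call.ref] + alts),
            )
            rec.info['DP'] = call.depth
            rec.info['AD'] = tuple(
                [call.counts.get(call.ref, 0)] + [call.counts[a] for a in alts]
            )
            rec.info['MAF'] = round(call.maf, 6)
            rec.info['VC'] = call.substitution_class
            dpc, dpb = call.depth_per_species
            rec.info['DPC'] = dpc
            rec.info['DPB'] = dpb
            if categories is not None:
                cat = categories.get((call.contig, call.position))
                if cat is not None:
                    rec.info['CAT'] = str(cat)
            if call.status == FILTERED_PASS:
                rec.filter.add('PASS')
            elif call.fail_reasons:
                for reason in call.fail_reasons:
                    rec.filter.add(reason)
            out.write(rec)
            n += 1
    return n


def read_pass_positions(path: str) -> dict[str, set[int]]:
    """Contig -> 0-based PASS record positions from a VCF."""
    out: dict[str, set[int]] = {}
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if 'PASS' in rec.filter:
                out.setdefault(rec.contig, set()).add(rec.start)
    return out


def calls_to_tsv(calls: Iterable[SnpCall], path: str) -> None:
    """Flat TSV mirror of the VCF (one row per substitution call)."""
    with open(path, 'w') as fh:
        fh.write(
            'contig\tpos0\tref\tmajor\tminor\tdepth\tmaf\tclass\tstatus\t'
            'fail_reasons\tcounts\n'
        )
        for c in sorted(calls, key=lambda c: (c.contig, c.position)):
            if not c.is_snp:
                continue
            counts = ';'.join(
                f'{a}={n}' for a, n in sorted(c.counts.items()) if n
            )
            fh.write(
                f'{c.contig}\t{c.position}\t{c.ref}\t{c.major}\t{c.minor}\t'
                f'{c.depth}\t{c.maf:.4f}\t{c.substitution_class}\t{c.status}\t'
                f'{",".join(c.fail_reasons)}\t{counts}\n'
            )
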