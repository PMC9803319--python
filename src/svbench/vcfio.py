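"""Reading and writing SV callsets as VCF 4.2 (symbolic alleles) and BED.

Reading accepts symbolic ALTs (``<DEL>``, ``<DUP>``, ``<DUP:TANDEM>``,
``<INV>``) with END and/or SVLEN, or explicit REF/ALT sequences.  ``<DUP>`` and
``<DUP:TANDEM>`` both parse to DUP (duplications are treated as tandem
throughout).  Records of unsupported types (insertions, breakends,
translocations) are skipped with a logged message, as are records failing the
filter configuration; skip counts are logged per file.

Coordinates: VCF POS is 1-based inclusive and END 1-based inclusive, so a
symbolic DEL at POS=101, END=200 maps to the internal half-open interval
[100, 200) of size 100.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pysam

from .intervals import GenomicInterval
from .variants import SV_TYPES, FilterConfig, StructuralVariant, SvCallSet

__all__ = ["read_sv_vcf", "read_sv_bed", "write_sv_vcf", "write_sv_bed"]

logger = logging.getLogger(__name__)

_ALT_TYPE = {
    "<DEL>": "DEL",
    "<DUP>": "DUP",
    "<DUP:TANDEM>": "DUP",
    "<INV>": "INV",
}


def _info_get(rec: "pysam.VariantRecord", key: str):
    """INFO lookup tolerant of keys absent from the header declaration."""
    try:
        val = rec.info.get(key)
    except (KeyError, ValueError):
        return None
    if isinstance(val, tuple):
        val = val[0]
    return val


def _record_sv_type(rec: "pysam.VariantRecord") -> Optional[str]:
    svtype = _info_get(rec, "SVTYPE")
    if svtype:
        svtype = str(svtype)
        if svtype.startswith("DUP"):
            return "DUP"
        return svtype if svtype in SV_TYPES else None
    alt = rec.alts[0] if rec.alts else None
    if alt in _ALT_TYPE:
        return _ALT_TYPE[alt]
    if alt and not alt.startswith("<") and rec.ref and len(rec.ref) > len(alt):
        return "DEL"  # explicit-sequence deletion
    return None


def _record_end(rec: "pysam.VariantRecord", sv_type: str) -> Optional[int]:
    """0-based exclusive end, from END, SVLEN, or explicit REF length."""
    alt = rec.alts[0] if rec.alts else ""
    symbolic = alt.startswith("<")
    if not symbolic:
        return rec.start + len(rec.ref)
    svlen = _info_get(rec, "SVLEN")
    # htslib infers rlen from SVLEN for symbolic alleles (padding-base
    # convention: stop == start + |SVLEN| + 1) when INFO/END is absent; in
    # that case the event span is [start, start + |SVLEN|).
    if svlen is not None and rec.stop == rec.start + abs(int(svlen)) + 1:
        return rec.start + abs(int(svlen))
    # Without END or SVLEN, rec.stop degenerates to start + len(ref).
    if rec.stop != rec.start + len(rec.ref or "N"):
        return rec.stop
    if svlen is not None:
        return rec.start + abs(int(svlen))
    return None


def _filter_status(rec: "pysam.VariantRecord") -> Optional[str]:
    keys = list(rec.filter.keys())
    if not keys:
        return None  # FILTER == '.'
    return keys[0] if len(keys) == 1 else ";".join(keys)


def read_sv_vcf(
    path: str | Path,
    filter: FilterConfig | None = None,
    caller: str = "",
    sample: str = "",
) -> SvCallSet:
    """Read DEL/DUP/INV records from a VCF, applying the callset filters.

    Returns only records passing all filters; skipped records (wrong type,
    missing coordinates, failed filters) are counted and logged.
    """
    filter = filter or FilterConfig()
    path = str(path)
    variants: list[StructuralVariant] = []
    n_skipped_type = n_skipped_coord = n_filtered = 0
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            sv_type = _record_sv_type(rec)
            if sv_type is None:
                n_skipped_type += 1
                continue
            end = _record_end(rec, sv_type)
            if end is None or end <= rec.start:
                logger.warning(
                    "%s: record %s at %s:%d has no END or SVLEN; skipped",
                    path, rec.id, rec.chrom, rec.pos,
                )
                n_skipped_coord += 1
                continue
            support = _info_get(rec, "SUPPORT")
            v = StructuralVariant(
                interval=GenomicInterval(rec.chrom, rec.start, int(end)),
                sv_type=sv_type,
                id=rec.id or ".",
                qual=rec.qual,
                source=caller or sample,
                support=int(support) if support is not None else None,
            )
            if not filter.passes(v, _filter_status(rec)):
                n_filtered += 1
                continue
            variants.append(v)
    if n_skipped_type or n_skipped_coord or n_filtered:
        logger.info(
            "%s: kept %d variants (%d unsupported type, %d missing coords, %d filtered)",
            path, len(variants), n_skipped_type, n_skipped_coord, n_filtered,
        )
    return SvCallSet(variants=variants, caller=caller, sample=sample)


def _build_header(
    calls: Iterable[StructuralVariant],
    contig_lengths: Optional[Mapping[str, int]],
    extra_header_lines: Iterable[str] = (),
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=svbench-0.1.0")
    for line in extra_header_lines:
        header.add_line(line)
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">'
    )
    # SVLEN declared as String: htslib >= 1.20 re-derives the record length
    # (and hence the printed END) from an Integer SVLEN under the VCF 4.4
    # padding-base convention, which conflicts with the POS=first-affected-base
    # convention used here.  The printed value is still a plain integer.
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=String,Description="Length of the variant; negative for deletions">'
    )
    header.add_line(
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Read support">'
    )
    header.add_line(
        '##ALT=<ID=DEL,Description="Deletion">'
    )
    header.add_line('##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">')
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    if contig_lengths is None:
        contig_lengths = {}
        for v in calls:
            contig_lengths[v.chrom] = max(contig_lengths.get(v.chrom, 0), v.interval.end)
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    return header


_ALT_OF = {"DEL": "<DEL>", "DUP": "<DUP:TANDEM>", "INV": "<INV>"}


def write_sv_vcf(
    calls: SvCallSet,
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
    extra_header_lines: Iterable[str] = (),
) -> None:
    """Write a callset as VCF 4.2 with symbolic ALT alleles.

    SVLEN is negative for deletions, positive otherwise; END carries the
    1-based inclusive end.  ``read_sv_vcf(write_sv_vcf(x))`` round-trips
    coordinates, types, sizes, ids, quals and support exactly.
    """
    variants = sorted(
        calls.variants, key=lambda v: (v.chrom, v.interval.start, v.interval.end)
    )
    header = _build_header(variants, contig_lengths, extra_header_lines)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, v in enumerate(variants):
            svlen = -v.size if v.sv_type == "DEL" else v.size
            rec = vf.new_record(
                contig=v.chrom,
                start=v.interval.start,
                stop=v.interval.end,
                alleles=("N", _ALT_OF[v.sv_type]),
                id=v.id if v.id != "." else f"{v.sv_type}_{i}",
                qual=v.qual,
                filter="PASS",
            )
            rec.info["SVTYPE"] = v.sv_type
            rec.info["SVLEN"] = str(svlen)
            if v.support is not None:
                rec.info["SUPPORT"] = v.support
            vf.write(rec)


def write_sv_bed(calls: SvCallSet, path: str | Path) -> None:
    """Write a callset as BED6 (0-based half-open, SV type in the name column)."""
    variants = sorted(
        calls.variants, key=lambda v: (v.chrom, v.interval.start, v.interval.end)
    )
    with open(path, "w") as fh:
        for v in variants:
            score = int(v.qual) if v.qual is not None else 0
            name = f"{v.sv_type}:{v.id}"
            fh.write(
                f"{v.chrom}\t{v.interval.start}\t{v.interval.end}\t{name}\t{score}\t.\n"
            )


def read_sv_bed(
    path: str | Path, caller: str = "", sample: str = ""
) -> SvCallSet:
    """Read a BED file written by :func:`write_sv_bed` (name column ``TYPE:id``)."""
    variants = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{i + 1}: expected >=4 BED columns")
            chrom, start, end, name = fields[:4]
            sv_type, _, vid = name.partition(":")
            qual = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            variants.append(
                StructuralVariant(
                    interval=GenomicInterval(chrom, int(start), int(end)),
                    sv_type=sv_type,
                    id=vid or ".",
                    qual=qual,
                    source=caller or sample,
                )
            )
    return SvCallSet(variants=variants, caller=caller, sample=sample)
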