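"""File formats: allele-count TSV, VCF 4.2, sample sheets, score tables.

Internal coordinates are 1-based rCRS throughout; VCF is 1-based by
standard, BED masks (0-based half-open) are converted by the genome module.
VCF records carry DP/AD/AF plus strand-split alt depths (ADF/ADR) so calls
round-trip losslessly; multiallelic records are split on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam

from .calling import COUNT_COLUMNS, VariantCall, classify_zygosity
from .mtgenome import GENOME_LENGTH, MtLocusMap

VCF_CONTIG = "chrM"


class ParseError(ValueError):
    """Malformed input record (message carries file and line context)."""


def read_allele_counts(path) -> pd.DataFrame:
    """Read an allele-count TSV (position, ref, A_fwd ... T_rev)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"position", "ref", *COUNT_COLUMNS} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if len(df) and not df.position.between(1, GENOME_LENGTH).all():
        bad = df.index[~df.position.between(1, GENOME_LENGTH)][0]
        raise ParseError(f"{path}, line {bad + 2}: position out of range")
    return df


def write_allele_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample, individual, tissue, status[, age, sex]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "individual", "tissue", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad_tissue = set(df.tissue) - {"FC", "SNpc"}
    if bad_tissue:
        raise ParseError(f"{path}: unknown tissue labels {sorted(bad_tissue)}")
    bad_status = set(df.status) - {"case", "control"}
    if bad_status:
        raise ParseError(f"{path}: unknown status labels {sorted(bad_status)}")
    return df


def read_score_table(path) -> dict:
    """Pathogenicity score TSV (position, alt, score) -> lookup dict."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {(int(r.position), str(r.alt)): float(r.score)
            for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# VCF

def _vcf_header(sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(VCF_CONTIG, length=GENOME_LENGTH)
    header.filters.add("strand_bias", None, None,
                       "Significant strand bias with skewed alt support")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("ADF", "R", "Integer", "Forward-strand allelic depths")
    header.formats.add("ADR", "R", "Integer", "Reverse-strand allelic depths")
    header.formats.add("AF", "A", "Float", "Alt allele fraction")
    header.add_sample(sample_id)
    return header


def write_vcf(calls, path, sample_id: str) -> None:
    """Write one sample's calls as an uncompressed VCF 4.2 file."""
    header = _vcf_header(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.position, c.alt_allele)):
            rec = vcf.new_record(
                contig=VCF_CONTIG, start=c.position - 1,
                stop=c.position, alleles=(c.ref_allele, c.alt_allele))
            rec.filter.add("strand_bias" if "strand_bias" in c.filters
                           else "PASS")
            sample = rec.samples[sample_id]
            sample["DP"] = c.depth
            sample["AD"] = (c.depth - c.alt_reads, c.alt_reads)
            sample["ADF"] = (c.ref_fwd, c.alt_fwd)
            sample["ADR"] = (c.ref_rev, c.alt_rev)
            sample["AF"] = c.vaf
            vcf.write(rec)


def read_vcf(path, locus_map: MtLocusMap | None = None) -> list[VariantCall]:
    """Read a single-sample VCF into calls, splitting multiallelic records.

    AF falls back to AD/DP when absent; strand-split depths fall back to an
    even split when ADF/ADR are missing.
    """
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ParseError(f"{path}: expected a single-sample VCF, "
                             f"found {len(samples)} samples")
        for rec in vcf:
            if rec.pos < 1 or rec.pos > GENOME_LENGTH:
                raise ParseError(
                    f"{path}: position {rec.pos} outside the mtDNA reference")
            fmt = rec.samples[samples[0]]
            depth = fmt.get("DP")
            ad = fmt.get("AD")
            af = fmt.get("AF")
            adf, adr = fmt.get("ADF"), fmt.get("ADR")
            for ai, alt in enumerate(rec.alts or ()):
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # indels are out of scope
                alt_reads = ad[ai + 1] if ad is not None else None
                if depth is None:
                    if ad is None:
                        raise ParseError(
                            f"{path}: record m.{rec.pos} lacks both DP and AD")
                    depth = sum(x for x in ad if x is not None)
                vaf = (float(af[ai]) if af is not None
                       else alt_reads / depth)
                if alt_reads is None:
                    alt_reads = round(vaf * depth)
                alt_f = adf[ai + 1] if adf is not None else alt_reads // 2
                alt_r = (adr[ai + 1] if adr is not None
                         else alt_reads - alt_reads // 2)
                ref_reads = (ad[0] if ad is not None
                             else depth - alt_reads)
                ref_f = adf[0] if adf is not None else ref_reads // 2
                ref_r = (adr[0] if adr is not None
                         else ref_reads - ref_reads // 2)
                filters = tuple(f for f in rec.filter.keys() if f != "PASS")
                call = VariantCall(
                    position=rec.pos, ref_allele=rec.ref, alt_allele=alt,
                    vaf=vaf, depth=int(depth), alt_reads=int(alt_reads),
                    alt_fwd=int(alt_f), alt_rev=int(alt_r),
                    ref_fwd=int(ref_f), ref_rev=int(ref_r),
                    zygosity=classify_zygosity(vaf), filters=filters)
                if locus_map is not None:
                    call = call.annotated(locus_map)
                calls.append(call)
    return calls


def read_variants(path, fmt: str = "auto",
                  locus_map: MtLocusMap | None = None):
    """Dispatch reader: ``vcf`` -> calls, ``counts-tsv`` -> count table."""
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "counts-tsv"
    if fmt == "vcf":
        return read_vcf(path, locus_map)
    if fmt == "counts-tsv":
        return read_allele_counts(path)
    raise ValueError(f"unknown variant format {fmt!r}")


def write_json_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=float) + "\n")
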