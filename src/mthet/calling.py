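"""Threshold heteroplasmy calling on per-site allele counts.

Low-level mtDNA heteroplasmy is detectable from deep amplicon sequencing as a
minor allele fraction well below the germline 50%/100% regimes.  The caller
here is a deliberately simple threshold caller over strand-split per-base
read counts that have already passed base-quality (>=30) and mapping-quality
(>=20) filtering upstream: a non-reference base is called when

* total depth     >= ``min_depth``      (default 1500x),
* supporting reads >= ``min_alt_reads`` (default 10), and
* allele fraction >= ``min_vaf``        (default 1%).

Calls with a variant allele fraction (VAF) in [1%, 99%) are heteroplasmic;
>=99% homoplasmic.  A Fisher-exact strand-bias filter with an additional skew
guard removes alt alleles supported almost exclusively by one strand.

A ``concordance_hook`` is provided to intersect two independent call sets
(mirroring tandem-caller workflows); the package itself ships the one caller.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mtgenome import Annotation, MtLocusMap

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = tuple(f"{b}_{s}" for b in BASES for s in ("fwd", "rev"))

DEFAULT_MIN_DEPTH = 1500
DEFAULT_MIN_ALT_READS = 10
DEFAULT_MIN_VAF = 0.01
HOMOPLASMY_VAF = 0.99


class NoCoverageError(ValueError):
    """Zero-depth site: 'no data' is distinct from 'no variant'."""


@dataclass(frozen=True)
class AlleleCounts:
    """Strand-split read counts for one rCRS site.

    ``counts[b]`` is a (fwd, rev) pair per base; depth is their grand total.
    """

    position: int
    ref_allele: str
    counts: dict  # base -> (fwd, rev)

    @property
    def depth(self) -> int:
        return int(sum(sum(v) for v in self.counts.values()))

    def base_reads(self, base: str) -> int:
        f, r = self.counts[base]
        return int(f) + int(r)

    @classmethod
    def from_row(cls, row) -> "AlleleCounts":
        """Build from a mapping with position, ref and the 8 strand columns."""
        return cls(position=int(row["position"]), ref_allele=str(row["ref"]),
                   counts={b: (int(row[f"{b}_fwd"]), int(row[f"{b}_rev"]))
                           for b in BASES})


@dataclass(frozen=True)
class VariantCall:
    """One called substitution in one sample."""

    position: int
    ref_allele: str
    alt_allele: str
    vaf: float
    depth: int
    alt_reads: int
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    zygosity: str  # {"heteroplasmic", "homoplasmic"}
    annotation: Annotation | None = None
    filters: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.filters

    def annotated(self, locus_map: MtLocusMap) -> "VariantCall":
        return replace(self, annotation=locus_map.annotate(
            self.position, self.ref_allele, self.alt_allele))


def classify_zygosity(vaf: float, min_vaf: float = DEFAULT_MIN_VAF) -> str:
    """Heteroplasmic if VAF in [min_vaf, 0.99), homoplasmic if >= 0.99."""
    if vaf < min_vaf:
        raise ValueError(
            f"vaf {vaf} below calling threshold {min_vaf}: not a call")
    return "heteroplasmic" if vaf < HOMOPLASMY_VAF else "homoplasmic"


def call_site(counts: AlleleCounts,
              min_depth: int = DEFAULT_MIN_DEPTH,
              min_alt_reads: int = DEFAULT_MIN_ALT_READS,
              min_vaf: float = DEFAULT_MIN_VAF) -> list[VariantCall]:
    """Call every qualifying non-reference base at one site.

    Multiple alt alleles at one position are emitted as separate calls.
    Raises :class:`NoCoverageError` at zero depth so that absence of data is
    never silently reported as absence of variation.
    """
    depth = counts.depth
    if depth == 0:
        raise NoCoverageError(f"no coverage at m.{counts.position}")
    calls = []
    if depth < min_depth:
        return calls
    ref = counts.ref_allele
    ref_f, ref_r = counts.counts[ref]
    for base in BASES:
        if base == ref:
            continue
        alt_f, alt_r = counts.counts[base]
        alt_reads = int(alt_f) + int(alt_r)
        vaf = alt_reads / depth
        if alt_reads >= min_alt_reads and vaf >= min_vaf:
            calls.append(VariantCall(
                position=counts.position, ref_allele=ref, alt_allele=base,
                vaf=vaf, depth=depth, alt_reads=alt_reads,
                alt_fwd=int(alt_f), alt_rev=int(alt_r),
                ref_fwd=int(ref_f), ref_rev=int(ref_r),
                zygosity=classify_zygosity(vaf, min_vaf)))
    return calls


def strand_bias_pass(call: VariantCall, alpha: float = 0.05,
                     skew_limit: float = 0.90) -> bool:
    """Strand-bias filter on the ref/alt x fwd/rev table.

    Fails only when the two-sided Fisher exact test rejects at ``alpha`` AND
    the alt reads are more than ``skew_limit`` on one strand — significance
    alone is not enough, because at mtDNA depths tiny, harmless strand
    imbalances are highly significant.
    """
    if call.alt_reads == 0:
        raise ValueError("strand-bias filter requires a call with alt reads")
    table = [[call.ref_fwd, call.ref_rev], [call.alt_fwd, call.alt_rev]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    skew = max(call.alt_fwd, call.alt_rev) / call.alt_reads
    return not (p < alpha and skew > skew_limit)


def apply_strand_filter(calls, alpha: float = 0.05,
                        skew_limit: float = 0.90) -> list[VariantCall]:
    """Tag failing calls with the ``strand_bias`` filter flag."""
    out = []
    for c in calls:
        if strand_bias_pass(c, alpha=alpha, skew_limit=skew_limit):
            out.append(c)
        else:
            out.append(replace(c, filters=c.filters + ("strand_bias",)))
    return out


def call_sample(count_table: pd.DataFrame,
                locus_map: MtLocusMap | None = None,
                min_depth: int = DEFAULT_MIN_DEPTH,
                min_alt_reads: int = DEFAULT_MIN_ALT_READS,
                min_vaf: float = DEFAULT_MIN_VAF,
                strand_alpha: float = 0.05,
                strand_skew_limit: float = 0.90) -> list[VariantCall]:
    """Vectorised per-sample calling over an allele-count table.

    ``count_table`` columns: position, ref, A_fwd ... T_rev (one row per
    covered site).  Zero-depth rows are skipped (no-coverage is handled at
    the sample level by the coverage QC).  Returns strand-filtered,
    optionally annotated calls sorted by position.
    """
    mat = count_table[list(COUNT_COLUMNS)].to_numpy(dtype=np.int64)
    depth = mat.sum(axis=1)
    positions = count_table["position"].to_numpy()
    refs = count_table["ref"].to_numpy()
    per_base = mat.reshape(-1, 4, 2)  # site x base x strand
    base_reads = per_base.sum(axis=2)
    base_idx = {b: i for i, b in enumerate(BASES)}
    ref_idx = np.array([base_idx[r] for r in refs])
    ok_depth = depth >= min_depth
    calls: list[VariantCall] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf_all = base_reads / depth[:, None]
    for bi, base in enumerate(BASES):
        cand = np.nonzero(ok_depth & (ref_idx != bi)
                          & (base_reads[:, bi] >= min_alt_reads)
                          & (vaf_all[:, bi] >= min_vaf))[0]
        for i in cand:
            ri = ref_idx[i]
            calls.append(VariantCall(
                position=int(positions[i]), ref_allele=str(refs[i]),
                alt_allele=base, vaf=float(vaf_all[i, bi]),
                depth=int(depth[i]), alt_reads=int(base_reads[i, bi]),
                alt_fwd=int(per_base[i, bi, 0]), alt_rev=int(per_base[i, bi, 1]),
                ref_fwd=int(per_base[i, ri, 0]), ref_rev=int(per_base[i, ri, 1]),
                zygosity=classify_zygosity(float(vaf_all[i, bi]), min_vaf)))
    calls.sort(key=lambda c: (c.position, c.alt_allele))
    calls = apply_strand_filter(calls, strand_alpha, strand_skew_limit)
    if locus_map is not None:
        calls = [c.annotated(locus_map) for c in calls]
    return calls


def concordance_hook(primary, secondary) -> list[VariantCall]:
    """Intersect two call sets on (position, alt), keeping primary records.

    Stands in for tandem-caller concordance filtering without re-implementing
    a second caller's quality model.
    """
    keys = {(c.position, c.alt_allele) for c in secondary}
    return [c for c in primary if (c.position, c.alt_allele) in keys]
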