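import math

import pytest

from mthet.calling import VariantCall, classify_zygosity
from mthet.mtgenome import load_locus_map, _data_path
from mthet.sample_qc import read_marker_panel


@pytest.fixture(scope="session")
def locus_map():
    return load_locus_map()


@pytest.fixture(scope="session")
def marker_panel():
    return read_marker_panel(_data_path("haplogroup_panel.tsv"))


def make_call(position, ref, alt, vaf, depth=5000, annotation=None,
              alt_fwd=None, alt_rev=None):
    """Build a consistent VariantCall for tests without running the caller."""
    alt_reads = max(1, round(vaf * depth))
    vaf = alt_reads / depth
    if alt_fwd is None:
        alt_fwd = alt_reads // 2
    if alt_rev is None:
        alt_rev = alt_reads - alt_fwd
    ref_reads = depth - alt_reads
    return VariantCall(
        position=position, ref_allele=ref, alt_allele=alt, vaf=vaf,
        depth=depth, alt_reads=alt_reads, alt_fwd=alt_fwd, alt_rev=alt_rev,
        ref_fwd=ref_reads // 2, ref_rev=ref_reads - ref_reads // 2,
        zygosity=classify_zygosity(vaf), annotation=annotation)


def brute_fisher_p(table):
    """Independent Fisher oracle: raw log-factorial hypergeometric sum."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_hyper(k):
        return (_lchoose(r1, k) + _lchoose(r2, c1 - k) - _lchoose(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = log_hyper(a)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = log_hyper(k)
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def _lchoose(n, k):
    return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))
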