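"""Cohort-level variant summarisation and case/control burden statistics.

The mutational-burden analysis asks whether one group of samples (cases)
carries more qualifying variants than another (controls), overall and within
strata (per locus, or per region class: coding / tRNA / rRNA / D-loop).
Counts are per-sample burdens; group comparisons use the Mann-Whitney U rank
test with Bonferroni correction across the locus family, sparse
high-heteroplasmy contingency tables use Fisher's exact test, and variant
spectra are summarised by the transition/transversion (Ti/Tv) ratio and the
mean heteroplasmic allele fraction.

A variant falling in overlapping genes (MTATP8/MTATP6, MTND4L/MTND4)
contributes once to each gene's stratum, so locus-stratified counts may sum
to slightly more than the coding total; the per-gene tests are unaffected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mtgenome import MtLocusMap, substitution_class

#: Strata reported as region classes alongside per-gene strata.
REGION_CLASSES = ("coding", "tRNA", "rRNA", "DLOOP")

VARIANT_TYPES = ("all", "heteroplasmic", "homoplasmic",
                 "nonsynonymous-heteroplasmic")


class UndefinedStatisticError(ValueError):
    """The requested statistic has no defined value on this input."""


class DegenerateTableError(ValueError):
    """Contingency table has a zero margin."""


# ---------------------------------------------------------------------------
# elementary summaries

def unique_variants(calls, locus_map: MtLocusMap | None = None) -> set:
    """Distinct (position, alt) pairs across a cohort's calls.

    Low-complexity positions are excluded when a locus map is given.
    """
    out = set()
    for c in calls:
        if locus_map is not None and locus_map.in_low_complexity(c.position):
            continue
        out.add((c.position, c.alt_allele))
    return out


def titv_ratio(substitutions):
    """Ti/Tv ratio and transversion fraction of a variant collection.

    ``substitutions``: iterable of (ref, alt) pairs or objects with
    ``ref_allele``/``alt_allele``.  Returns ``(ratio, tv_fraction)``; with
    zero transversions the ratio is reported as ``math.inf`` (a distinct
    signal, not an error).
    """
    ti = tv = 0
    for s in substitutions:
        ref, alt = (s if isinstance(s, tuple)
                    else (s.ref_allele, s.alt_allele))
        if substitution_class(ref, alt) == "transition":
            ti += 1
        else:
            tv += 1
    total = ti + tv
    if total == 0:
        raise UndefinedStatisticError("no substitutions")
    if tv == 0:
        return math.inf, 0.0
    return ti / tv, tv / total


def _is_het(call) -> bool:
    return call.zygosity == "heteroplasmic"


def _matches_restriction(call, restriction: str) -> bool:
    if restriction == "all":
        return True
    if restriction == "heteroplasmic":
        return _is_het(call)
    if restriction == "homoplasmic":
        return call.zygosity == "homoplasmic"
    if restriction == "nonsynonymous-heteroplasmic":
        return (_is_het(call) and call.annotation is not None
                and call.annotation.consequence == "nonsynonymous")
    raise ValueError(f"unknown restriction {restriction!r}")


def mean_heteroplasmy(calls, restriction: str = "heteroplasmic") -> float:
    """Arithmetic mean VAF of qualifying heteroplasmic calls."""
    vafs = [c.vaf for c in calls if _matches_restriction(c, restriction)]
    if not vafs:
        raise UndefinedStatisticError(
            f"no calls qualify under restriction {restriction!r}")
    return float(np.mean(vafs))


# ---------------------------------------------------------------------------
# hypothesis tests

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by summation of hypergeometric outcomes whose probability does
    not exceed the observed table's.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a nonnegative 2x2 integer table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def pearson_chi2_2x2(table):
    """Uncorrected Pearson chi-squared statistic and 1-df p for a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin in contingency table")
    n = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    statistic = float(((arr - expected) ** 2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p*m)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p={p} outside [0, 1]")
    if m < 1:
        raise ValueError(f"family size m={m} must be >= 1")
    return min(1.0, p * m)


def _mann_whitney_u(x, y) -> float:
    """U statistic for x (midrank tie handling)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def mann_whitney(x, y, exact_limit: int = 8):
    """Mann-Whitney U test, two-sided, with midrank tie handling.

    For group sizes both <= ``exact_limit`` the p-value is exact: the rank
    vector is fixed and U is enumerated over all ways of assigning group
    labels, giving the permutation distribution even in the presence of ties
    (which the classical no-tie tables cannot handle).  Larger groups use the
    normal approximation with tie correction.  The two-sided exact p doubles
    the smaller tail, capped at 1 (the permutation distribution of U is
    symmetric about n1*n2/2, so this equals the symmetric-tail rule).

    Returns ``(U, p)`` with U the first group's statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    u_obs = _mann_whitney_u(x, y)
    n1, n2 = len(x), len(y)
    if n1 <= exact_limit and n2 <= exact_limit:
        ranks = stats.rankdata(np.concatenate([x, y]))
        offset = n1 * (n1 + 1) / 2
        u_values = np.array([sum(combo) - offset
                             for combo in itertools.combinations(ranks, n1)])
        eps = 1e-9
        lo = np.mean(u_values <= u_obs + eps)
        hi = np.mean(u_values >= u_obs - eps)
        p = min(1.0, 2 * min(lo, hi))
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic").pvalue)
    return u_obs, p


# ---------------------------------------------------------------------------
# pathogenicity surrogate

# Grantham (1974) amino-acid physicochemical distance, computed from the
# published composition/polarity/volume properties; 0 (identical) to 215
# (Leu-...max Cys-Trp region).  Used, rescaled to [0, 1], as the default
# nonsynonymous severity surrogate when no external score table is supplied.
_GRANTHAM_PROPS = {  # aa: (composition, polarity, volume)
    "S": (1.42, 9.2, 32), "R": (0.65, 10.5, 124), "L": (0.0, 4.9, 111),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61), "A": (0.0, 8.1, 31),
    "V": (0.0, 5.9, 84), "G": (0.74, 9.0, 3), "I": (0.0, 5.2, 111),
    "F": (0.0, 5.2, 132), "Y": (0.20, 6.2, 136), "C": (2.75, 5.5, 55),
    "H": (0.58, 10.4, 96), "Q": (0.89, 10.5, 85), "N": (1.33, 11.6, 56),
    "K": (0.33, 11.3, 119), "D": (1.38, 13.0, 54), "E": (0.92, 12.3, 83),
    "M": (0.0, 5.7, 105), "W": (0.13, 5.4, 170),
}
_GRANTHAM_SCALE = 50.723  # normalises the mean inter-residue distance to 100
_GRANTHAM_MAX = 215.0


def grantham_distance(aa1: str, aa2: str) -> float:
    """Grantham physicochemical distance between two amino acids."""
    c1, p1, v1 = _GRANTHAM_PROPS[aa1]
    c2, p2, v2 = _GRANTHAM_PROPS[aa2]
    return _GRANTHAM_SCALE * math.sqrt(
        1.833 * (c1 - c2) ** 2 + 0.1018 * (p1 - p2) ** 2
        + 0.000399 * (v1 - v2) ** 2)


def surrogate_pathogenicity(call) -> float:
    """Default severity surrogate in [0, 1].

    0 for synonymous/noncoding calls; rescaled Grantham distance of the
    amino-acid change for nonsynonymous calls; 1.0 for stop gain/loss.
    """
    ann = call.annotation
    if ann is None or ann.consequence != "nonsynonymous":
        return 0.0
    score = 0.0
    for e in ann.coding_effects:
        if e.ref_aa == e.alt_aa:
            continue
        if "*" in (e.ref_aa, e.alt_aa):
            score = max(score, 1.0)
        else:
            score = max(score, min(1.0, grantham_distance(e.ref_aa, e.alt_aa)
                                   / _GRANTHAM_MAX))
    return score


def score_call(call, score_table=None, on_missing: str = "surrogate") -> float | None:
    """Score one call from a (position, alt)->score table or the surrogate.

    ``on_missing``: "surrogate" (default), "skip" (return None) or a float
    default.
    """
    if score_table is not None:
        key = (call.position, call.alt_allele)
        if key in score_table:
            return float(score_table[key])
        if on_missing == "skip":
            return None
        if isinstance(on_missing, (int, float)):
            return float(on_missing)
    return surrogate_pathogenicity(call)


def pathogenicity_compare(calls_a, calls_b, score_table=None,
                          strata=("total",), on_missing="surrogate"):
    """Per-stratum pathogenicity score distributions and rank tests.

    Strata are "total" or canonical locus symbols.  Returns a tidy DataFrame
    with per-group means and Mann-Whitney two-sided p per stratum.
    """
    def scores_for(calls, stratum):
        vals = []
        for c in calls:
            if stratum != "total" and (
                    c.annotation is None or stratum not in c.annotation.loci):
                continue
            s = score_call(c, score_table, on_missing)
            if s is not None:
                vals.append(s)
        return vals

    rows = []
    for stratum in strata:
        a = scores_for(calls_a, stratum)
        b = scores_for(calls_b, stratum)
        if a and b:
            u, p = mann_whitney(a, b)
        else:
            u, p = math.nan, math.nan
        rows.append({"stratum": stratum, "n_a": len(a), "n_b": len(b),
                     "mean_a": float(np.mean(a)) if a else math.nan,
                     "mean_b": float(np.mean(b)) if b else math.nan,
                     "U": u, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort burden report

@dataclass
class BurdenReport:
    """Bundle of tidy tables produced by :func:`burden_report`."""

    burden: pd.DataFrame        # per sample x stratum x variant_type
    tests: pd.DataFrame         # case/control Mann-Whitney per stratum
    high_het: pd.DataFrame      # >10%-heteroplasmy Fisher tables per tissue
    spectrum: pd.DataFrame      # Ti/Tv and mean VAF per tissue


def _call_strata(call):
    strata = ["total"]
    if call.annotation is not None:
        strata += list(call.annotation.loci)
        rc = call.annotation.region_class
        if rc in REGION_CLASSES:
            strata.append(rc)
    return strata


def sample_burden(samples, locus_map: MtLocusMap) -> pd.DataFrame:
    """Per-sample stratified burden counts and mean VAF (tidy).

    Masked (low-complexity) positions and filter-failing calls are excluded.
    Every sample appears in every (stratum, variant_type) cell it could
    populate, with zero counts kept, so group tests see true zeros.
    """
    strata_seen: set[str] = {"total", *REGION_CLASSES}
    per_sample = []
    for s in samples:
        cells: dict[tuple[str, str], list[float]] = {}
        for c in s.calls:
            if not c.passed or locus_map.in_low_complexity(c.position):
                continue
            for vt in VARIANT_TYPES:
                if not _matches_restriction(c, vt):
                    continue
                for stratum in _call_strata(c):
                    cells.setdefault((stratum, vt), []).append(c.vaf)
                    strata_seen.add(stratum)
        per_sample.append((s, cells))
    rows = []
    for s, cells in per_sample:
        for stratum in sorted(strata_seen):
            for vt in VARIANT_TYPES:
                vafs = cells.get((stratum, vt), [])
                rows.append({
                    "sample": s.sample_id, "individual": s.individual,
                    "tissue": s.tissue, "status": s.status,
                    "stratum": stratum, "variant_type": vt,
                    "count": len(vafs),
                    "mean_vaf": float(np.mean(vafs)) if vafs else math.nan})
    return pd.DataFrame(rows)


def burden_report(samples, locus_map: MtLocusMap,
                  test_variant_type: str = "nonsynonymous-heteroplasmic",
                  high_het_cut: float = 0.10) -> BurdenReport:
    """The full case/control burden analysis for a QC-passed cohort.

    * per-tissue, per-stratum Mann-Whitney tests of per-sample burden
      (``test_variant_type``), Bonferroni-corrected across the locus family
      within each tissue;
    * per-tissue Fisher exact tests of the share of coding heteroplasmic
      variants above ``high_het_cut`` (strictly greater) in cases vs controls;
    * per-tissue Ti/Tv and mean heteroplasmic VAF summaries.
    """
    statuses = {s.status for s in samples}
    if not {"case", "control"} <= statuses:
        raise ValueError("need both case and control samples for the report")
    burden = sample_burden(samples, locus_map)
    tissues = sorted({s.tissue for s in samples})

    test_rows = []
    for tissue in tissues:
        sub = burden[(burden.tissue == tissue)
                     & (burden.variant_type == test_variant_type)]
        loci = sorted(st for st in sub.stratum.unique()
                      if st not in ("total", *REGION_CLASSES))
        family = max(len(loci), 1)
        for stratum in ["total", *REGION_CLASSES, *loci]:
            cell = sub[sub.stratum == stratum]
            cases = cell[cell.status == "case"]["count"].to_numpy()
            ctrls = cell[cell.status == "control"]["count"].to_numpy()
            computable = len(cases) >= 2 and len(ctrls) >= 2
            if computable:
                u, p = mann_whitney(cases, ctrls)
            else:
                u, p = math.nan, math.nan
            test_rows.append({
                "tissue": tissue, "stratum": stratum,
                "variant_type": test_variant_type,
                "n_case": len(cases), "n_control": len(ctrls),
                "mean_case": float(cases.mean()) if len(cases) else math.nan,
                "mean_control": float(ctrls.mean()) if len(ctrls) else math.nan,
                "U": u, "p": p,
                "p_adjusted": (bonferroni(p, family)
                               if stratum in loci and computable else
                               (p if computable else math.nan)),
                "computable": computable})
    tests = pd.DataFrame(test_rows)

    high_rows, spec_rows = [], []
    for tissue in tissues:
        per_status = {}
        for status in ("case", "control"):
            calls = [c for s in samples
                     if s.tissue == tissue and s.status == status
                     for c in s.calls
                     if c.passed and not locus_map.in_low_complexity(c.position)]
            het_coding = [c for c in calls if _is_het(c)
                          and c.annotation is not None
                          and c.annotation.region_class == "coding"]
            per_status[status] = het_coding
            all_het = [c for c in calls if _is_het(c)]
            ti_tv = tv_frac = math.nan
            subs = [(c.ref_allele, c.alt_allele) for c in calls]
            if subs:
                try:
                    ti_tv, tv_frac = titv_ratio(subs)
                except UndefinedStatisticError:
                    pass
            spec_rows.append({
                "tissue": tissue, "status": status, "n_calls": len(calls),
                "titv": ti_tv, "tv_fraction": tv_frac,
                "mean_het_vaf": (float(np.mean([c.vaf for c in all_het]))
                                 if all_het else math.nan),
                "mean_nonsyn_het_vaf": (float(np.mean(
                    [c.vaf for c in all_het
                     if c.annotation is not None
                     and c.annotation.consequence == "nonsynonymous"]))
                    if any(c.annotation is not None
                           and c.annotation.consequence == "nonsynonymous"
                           for c in all_het) else math.nan)})
        case_hi = sum(c.vaf > high_het_cut for c in per_status["case"])
        ctrl_hi = sum(c.vaf > high_het_cut for c in per_status["control"])
        table = [[case_hi, len(per_status["case"]) - case_hi],
                 [ctrl_hi, len(per_status["control"]) - ctrl_hi]]
        p = fisher_exact_2x2(table) if sum(map(sum, table)) else math.nan
        high_rows.append({
            "tissue": tissue, "case_high": case_hi,
            "case_total": len(per_status["case"]),
            "control_high": ctrl_hi,
            "control_total": len(per_status["control"]),
            "fisher_p": p})
    return BurdenReport(burden=burden, tests=tests,
                        high_het=pd.DataFrame(high_rows),
                        spectrum=pd.DataFrame(spec_rows))
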