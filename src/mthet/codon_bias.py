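"""Reference-set filter chain and codon-usage comparison.

To ask whether brain-tissue variants are unusual relative to population
mtDNA variation, the tissue cohorts are compared against a large collection
of public whole-mtDNA records.  The collection is cleaned by a sequential
record-level filter chain — pathogenic-variant carriers, non-human records,
non-European marker carriers (any of m.8701A, m.8540T, m.10873T by default),
truncated sequences (<16,500 bp), and finally records outside the major
European haplogroups — with a per-step removal ledger.  The surviving
records' coding variants are then tabulated as percentages of synonymous and
nonsynonymous changes by codon position (a 2x3 table per group summing to
100%), the codon-usage statistic compared between groups.

The module operates on flagged record tables, not raw GenBank downloads:
database retrieval, alignment and fine haplogrouping of tens of thousands of
records are upstream, out-of-scope steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Filter chain, in application order; each record is ledgered under the
#: first filter it fails.
FILTER_STEPS = ("pathogenic", "non_human", "non_european", "truncated",
                "minor_haplogroup")

#: Marker alleles whose presence flags a record as non-European.
NON_EUROPEAN_MARKERS = frozenset({(8701, "A"), (8540, "T"), (10873, "T")})

MAJOR_EUROPEAN_HAPLOGROUPS = frozenset(
    {"H", "V", "J", "T", "U", "K", "W", "X", "I", "R", "N"})

MIN_FULL_LENGTH = 16500


@dataclass(frozen=True)
class RefSeqRecord:
    """One reference-collection mtDNA record with its QC flags.

    ``variants``: (position, alt, consequence, codon_position) tuples for the
    record's coding variants (codon_position in {1,2,3}; consequence in
    {synonymous, nonsynonymous}); non-coding variants may carry
    codon_position 0 and are ignored by the usage table.
    """

    record_id: str
    length: int
    species: str = "Homo sapiens"
    carries_pathogenic: bool = False
    marker_alleles: frozenset = frozenset()
    haplogroup: str = "H"
    variants: tuple = ()


def filter_reference_chain(records,
                           major_haplogroups=MAJOR_EUROPEAN_HAPLOGROUPS,
                           non_european_rule: str = "any",
                           min_length: int = MIN_FULL_LENGTH):
    """Apply the sequential reference filters; return survivors and ledger.

    ``non_european_rule``: "any" (default) removes records carrying any of
    the three non-European marker alleles; "all" requires all three.
    ``major_haplogroups=None`` skips the final haplogroup filter (the
    chain's first four steps only).

    Returns ``(survivors, ledger)`` with ``ledger`` a dict mapping each
    filter step to its removal count (input = survivors + sum of removals).
    """
    if non_european_rule not in ("any", "all"):
        raise ValueError(f"unknown non_european_rule {non_european_rule!r}")
    ledger = dict.fromkeys(FILTER_STEPS, 0)
    survivors = []
    for rec in records:
        if rec.carries_pathogenic:
            ledger["pathogenic"] += 1
        elif rec.species != "Homo sapiens":
            ledger["non_human"] += 1
        elif (len(rec.marker_alleles & NON_EUROPEAN_MARKERS)
              >= (1 if non_european_rule == "any"
                  else len(NON_EUROPEAN_MARKERS))):
            ledger["non_european"] += 1
        elif rec.length < min_length:
            ledger["truncated"] += 1
        elif (major_haplogroups is not None
              and rec.haplogroup not in major_haplogroups):
            ledger["minor_haplogroup"] += 1
        else:
            survivors.append(rec)
    return survivors, ledger


def codon_usage_table(variant_sets: dict) -> dict[str, pd.DataFrame]:
    """Per-group codon-usage tables.

    ``variant_sets`` maps group label -> iterable of
    (position, alt, consequence, codon_position) tuples (or objects exposing
    ``annotation`` with coding effects).  Each group yields a 2x3 DataFrame
    (rows synonymous/nonsynonymous, columns codon positions 1-3) of
    percentages of that group's coding variants, summing to 100.

    Raises :class:`ValueError` for a group with zero coding variants.
    """
    out = {}
    for group, variants in variant_sets.items():
        counts = pd.DataFrame(
            0.0, index=["synonymous", "nonsynonymous"], columns=[1, 2, 3])
        total = 0
        for v in variants:
            if hasattr(v, "annotation"):
                ann = v.annotation
                if ann is None or not ann.coding_effects:
                    continue
                effect = ann.coding_effects[0]
                consequence = ann.consequence
                codon_position = effect.codon_position
            else:
                _, _, consequence, codon_position = v
            if consequence not in ("synonymous", "nonsynonymous") \
                    or codon_position not in (1, 2, 3):
                continue
            counts.loc[consequence, codon_position] += 1
            total += 1
        if total == 0:
            raise ValueError(f"group {group!r} has no coding variants: "
                             "codon-usage table undefined")
        out[group] = counts / total * 100.0
    return out
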