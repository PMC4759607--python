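"""Coverage QC, marker-panel haplogroup assignment, and cohort bookkeeping.

Paired-tissue somatic analysis is only meaningful when (i) both tissues are
sequenced deeply across essentially the whole molecule, and (ii) both tissues
carry the same germline mtDNA backbone — a haplogroup mismatch between two
tissues of one individual indicates a sample swap or contamination, not
biology.  This module removes samples whose coverage fraction at the minimum
depth is too low, assigns macro-haplogroups from a small bundled marker panel
(sufficient for concordance checking; fine-clade phylogenetics is out of
scope), and writes an exclusion ledger so every removed pair is accounted
for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import VariantCall
from .mtgenome import GENOME_LENGTH

DEFAULT_MIN_DEPTH = 1500
DEFAULT_MIN_FRACTION = 0.99

#: QC exclusion reasons, in the order they are applied (a pair failing both
#: is ledgered once, under the first).
REASON_DISCORDANT = "haplogroup_discordant"
REASON_COVERAGE = "coverage_fail"


@dataclass
class Sample:
    """One sequenced tissue sample and its post-calling variant set."""

    sample_id: str
    individual: str
    tissue: str  # {"FC", "SNpc"}
    status: str  # {"case", "control"}
    calls: list[VariantCall] = field(default_factory=list)
    age: float | None = None
    sex: str | None = None


@dataclass
class SamplePair:
    """One individual's FC and SNpc samples: the unit of somatic analysis."""

    individual: str
    status: str
    fc: Sample
    snpc: Sample
    fc_haplogroup: str | None = None
    snpc_haplogroup: str | None = None
    qc_flags: tuple[str, ...] = ()


def coverage_pass(profile, min_depth: int = DEFAULT_MIN_DEPTH,
                  min_fraction: float = DEFAULT_MIN_FRACTION) -> bool:
    """True iff >= ``min_fraction`` of positions have depth >= ``min_depth``.

    ``profile`` is the per-position depth over all 16,569 rCRS positions.
    """
    depths = np.asarray(profile)
    if depths.size == 0:
        raise ValueError("empty coverage profile")
    if depths.size != GENOME_LENGTH:
        raise ValueError(
            f"profile covers {depths.size} positions, expected {GENOME_LENGTH}")
    return float((depths >= min_depth).mean()) >= min_fraction


# ---------------------------------------------------------------------------
# haplogroup assignment

def read_marker_panel(path) -> dict[str, frozenset]:
    """Read a marker panel TSV (haplogroup, position, alt) into label->markers.

    The root label (matching the reference backbone; H for rCRS-like panels)
    appears with an empty marker set.
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    panel: dict[str, set] = {}
    for r in tab.itertuples(index=False):
        panel.setdefault(str(r.haplogroup), set())
        if not pd.isna(r.position):
            panel[str(r.haplogroup)].add((int(r.position), str(r.alt)))
    return {k: frozenset(v) for k, v in panel.items()}


def assign_haplogroup(calls, marker_panel: dict[str, frozenset],
                      root_label: str | None = None) -> str:
    """Best-matching panel haplogroup for a sample's homoplasmic backbone.

    Scores each panel haplogroup by the fraction of its defining variants
    present among the sample's homoplasmic calls; ties broken by the larger
    defining set (most derived), then lexicographically.  With no marker
    matched at all the root label is returned (reference-like backbone).
    Heteroplasmic calls never influence the assignment.
    """
    if not marker_panel:
        raise ValueError("empty marker panel")
    if root_label is None:
        roots = [k for k, v in marker_panel.items() if not v]
        root_label = min(roots) if roots else min(marker_panel)
    present = {(c.position, c.alt_allele) for c in calls
               if c.zygosity == "homoplasmic"}
    best = None
    for label, markers in marker_panel.items():
        if not markers:
            continue
        hits = len(markers & present)
        if hits == 0:
            continue
        key = (hits / len(markers), len(markers), [-ord(ch) for ch in label])
        if best is None or key > best[0]:
            best = (key, label)
    return root_label if best is None else best[1]


def pair_concordant(pair: SamplePair) -> bool:
    """True iff the two tissues' haplogroup labels are identical."""
    if pair.fc_haplogroup is None or pair.snpc_haplogroup is None:
        raise ValueError(f"pair {pair.individual}: haplogroups not assigned")
    return pair.fc_haplogroup == pair.snpc_haplogroup


def assign_pair_haplogroups(pair: SamplePair,
                            marker_panel: dict[str, frozenset]) -> SamplePair:
    pair.fc_haplogroup = assign_haplogroup(pair.fc.calls, marker_panel)
    pair.snpc_haplogroup = assign_haplogroup(pair.snpc.calls, marker_panel)
    return pair


# ---------------------------------------------------------------------------
# cohort QC

def apply_cohort_qc(pairs, coverage_fail=None,
                    marker_panel: dict[str, frozenset] | None = None):
    """Sequential cohort QC: haplogroup concordance, then coverage.

    ``coverage_fail`` is either a set of individual ids that failed
    coverage-based QC, or a mapping sample_id -> per-position depth profile
    (both tissues must then pass :func:`coverage_pass`).  If ``marker_panel``
    is given, haplogroups are (re)assigned before the concordance check.

    Returns ``(retained_pairs, ledger)`` where the ledger is a DataFrame
    (individual, status, reason) with one row per excluded pair; a pair
    failing both checks is ledgered once, under discordance.
    """
    ledger_rows = []
    retained = []
    coverage_fail = coverage_fail or set()
    for pair in pairs:
        if marker_panel is not None:
            assign_pair_haplogroups(pair, marker_panel)
        if not pair_concordant(pair):
            pair.qc_flags += (REASON_DISCORDANT,)
            ledger_rows.append({"individual": pair.individual,
                                "status": pair.status,
                                "reason": REASON_DISCORDANT})
            continue
        if isinstance(coverage_fail, (set, frozenset)):
            cov_ok = pair.individual not in coverage_fail
        else:
            cov_ok = (coverage_pass(coverage_fail[pair.fc.sample_id])
                      and coverage_pass(coverage_fail[pair.snpc.sample_id]))
        if not cov_ok:
            pair.qc_flags += (REASON_COVERAGE,)
            ledger_rows.append({"individual": pair.individual,
                                "status": pair.status,
                                "reason": REASON_COVERAGE})
            continue
        retained.append(pair)
    ledger = pd.DataFrame(ledger_rows,
                          columns=["individual", "status", "reason"])
    return retained, ledger


def cohort_counts(pairs) -> dict[str, int]:
    """Retained-pair counts by status plus the total."""
    out = {"case": 0, "control": 0}
    for p in pairs:
        out[p.status] = out.get(p.status, 0) + 1
    out["total"] = sum(v for k, v in out.items() if k != "total")
    return out
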