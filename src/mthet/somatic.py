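"""Four-class somatic variant taxonomy for paired FC -> SNpc tissue.

Treating the frontal cortex (FC) as each individual's ancestral mtDNA state
and the substantia nigra pars compacta (SNpc) as the vulnerable tissue, every
variant observed in at least one tissue of a pair falls into exactly one of:

* ``de_novo``         — called in SNpc but not FC (somatic gain);
* ``loss``            — called in FC but not SNpc (somatic loss);
* ``positive_shift``  — called in both, heteroplasmy higher in SNpc;
* ``negative_shift``  — called in both, heteroplasmy lower in SNpc;
* ``unchanged``       — called in both, |delta| below the shift band.

"Called" means passing the calling module's thresholds (VAF >= 1% with
depth/support): a variant at 0.9% in FC and 1.2% in SNpc is a de-novo gain,
not a shift, because the classes are defined on presence/absence of calls.
Homoplasmic-in-both variants (the germline backbone) are excluded from the
shift classes — fixed alleles have no room to shift.  The minimum shift
delta (default 1 VAF percentage point) suppresses binomial sampling noise at
typical amplicon depths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import mann_whitney, pearson_chi2_2x2, bonferroni
from .mtgenome import Annotation, MtLocusMap
from .sample_qc import SamplePair

SOMATIC_CLASSES = ("de_novo", "loss", "positive_shift", "negative_shift")
DEFAULT_MIN_SHIFT_DELTA = 0.01


@dataclass(frozen=True)
class SomaticEvent:
    """One FC -> SNpc differential variant in one individual."""

    individual: str
    status: str
    position: int
    ref: str
    alt: str
    somatic_class: str  # SOMATIC_CLASSES or "unchanged"
    het_fc: float  # VAF in FC, 0.0 if absent
    het_snpc: float  # VAF in SNpc, 0.0 if absent
    annotation: Annotation | None = None

    @property
    def delta(self) -> float:
        return self.het_snpc - self.het_fc


def classify_somatic(pair: SamplePair,
                     min_shift_delta: float = DEFAULT_MIN_SHIFT_DELTA,
                     include_unchanged: bool = False) -> list[SomaticEvent]:
    """Classify every differential variant of one QC-passed pair.

    Calls are matched across tissues on (position, alt); filter-failing
    calls are ignored.  Raises on a reference-allele mismatch between the
    tissues at a shared site (upstream data inconsistency).
    """
    fc = {(c.position, c.alt_allele): c for c in pair.fc.calls if c.passed}
    sn = {(c.position, c.alt_allele): c for c in pair.snpc.calls if c.passed}
    for key in fc.keys() & sn.keys():
        if fc[key].ref_allele != sn[key].ref_allele:
            raise ValueError(
                f"{pair.individual} m.{key[0]}: ref alleles disagree between "
                f"tissues ({fc[key].ref_allele} vs {sn[key].ref_allele})")
    events = []
    for key in sorted(fc.keys() | sn.keys()):
        f, s = fc.get(key), sn.get(key)
        ref = (f or s).ref_allele
        annotation = (s or f).annotation
        het_fc = f.vaf if f is not None else 0.0
        het_snpc = s.vaf if s is not None else 0.0
        if f is None:
            cls = "de_novo"
        elif s is None:
            cls = "loss"
        elif f.zygosity == "homoplasmic" and s.zygosity == "homoplasmic":
            cls = "unchanged"  # fixed backbone allele: no room to shift
        else:
            delta = het_snpc - het_fc
            if abs(delta) < min_shift_delta:
                cls = "unchanged"
            else:
                cls = "positive_shift" if delta > 0 else "negative_shift"
        if cls == "unchanged" and not include_unchanged:
            continue
        events.append(SomaticEvent(
            individual=pair.individual, status=pair.status,
            position=key[0], ref=ref, alt=key[1], somatic_class=cls,
            het_fc=het_fc, het_snpc=het_snpc, annotation=annotation))
    return events


def events_frame(events) -> pd.DataFrame:
    """Tidy per-event table (one row per differential variant)."""
    rows = []
    for e in events:
        ann = e.annotation
        rows.append({
            "individual": e.individual, "status": e.status,
            "position": e.position, "ref": e.ref, "alt": e.alt,
            "class": e.somatic_class, "het_fc": e.het_fc,
            "het_snpc": e.het_snpc, "delta": e.delta,
            "loci": ";".join(ann.loci) if ann else "",
            "consequence": ann.consequence if ann else "",
            "region_class": ann.region_class if ann else ""})
    return pd.DataFrame(rows, columns=[
        "individual", "status", "position", "ref", "alt", "class",
        "het_fc", "het_snpc", "delta", "loci", "consequence", "region_class"])


def somatic_summary(events, pairs=None) -> dict:
    """Cohort summary: class totals, per-sample class burden, breakdowns.

    ``pairs`` (optional) supplies the full cohort so individuals with zero
    events of a class still appear with zero burden — required for honest
    rank tests.
    """
    df = events_frame(e for e in events if e.somatic_class != "unchanged")
    individuals = ({p.individual: p.status for p in pairs} if pairs is not None
                   else dict(zip(df.individual, df.status, strict=True)))
    totals = {cls: int((df["class"] == cls).sum()) for cls in SOMATIC_CLASSES}
    per_sample = []
    for ind, status in individuals.items():
        sub = df[df.individual == ind]
        row = {"individual": ind, "status": status}
        for cls in SOMATIC_CLASSES:
            row[cls] = int((sub["class"] == cls).sum())
        row["total"] = int(len(sub))
        per_sample.append(row)
    per_sample = pd.DataFrame(per_sample, columns=[
        "individual", "status", *SOMATIC_CLASSES, "total"])
    by_type = (df.groupby(["class", "status", "region_class", "consequence"])
               .size().rename("n").reset_index()
               if len(df) else pd.DataFrame(
                   columns=["class", "status", "region_class", "consequence", "n"]))
    df_loc = df.assign(locus=df.loci.str.split(";")).explode("locus")
    df_loc = df_loc[df_loc.locus != ""]
    by_locus = (df_loc.groupby(["class", "status", "locus"])
                .size().rename("n").reset_index()
                if len(df_loc) else pd.DataFrame(
                    columns=["class", "status", "locus", "n"]))
    return {"totals": totals, "n_events": int(len(df)),
            "per_sample": per_sample, "by_type": by_type,
            "by_locus": by_locus, "events": df}


def compare_class_rates(summary, loci=None) -> dict:
    """Case/control tests on the somatic classes.

    Per class: two-sided Mann-Whitney on per-sample event counts (direction
    reported as the sign of the case-minus-control mean difference).  Per
    locus: Pearson chi-squared on the case/control split of nonsynonymous
    de-novo events vs all other loci, Bonferroni-corrected across loci.
    """
    per_sample = summary["per_sample"]
    statuses = set(per_sample.status)
    if not {"case", "control"} <= statuses:
        raise ValueError("need both case and control individuals")
    class_rows = []
    for cls in SOMATIC_CLASSES:
        cases = per_sample[per_sample.status == "case"][cls].to_numpy()
        ctrls = per_sample[per_sample.status == "control"][cls].to_numpy()
        u, p = mann_whitney(cases, ctrls)
        diff = float(cases.mean() - ctrls.mean())
        class_rows.append({
            "class": cls, "mean_case": float(cases.mean()),
            "mean_control": float(ctrls.mean()),
            "direction": ("case_elevated" if diff > 0 else
                          "control_elevated" if diff < 0 else "none"),
            "U": u, "p": p})
    class_tests = pd.DataFrame(class_rows)

    ev = summary["events"]
    nonsyn = ev[(ev.consequence == "nonsynonymous")
                & (ev["class"] == "de_novo")]
    nonsyn = nonsyn.assign(locus=nonsyn.loci.str.split(";")).explode("locus")
    locus_rows = []
    loci = sorted(loci) if loci is not None else sorted(nonsyn.locus.unique())
    family = max(len(loci), 1)
    for locus in loci:
        a = int(((nonsyn.locus == locus) & (nonsyn.status == "case")).sum())
        b = int(((nonsyn.locus != locus) & (nonsyn.status == "case")).sum())
        c = int(((nonsyn.locus == locus) & (nonsyn.status == "control")).sum())
        d = int(((nonsyn.locus != locus) & (nonsyn.status == "control")).sum())
        try:
            stat, p = pearson_chi2_2x2([[a, b], [c, d]])
            p_adj = bonferroni(p, family)
        except ValueError:
            stat, p, p_adj = math.nan, math.nan, math.nan
        locus_rows.append({"locus": locus, "case_in": a, "case_out": b,
                           "control_in": c, "control_out": d,
                           "chi2": stat, "p": p, "p_adjusted": p_adj})
    return {"class_tests": class_tests,
            "locus_tests": pd.DataFrame(locus_rows)}
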