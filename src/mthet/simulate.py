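"""Generative model for paired-tissue mtDNA cohorts, plus bookkeeping fixtures.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised and power-checked without tissue data:

* each individual draws a germline backbone — a macro-haplogroup from
  European-like frequencies (its panel markers become homoplasmic calls in
  both tissues) plus private homoplasmies;
* FC heteroplasmic variants arrive as Poisson counts with Beta-distributed
  allele fractions concentrated below 10%; case samples place extra
  nonsynonymous-prone variants in the complex-III/IV genes (MTCO1, MTCO2,
  MTCYB) via locus weight multipliers;
* SNpc inherits each FC heteroplasmy with a retention probability (failures
  are somatic losses), retained variants may shift their heteroplasmy, and
  SNpc gains de-novo variants at a per-status Poisson rate — the four-class
  somatic truth is recorded at generation time;
* read evidence is drawn per site: negative-binomial depth (floored),
  binomial alt reads at the true allele fraction, uniform per-base
  sequencing error, binomial 50:50 strand split.

True heteroplasmies are drawn with guard margins away from the calling and
shift-classification boundaries (VAF >= 3%, shift deltas either exactly 0 or
>= 5 VAF points), so at zero sequencing error the caller and a classifier
whose shift band lies between those margins recover the recorded truth;
real data respects no such margins, and passing recovery tests therefore
validates the machinery, not boundary behaviour.

``make_bookkeeping_fixture`` builds the two deterministic accounting
fixtures (paired-cohort QC composition; reference filter-chain composition)
whose category flags are disjoint by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import BASES, COUNT_COLUMNS
from .codon_bias import MAJOR_EUROPEAN_HAPLOGROUPS, NON_EUROPEAN_MARKERS, RefSeqRecord
from .mtgenome import GENOME_LENGTH, MtLocusMap, load_locus_map
from .sample_qc import Sample, SamplePair, read_marker_panel

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"),
                  "C": ("A", "G"), "T": ("A", "G")}

#: European-like macro-haplogroup frequencies for germline sampling.
DEFAULT_HAPLOGROUP_FREQS = {
    "H": 0.42, "U": 0.12, "J": 0.09, "T": 0.09, "K": 0.08,
    "V": 0.05, "W": 0.04, "X": 0.04, "I": 0.07,
}


@dataclass
class SimParams:
    """Full generative parameterisation of a synthetic paired cohort.

    Defaults reproduce the study conditions the analysis targets: 97 case and
    23 control pairs, ~5000x mean depth floored at 1500x, low-level
    heteroplasmy (Beta(1.3, 30) truncated to [0.03, 0.90]; ~85% of draws
    below 10%), case-elevated heteroplasmic burden and de-novo gain rate,
    and a mildly transversion-rich mutational spectrum (Ti:Tv draw odds 9:1).
    """

    n_case_pairs: int = 97
    n_control_pairs: int = 23
    # read-depth model
    depth_mean: float = 5000.0
    depth_dispersion: float = 8.0
    depth_floor: int = 1500
    # germline model
    haplogroup_freqs: dict = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_FREQS))
    private_homoplasmy_rate: float = 8.0
    homoplasmy_vaf: float = 0.999
    # heteroplasmy model (FC tissue)
    het_rate_fc: dict = field(
        default_factory=lambda: {"case": 7.0, "control": 5.0})
    vaf_beta: tuple = (1.3, 30.0)
    vaf_floor: float = 0.03
    vaf_ceil: float = 0.90
    case_locus_boost: dict = field(
        default_factory=lambda: {"MTCO1": 3.0, "MTCO2": 3.0, "MTCYB": 3.0})
    transition_prob: float = 0.90
    # somatic dynamics (FC -> SNpc)
    retention_prob: float = 0.75
    unchanged_prob: float = 0.40  # retained variant keeps its heteroplasmy
    shift_gap: float = 0.05      # minimum |delta| of a true shift
    shift_scale: float = 0.05    # exponential scale of |delta| above the gap
    positive_shift_prob: float = 0.28
    de_novo_rate: dict = field(
        default_factory=lambda: {"case": 6.0, "control": 3.0})
    # error and QC structure
    error_rate: float = 1e-3
    discordant_prob: float = 0.0
    coverage_fail_prob: float = 0.0
    seed: int = 0

    def validate(self) -> "SimParams":
        if not 0 <= self.error_rate < 1:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 1)")
        if min(self.vaf_beta) <= 0:
            raise ValueError("Beta parameters must be positive")
        for name in ("retention_prob", "unchanged_prob",
                     "positive_shift_prob", "transition_prob",
                     "discordant_prob", "coverage_fail_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        rates = [self.private_homoplasmy_rate, *self.het_rate_fc.values(),
                 *self.de_novo_rate.values()]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be nonnegative")
        if not 0 < self.vaf_floor < self.vaf_ceil <= 1:
            raise ValueError("need 0 < vaf_floor < vaf_ceil <= 1")
        return self


class SimulatedCohort:
    """A generated cohort: sample sheet, truth tables, lazy read evidence.

    Allele-count tables are regenerated deterministically per sample from
    stored child seeds, so the cohort object stays small while "same params,
    same seed" always yields byte-identical outputs.
    """

    def __init__(self, params, locus_map, sample_sheet, truth_variants,
                 truth_events, haplogroups, coverage_fail_individuals,
                 sample_seeds):
        self.params = params
        self.locus_map = locus_map
        self.sample_sheet = sample_sheet
        self.truth_variants = truth_variants
        self.truth_events = truth_events
        self.haplogroups = haplogroups  # individual -> (fc_hg, snpc_hg)
        self.coverage_fail_individuals = coverage_fail_individuals
        self._sample_seeds = sample_seeds

    @property
    def sample_ids(self):
        return list(self.sample_sheet["sample"])

    def depth_profile(self, sample_id: str) -> np.ndarray:
        return self._depths(sample_id)

    def _depths(self, sample_id: str) -> np.ndarray:
        p = self.params
        rng = np.random.default_rng(self._sample_seeds[sample_id])
        r = p.depth_dispersion
        depths = rng.negative_binomial(
            r, r / (r + p.depth_mean), size=GENOME_LENGTH)
        depths = np.maximum(depths, p.depth_floor)
        row = self.sample_sheet[self.sample_sheet["sample"] == sample_id]
        if row.iloc[0]["individual"] in self.coverage_fail_individuals:
            # knock ~2% of positions below the depth floor
            n_low = int(0.02 * GENOME_LENGTH)
            low = rng.choice(GENOME_LENGTH, size=n_low, replace=False)
            depths[low] = rng.integers(10, p.depth_floor // 2, size=n_low)
        return depths

    def allele_counts(self, sample_id: str) -> pd.DataFrame:
        """Strand-split per-site allele counts for one sample (16,569 rows)."""
        p = self.params
        depths = self._depths(sample_id)
        # a second, offset stream so depth and read draws stay independent
        rng = np.random.default_rng(self._sample_seeds[sample_id] + 1)
        seq = np.frombuffer(self.locus_map.sequence.encode(), dtype="S1")
        ref_idx = np.searchsorted(np.array([b"A", b"C", b"G", b"T"]), seq)
        counts = np.zeros((GENOME_LENGTH, 4), dtype=np.int64)
        if p.error_rate > 0:
            counts = rng.binomial(depths[:, None], p.error_rate / 3,
                                  size=(GENOME_LENGTH, 4))
            counts[np.arange(GENOME_LENGTH), ref_idx] = 0
        truth = self.truth_variants
        mine = truth[truth["sample"] == sample_id]
        base_col = {b: i for i, b in enumerate(BASES)}
        for r in mine.itertuples(index=False):
            i = r.position - 1
            p_eff = r.true_vaf * (1 - p.error_rate) \
                + (1 - r.true_vaf) * p.error_rate / 3
            counts[i, base_col[r.alt]] += rng.binomial(depths[i], p_eff)
        nonref = counts.sum(axis=1)
        ref_counts = np.maximum(depths - nonref, 0)
        counts[np.arange(GENOME_LENGTH), ref_idx] = ref_counts
        fwd = rng.binomial(counts, 0.5)
        rev = counts - fwd
        data = {"position": np.arange(1, GENOME_LENGTH + 1),
                "ref": list(self.locus_map.sequence)}
        for bi, b in enumerate(BASES):
            data[f"{b}_fwd"] = fwd[:, bi]
            data[f"{b}_rev"] = rev[:, bi]
        return pd.DataFrame(data, columns=["position", "ref", *COUNT_COLUMNS])


def _draw_alt(rng, ref: str, transition_prob: float) -> str:
    if rng.random() < transition_prob:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][rng.integers(2)]


def _truncated_beta(rng, a, b, lo, hi):
    for _ in range(1000):
        v = rng.beta(a, b)
        if lo <= v <= hi:
            return float(v)
    return float(lo)  # pathological parameterisation; clamp


def simulate_cohort(params: SimParams,
                    locus_map: MtLocusMap | None = None,
                    marker_panel: dict | None = None) -> SimulatedCohort:
    """Generate a full paired cohort under ``params``.

    Returns a :class:`SimulatedCohort`; see the module docstring for the
    generative model.  All randomness flows from ``params.seed``.
    """
    params.validate()
    if locus_map is None:
        locus_map = load_locus_map()
    if marker_panel is None:
        from .mtgenome import _data_path
        marker_panel = read_marker_panel(_data_path("haplogroup_panel.tsv"))
    rng = np.random.default_rng(params.seed)

    # position weights: uniform, zeroed on the low-complexity mask, boosted
    # in the case-enriched loci for case individuals
    base_w = np.ones(GENOME_LENGTH)
    for pos in locus_map.low_complexity:
        base_w[pos - 1] = 0.0
    case_w = base_w.copy()
    for locus_name, mult in params.case_locus_boost.items():
        locus = locus_map[locus_name]
        case_w[locus.start - 1:locus.end] *= mult

    hg_labels = list(params.haplogroup_freqs)
    hg_p = np.array([params.haplogroup_freqs[h] for h in hg_labels])
    hg_p = hg_p / hg_p.sum()

    statuses = (["case"] * params.n_case_pairs
                + ["control"] * params.n_control_pairs)
    sheet_rows, truth_rows, event_rows = [], [], []
    haplogroups, coverage_fail = {}, set()
    n_pairs = len(statuses)
    seed_seq = np.random.SeedSequence(params.seed)
    child_states = seed_seq.generate_state(2 * n_pairs + 1)[1:]

    for k, status in enumerate(statuses):
        ind = f"IND{k + 1:04d}"
        fc_id, sn_id = f"{ind}_FC", f"{ind}_SNpc"
        age = float(np.round(rng.normal(78.0, 6.0), 1))
        sex = "M" if rng.random() < 0.55 else "F"
        for sid, tissue in ((fc_id, "FC"), (sn_id, "SNpc")):
            sheet_rows.append({"sample": sid, "individual": ind,
                               "tissue": tissue, "status": status,
                               "age": age, "sex": sex})

        # germline backbone
        hg = hg_labels[rng.choice(len(hg_labels), p=hg_p)]
        sn_hg = hg
        if rng.random() < params.discordant_prob:
            others = [h for h in hg_labels if h != hg]
            sn_hg = others[rng.integers(len(others))]
        haplogroups[ind] = (hg, sn_hg)
        if rng.random() < params.coverage_fail_prob:
            coverage_fail.add(ind)

        germline: dict[str, set] = {fc_id: set(), sn_id: set()}
        for sid, label in ((fc_id, hg), (sn_id, sn_hg)):
            germline[sid] |= set(marker_panel.get(label, ()))
        n_priv = rng.poisson(params.private_homoplasmy_rate)
        taken = {pos for s in germline.values() for pos, _ in s}
        w = base_w.copy()
        w[[p - 1 for p in taken]] = 0.0
        priv_pos = rng.choice(GENOME_LENGTH, size=n_priv, replace=False,
                              p=w / w.sum()) + 1
        for pos in priv_pos:
            alt = _draw_alt(rng, locus_map.ref_base(int(pos)),
                            params.transition_prob)
            germline[fc_id].add((int(pos), alt))
            germline[sn_id].add((int(pos), alt))
        for sid in (fc_id, sn_id):
            for pos, alt in sorted(germline[sid]):
                truth_rows.append({
                    "sample": sid, "individual": ind, "tissue": sid.split("_")[1],
                    "status": status, "position": pos,
                    "ref": locus_map.ref_base(pos), "alt": alt,
                    "true_vaf": params.homoplasmy_vaf, "origin": "germline"})

        # FC heteroplasmies and their SNpc fate
        w = (case_w if status == "case" else base_w).copy()
        used = {pos for pos, _ in germline[fc_id] | germline[sn_id]}
        w[[p - 1 for p in used]] = 0.0
        n_het = rng.poisson(params.het_rate_fc[status])
        n_dn = rng.poisson(params.de_novo_rate[status])
        positions = rng.choice(GENOME_LENGTH, size=n_het + n_dn,
                               replace=False, p=w / w.sum()) + 1
        a, b = params.vaf_beta
        for j, pos in enumerate(positions):
            pos = int(pos)
            ref = locus_map.ref_base(pos)
            alt = _draw_alt(rng, ref, params.transition_prob)
            vaf = _truncated_beta(rng, a, b, params.vaf_floor, params.vaf_ceil)
            if j >= n_het:  # de-novo in SNpc
                truth_rows.append({"sample": sn_id, "individual": ind,
                                   "tissue": "SNpc", "status": status,
                                   "position": pos, "ref": ref, "alt": alt,
                                   "true_vaf": vaf, "origin": "de_novo"})
                event_rows.append({"individual": ind, "status": status,
                                   "position": pos, "ref": ref, "alt": alt,
                                   "class": "de_novo", "het_fc": 0.0,
                                   "het_snpc": vaf})
                continue
            truth_rows.append({"sample": fc_id, "individual": ind,
                               "tissue": "FC", "status": status,
                               "position": pos, "ref": ref, "alt": alt,
                               "true_vaf": vaf, "origin": "heteroplasmy"})
            if rng.random() >= params.retention_prob:
                event_rows.append({"individual": ind, "status": status,
                                   "position": pos, "ref": ref, "alt": alt,
                                   "class": "loss", "het_fc": vaf,
                                   "het_snpc": 0.0})
                continue
            sn_vaf, cls = vaf, "unchanged"
            if rng.random() >= params.unchanged_prob:
                mag = params.shift_gap + rng.exponential(params.shift_scale)
                sign = 1.0 if rng.random() < params.positive_shift_prob else -1.0
                cand = float(np.clip(vaf + sign * mag,
                                     params.vaf_floor, params.vaf_ceil))
                if abs(cand - vaf) >= params.shift_gap:
                    sn_vaf = cand
                    cls = "positive_shift" if cand > vaf else "negative_shift"
            truth_rows.append({"sample": sn_id, "individual": ind,
                               "tissue": "SNpc", "status": status,
                               "position": pos, "ref": ref, "alt": alt,
                               "true_vaf": sn_vaf, "origin": "retained"})
            event_rows.append({"individual": ind, "status": status,
                               "position": pos, "ref": ref, "alt": alt,
                               "class": cls, "het_fc": vaf,
                               "het_snpc": sn_vaf})

    sample_sheet = pd.DataFrame(sheet_rows)
    sample_seeds = {sid: int(child_states[i] % (2 ** 31))
                    for i, sid in enumerate(sample_sheet["sample"])}
    truth_variants = pd.DataFrame(truth_rows, columns=[
        "sample", "individual", "tissue", "status", "position", "ref",
        "alt", "true_vaf", "origin"])
    truth_events = pd.DataFrame(event_rows, columns=[
        "individual", "status", "position", "ref", "alt", "class",
        "het_fc", "het_snpc"])
    return SimulatedCohort(params, locus_map, sample_sheet, truth_variants,
                           truth_events, haplogroups, coverage_fail,
                           sample_seeds)


# ---------------------------------------------------------------------------
# deterministic bookkeeping fixtures

def make_bookkeeping_fixture(kind: str, seed: int = 7):
    """Deterministic accounting fixtures with disjoint category flags.

    ``cohort_qc``: 120 sample pairs (97 cases, 23 controls); 8 pairs
    haplogroup-discordant (6 cases, 2 controls) and 9 further pairs
    coverage-failed (7 cases, 2 controls), the two failure sets disjoint.
    Returns ``(pairs, coverage_fail_individuals)``.

    ``reference_chain``: 18,114 mtDNA records — 458 pathogenic carriers,
    7 non-human, 7,051 non-European-marker carriers, 663 truncated, 2,206
    minor-haplogroup, 7,729 clean major-haplogroup records.  Each flagged
    record fails exactly one filter.  Returns the record list.
    """
    rng = np.random.default_rng(seed)
    if kind == "cohort_qc":
        pairs, coverage_fail = [], set()
        spec = [("case", 97, 6, 7), ("control", 23, 2, 2)]
        for status, n, n_disc, n_cov in spec:
            for i in range(n):
                ind = f"{status[:4].upper()}{i + 1:03d}"
                fc = Sample(f"{ind}_FC", ind, "FC", status)
                sn = Sample(f"{ind}_SNpc", ind, "SNpc", status)
                hg = "H"
                sn_hg = "J" if i < n_disc else hg
                if n_disc <= i < n_disc + n_cov:
                    coverage_fail.add(ind)
                pairs.append(SamplePair(ind, status, fc, sn,
                                        fc_haplogroup=hg, snpc_haplogroup=sn_hg))
        return pairs, coverage_fail
    if kind == "reference_chain":
        minor = ("L0", "L1", "L2", "L3", "M", "D", "A", "B", "C")
        major = sorted(MAJOR_EUROPEAN_HAPLOGROUPS)
        markers = sorted(NON_EUROPEAN_MARKERS)
        records = []

        def add(n, **kw):
            for _ in range(n):
                defaults = dict(record_id=f"R{len(records) + 1:05d}",
                                length=16569, species="Homo sapiens",
                                carries_pathogenic=False,
                                marker_alleles=frozenset(),
                                haplogroup=major[len(records) % len(major)])
                defaults.update(kw)
                records.append(RefSeqRecord(**defaults))

        add(458, carries_pathogenic=True)
        add(7, species="Pan troglodytes")
        for i in range(7051):
            add(1, marker_alleles=frozenset({markers[i % 3]}))
        add(663, length=15800)
        for i in range(2206):
            add(1, haplogroup=minor[i % len(minor)])
        # clean records carry coding variants with a population-like codon
        # usage: heavily synonymous third-position changes
        usage_cells = [("synonymous", 3), ("synonymous", 1),
                       ("nonsynonymous", 1), ("nonsynonymous", 2),
                       ("nonsynonymous", 3)]
        usage_probs = np.array([0.62, 0.08, 0.10, 0.08, 0.12])
        for _ in range(7729):
            n_var = 1 + rng.poisson(1.5)
            cells = rng.choice(len(usage_cells), size=n_var, p=usage_probs)
            add(1, variants=tuple(
                (int(rng.integers(5904, 7446)), "N",
                 usage_cells[ci][0], usage_cells[ci][1]) for ci in cells))
        order = rng.permutation(len(records))
        return [records[i] for i in order]
    raise ValueError(f"unknown fixture kind {kind!r}")
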