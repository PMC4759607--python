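"""Case/control mutational-burden statistics on a simulated cohort.

Burden = per-sample count of qualifying variants in a stratum. The report
runs Mann-Whitney tests per locus (Bonferroni-corrected), Fisher's exact
test on the share of coding heteroplasmies above 10% VAF, and summarises
the substitution spectrum (Ti/Tv) and mean heteroplasmic allele fraction.
"""

from mthet import PipelineConfig, SimParams, burden_report, simulate_cohort
from mthet.pipeline import call_cohort

sim = simulate_cohort(SimParams(n_case_pairs=20, n_control_pairs=10, seed=8))
samples, _ = call_cohort(sim.sample_sheet, sim.allele_counts, sim.locus_map,
                         PipelineConfig())
rep = burden_report(list(samples.values()), sim.locus_map,
                    test_variant_type="heteroplasmic")

total = rep.tests[(rep.tests.stratum == "total")
                  & (rep.tests.tissue == "SNpc")].iloc[0]
print(f"SNpc heteroplasmic burden, cases vs controls: "
      f"mean {total.mean_case:.1f} vs {total.mean_control:.1f}, "
      f"Mann-Whitney p = {total.p:.2e}")
print("(cases are simulated with a higher per-tissue heteroplasmy rate, so "
      "a small p here means the test recovers the injected excess)")

for _, r in rep.high_het.iterrows():
    print(f"{r.tissue}: >10%-VAF coding heteroplasmies "
          f"{r.case_high}/{r.case_total} (cases) vs "
          f"{r.control_high}/{r.control_total} (controls), "
          f"Fisher p = {r.fisher_p:.2f}")

for _, r in rep.spectrum.iterrows():
    print(f"{r.tissue} {r.status}: Ti/Tv = {r.titv:.1f} "
          f"({100 * r.tv_fraction:.1f}% transversions), "
          f"mean het VAF = {r.mean_het_vaf:.3f}")
print("(the generator draws transitions with 9:1 odds, so Ti/Tv near 9 and "
      "mean VAF well below 0.10 confirm the intended low-level spectrum)")
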