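"""End-to-end synthetic cohort analysis: simulate, align, fit, classify.

Generates a 600-gene cohort with a directly positioned +1 nucleosome and an
indirectly (statistically) positioned -1 nucleosome, builds the read-density
map, averages it around the flanking nucleosomes, fits the barrier model,
and runs the four-scenario boundary comparison.
"""

import numpy as np

import nucbarrier as nb

sc = nb.SyntheticConfig(seed=12, n_genes=600)
cohort = nb.simulate_cohort(sc)
chrom_len = cohort.truth.attrs["chrom_length"]
print(f"{sc.n_genes} genes, {len(cohort.configuration.dyads)} nucleosomes, "
      f"{cohort.reads['read_id'].nunique()} reads on a {chrom_len/1e6:.1f} Mb chromosome")

dmap = nb.reads_to_density(cohort.reads, b=sc.b, chrom_sizes={sc.chrom: chrom_len})
anchors = nb.find_flanking(cohort.genes, cohort.calls)
pp = nb.align_average(dmap, anchors, window=2000, anchor_col="plus1")
pm = nb.align_average(dmap, anchors, window=2000, anchor_col="minus1")

cfg = nb.FitConfig(seed=12, n_starts=60)
fp = nb.fit_profile(pp, cfg, basin="free")
print(f"+1 side: A={fp.A:.2f}, x0={fp.x0:+.1f} bp, dbar={fp.dbar:.1f} bp "
      f"-> {fp.scenario} positioning (true spacing {sc.dbar:.0f} bp)")

fm = nb.fit_minus_fixed(pm, fp.A, fp.dbar, cfg)
print(f"-1 side: x0={fm.x0:+.1f} bp -> {fm.scenario} positioning "
      f"(an offset near -b = -147 means the array is phased by a repelling "
      f"edge, not a pinned nucleosome)")

scen = nb.compare_scenarios(pp, pm, cfg)
print("simultaneous four-scenario comparison (shared A and dbar):")
for k in sorted(scen, key=lambda k: scen[k].chi2):
    v = scen[k]
    print(f"  {k}: chi2/point={v.chi2:.3e}  x0+={v.x0_plus:+7.1f}  "
          f"x0-={v.x0_minus:+7.1f}")
print("(scenario C = direct +1 / indirect -1 should rank first)")

ratio = nb.density_ratio(dmap, cohort.genes, cohort.calls)
print(f"intergenic/genic density ratio (NFRs excluded): {ratio:.3f}")
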