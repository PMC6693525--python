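"""Design a SPET probe panel from candidate SNPs.

Builds a small synthetic reference + germplasm, ascertains candidate SNPs
from the cultivated cohort, and runs the full design pipeline: feature
classification, cohort-count eligibility, 5/15 kbp spacing, 40-base probe
placement, and the target-within-25-bp window check.
"""

import spetkit as sk
from spetkit.simulate import SimulationConfig, generate_reference, simulate_germplasm, _ascertain_candidates

sim = SimulationConfig(contig_length=200_000, genes_per_contig=50)
genome, annotation = generate_reference(sim, seed=1)
germplasm = simulate_germplasm(genome, sim.species, seed=2)
snps = _ascertain_candidates(germplasm, sim.ascertainment_species)

config = sk.RunConfig.for_mode("tomato-like", seed=1)
panel, report = sk.design_panel(snps, genome, annotation, config)

print("stage counts (candidates surviving each design rule):")
for stage, count in report.stage_counts:
    print(f"  {stage:18s} {count}")
print(f"\nfirst probe: {panel[0].id} {panel[0].contig}:{panel[0].start}-"
      f"{panel[0].end} ({panel[0].orientation}, target {panel[0].target_pos})")
print("Counts shrink at each stage; every kept probe is a 40-base reference")
print("subsequence whose target SNP sits within 25 bp of its 3' end.")
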