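# Methods

## The assay being modelled

SPET (single primer enrichment technology) genotyping sequences the region
adjacent to a single ~40-base capture probe. Each probe is designed against
one target SNP, placed so the target falls within the first 25 bp after the
probe 3′ end; after trimming, roughly 110 bp of usable readout remain, in
which additional ("non-target" or accessory) SNPs segregate. spetkit
implements the three computational layers of such an assay — panel design,
genotyping, and germplasm analysis — plus a simulator that generates the
study conditions those layers are meant to operate under.

## Panel design

Candidate SNPs are biallelic sites with cohort allele counts. Eligibility
depends on the crop mode:

| parameter | tomato-like | eggplant-like | meaning |
|---|---|---|---|
| alt allele count | > 8 (strict) | ≥ 4 | cohort evidence for the alternative allele |
| minor allele frequency | — | > 0.25 | informativeness floor |
| anchored contigs only | yes | yes | no unplaced scaffolds |
| genic sites only | yes | yes | intergenic candidates dropped |

Spacing between *selected* SNPs is ≥ 5 kbp when both members of a pair lie
in CDS and ≥ 15 kbp whenever either member is intron/UTR (the stricter rule
wins for mixed pairs). Selection is greedy left-to-right within each contig
with CDS preferred at equal positions; a `random` offer order driven by the
run seed is available for panels assembled by random draw. Greedy scanning
gives a deterministic, auditable subset that is maximal with respect to its
offer order; the test suite verifies validity and maximality against a
brute-force all-pairs oracle on random instances.

Probes are 40-base forward-strand reference subsequences placed immediately
adjacent to the target (target offset 1 from the 3′ end), on whichever
flank fits: a side whose full 110 bp readout stays on-contig is preferred,
then readout-right; probes containing N are rejected. Boundary readings are
plain-language: "at least N kbp" → ≥ N, "greater than 8" → strict, coverage
bands inclusive. Pilot coverage selection keeps probes inside the
mode-specific mean-depth band (46–90× / 79–130×) with fewer than 4 (≤ 5
reads) / 3 (< 5 reads) low-coverage pilot samples.

## Simulator

The generator's defaults are the study conditions, not tuning knobs:

- genome: 2 chromosomes × 500 kb, 120 non-overlapping gene models per
  chromosome (5′UTR 100 bp, 3 CDS exons of 300 bp split by 200 bp introns,
  3′UTR 100 bp) — genic fraction ≈ 36%, comparable to a gene-rich
  chromosome arm at desk scale;
- germplasm ladder: `crop` (divergence 0, 20 selfing generations, 12
  accessions, within-species polymorphism density 0.002/bp), `wild_close`
  (0.01, outcrossing, 4, 0.008), `wild_mid` (0.03, 4, 0.010), `wild_far`
  (0.06, 4, 0.012). The divergence values span the range from a crop's
  direct wild ancestor to distant relatives of a Solanum-like clade; the
  crop's 12 accessions give a 24-chromosome cohort so the tomato-like
  "alt count > 8" rule behaves like a real resequencing panel;
- per-species backbone: Poisson(divergence × genome length) substitutions
  fixed in all accessions; within-species variation: a shared pool of
  Poisson(diversity × L) sites with Beta(0.5, 0.5) allele frequencies from
  which each haplotype samples. A per-accession-private variant model would
  cap cohort allele counts at 2 and make count-based ascertainment
  impossible, so polymorphism is modelled at the species level;
- selfing: after g generations a heterozygous site is fixed (to a uniform
  allele) with probability 1 − 2⁻ᵍ; g = 20 makes the crop effectively fully
  inbred;
- infinite sites holds genome-wide (positions never reused across species
  or haplotypes), so every variant site has exactly one alternative allele
  and truth bookkeeping is unambiguous;
- coverage: reads per probe × accession ~ NegBin(mean 60, dispersion k = 5)
  (k = None gives constant depth for noise-free experiments); capture: a
  read from a haplotype with m probe-footprint mismatches survives with
  (1 − λ)^m, λ = 0.3 — the one-parameter mechanism that produces the
  divergence → missing-data gradient; sequencing error: uniform 2×10⁻⁴ per
  base. λ has no measured counterpart; it is a free parameter chosen to
  give realistic dropout at the ladder's divergences, not an inferred
  value;
- candidate ascertainment: the candidate VCF is built from the crop
  accessions only, reproducing panel-design ascertainment bias (wild-only
  variation is invisible to the panel but present in the truth VCF).

What the simulator does **not** model: recombination/linkage, indels,
repeat mutation, PCR duplicates, quality-score structure, paralogy and
mis-mapping. Passing tests therefore demonstrate the correctness of the
implemented rules and the qualitative gradients they produce — not
calibration against any real dataset's counts.

## Genotyping

Reads carry their probe of origin, so tallying maps readout offsets
directly to reference coordinates; there is no alignment step and hence no
mapping-quality-based filtering. Calling is per site × sample from the four
base counts: depth < 10 → missing; minor-read fraction ≤ 0.04 → homozygous
for the major base; 0.25 ≤ fraction ≤ 0.5 → heterozygous; the band in
between is ambiguous and stays missing (conservative: these are the calls
a variant-caller's quality filters would discard). The published re-call
rules mix site-level MAF with genotype-level depth; spetkit applies the
0.04 threshold per genotype as the hom/ambiguity floor, one coherent
mechanism with the same intent. Site discovery keeps every position where
at least one sample's call carries a non-reference base; the alternative
allele is the most frequent non-reference base across samples, and
carriers of a third allele are set missing at that site (logged). Site
filters follow vcftools semantics: mean depth over *all* samples
(zero-depth included) ≥ 30, called fraction ≥ max-missing (0.80
tomato-like / 0.95 eggplant-like), at least one non-reference call, then
the ≥ 80% genotyping-ratio rule (boundary inclusive). All filters are
idempotent.

## Diversity and relationships

PIC = 1 − Σ pⱼ² uses called genotypes only (so frequencies sum to 1).
Reference identity is the fraction of non-missing calls that are hom-ref —
a heterozygote is not identical to the reference; this is a declared
definition, chosen for inbred-control interpretability. Duplicates are
connected components of the graph whose edges are pairs with discordance
strictly below 0.002, the band observed for sequencing replicates of inbred
controls. Mislabel flagging compares an accession's mean discordance to
each passport group: flagged when the nearest group is foreign and closer
than half (configurable margin) the passport-group mean.

Distances are allele-sharing over pairwise-complete sites (share 1 /
0.5 / 0 for identical / het-vs-hom / opposite homozygotes). Trees come
from neighbor joining on the Q-criterion — a self-contained, oracle-testable
replacement for external maximum-likelihood tree software — with ties
broken toward the lowest node-index pair and negative branch-length
estimates clamped to zero, the deficit moved to the sister branch (at the
final 3-way join, clamped only). Branch supports use standard
site-resampling bootstrap (resample SNP columns with replacement, rebuild,
count bipartitions). Robinson–Foulds is the symmetric difference of
non-trivial bipartition sets, normalised by the total internal-edge count
of both trees, i.e. 2(n−3) for binary trees. PCA encodes alt-allele dosage
0/1/2, mean-imputes missing calls, centres by site mean and scales by
√(p(1−p)); variance fractions are eigenvalue shares of the accession
covariance. Distances use pairwise-complete sites while PCA uses mean
imputation — each the standard choice for its method, stated here so the
difference is not silent.

## Numerical and edge-case choices

- Coordinates: 1-based inclusive everywhere in the API (VCF/GFF dialect);
  BED output 0-based half-open.
- Anchored-chromosome detection is a configurable id pattern (default
  `chr*|[0-9]+`); reference builds differ and no inference is attempted.
- PIC raises on frequency vectors not summing to 1 within 10⁻⁹.
- Accessions (or pairs) with zero called/co-called sites yield
  undefined-with-warning statistics rather than silent zeros; a pair with
  no co-called sites is an error in distance construction, where a tree
  could not be built anyway.
- Degenerate PCA sites (monomorphic after imputation) are excluded by the
  scale guard; requesting more components than the rank truncates with a
  warning.
- Determinism: every stochastic step takes a seed; identical seeds give
  byte-identical fixture manifests, panels, trees and supports.

## Problem sizes used in the checks

The test suite and acceptance script run the simulator at the default
1 Mb / 24-accession scale for end-to-end checks, and a 120–240 kb scale for
multi-seed sweeps (20 seeds for the divergence-gradient and zero-coverage
monotonicity checks). Replicate concordance is computed on one inbred
accession sequenced twice at the default 60× error model over ~50–100
high-confidence sites; spacing/NJ/RF oracles run on hundreds of random
instances per the sizes stated in their tests. These sizes are the
package's chosen desk-scale defaults; the pipeline itself is linear in
probes × accessions × depth and runs unchanged at larger scales.

## Known limitations

- The hybridization-failure curve is a single-parameter exponential; real
  capture chemistry saturates and depends on mismatch position.
- The genotyper assumes reads are correctly assigned to probes; cross-
  hybridization and multi-mapping artefacts are out of scope.
- NJ + bootstrap replaces likelihood-based tree inference; topologies on
  deeply structured data may differ from an ML tree's.
- Thermodynamic probe scoring (Tm, secondary structure, multiplexing
  compatibility) is not modelled; the panel designer is purely positional.
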