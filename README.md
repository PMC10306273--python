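# lepisex

Identification and characterization of lepidopteran ZW sex chromosomes from
RAD-seq read depth and W sequence-tag homology — with a scenario simulator
that makes every stage testable without any external data.

## The problem

In Lepidoptera, females are the heterogametic sex (ZW; males ZZ). W
chromosomes are hard to identify and to interpret: they are repeat-rich,
poorly conserved, and can originate in different ways — classically by
fusion of the Z with an autosome (the unfused autosome copy degenerates into
a W) or, alternatively, by recruitment of a B-like supernumerary chromosome.
The two histories leave different genomic footprints. This package
implements the computational machinery used to detect those footprints:

1. **RAD-seq depth sex-linkage.** Restriction-site-associated reads stack at
   discrete loci. With cohorts of sexed individuals aligned to a male
   (W-less) genome, Z-specific loci show a female:male depth ratio near
   1/2 (one Z in females, two in males), autosomal loci near 1, and
   W-diagnostic loci are present in every female and absent in every male.
2. **W sequence tags.** Short (150 bp) probes extracted from the W and
   aligned uniquely elsewhere quantify homology as *alignment density*
   (unique tags per Mb of target chromosome) and synteny as the Spearman
   correlation r_s between tag positions on the W and on the target. A
   fusion-derived W is collinear with part of the Z (r_s near 1, tags
   concentrated in the fused, peripheral portion); a B-derived W is not.
3. **Composition diagnostics.** A degenerate W combines a low proportion of
   non-repeat DNA, elevated GC, and a deficit of uniquely placeable RAD
   loci; intact chromosome builds end in (TTAGG)n insect telomere arrays.

The unique-alignment contract mirrors mismatch-threshold read mapping: an
ungapped placement scores 30 per mismatch, and a query is reported only if
its best placement is within the score budget (t400 for 91 bp reads, t600
for 150 bp tags) *and* no other placement ties it. A brute-force oracle with
the identical contract backs the seed-and-extend implementation in tests.

The simulator generates both W-origin scenarios from an ancestral
multi-chromosome genome — telomeres, GC-biased W substitutions, indels,
autosome→W translocations with tandem-repeat expansion (the signature
footprint: a segment expanded ~2.45× by repeat multiplication), and sexed
RAD cohorts (PstI digest, reads carrying the TGCAG residual,
negative-binomial depth, W hemizygous in females) — together with a
ground-truth table of every homology and event interval.

## Worked example

```python
from lepisex import (ScenarioConfig, simulate_ancestral_genome, apply_scenario,
                     GenomeIndex, AlignerParams, extract_tags_masked,
                     positional_correlation, compute_density)
from lepisex.chromstats import mask_repeats_simple
from lepisex.tags import align_tags

cfg = ScenarioConfig(seed=1)                # fusion scenario by default
ancestral = simulate_ancestral_genome(cfg)  # 4 autosomes + Z, 0.67 Mb
male, female, truth = apply_scenario(ancestral, cfg)

masked = mask_repeats_simple(female, chroms=["W"])
tags = extract_tags_masked("W", female.chromosomes["W"], masked.mask["W"])
hits = align_tags(tags, GenomeIndex(male), AlignerParams(score_threshold=600))
print(compute_density(hits, male))
print(positional_correlation(hits, min_tags=120))
```

prints (seed 1):

```
chrom  n_unique  chrom_len      density
   A1         0     150000     0.000000
   A2         0     130000     0.000000
   A3        23     110000   209.090909
    Z       721     320000  2253.125000

chromosome  n_tags  r_s
         Z     721  1.0
```

721 of 820 W tags land uniquely on the neo-Z with a perfect positional
correlation — the fusion footprint (the 23 tags on A3 mark the translocated
segment; A3 stays below the 120-tag reporting gate for r_s). The same
pipeline run on a B-origin simulation leaves every chromosome below the tag
gate.

The `analysis/` directory holds the full narrative, as numbered scripts:
simulation of both scenarios (01), RAD depth sex-linkage and hemizygosity
segmentation (02), W-tag homology, peripheral enrichment and expansion
detection (03), composition diagnostics (04), and ten-seed scenario
discrimination (05). Each writes its tables under `results/`. A `lepisex`
command-line interface exposes the individual stages
(`simulate`, `preprocess`, `align`, `rad-depth`, `tags`, `stats`,
`analyze`, `compare`).

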