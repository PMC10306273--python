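# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the simulations do and do not establish about
real data.

## 1. Scenario simulator

### Ancestral genome

`simulate_ancestral_genome` draws each chromosome i.i.d. per base at a
configurable GC content (default 0.37, a typical lepidopteran value), with
`telomere_copies` (default 30) tandem copies of TTAGG at the left end and of
its reverse complement at the right end. The default karyotype is four
autosomes (150, 130, 110, 120 kb) plus a 200 kb Z — a ~20× linear
scale-down of a butterfly chromosome set, chosen so that a full 38-individual
RAD study simulates, aligns and analyses in seconds while leaving enough
PstI sites (~1 per 8.6 kb at GC 0.37; ~80 genome-wide) for stable
depth-ratio averages. All downstream statistics are per-Mb or per-locus
rates, so conclusions do not depend on the absolute scale, only on counts.

### Fusion scenario

The Z is concatenated with the last autosome (neo-Z = Z ++ A; the fused
autosome's length is a validated config field). The concatenation is kept
verbatim, including the now-internal telomeric sequence — real fusions
erode internal telomeres, but keeping the exact zero-mutation identity
`W == neoZ[z_length:]` makes the degeneration model separately testable.
The unfused copy of A becomes the W and degenerates in a fixed order:

1. **Substitutions** at `substitution_rate` (default 0.05): every hit
   changes the base; the replacement is G or C with probability
   0.5 + `w_gc_shift` (default 0.15), emulating GC accumulation on
   degenerate W chromosomes. Five percent backbone divergence keeps 150 bp
   tags well inside the t600 budget (mean ~7.5 mismatches) while giving the
   W a detectably elevated GC (≈ +0.012 over the ancestral 0.37, many
   standard errors at 130 kb).
2. **Indels** at `indel_rate` 0.001/base, geometric lengths (mean 5 bp);
   insertions are unsourced random sequence, deletions split the homology
   map.
3. **Translocation** of `n_translocations` (default 1) segments of
   `translocation_len` (4 kb) copied from random donor autosomes into
   random internal W positions (telomeres excluded). The default of a
   single event mirrors the one dominant autosome→W translocated region the
   fusion scenario is modeled on; it is deliberately not a repeat-storm.
4. **Tandem expansion** of each translocated segment to exactly
   `round(expansion_factor × len)` occupied bases (default factor 2.45,
   the 81.6 kb → 200 kb ratio at 1/20 scale: 4 kb → 9.8 kb). Mechanically, a
   unit of `expansion_unit_len` (300 bp) sampled inside the segment is
   multiplied in place into a tandem array; the truth table records the
   whole occupied block as `translocation` and the array sub-interval as
   `expansion`.

Degeneration is applied in that order so every truth interval is emitted
once, in final W coordinates: substitutions and indels operate on a
position-source map (remnant-homology runs are read off the surviving
consecutive source runs), and translocations are inserted left-to-right
with a running offset so earlier insertions cannot shift later records.

### B-origin scenario

The W is a fresh random backbone of `fused_autosome_length` bases at
GC + `w_gc_shift` (B-like chromosomes accumulate GC-rich repetitive
content), with telomeres, receiving the same translocation+expansion events
(donors here include the Z). No remnant homology exists, which is exactly
the discriminating property.

### RAD cohort

Each of `n_per_sex` (default 19) individuals per sex receives an
independent, seed-derived random substream. Every exact CTGCAG occurrence
on every chromosome copy the karyotype provides (autosomes ×2; Z ×2 males /
×1 females; W ×1 females) yields reads on both flanks, each beginning with
the 5′ residual TGCAG; read counts per (site, copy, flank) are
negative-binomial with mean `mean_depth` (20) and dispersion 5 — RAD
coverage is overdispersed relative to Poisson. Sticky-end geometry beyond
the residual is ignored; it does not affect depth analysis. Per-base
errors at `error_rate` 0.002. Preprocessing keeps residual-bearing reads,
trims to 91 bp and, above the 8-million-read cap, downsamples to exactly
the cap by seeded reservoir sampling.

## 2. Unique alignment

Ungapped seed-and-extend with one exact 15-mer seed required: seeds are
taken at non-overlapping query offsets (plus a final tail seed), candidate
placements on both strands are scored at 30 per mismatch (N always
mismatches, including N–N), and a hit is reported iff the single best
placement is unique (ties rejected) and within `score_threshold`
(t400 → 13 mismatches for reads; t600 → 20 for tags; robustness runs use
t300/t1,200). "Unique" means *single best with tie rejection*, the stricter
of the readings the threshold convention admits.

Limitations, by construction: no gaps (a tag spanning an indel pays the
full mismatch tail and is usually rejected — acceptable for intra-genus
comparisons of short probes) and sensitivity bounded by the pigeonhole of
6 seeds on a 91 bp read (misses possible above ~6 clustered mismatches; at
the simulated divergences ≤5% the oracle-equivalence suite observes no
misses). The brute-force oracle scans every placement with no seeding and
is used only for verification.

## 3. Tag homology statistics

* Masked-mode extraction emits floor(L/150) non-overlapping tags
  left-aligned in each unmasked run (left alignment is a documented
  convention so counts are reproducible); stepped mode emits a 150 bp tag
  every 500 bp regardless of masking.
* Alignment density = unique tags per Mb of target chromosome,
  zero-count chromosomes included.
* Positional correlation = Spearman r_s (average ranks on ties) between W
  source positions and target positions, reported only for chromosomes
  with ≥120 uniquely aligned tags. Source/target denominators follow the
  target chromosome ("tags aligning to the Z" = target coordinates).
* Peripheral enrichment = fraction of a chromosome's tags starting in the
  terminal windows (1 Mb on real-scale data; the pipeline shrinks the
  window to len/4 when a chromosome is shorter than twice the window, and
  the standalone function instead errors with advice).
* Collinear blocks = maximal runs of source-consecutive tags with strictly
  monotone target positions (either direction) and target gaps ≤ 100 kb;
  runs under 5 tags are suppressed.
* Expansion detection clusters stepped-tag placements by single linkage on
  the target (link ≤ 2×step) and additionally splits clusters at W-side
  gaps > 4×step: a genuine tandem-array signature is compact on both axes.
  Without the W-side split, a W region that merely flanks an unrelated
  insertion between two collinear anchors shows an inflated max–min W span
  and produces spurious calls. A cluster of ≥10 tags with
  W-span/target-span ≥ 1.5 is reported; on the default simulation the
  single truth event is recovered with span_ratio within ±20% of 2.45
  (boundary tags blur the spans by up to ±1 step).

## 4. RAD depth statistics

* A locus is an exact read-start stack, keyed by (chromosome, start,
  strand): preprocessed reads begin at the restriction residual, so starts
  are discrete and merging windows would only blur sex-linkage signal. An
  individual "represents" a locus iff it contributed ≥1 read.
* Filters follow the published thresholds: representation in ≥18 of 19
  individuals per sex and total depth within 450–2,400× (at mean depth 20
  per site copy, an autosomal locus totals ≈1,520×, a Z locus ≈1,140×, so
  the band is the natural one for this cohort design); female-limited loci
  require all 19 females, zero male reads, pooled female depth 225–1,200×.
* The ratio track uses mean-of-individual depths per sex (a pooled-sum
  mode is available; identical for balanced cohorts); loci with zero male
  depth are flagged and excluded. No cross-individual normalization beyond
  the read cap is applied.
* Hemizygosity segmentation slides a 25-locus median (windows in loci, not
  bp, to equalize information) and labels runs below 0.75 — the midpoint
  of the 0.5 and 1.0 expectations — hemizygous; segment bounds fall at
  locus midpoints. Chromosomes with fewer loci than the window get a
  single labeled segment and a warning.
* Locus density uses females only (males carry no W) and loci represented
  in ≥10 females; the 95% compatibility interval for the autosomal median
  density resamples the per-autosome density values with replacement,
  10,000 times. The draw order is frozen (one `integers(0,n,(n_boot,n))`
  call from `default_rng(seed)`, row medians, percentile 2.5/97.5) so a
  given seed is exactly reproducible.

## 5. Composition diagnostics

GC is computed over unambiguous bases; the non-repeat proportion is the
unmasked fraction (uppercase for soft masks, non-N for hard masks).
Telomere detection requires ≥10 tandem motif copies (any phase, ≤1
mismatch per copy) within the terminal 2 kb — the numeric rule is a
package convention; thresholds are exposed. The simple masker (masking
every base covered by a 15-mer occurring ≥5 times genome-wide, extended
through tandem arrays detected by self-offset identity ≥90% at periods
≤500 bp) is adequate for *synthetic* genomes only: real genomes should
arrive pre-masked, and the masker makes no attempt at repeat
classification.

## 6. What the simulations do and do not show

The generator reproduces the *structure* of the two W-origin histories —
collinearity, hemizygous depth, repeat expansion, composition shifts — but
not the full texture of real data: no gapped variation, no transposable
element families or repeat landscape (repeats arise only from telomeres
and tandem expansions, so a default W is ~95% unique sequence, far above a
real W), no heterozygosity, library-prep or GC-coverage bias, no
cross-species divergence model beyond independent re-degeneration, and no
contaminant (e.g. endosymbiont) contigs. Consequences worth naming:

* The RAD-density deficit of the W is a *repeat-content* property; it is
  demonstrated under a repeat-rich configuration (10 translocations), not
  under the single-translocation default, where a mostly-unique W
  legitimately shows autosome-like locus density.
* Independently re-degenerated Ws from the same ancestor stay backbone-
  collinear (substitutions, indels and insertions never reorder
  sequence), so their divergence shows as a collapsed unique-alignment
  rate rather than a depressed r_s; the cross-genome comparison reports
  both and the tests assert the alignment-rate ordering.
* Translocated W segments align uniquely to their donor position in the
  male genome and raise that locus's female:male ratio toward 1.5 — a
  real property of autosome→W transfers that slightly lifts the autosomal
  mean ratio; with the default single event the effect is below 0.01.

Determinism: every stage derives its generator from the run seed (per-
individual substreams use `[seed, stage, index]` seed sequences), and
identical configurations produce byte-identical FASTA/FASTQ/BED output
(gzip members are written with a zeroed timestamp).

Problem sizes: the default study (0.67 Mb ancestral genome, 38
individuals, ~190k reads, ~820 W tags) was chosen as the smallest scale at
which all depth and homology statistics are comfortably estimable; the
test suite and the acceptance script run it end to end.
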