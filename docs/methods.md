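# Methods

## Scope and model

`karyoshatter` implements an integrative copy-number analysis for
myelodysplastic syndromes (MDS) and chronic myelomonocytic leukemia (CMML)
cohorts profiled by array comparative genomic hybridization (aCGH) with
targeted sequencing of recurrently mutated genes. The analysis operates on
probe-level log2 ratios (sample vs. control intensity) and proceeds in
stages:

1. **Segmentation.** Each chromosome's probe values are partitioned into
   piecewise-constant segments by minimizing the penalized residual sum of
   squares `sum_seg RSS(seg) + beta * n_segments` with a minimum segment
   length. The optimizer is PELT (pruned exact linear time). Pruning of a
   dominated candidate is *delayed by one minimum segment length*, which
   closes the classical interaction between pruning and a minimum-length
   constraint: a candidate pruned at time `t` is only discarded for times
   `u >= t + min_probes`, where the dominating candidate `t` is itself
   admissible. The result is therefore exactly the exhaustive
   dynamic-programming optimum (verified against an independent O(n^2) DP
   on randomized profiles in the test suite).
2. **CNA calling.** Segment means are thresholded into copy states
   1 (loss), 2 (normal), 3 (gain); only three states are modeled, so
   homozygous deletions and high-level amplifications collapse into 1 and 3.
   Adjacent same-direction aberrant segments merge when no diploid segment
   intervenes. Calls matching a germline CNV catalogue at reciprocal
   overlap >= 0.5 are flagged and excluded from somatic counts. Calls
   <= 5 Mb are *cryptic* (below banded-metaphase resolution, inclusive
   bound); losses strictly > 100 kb overlapping a sequencing-panel gene are
   flagged for follow-up sequencing of the remaining allele.
3. **Chromothripsis.** Per chromosome, the segment state sequence is
   run-length encoded; the switch count is the RLE length minus one. A
   chromosome is chromothriptic when switches >= 10 AND distinct states
   <= 3. Both bounds are configurable; the state bound encodes the
   signature of a single catastrophic shattering event (oscillation between
   few states) as opposed to stepwise aberration accumulation. Switches are
   counted over the whole chromosome, never pooled across chromosomes.
   Genes commonly affected across all positive patients are reported with a
   direction (amplified / deleted / mixed) from the states of the segments
   overlapping them.
4. **Mutation integration.** Variant tables (sample, gene, cDNA change,
   protein change, type, VAF %, COSMIC id) are filtered — intronic variants
   and known SNPs are not scored — then classified by VAF: >= 80%
   (inclusive) is `homozygous_or_hemizygous`, below is `heterozygous`.
   VAF alone cannot distinguish homozygosity from hemizygosity (mutation on
   the single allele remaining after deletion); the two are deliberately one
   class, and the distinction is surfaced by the biallelic status
   (deletion_plus_mutation / deletion_only / mutation_only / wild_type)
   computed against overlapping loss calls. Minimal deleted regions (MDRs)
   are the interval intersection of the deletions at a locus across
   patients; an empty intersection is reported as absent, never as a
   zero-length interval.
5. **Cytogenetic concordance.** A small ISCN subset is parsed (del, dup,
   +N, -N, -Y, balanced t(...), clones with `[n]` cell counts); unsupported
   tokens degrade to kind `other` with a warning instead of failing.
   Metaphase adequacy bands: >= 20, 11–19, <= 10, and 0 (non-informative,
   absence of mitosis). Complex karyotype: >= 3 clonal abnormalities by
   cytogenetics, >= 5 copy-number changes by array. A CC abnormality is
   matched to array calls at arm (or chromosome) level with any-overlap
   (>= 1 bp) and matching direction — banded-metaphase breakpoints are too
   coarse for a reciprocal-overlap rule; a reciprocal minimum can be
   imposed. Balanced translocations are copy-neutral and counted
   `expected_undetectable`. Association tests: Fisher's exact (2x2,
   two-sided) for categorical contrasts, Wilcoxon rank-sum for continuous
   ones; degenerate tables raise instead of fabricating a p-value.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `loss_threshold` / `gain_threshold` | −0.25 / +0.25 | log2 ratio | midway between diploid (0) and single-copy levels (−1, +0.585); vendor thresholds are not recoverable, so these are explicit and configurable |
| `min_probes` | 5 | probes | minimum evidence per segment |
| `segmentation_penalty` | 0.5 | squared log2 units | >> the spurious-split gain of N(0, 0.1) noise (~2·σ²·log n ≈ 0.14 at n = 1000) and << the gain of a true single-copy step over 5+5 probes (≥ 0.85) |
| `cnv_overlap_fraction` | 0.5 | fraction | reciprocal-overlap rule for germline CNV exclusion |
| `cryptic_max` | 5 Mb | bp | inclusive bound of the cryptic class |
| `followup_min` | 100 kb | bp | strict lower bound for sequencing follow-up of deletions |
| `min_switches` / `max_states` | 10 / 3 | count | chromothripsis oscillation criterion |
| `hom_vaf_threshold` | 80 | % VAF | separates observed heterozygous (40–55%) from homozygous/hemizygous (> 89%) clusters; any cutoff in (76.5, 89] gives identical labels on those clusters |

## Synthetic cohorts

The generator fabricates its own genome — 24 chromosomes with round
lengths summing to ~3.1 Gb, a 0.4 centromere fraction (0.15 for the
acrocentrics), and panel genes at fixed fractional positions — so no real
genomic coordinate is baked in; real BED annotation can be substituted at
every entry point. Probes are evenly spaced and allocated proportionally to
chromosome length by largest-remainder apportionment (counts are exact and
deterministic). Probe value = log2(state/2) + i.i.d. Gaussian noise.

Defaults emulate an MDS/CMML cohort: 301 patients, ~135,000 probes
(down-scalable), 63.5% male, 13.3% non-informative cytogenetics, large
recurrent aberrations (del(5q) 8.3%, del(20q) 4.3%, −Y 3.3%, +8 3.3%,
del(7q) 3.0%, +1q 1.7%, del(17p) 1.3%, del(11q) 1.3% of patients), cryptic
deletions at panel genes in 12.6%, and chromothripsis of chromosome 13 in
1% with 11–18 implanted switches. Each class is implanted in
round(fraction × n) patients drawn without replacement (stratified
implantation): counts are exact and reproducible rather than binomially
dispersed, which keeps recovery experiments well-defined (e.g. "3
chromothriptic patients in a cohort of 100" at prevalence 0.03). −Y is
implanted only in males; females emit no chrY probes (sex-matched
reference). Variant allele fractions are resampled as
Binomial(depth, VAF/100) at depth 500 by default. Karyotype strings encode
only implanted events >= 10 Mb (configurable) — cryptic events are
CC-invisible by construction — and non-informative patients emit no
metaphases. Implanted-event truth is recorded both as requested and as
*probe-aligned* intervals (the bp span of the probes the event covers);
exact-recovery comparisons use the probe-aligned interval, since
segmentation cannot see between probes.

The noise model is i.i.d. Gaussian on log2 ratios. Real arrays add GC
waves, batch effects, mosaicism and subclonal fractions; passing recovery
tests here demonstrates correctness of the calling logic under the stated
model, not robustness to those artifacts.

## Problem sizes

Recovery experiments in the tests and the acceptance script use 100-patient
cohorts at 24,000 probes genome-wide (~890 probes on chr13; chromothripsis
segments of >= 20 probes), noise SD 0.1 or 0 as stated. The
segmentation-vs-DP cross-check uses 50 random profiles of 10–200 probes.
These sizes exercise every code path at full fidelity; the generator scales
to the 135k-probe default unchanged.

## Numerical and design choices

- Coordinates are 0-based half-open internally (BED-compatible); reports
  and SEG files render 1-based inclusive positions. A segment's interval is
  the span of its member probes (`first_pos − 1`, `last_pos`).
- Threshold ties are inclusive on both calling thresholds and the VAF
  cutoff; the follow-up size bound is strict (>), the cryptic bound
  inclusive (<=). Ties in largest-remainder probe allocation break by
  chromosome order.
- "Changes in segmental copy number" are counted as RLE transitions of the
  segment state sequence, not as rearrangement breakpoints: a 19-segment
  oscillating chromosome has 18 switches. Whether oscillation must return
  between the *same* two states is left open by the criterion; the detector
  requires only >= 10 transitions with <= 3 distinct states (the state
  bound is configurable).
- The exclusive-class validator rejects frequency tables whose same-
  chromosome classes sum above 1; within a patient, conflicting implants
  are resolved by skipping the cryptic event's colliding gene (e.g. a
  del(17p) carrier receives a cryptic deletion at a different panel gene).
- Degenerate inputs: empty chromosomes yield empty state sequences (0
  switches); chromosomes with fewer than `min_probes` probes are skipped
  with a warning; disjoint MDR inputs return an absent result; degenerate
  contingency tables raise.

## Known limitations

- Three-state copy model: no homozygous-deletion, amplification, or
  allele-specific states; no subclonal fraction estimation.
- No intensity normalization or wave correction; probe tables are assumed
  pre-normalized.
- The ISCN parser covers the simplified grammar above, not ISCN 2013 in
  full; derivative and marker chromosomes parse to `other`.
- Chromothripsis is inferred from copy-number oscillation alone;
  rearrangement-graph evidence (read pairs, breakpoint junctions) is out of
  scope, so a positive call is a copy-number signature, not a proof of a
  one-step origin.
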