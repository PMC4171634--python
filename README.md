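# methcrosstalk

Differential DNA-methylation analysis for methylated-DNA capture sequencing
(MBD/5mC-seq), built around the question of how histone-modifier knockdowns
reshape the methylome: which promoters gain or lose CpG methylation when
H3K4me3, H3K27me3 or H2AK119ub is depleted, and whether those changes
concentrate in particular chromatin states (e.g. bivalent promoters) or in
gene sets such as the loci commonly hypermethylated in cancer.

It is written for computational epigenomicists who have mapped capture-seq
tags (BED) per condition and want a tested, reproducible path from tags to
enrichment statistics — plus a synthetic-study generator with planted
ground truth, so every step of that path is validated against known answers.

## What it computes

* **Island calling** — the genome is tiled into *w* = 200 bp windows; with
  background rate λ = *N·w* / (*G*·EGF) (library size *N*, genome *G*,
  effective genome fraction 0.854), windows with P(X ≥ c; λ) < 0.2 are
  eligible and score −ln p(c; λ); eligible windows within a 600-bp gap merge
  into islands filtered at a score threshold set so the expected number of
  background islands is ≤ the E-value (1000), estimated by Monte-Carlo null
  genomes.
* **Differential regions** — per region, tags-per-million counts in two
  libraries, a two-sided Poisson test of the library-size-scaled counts,
  Benjamini–Hochberg q across regions (q < 0.01), and
  log2FC = log2(a + 1) − log2(b + 1).
* **Feature annotation** — promoter (TSS ± 1 kb), body, 3′ end (TTS + 1 kb),
  CGI and 2-kb shores; promoter CpG classes HCP/ICP/LCP from 500-bp-window
  CpG observed/expected ((#CG·L)/(#C·#G)) and GC content.
* **Hyper/hypo calls** — a feature is hypermethylated at log2FC ≥ 1
  (2-fold or greater, boundary inclusive), hypomethylated at ≤ −1; calls
  roll up to genes per feature class and across conditions into a
  log2-change matrix with hierarchical clustering (Euclidean, average
  linkage).
* **Enrichment statistics** — chromatin-state categories (K4-only,
  bivalent, K27-only, ub-only, K27+ub, unmarked) per promoter from mark
  peak overlap; two-tailed Fisher exact tests (probability-mass convention)
  with the conservative EASE adjustment (overlap cell minus one) for state
  strata, multi-set overlaps, and external gene lists (e.g. a 1009-gene
  cancer-hypermethylation panel against a 23,218-gene universe, baseline
  4.345%).
* **Profiles** — FPKM-normalized metagene (−10 kb → TSS → TTS → +10 kb,
  length-normalized body) and point profiles (±5 kb) stratified by CpG
  class or CGI context.
* **Validation assays** — array-style Δβ calls (|Δβ| > 0.2, Welch-t
  p < 0.05, −1700 bp promoter rule) and MeDIP-qPCR enrichment
  2^−(sample Ct − input Ct).

## Worked example

Simulate a control and a knockdown in which bivalent promoters gain
2.5-fold methylation, then recover that design from the tags alone:

```python
from methcrosstalk import (SimConfig, simulate_genome, assign_chromatin_states,
                           simulate_mbd_library, call_islands, state_enrichment)
from methcrosstalk.diffmeth import (feature_differential, gene_level_rollup,
                                    rollup_counts)

cfg = SimConfig(seed=7)                       # 3 x 2 Mb, 300 genes, 5e5 tags
annot = simulate_genome(cfg)
truth, peaks = assign_chromatin_states(annot, cfg)
ctrl = simulate_mbd_library(annot, truth, "control", cfg)
kd = simulate_mbd_library(annot, truth, "siKD", cfg)

islands = call_islands(kd, annot.chrom_lengths)          # 1170 islands
feat = feature_differential(kd, ctrl, annot)             # per-feature test
calls = gene_level_rollup(feat, annot, "siKD")
print(rollup_counts(calls))

hyper = set(calls[(calls.feature_class == "promoter")
                  & (calls.status == "hyper")].gene)
print(state_enrichment(hyper, truth.states, list(annot.genes.name)))
```

which prints (abbreviated):

```
  feature_class status  n_genes
            cgi  hyper       51
       promoter  hyper       60
          shore  hyper        2
three_prime_end   hypo        1

  category  n_called  observed  expected   fold  p_ease direction tier
   K4_only         0      0.00    0.3500  0.000  0.0000     under    *
  bivalent        60      1.00    0.2567  3.896  0.0000      over    *
  ...
```

All 60 hypermethylated promoters are bivalent (fold 3.9 over the 25.7%
genome-wide prevalence, EASE-Fisher p < 1e-4, tier `*`), and K4-monovalent
promoters are significantly under-represented — the planted design,
recovered end-to-end.  The CGI calls mirror the promoter calls because the
planted stratum's promoters are largely CGI promoters; CpG-poor (LCP)
promoters produce too few capture fragments to be testable, which is a
property of the assay the generator reproduces.

The same analysis runs from the shell:

```bash
methcrosstalk run-all --out results/demo --seed 7         # bundled demo config
methcrosstalk call-islands --tags kd.bed --chrom-sizes sizes.tsv --out islands.tsv
```

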