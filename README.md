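# pycher — ChIP-chip promoter tiling-array analysis

`pycher` re-implements, as a tested and reusable pipeline, the classic
ChIP-chip analysis of transcription-factor binding in tissue: from
two-channel tiling-array probe intensities to ChIP-enriched regions
("chers"), promoter/gene assignment, binding-site (PWM) detection with
TSS distances, and GO/KEGG-style over-representation of differentially
expressed target genes.  It is aimed at anyone who needs to reanalyse
legacy NimbleGen-style promoter-array experiments — or to benchmark
region-calling heuristics — and ships a synthetic-data generator that
emulates the whole experiment with saved ground truth for every stage.

## The method

Per probe, the enrichment signal is the log ratio of the
immunoprecipitated (Cy5) and input (Cy3) channels,
`r_i = log2(IP_i / input_i)`, computed after removing multi-mapping
reporters.  The array is centred by subtracting the one-step
**Tukey-biweight** location `T = Σ w_i r_i / Σ w_i` with
`w_i = (1 − u_i²)²` for `|u_i| < 1` (else 0), `u_i = (r_i − med) / (5·MAD + ε)`.
Centred ratios are smoothed with a **running median** over a 900-bp
window, masked wherever the window holds fewer than seven probes.

**Cher calling.**  Candidate regions are maximal runs of ≥ 7 consecutive
probes above the median of the smoothed values; the enrichment threshold
`y0` is the 99th percentile of the candidates' maximum smoothed levels
(top 1% of potential chers).  Runs of ≥ 7 probes strictly above `y0`,
merged when separated by < 450 bp, are reported as chers with
`score = Σ (smoothed − y0)` over their probes and `max_peak` the regional
maximum.  A cher annotates a gene when it overlaps the 10-kb strand-aware
window upstream of any TSS, or the gene body.

**Motif scanning** follows the information-weighted (Match-style) scheme:
with `I(i) = Σ_B f(i,B) ln 4f(i,B)`, a window scores
`MSS = (Current − Min)/(Max − Min)` where `Current = Σ_i I(i) f(i, s_i)`;
the core score CSS applies the same formula over the five consecutive
most-informative positions.  Both strands are scanned with the two-stage
CSS-then-MSS cutoff filter.  Signed TSS distances use the most proximal
TSS: `d = (TSS − site) × strand`.

**Enrichment.**  Target genes (e.g. differentially expressed genes whose
promoters carry a cher) are tested per ontology term with the upper-tail
hypergeometric probability `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`, where
`N`/`n` count only annotated genes; annotations are propagated to all DAG
ancestors, FDR is controlled by Benjamini–Hochberg across all tested
terms, and terms carry a hierarchy level (roots = 1) for level-wise
reporting.

## Worked example

The numbered scripts under `analysis/` run the complete study on a
synthetic experiment (1200 tiled promoters, 20 spiked with 1.5 log2
enrichment over 800 bp, noise sd 0.3):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_call_chers.py
...
python analysis/07_evaluate.py
```

With seed 1 this prints, along the way:

```
120000 probes read; 3600 non-unique removed (3.0%)
Tukey-biweight location: -0.0006 log2 (subtracted from every probe)
threshold y0 = 0.4571 log2 (99% quantile of 3108 candidate regions)
called 20 chers; median span 750 bp, median score 7.15
20 chers -> 20 target genes (17 upstream assignments, 3 within-gene)
17 motif hits in 17/20 chers (85.0% of chers contain a TFBS)
  [all] 34 terms tested; top: T0039 (level 6, 11/250 genes, expected 4.2,
        p=0.000728, FDR=0.0247)
spike recovery: sensitivity=1.000, precision=1.000
```

Every planted spike is recovered as a cher with no false positives; the
planted over-represented term (`T0039`) tops the FDR ranking of the
enrichment of DE target genes; and the worked qPCR example recomputes the
published validation-assay offsets exactly (e.g. RUNX1/MTMR11 site
149914981 vs assay midpoint 149915029 → Δ = +48 bp).

The same pipeline is available as a CLI (`pycher run --config run.yaml`,
or stage-wise `pycher simulate | ingest | normalize | smooth | callchers |
annotate | fetch-seqs | scan | enrich | evaluate`); each run writes a
manifest with parameters, input checksums and per-stage record counts.

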