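# regulonscan

Tools for asking a classic regulatory-genomics question: *when silencing a
master transcription factor reshapes the transcriptome, which downstream
regulator's binding sites explain the genes that move?* The motivating case
is Ewing sarcoma, where knocking down the EWS-FLI1 fusion oncoprotein
de-represses a large gene group, and the promoters of those de-repressed
genes turn out to be enriched for forkhead-box (FOXO1) binding motifs.

The package implements that in-silico analysis chain as a tested, reusable
pipeline, exercisable end to end on synthetic data with planted ground
truth:

1. **Differential expression** of a knockdown time course (log2 expression
   matrices + sample sheet) with an empirical-Bayes **moderated t-statistic**.
   Per gene, the pooled residual variance s²_g (d_g df) is shrunk toward a
   prior s²₀ carrying d₀ df,

       s̃²_g = (d₀·s²₀ + d_g·s²_g) / (d₀ + d_g),
       t_g = logFC_g / (s̃_g·√(1/n_A + 1/n_B)),   t_g ~ t(d₀ + d_g),

   with (d₀, s²₀) estimated by moment-matching log s²_g, and
   Benjamini–Hochberg adjustment within each contrast.
2. **Promoter motif counting**: UCSC-dialect `refGene.txt` /
   `tfbsConsSites.txt` tables (0-based half-open), strand-aware 1-kb
   upstream windows merged per gene, conserved TFBS hits counted per gene
   and motif (midpoint rule by default).
3. **The binned correlation statistic**: genes ordered by logFC, split into
   100 equally sized bins; per motif, Pearson r between per-bin motif-hit
   sums and per-bin mean logFC. A motif whose targets track the expression
   response stands out from the near-zero background.
4. **Gene-set overlap**: threshold sets (e.g. logFC > 1, adjusted p < 0.05)
   compared by the exact hypergeometric upper tail P(X ≥ k), computed in
   log space (accurate far below 1e-300), plus Venn region counts.
5. **In-vivo growth statistics**: a distribution-free permutation test on
   the AUC of mean log-volume curves between two xenograft arms, and exact
   two-sample rank-sum tests per day.
6. **Synthetic-data generators** with known truth: a knockdown time course
   with activated/repressed/null gene groups, a promoter landscape with
   Poisson-planted motif enrichment in the regulon, and two-arm exponential
   tumor growth with lognormal noise.

## Worked example

```bash
regulonscan all --out-dir demo_run --seed 7
```

simulates a five-point (0, 18, 36, 53, 72 h) knockdown course of 2000 genes
(15% activated, 15% repressed, planted |logFC| 1.5), a promoter landscape in
which the motif `V$FOXO1_01` is Poisson-enriched (rate 3 vs 1) in the
repressed regulon, and a two-arm growth experiment — then runs every
analysis stage. From `demo_run/report.json` of that exact command:

```
top motifs, 36 h contrast:   V$FOXO1_01  r = 0.687   <- planted motif, rank 1
                             V$BG003_01  r = 0.091
                             V$BG023_01  r = 0.067
overlap up_strict vs up_relaxed: N=1374, K=155, n=308, k=155,
                             expected k = 34.7, log10 p = -117.4
growth permutation test:     T_obs = 16.76, p = 0.001 (999 permutations)
```

The planted forkhead-box motif tops the correlation ranking by a wide
margin (background motifs hover near |r| ≈ 0.1); the strict knockdown-up
set is wholly contained in the relaxed set, far beyond its chance
expectation; and the halved growth rate of the treated arm is detected at
the permutation floor. The same calls are available as a library
(`regulonscan.pipeline_cli.run_pipeline`, or the per-module functions).

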