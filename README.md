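# ageswitch

Analysis pipeline for a two-window ("midlife switch") model of age-related
transcript expression, together with a planted-truth synthetic-data generator
that exercises every stage:

1. **Probe quantification** (`ageswitch.probe_quant`) — exact 25-mer probe
   matching against a transcriptome, single-match filtering, per-sample GC-bin
   median adjustment, detection/variance filtering, and Tukey median-polish
   summarization into a transcript-by-sample log2 expression matrix.
2. **Age association** (`ageswitch.age_assoc`) — per-cohort covariate-adjusted
   (residualize-then-rank-correlate) Spearman scans inside explicit age
   windows (defaults 20–55 and 51–86 years), Benjamini–Hochberg FDR, and a
   cross-cohort signature requiring sign consistency plus a mean-q threshold.
3. **Switch classification** (`ageswitch.switch_classify`) — labels signature
   transcripts GROUP1 (trajectory continues after the knot at 55 y), GROUP2
   (correlation falls to ~zero), or UNCLASSIFIED; per-decade coefficient-of-
   variation stochasticity controls and low-CV housekeeping detection across
   tissues.
4. **Concordance** (`ageswitch.concordance`) — cross-tissue direction
   agreement with an exact binomial test.
5. **Connectivity screening** (`ageswitch.connectivity`) — bidirectional
   normalized KS matching of an up/down query signature against compound
   reference rankings on a [−100, 100] scale, with hypergeometric
   compound-class enrichment among hits.
6. **Network & heritability** (`ageswitch.network_heritability`) —
   permutation-FDR-thresholded Spearman correlation network with degree-based
   hub statistics compared between coding and noncoding transcripts, and
   one-way ANOVA intraclass correlations over monozygotic twin pairs with a
   bootstrap contrast of mean ICC between biotype classes.

The generator (`ageswitch.synthetic`) plants known GROUP1 / GROUP2 / null /
housekeeping trajectories with covariate confounding, cohort batch shifts,
GC-biased multi-mapping probes, twin panels with biotype-specific
heritability, and compound libraries with planted mimics/opposers — every
output carries truth labels for recovery testing.

## CLI

One entry point with per-stage subcommands:

```sh
# full orchestrated run from a single YAML config (deterministic per seed)
ageswitch run --config configs/demo.yaml --seed 1 --out-dir runs/demo

# individual stages on files
ageswitch quantify --probes probes.fasta --transcriptome tx.fasta \
    --intensities intensities.tsv --out-dir out/ --gc-bins 10
ageswitch age-scan --expression expr.tsv --metadata meta.tsv \
    --window 20 55 --covariates vo2max,insulin_sensitivity --out-dir out/
ageswitch classify --signature signature.tsv --window2-results w2.tsv \
    --zero-band 0.1 --keep-min 0.2 --out-dir out/
ageswitch concordance --signature signature.tsv --other-results brain.tsv \
    --out report.json
ageswitch screen --query query.gmt --library library.tsv --out-dir out/
ageswitch network --expression expr.tsv --fdr 0.01 --permutations 10000 \
    --seed 1 --out-dir out/
ageswitch heritability --expression twins.tsv --pairs pairs.tsv \
    --annotation annotation.tsv --out-dir out/
```

`ageswitch run` writes `run_report.json` with per-stage parameters, output
file hashes, and headline numbers (signature size, GROUP2 fraction,
concordance fraction, hit counts, ICC difference). Runs with the same config
and seed are byte-identical.

## File formats

Everything is plain text: FASTA for transcriptome/probes, TSV for matrices
(first column = row id) and tables, a two-line GMT-like file for query
signatures (up line, down line), TSV compound libraries with comma-joined
rankings, JSON for reports. Expression values are log2; CV computations
convert to the linear scale internally.
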