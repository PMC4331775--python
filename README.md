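# dualsens

Dual-contrast transcriptome sensitivity analysis for hormone-response
studies: given expression arrays from a two-tissue, four-condition
castration design — sham-operated, castrated (cx), castrated +
testosterone (cx_T) and castrated + recombinant follistatin (cx_F) —
the package identifies which genes are **androgen sensitive**, which are
**follistatin sensitive**, and which biological processes are
over-represented in each set. It is aimed at analysts working with
probe-level microarray data (or any log2 expression matrix) who want a
fully scriptable, auditable version of this classic analysis, plus a
synthetic-data generator with planted ground truth for validating every
stage.

## The method

1. **RMA preprocessing.** Probe intensities are background-corrected
   under the normal-background + exponential-signal convolution model
   (`E[s | o]` with mode / half-normal / mean-exceedance parameter
   estimates), quantile-normalized so all arrays share one empirical
   distribution, log2-transformed, and summarized per probeset with
   Tukey's median polish.

2. **Moderated-t differential expression.** For each tissue and each
   contrast (cx vs sham, cx_T vs cx, cx_F vs cx) a two-group linear
   model gives the log2 fold change b, pooled variance s², scale
   u = sqrt(1/n₁+1/n₂) and residual df d. An empirical-Bayes scaled
   inverse-chi-square prior (s₀², d₀), estimated by digamma/trigamma
   moment matching across genes, shrinks the variances:

   s̃² = (d₀s₀² + d s²)/(d₀ + d),  t̃ = b/(u·s̃),  df = d₀ + d.

   Two-sided p-values are Benjamini–Hochberg adjusted; the adjusted
   value is reported as the q-value.

3. **Dual-contrast classification.** A gene is androgen sensitive iff
   q < 0.2 in *both* cx_vs_sham and T_vs_cx; follistatin sensitive iff
   q < 0.2 in both cx_vs_sham and F_vs_cx. Genes partition into
   uniquely-androgen / uniquely-follistatin / both / neither, summarised
   as Venn counts per tissue.

4. **GO over-representation.** Annotations are restricted to the
   biological_process branch, propagated to all is_a ancestors (so the
   root covers every annotated gene), and terms with more than 5 and
   fewer than 300 propagated genes are scored with the upper-tail
   hypergeometric test P(X ≥ x | n, m, k), BH-adjusted, and reported at
   adjusted p < e⁻³ by default.

The synthetic generator plants known condition effects (|δ| ∈ [0.5, 2]
log2 units) with a tissue-asymmetric structure — overlapping androgen
and follistatin programs in muscle, follistatin-inert prostate — so
recovery, error control and the qualitative muscle/prostate contrast are
all measurable against truth.

## Worked example

```python
import dualsens as ds

cfg = ds.PipelineConfig(synth_cfg=ds.SynthConfig(n_genes=2000),
                        out_dir="demo_run", seed=1)
result = ds.run_pipeline(cfg)          # simulate -> RMA -> DE -> classify -> enrich
print(ds.make_report(result))
```

prints (abridged):

```
dualsens run report
===================
seed: 1
q threshold: 0.2
GO term filter: count in (5, 300) exclusive
enrichment alpha (adjusted p): 0.0497871

[muscle]
  androgen-sensitive: 67   follistatin-sensitive: 59   both: 29
  ...
  enrichment[androgen]: 1 of 137 terms significant; top GO:9000000 (adj p = 1.07e-52)

[prostate]
  androgen-sensitive: 51   follistatin-sensitive: 1   both: 1
  ...
```

Muscle shows a large shared androgen/follistatin programme (29 of 67
androgen-sensitive genes also follistatin sensitive, ≈ the planted 46%
overlap), while in prostate the follistatin response is essentially
absent (1 gene vs 51 androgen-sensitive) — the tissue asymmetry the
method is designed to expose. The planted enriched term (GO:9000000)
tops every muscle gene-set enrichment. All stage outputs
(expression matrix, contrast tables, calls, Venn counts, enrichment
tables, `summary.json`, `report.txt`, the provenance `config.yaml`) are
tab-delimited files in `demo_run/`.

The same stages are available as CLI subcommands on plain files:

```bash
dualsens simulate --out sim --seed 1
dualsens preprocess --probes sim/probes.tsv --samples sim/samples.tsv --out expr.tsv
dualsens de --expr expr.tsv --samples sim/samples.tsv --tissue muscle --out de/
dualsens classify --de-dir de/ --tissue muscle --q 0.2 --out calls/
dualsens enrich --obo sim/ontology.obo --ann sim/annotations.tsv \
    --genes list.txt --min 5 --max 300 --alpha 0.0498 --out enrich.tsv
dualsens run --out full_run --seed 1
```

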