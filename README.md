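# cogepipe

Downstream transcriptomic analysis for stepwise tumor-progression series
(an ordered chain of cell lines with replicates, e.g. a parental oral-cancer
line and increasingly invasive derivatives):

* **differential** — per-gene parental-vs-derived Student t-tests on
  replicate FPKM values, Benjamini–Hochberg FDR correction within each pair
  (α = 0.05 by default), and direction labels from the derived/parental
  ratio: `< 0.8` DOWN, `[0.8, 1.2]` CONTINUUM, `> 1.2` UP, with
  zero-expression EXCLUSIVE labels taking precedence;
* **coge** — classification of every gene into one of 11 clusters of gene
  expression (CoGE) by crossing its regulation in two successive
  comparisons, plus a progression-consistency filter that reports genes
  carrying the identical label through the whole series (biomarker
  candidates);
* **hallmarks** — mapping pathway gene sets (GMT) and a pathway→hallmark
  table onto the 8+2 cancer hallmarks, then scoring each hallmark's
  absolute (shared pathway/gene counts) and relative (per-CoGE percentage)
  contribution to a reference hallmark (invasion & metastasis), with
  Fig.-3-style aggregation and ranking;
* **synthetic** — a simulator with planted DOWN/UP/CONTINUUM/exclusive/null
  genes and lognormal replicate noise, so the whole pipeline is testable
  offline with known ground truth;
* **fixtures** — the published worked-example tables (the 26-gene FPKM
  matrix and the hallmark-contribution percentage grid) packaged with
  checksums.

## CLI

```sh
# generate a synthetic 5-line x 7-replicate dataset with ground truth
cogepipe simulate --outdir sim/ --seed 1

# run the full pipeline (hallmark inputs optional)
cogepipe run --expr sim/expression.tsv --samples sim/samples.tsv \
    --gmt sim/pathways.gmt --hallmarks sim/hallmark_map.tsv \
    --alpha 0.05 --mode p --outdir results/

# materialize a packaged fixture
cogepipe fixtures table3 --outdir fixtures/
```

`run` writes `deg_table.tsv`, `coge_table.tsv`, `consistent_genes.tsv`,
`contributions_absolute.csv`, `contributions_relative.csv`,
`contributions_summary.csv` and `summary.json` (config echo, version and
per-stage counts). Result tables are byte-deterministic for identical
inputs. Key flags: `--mode {p,q}` selects raw-p or FDR-corrected DEG
calling, `--ratio-low/--ratio-high` move the fold-change thresholds,
`--continuum-requires-prev` makes CONTINUUM cluster membership require DEG
status in the predecessor comparison too, and `--min-expression` restricts
the tested (and BH-corrected) gene family.

Expression input is a TSV with a `gene_id` column followed by sample
columns, plus a sample sheet (`sample_id`, `cell_line`, `replicate`,
optional `line_order`). Decimal commas in expression values are accepted
and normalized.

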