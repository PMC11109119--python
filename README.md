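# crcith

Intra-tumor heterogeneity scoring and heterogeneity-robust consensus
subtyping for multiregional colorectal cancer (CRC) transcriptomics.

## The problem

Bulk transcriptomic classifications of CRC — most prominently the four
consensus molecular subtypes (CMS) — are built from single tissue
samples, yet tumors are spatially heterogeneous: different regions of
one tumor can classify as different subtypes, largely because stromal
infiltration varies across regions. This compromises the biomarker
value of single-sample subtyping. With multiregional samples one can
(i) quantify, gene by gene, how much expression varies *within* versus
*between* tumors, (ii) call subtype heterogeneity from a single bulk
sample, and (iii) rebuild subtypes from the genes that are uniform
across tumor regions, yielding classifications robust to heterogeneity.

`crcith` implements that pipeline for analysts working with log2-scale
gene × sample expression matrices plus a sample sheet linking samples
to tumors and patients:

* **ITH scoring** — per gene, a one-way random-effects model with tumor
  as the grouping factor gives the intraclass correlation
  `ICC = σ_t² / (σ_t² + σ_e²)` and the ITH score `1 − ICC`; genes are
  filtered on the 10–90th percentile expression range (> 1) and
  categorised low / intermediate / high.
* **Single-sample CMS heterogeneity** — per-class template gene sets
  from one-vs-rest moderated t-tests (BH-adjusted p < 0.001,
  |log2FC| > 1); a rank-based enrichment score in [0, 1] per template
  with a sample-specific permutation null; a sample with more than one
  significant class (p < 0.05) is heterogeneous, with none it is
  unclassified.
* **Nearest-template prediction** — cosine distance of the z-scored
  profile to signed class templates, permutation p, BH-FDR < 0.05.
* **Consensus NMF subtyping** — KL-divergence NMF (multiplicative
  updates) on anti-logged expression restricted to ITH-low genes, over
  ranks 2–10 with repeated random starts; consensus, cophenetic and
  silhouette diagnostics; the rank preceding the first large drop is
  selected; clusters are mapped onto a reference framework by Hungarian
  assignment.
* **Survival analysis** — Kaplan–Meier, log-rank, Cox proportional
  hazards (Efron ties, Schoenfeld PH check) and a per-covariate
  explained-variation partition of the likelihood-ratio pseudo-R²
  `1 − exp(−LR/n)` with bootstrap intervals.
* **Synthetic cohorts** — a generator with planted variance structure,
  subtypes, subtype mixtures, a stromal confounder, MSI labels and
  survival, so every stage has a recoverable ground truth.

See `docs/methods.md` for the models, assumptions and numerical
choices.

## Worked example

Simulate a multiregional cohort, score gene-wise heterogeneity, and
discover subtypes on the ITH-low genes:

```bash
crcith simulate --seed 7 --out cohort/
crcith ith-score --expr cohort/expression.tsv --sheet cohort/samples.tsv \
    --out cohort/ith.tsv
```

which prints the per-gene category tally (555 flat genes fail the
expression-range filter; the retained genes split into the three
heterogeneity categories):

```
categories: {'low': 695, 'intermediate': 679, 'not_scored': 555, 'high': 71}
```

Continuing in Python:

```python
import pandas as pd
from crcith import io, nmf

cohort = io.join_cohort(io.read_expression("cohort/expression.tsv"),
                        io.read_sample_sheet("cohort/samples.tsv"))
ith = pd.read_csv("cohort/ith.tsv", sep="\t", index_col=0)
low = ith.index[ith["category"] == "low"]

expr = cohort.expr.subset_genes(low)
models = nmf.consensus_scan(nmf.antilog(expr), range(2, 7),
                            expr.sample_ids, n_runs=20, seed=3)
print(nmf.select_rank(models))
for k, m in models.items():
    print(k, round(m.cophenetic, 3), round(m.mean_silhouette, 3))
```

```
4
2 1.0 1.0
3 1.0 0.997
4 0.993 0.953
5 0.99 0.793
6 0.985 0.755
```

The diagnostics stay near ceiling up to rank 4 — the number of planted
subtypes — and the silhouette drops sharply beyond it, so rank 4 is
selected; the rank-4 labels recover the planted subtypes exactly on
this cohort (adjusted Rand index 1.0, versus ≈ 0 when the same
clustering is run on ITH-high genes, which carry the stromal
confounder instead of subtype signal).

## CLI

`crcith --help` lists the subcommands: `simulate`, `ith-score`,
`derive-templates`, `score-samples`, `classify-ntp`,
`summarize-tumors`, `nmf`, `survive`. Each is a thin wrapper over the
library modules (`crcith.ith`, `crcith.signatures`,
`crcith.multiregion`, `crcith.nmf`, `crcith.survival`,
`crcith.simulate`, `crcith.io`).
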