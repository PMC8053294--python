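# diaflux

Downstream functional interpretation of bulk RNA-seq differential-expression
results: impact/flux scoring of KEGG-style pathways and transcription-factor
(TF) regulons, Activated/Inhibited state calls, over-representation testing
with Benjamini–Hochberg FDR control, and multi-level pathway network
assembly. The package is aimed at transcriptomics analysts who already have
an edgeR/DESeq2-style statistics table (gene, log2 fold-change, P, FDR) and
want to rank *which* pathways and upstream regulators changed, *how much*,
and *in which direction*.

## The scores

Differentially expressed genes (DEG) are the genes with FDR ≤ a cutoff
(0.10 by default; a stricter 0.05 summary is reported alongside). For a gene
set with background *B* (members present in the analyzed universe) and DEG
subset *D = B ∩ DEG*:

- proportion  π = |D| / |B|
- magnitude  m = mean over D of |log2FC|
- significance  s = mean over D of −log₁₀ P
- **impact**  I = 100 · π · m · s  — the set's biological importance
- direction  d = Σ_D log2FC / Σ_D |log2FC| ∈ [−1, 1]
- **flux**  F = I · d — signed impact; positive = activation, negative =
  inhibition. |F| ≤ I always, with equality exactly when the set's DEG share
  one fold-change sign.

Pathway scores are averaged over a pathway → subcategory → category
hierarchy and ranked into top up-/downregulated lists. TF regulons are
additionally tested for DEG over-representation with the one-sided
hypergeometric tail (conditioning on the analyzed universe), BH-adjusted
across the whole library; each regulon surviving FDR ≤ 0.05 gets an impact,
a flux, and a **predicted state** from the flux sign (Activated / Inhibited /
Indeterminate at exactly zero). Finally, seed pathways of interest are
expanded breadth-first through a pathway-link graph (seeds at level 0), DEG
attach via membership edges and significant TFs via regulation edges,
yielding a TF → gene → pathway tri-partite network exported as
nodes.tsv/edges.tsv.

## Worked example

The package ships a seeded generator of synthetic cohorts (an edgeR-shaped
table over 10,000 genes with 50 gene sets, 5 planted activated + 5 planted
inhibited) so the whole chain runs without any download:

```sh
python analysis/01_simulate_cohort.py     # writes results/sim_inputs/
python analysis/02_pathway_impact.py
python analysis/03_tf_state.py
python analysis/04_network.py
```

Output of the first two steps (seed 11):

```
FDR <= 0.05: 326 DEG (164 up, 162 down) of 10000 genes
FDR <= 0.10: 348 DEG (175 up, 173 down) of 10000 genes
...
most impacted category: catB (I=185.5, F=+4.0), catA (I=178.2, F=+1.0)
top upregulated pathways: set004 (I=848.3), set003 (I=845.3), set002 (I=828.2), ...
```

and the regulon state report (step 3):

```
10 regulons significant at FDR <= 0.05
  rank  1  set001  I= 696.22  F= +696.22  Activated     p=3.10e-40  FDR=3.10e-39
  ...
planted sets recovered: 10/10; direction calls correct: 10/10
```

348 of 10,000 genes (3.5%) pass FDR ≤ 0.10; all ten planted regulons are
recovered at FDR ≤ 0.05 and every flux sign matches the planted direction —
positive flux for the five activated sets, negative for the five inhibited.

The same chain is available as a CLI (`diaflux simulate|score-pathways|
tf-state|network|run`) and as one call, `diaflux.run_pipeline(PipelineConfig(...))`,
which writes all stage outputs plus a provenance manifest (config, input
checksums, package version) and is byte-identical on rerun.

To analyze real data instead, provide the four inputs: the DE statistics
TSV (`gene_id`, `log2fc`, `pvalue`, `fdr`), GMT libraries for pathways
and/or regulons, a pathway hierarchy TSV, and a pathway-link edge TSV.

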