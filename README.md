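# spermsurf

Label-free quantitative analysis of sperm surface proteomes, aimed at
nominating sex-chromosome-linked, surface-accessible transmembrane
proteins as candidate markers that distinguish X-chromosome-bearing from
Y-chromosome-bearing spermatozoa.

## Scientific problem

Sexed semen is produced by sorting X- from Y-bearing sperm, which today
relies on DNA content. An immunological alternative requires a protein
that is (i) exposed on the cell surface, so an antibody can reach it in
a live cell, and (ii) present on X-bearing sperm but absent from
Y-bearing sperm. A cell-surface-biotinylation LC-MS/MS experiment
produces label-free quantification (LFQ) intensities for four sample
groups: unsorted sperm (`BU`), X-sorted sperm (`BX`), Y-sorted sperm
(`BY`), and a no-biotin control (`BC`), each in replicate. This package
takes such protein-group intensity tables and turns them into a ranked
list of candidate marker proteins, with the statistical and annotation
steps needed to defend each call.

## What the pipeline does

1. **Ingest.** Read a protein-groups table (MaxQuant-style columns,
   `LFQ intensity <sample>`; zero means *not quantified*), drop decoy
   and contaminant entries, log2-transform, and keep proteins with at
   least two quantified replicates in some non-control condition.
2. **Imputation.** Missing values in sperm samples are treated as
   censored at the detection limit and drawn from a per-sample
   downshifted normal: mean `μ_s − 1.8·σ_s`, width `0.3·σ_s`.
3. **Differential abundance.** Empirical-Bayes moderated *t*-tests per
   contrast (`BU−BX`, `BU−BY`, `BX−BY`). Per-protein variances `s_g²`
   are shrunk toward a prior `(d₀, s₀²)` estimated by moment matching
   on log variances:
   `s̃_g² = (d₀·s₀² + df_g·s_g²)/(d₀ + df_g)`, with
   `t = Δ / (s̃_g·√(1/n₁+1/n₂)) ~ t(df_g + d₀)`.
   P-values are Benjamini–Hochberg adjusted; a protein is significant
   when `p_adj < 0.05` **and** `|log2FC| ≥ 2`.
4. **Detection profiling.** From the observed (pre-imputation) mask:
   per-condition replicate counts, a `BU/BX/BY` Venn partition,
   condition-exclusive sets, and a z-scored, hierarchically clustered
   heatmap matrix.
5. **Annotation and topology.** Gene Ontology cellular-component terms
   are mapped to surface-evidence categories; membrane topology comes
   from predicted classes (`TM`, `SP+TM`, `GLOB`, `SP`, `BETA`,
   `SP+BETA`) with per-residue segment strings.
6. **Candidate selection.** A protein is *surface accessible* if it has
   a direct surface GO category, or a membrane GO category together
   with supporting topology (a TM region or a predicted outside
   segment), or an extracellular GO category together with a TM region.
   *Accessible* candidates are additionally detected in ≥1 `BX`
   replicate and 0 `BY` replicates; *prioritized* candidates further
   require ≥2 `BX` replicates and ≥1 transmembrane region.
7. **Extras.** GO overrepresentation (two-sided Fisher exact with
   Bonferroni correction) and an affine-gap global protein aligner
   (BLOSUM62, gap cost `open + (L−1)·extend`) for comparing the
   extracellular segments of orthologous candidates.

A synthetic-data generator (`spermsurf simulate`) produces realistic
datasets with planted ground-truth markers, detection-limit censoring,
decoys and contaminants, and a truth ledger, which drives the test
suite and the acceptance script.

## Worked example

The package ships a 19-protein curated candidate panel
(`spermsurf.datasets.EXAMPLE_CANDIDATES`) with detection profiles,
surface annotation, and topology calls. Running the selection engine on
it:

```python
from spermsurf.datasets import example_engine_inputs
from spermsurf.targets import call_targets

profiles, interest, topo = example_engine_inputs()
calls = call_targets(profiles, interest, topo)
print(f"{sum(c.is_transmembrane for c in calls)} transmembrane of {len(calls)}")
for c in sorted(calls, key=lambda c: (c.tier != "prioritized", c.protein_id)):
    if c.tier == "prioritized":
        print(f"{c.protein_id:10s} tier={c.tier:11s} TM={c.is_transmembrane}")
```

prints

```
7 transmembrane of 19
D3K0R6     tier=prioritized TM=True
F1N3G6     tier=prioritized TM=True
O77780     tier=prioritized TM=True
Q03763     tier=prioritized TM=True
Q3MHW6     tier=prioritized TM=True
```

i.e. 7 of the 19 panel proteins are transmembrane and 5 survive the
prioritized tier (detected in ≥2 X-sorted replicates, never in
Y-sorted, surface accessible, ≥1 TM region). The remaining accessible
proteins fail either the TM requirement or the replicate requirement —
e.g. `Q3T0C6` is transmembrane but was detected in only one X-sorted
replicate, so it stays in the `accessible` tier.

The same works end to end from the command line on synthetic data:

```
$ spermsurf simulate --out-dir demo/data --seed 7
$ spermsurf run --config demo/run.yaml
{"n_retained": 482, "n_prioritized": 5, "out_dir": "demo/out"}
$ head -6 demo/out/target_report.tsv | cut -f1-6
protein_id  gene_name  chromosome  x_linked  tier         surface_accessible
SYNP0000    GENE0000   14          False     prioritized  True
SYNP0001    GENE0001   23          False     prioritized  True
SYNP0002    GENE0002   17          False     prioritized  True
SYNP0003    GENE0003   24          False     prioritized  True
SYNP0004    GENE0004   19          False     prioritized  True
```

where `demo/run.yaml` lists the four input paths, `out_dir`, and
`seed` (see `spermsurf.pipeline.RunConfig` for all keys). The five
prioritized proteins are exactly the five planted X-specific
surface-transmembrane markers recorded in the generator's truth ledger.

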