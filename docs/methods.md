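# Methods

This note records the statistical model, the rules, the default
parameters, and the numerical choices behind `spermsurf`, together with
the reasoning for each.

## Data model and ingest

Input is a protein-groups table in the common label-free search-engine
layout: one row per protein group, identifier columns
(`Majority protein IDs`, `Gene names`, `Chromosome`), decoy and
contaminant flags (`Reverse`, `Potential contaminant`), and one
`LFQ intensity <sample>` column per run. An intensity of zero means
*not quantified*, not *zero abundance*; ingest maps zeros to missing
and log2-transforms the rest. Sample names encode the condition as
their leading alphabetic run (`BX_2` → condition `BX`); `BC` is the
no-biotin control.

Filtering keeps a protein if it has at least `min_valid = 2` quantified
replicates in at least one non-control condition. Two is the smallest
count that distinguishes reproducible detection from a one-off
identification; the control is excluded because proteins seen only
there are labelling background.

## Missing values

Missingness in this kind of experiment is dominated by the detection
limit (missing not at random), so mean- or zero-imputation would bias
fold changes upward. Missing values in non-control samples are instead
drawn from a per-sample downshifted normal,

    x ~ N(μ_s − shift·σ_s, (width·σ_s)²),  shift = 1.8, width = 0.3,

where μ_s and σ_s are the observed mean and SD of sample *s*. This
places imputed values in the lower tail of each sample's intensity
distribution, which is where censored observations live. The shift and
width defaults are the values commonly used with this imputation family
and are exposed as parameters. The control condition is left missing:
it enters detection profiling, never the statistics. The observed mask
is retained so that every detection-based decision ignores imputed
cells.

## Differential abundance

Per-protein residual variances `s_g²` (pooled across non-control
conditions, residual df `df_g = Σ(n_c − 1)`) are assumed to follow a
scaled inverse-χ² prior with df `d₀` and scale `s₀²`. The prior is
estimated by moment matching on `log s_g²`: the excess variance of
`log s_g²` over the known sampling variance `ψ′(df_g/2)` determines
`d₀` through the inverse trigamma function (Newton iteration on
`ψ′(d₀/2) = excess`), and `s₀²` follows from the mean. If the observed
spread does not exceed the sampling spread the prior df is infinite and
every protein receives `s₀² = mean(s_g²)`.

The moderated statistic for contrast (A, B) is

    s̃_g² = (d₀·s₀² + df_g·s_g²)/(d₀ + df_g)
    t_g  = (mean_A − mean_B) / (s̃_g·√(1/n_A + 1/n_B)),   t_g ~ t(df_g + d₀),

with the Student reference collapsing to normal at infinite df and to
the ordinary two-sample pooled *t* at `d₀ = 0` (accepted as the
explicit no-moderation limit). P-values are two-sided,
Benjamini–Hochberg adjusted per contrast, and a protein is called
significant when `p_adj < 0.05` (strict) **and** `|log2FC| ≥ 2`. The
fold-change floor keeps statistically significant but biologically
small differences out of the candidate list. The implementation is
hand-written because the shrinkage estimator is central to the package;
it is cross-checked in the tests against `scipy.stats.ttest_ind`
(at `d₀ = 0`) and against R `limma::eBayes` on the same matrices.

## Detection profiling

All presence/absence reasoning uses the pre-imputation observed mask.
For each protein: per-condition replicate counts, the eight-region
partition of `BU/BX/BY` detection (Venn), and derived exclusive sets
(detected only in `BX`, absent from `BY`, etc.). The heatmap matrix
contains the union of significant and condition-exclusive proteins,
row-z-scored (ddof 1) and ordered by average-linkage hierarchical
clustering on Euclidean distances (scipy); rows with fewer than two
finite values or zero spread are excluded with a warning rather than
silently dropped.

## Annotation and topology

Cellular-component GO terms are mapped to evidence categories:
plasma-membrane (`PM`, `ICPM`, `ACPM`), cell-surface (`CS`, `ESPM`,
`ECESPM`, `ACESPM`, `ICESPM`, `ESCW`, `ESCOM`), and extracellular-space
(`ES`). Annotation may come from more than one source (e.g. a curated
database and an orthology-transfer tool); GO sets are unioned per
protein and validated against the `GO:0000000` syntax. A protein with
only `ES` evidence is *of interest* only if it is also transmembrane —
a secreted protein in the extracellular space is not a sortable surface
marker.

Topology uses per-protein predicted classes (`TM`, `SP+TM`, `GLOB`,
`SP`, `BETA`, `SP+BETA`) with per-residue segment strings (signal
peptide / inside / outside / α-helical membrane / β-strand membrane),
read either from a three-line text format or a tabular one. A protein
is *transmembrane* if its class includes a membrane-spanning component
and it has ≥1 membrane region.

## Candidate selection

Surface accessibility is a three-way disjunction:

1. any direct cell-surface category; or
2. a plasma-membrane category **and** supporting topology (≥1 TM
   region or a predicted outside segment); or
3. extracellular-space evidence **and** ≥1 TM region.

Tiers, evaluated on observed detection only:

- **accessible** — surface accessible, detected in ≥1 `BX` replicate
  and 0 `BY` replicates;
- **prioritized** — additionally ≥2 `BX` replicates and transmembrane.

Any detection in `BY` vetoes candidacy outright: a marker seen on
Y-bearing sperm cannot separate the populations regardless of fold
change. The direction is a parameter, so the same engine nominates
Y-specific candidates by swapping `BX`/`BY`. Proteins missing a
topology record default to globular with a warning — absence of a
prediction must not manufacture a transmembrane call.

## Enrichment and cross-species alignment

Overrepresentation of annotation terms in a protein set against a
background uses the two-sided Fisher exact test (scipy) with Bonferroni
correction and fold enrichment `FE = (k/n)/(K/N)`. The tests verify
scipy's p-values against an exact rational hypergeometric summation.

Candidate comparison across species uses a hand-written global
affine-gap aligner (Needleman–Wunsch/Gotoh, three-matrix DP) with
BLOSUM62 and gap cost `open + (L−1)·extend` (defaults 10 / 0.5).
Traceback ties resolve deterministically (match > gap-in-query >
gap-in-subject) so outputs are reproducible. Segment similarity
projects the whole-sequence alignment onto predicted outside segments
and reports per-segment identity — the regions an antibody could
actually bind. The aligner is validated against exhaustive alignment
path enumeration on short sequences and against Biopython's
`PairwiseAligner` scores.

## Synthetic data generator

The generator emulates the quantitative structure of a
surface-biotinylation LFQ experiment:

- protein mean `m_g ~ N(base, between²)` with `base = 25`,
  `between = 2` (log2 units, typical LFQ dynamic range);
- group variance `σ_g² ~ scaled-inv-χ²(d₀ = 4, s₀ = 0.5)`, matching the
  prior family the analysis assumes so that prior recovery can be
  tested against ground truth;
- replicate `x ~ N(group mean, σ_g)`; 3 replicates per condition;
- detection-limit censoring: a value is missing with probability
  `expit((DL − x)/softness)`, `DL = 22`, `softness = 0.5`, using common
  random numbers so that lowering a mean can only increase missingness;
- the control condition is entirely missing (no biotin, no capture);
- planted markers (default 8, of which 5 are transmembrane and
  surface-annotated) get `+4` log2 in `BX` and a `BY` mean pushed far
  below the detection limit, so truth is "present on X-sorted, absent
  from Y-sorted";
- decoy (`REV…`) and contaminant (`CONT…`) rows, annotation leakage
  (5% of background proteins get a decoy surface term), and a truth
  ledger with every latent variable.

It does **not** emulate peptide-level identification, match-between-runs
correlation structure, ionization competition, or shared-peptide
protein-group ambiguity; means and variances are protein-level.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline derives stage seeds from the run seed, and derived seeds are
  kept below 2³¹.
- Tables are written with fixed float formatting (`%.6f`), so identical
  seeds yield byte-identical output files; the run manifest records
  parameters and SHA-256 checksums of all inputs.
- Heatmap leaf order comes from scipy's dendrogram ordering; identical
  rows are adjacent but the global order is scipy's deterministic
  convention rather than a bespoke tie-break.
- Inverse trigamma uses Newton iteration from the asymptotic start
  `d ≈ 2/excess`, converging in a handful of steps for all realistic
  inputs.

## Problem sizes and limitations

Defaults target desk-scale datasets: ~500–5000 proteins, 4 conditions
× 3 replicates. The moderated-test chain is vectorized and handles
these sizes in well under a second; the generator, full pipeline, and
acceptance script run in seconds. Known limitations: two-group
contrasts only (no general design matrices), a single pooled variance
per protein (no per-condition variance modelling), imputation assumes
roughly normal per-sample intensity distributions, and the selection
rules are deliberately hard-threshold — a protein detected once in
`BY` is vetoed even if that detection is marginal. These are the
trade-offs of an interpretable, auditable candidate list.
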