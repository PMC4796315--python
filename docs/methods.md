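# Methods

## Model and selection cascade

A sponge pair is a lncRNA *L* and a protein-coding gene *G* whose
transcripts carry MREs for many common miRNA seed families and whose
expression co-varies positively across tumours. The pipeline scores
every lncRNA × driver-gene pair with:

* **Shared-family enrichment (P₁).** With a universe of *N* usable
  families, *m* targeting the lncRNA, *n* targeting the PCG and *k*
  shared, P₁ = P(X ≥ k) for X ~ Hypergeom(N, n, m) — the one-tailed
  Fisher's exact test on target/non-target membership. The universe is
  the conserved, expression-filtered family set (families flagged
  non-conserved or outside the top-50% expression tier are excluded from
  profiles and from N).
* **Co-expression (P₂, r).** One-tailed Pearson test (H₁: ρ > 0) via the
  exact t transform t = r√((n−2)/(1−r²)) on n−2 df, computed over
  tumour samples only (primary + metastatic; configurable). Restricting
  to tumours avoids spurious correlation induced by a common
  normal-vs-tumour shift.
* **Combination.** Fisher's method for two tests:
  χ² = −2(ln P₁ + ln P₂), P_comb = exp(−χ²/2)(1 + χ²/2) (the closed-form
  df = 4 upper tail). P₁ and P₂ are treated as independent — sequence
  and expression are separate data sources.
* **FDR.** Benjamini–Hochberg, computed once over the full scored pair
  list (never per gene). Pairs sharing zero families stay in the pool
  with P₁ = 1 so the denominator is well defined. BH ties break by
  stable input order (sorted lncRNA, then gene ID), making runs
  reproducible.

Filters: q ≤ `fdr_threshold` (0.05); shared-count rule
(≥ `min_shared_mirnas` = 10 member miRNAs over the shared families, and
≥ `min_unique_sites` = 8 unique site intervals); replication
(r ≥ `min_replication_r` = 0.25 in **every** cohort, discovery
included). The cascade is a pure conjunction: relaxing any one filter
can only add edges.

Two contracts were genuinely open and are resolved as package defaults,
both configurable:

* the "≥ 10 shared miRNAs" threshold counts *member miRNAs* of the
  shared families, not families (`shared_count_unit`);
* the "≥ 8 unique sites" rule applies to
  min(sites on lncRNA, sites on PCG) (`site_count_rule`: `min`, `lnc`
  or `sum`) — the strictest symmetric reading, since the source
  procedure does not say on which transcript sites are counted.

The replication gate requires r ≥ 0.25 in both cohorts rather than in
the non-discovery cohort only; "two independent clinical cohorts" is
read as both.

Driver pre-filtering (`select_driver_genes`) keeps genes with two-tailed
Mann–Whitney p ≤ `alpha_de` (0.01) for normal-vs-primary *or*
primary-vs-metastatic; either contrast qualifies.

## Site annotation

The built-in matcher calls canonical seed sites only: on the sense
strand of a transcript (DNA alphabet, U→T on input, 0-based half-open
coordinates), an 8mer is revcomp(seed 2–8) + A, a 7mer-m8 is
revcomp(seed 2–8), a 7mer-A1 is revcomp(seed 2–7) + A. A 7mer-A1 nested
inside an 8mer (same end) is suppressed, so each locus is reported once
with its strongest type. This is a deliberate simplification — no
context scoring, conservation branch lengths, 6mers or non-canonical
sites — sufficient for self-contained end-to-end runs; externally
predicted site tables are imported through the same profile
representation (`import_site_table`), with unknown-family rows dropped
and counted.

Gene-level aggregation takes the transcript with the maximum total site
count (ties broken by transcript ID) rather than the union across
isoforms, which would double-count overlapping sites. lncRNA profiles
are annotated on the whole transcript, PCG profiles on the 3′UTR (the
sequence supplied for a PCG is assumed to be its 3′UTR).

## Synthetic cohorts

`simulate_catalog_and_sites` + `simulate_expression` generate the study
conditions end to end. Defaults (the standard design): 60 families with
1–3 members each, 30 lncRNAs × 10 PCGs, 5 planted pairs with K = 12
disjoint shared families and ≥ 8 unique planted sites per gene, two
cohorts of 150 samples (50 normal / 50 primary / 50 metastatic),
repression coupling β = 0.8, noise SD 1.0 (log2 units), tumour state
shift +2.0, copy-number loss in 30% of tumour samples with effect −1.5
on one designated focal gene.

Expression follows
`x[g,s] = μ_g + shift·1[tumour] + cn_effect[g,s] − β·Σ_f min(S[g,f],4)·a[f,s] + ε`,
with per-cohort i.i.d. family activities a ~ N(0,1) and ε ~ N(0, σ²).
Repression linear in the capped site count is a deliberate
simplification of titration kinetics; the cap at 4 sites bounds the
dynamic range. Activities are latent and never emitted, because the
inference itself uses no measured miRNA expression. Baselines
μ_g ~ N(8, 1) log2 units, typical of array intensities.

Choices worth noting:

* Planted family blocks are **disjoint across pairs**. Shared blocks
  would couple different planted pairs through common activities and
  make cross-pair edges *correct* rather than false, destroying the
  precision benchmark's meaning; a design requesting more disjoint
  families than the catalog holds is rejected.
* Background gene–family assignment is sparse (probability 0.05 per
  gene × family), so non-planted pairs share families only by chance.
* Copy-number loss affects a single designated focal gene with its own
  loss-sample draw, matching a per-sample `cn_status` metadata column;
  a shared loss indicator across many genes would induce spurious
  gene–gene correlation.
* All draws are keyed per entity (gene/family/cohort), so enlarging a
  design leaves existing genes' draws untouched, and identical
  (design, seed) gives bit-identical outputs.

What the simulation does **not** emulate: probe-level array noise,
isoform mixtures, non-Gaussian expression, miRNA–miRNA interactions,
transcription-factor confounding, and realistic genome-scale pair
counts. Passing recovery tests therefore demonstrate correctness of the
procedure under its own model assumptions, not performance on real
tumour data.

## Numerical choices

* p-values are floored at the smallest positive double (≈ 4.9e−324) so
  Fisher's method never takes log 0; they are never reported as 0.
* Constant expression vectors make Pearson r undefined; such pairs are
  skipped with a warning (discovery) or get r = NaN for that cohort
  (replication), and NaN never passes the replication gate.
* Mann–Whitney uses the exact null when min(n₁, n₂) ≤ 8 and the pooled
  sample is tie-free, else the normal approximation with tie and
  continuity corrections.
* The shared-family test is discrete: at small universe sizes its
  attainable p-values are coarse and the test is conservative
  (type-I error below nominal). Calibration is therefore benchmarked in
  a dense-lattice regime (universe 5000, margins ~ Binomial(N, ½)),
  where the empirical size matches α within Monte-Carlo error; at small
  N only conservatism is guaranteed.
* Floats are serialised with 12 significant digits; reader/writer pairs
  round-trip to that precision.

## Benchmark problem sizes

Recovery: median precision/recall over 25 seeds of the standard design.
Null: 100 seeds with β = 0 (sites planted, expression decoupled), where
the FDR and replication gates jointly yield zero edges in ≥ 95% of
runs. Type-I calibration: 10,000 replicates per test. These sizes give
Monte-Carlo standard errors small relative to the asserted margins.

## Known limitations

* The matcher's canonical-site-only model under-calls real TargetScan
  sites; quantitative site counts on real transcripts should come from
  imported prediction tables.
* The replication gate uses a fixed r threshold, not a test with a
  cohort-size-dependent critical value; small cohorts make r ≥ 0.25 a
  weak guarantee.
* Fisher's method assumes P₁ ⊥ P₂; on real data, expression-dependent
  annotation universes could violate this.
* The packaged per-gene count table is a published-summary fixture for
  the summarization path; the package does not re-derive that network
  from raw arrays.
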