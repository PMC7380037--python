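# Methods

This note documents the models, rules and numerical choices behind
`trophodiet`, in the order data flows through the pipeline.

## Data model

The pipeline's single currency is the `MotuTable`: a non-negative
integer read-count matrix (MOTU × sample) joined to per-MOTU taxonomy
(assignment rank, kingdom…species path, best-identity score of the
reference-database match) and per-sample metadata (sample type —
stomach, sediment, empty stomach or PCR-negative control — site,
estuary, country, and the number of stomachs pooled into the sample,
1–8).  Counts are always integers; relative abundances are derived on
demand and never stored, so there is one source of truth.  Construction
validates all invariants (key agreement across the three frames,
non-negative integral counts, sample types from the closed vocabulary,
one estuary per site) and fails loudly rather than dropping anything.
Files are read and written as a tab-separated UTF-8 trio
(`*_counts.tsv`, `*_taxonomy.tsv`, `*_metadata.tsv`), the dialect the
obitools-style metabarcoding toolchain produces; archived datasets with
different column names should be renamed to this canonical layout
before loading.

Empty-stomach samples are carried as a sample type but excluded from all
diet statistics: they are comparative controls for what a "digested
background" looks like, not diet observations.

## Filter cascade

Stages run in a configurable order; the default is

1. **merge_species_motus** — MOTUs assigned at species rank to the same
   species name are summed cell-wise; the record with the highest best
   identity represents the merged MOTU.  Genus-level co-assignments are
   *not* merged: two genus-only MOTUs may be distinct congeners.  Reads
   are conserved exactly.
2. **renormalize_tag_switching** (threshold 0.01) — for each MOTU,
   every cell strictly below threshold × (that MOTU's total reads) is
   zeroed.  This is the standard per-MOTU tag-jump correction: library
   cross-talk leaks a small, roughly constant fraction of a template's
   reads into other samples, producing low-count false positives whose
   size scales with the MOTU's own total.  A MOTU occupying a single
   cell is a fixed point.  *Limitation:* with `n` samples, an evenly
   spread MOTU has mean cell share 1/n; at ~100 samples a 1% threshold
   sits exactly at that share and will zero legitimate occurrences of
   uniformly distributed taxa.  The rule is therefore only appropriate
   when communities turn over between sites (the usual field
   situation); the threshold is exposed in `FilterConfig`.
3. **remove_contaminants** — whole-MOTU removal by taxonomy predicates
   (`rank` = field, `name` = value); defaults: kingdom Bacteria, and a
   human blacklist (*Homo sapiens*).  Terrestrial taxa can be added as
   further rules.
4. **min_reads_filter** (threshold 5) — cells with four or fewer reads
   are zeroed sample-by-sample; rows that become all-zero are dropped.
   The alternative reading of the rule — removing whole MOTUs whose row
   maximum is below the threshold — is available via
   `min_reads_mode="motu"`; cell-level action is the default because
   the rule is a per-sample noise floor, not a global prevalence test.
5. **negative_control_filter** (threshold 0.10) — a MOTU is removed
   from all samples when strictly more than 10% of its reads fall in
   PCR-negative controls; exactly 10% is retained.  Control columns are
   consumed by this stage and never reach diet statistics.
6. **remove_focal_taxa** — the consumer's own reads (and, by default,
   the ubiquitous stomach fungus *Purpureocillium lilacinum*) are
   removed by species-name match; the report records each sample's
   pre-removal focal read proportion, the classic predator-read
   fraction summary.  A name matching nothing warns rather than fails,
   so one configuration can serve partially overlapping datasets.
7. **sample_depth_filter** (threshold 1,000, scope = stomach) — stomach
   samples with strictly fewer than 1,000 remaining diet reads are
   dropped.  The rule runs after focal removal so depth measures diet
   reads, not consumer DNA.  Afterwards, sediment samples whose site no
   longer has any stomach sample are dropped too
   (`drop_orphan_sediment`): they can no longer enter any paired
   statistic.

All inequality directions are deliberate: strict `<`/`>` where the rule
is phrased as "below"/"higher than", inclusive zeroing for "four or
fewer".  Every stage emits a `StageRecord`; the concatenated
`FilterReport` must reconcile exactly — `reads_in − reads_out` equals
the enumerated removed reads at every stage, and stage k's input equals
stage k−1's output.  Threshold stages are idempotent; no stage ever
increases a cell.

## Selectivity and trophic significance

Jacobs' index `D = (r − p)/(r + p − 2rp)` is computed per
(stomach, paired sediment) pair from that pair's relative abundances;
pairing maps each stomach sample to the single pooled sediment sample of
its site.  Pairs with `r = p = 0` carry no information (0/0) and are
excluded rather than imputed; a MOTU with no informative pair is flagged
(`n_pairs = 0`, `D = NaN`) instead of propagating NaN arithmetic.  The
per-MOTU summary is the mean over informative pairs with the sample
standard error (SD/√n; 0 when n = 1).  The result is clipped to [−1, 1]
to absorb one-ulp floating-point overshoot at the extremes.

Mean relative abundance `a` averages over **all** retained stomach
samples, zeros included — presence is accounted for separately by `f`,
and zero-inclusive averaging is what makes `a·f·(D+1)` a population-level
score rather than a when-present intensity.  `TS` uses the MOTU's mean
`D` (not per-pair TS averaged).  Relative TS normalises by the TS total
over all MOTUs by default (configurable to the reported subset); the
High/Medium/Low bins are >10%, [1%, 10%], <1% — an exhaustive
order-preserving partition, with both boundary values falling in
Medium.  The reporting threshold keeps MOTUs at ≥0.5% mean relative
abundance; pass 0 to report everything.  Categories rather than exact
scores are the headline output because taxon-level read abundances in
metabarcoding are at best semi-quantitative.

The phylum summary aggregates counts to one row per phylum (missing
phylum → "unassigned") *before* computing the same descriptors, so
phylum-level `D` reflects phylum-level compositions, not an average of
MOTU-level indices.

## Community statistics

Bray–Curtis dissimilarities are computed on relative abundances
(optionally square-root transformed, the usual moderation of dominant
taxa for ordination-style analyses) via `scipy`'s pairwise machinery and
returned as a `skbio.DistanceMatrix`.

Mantel (Pearson correlation of lower-triangle entries, rows+columns of
the second matrix permuted jointly, one-sided greater) and PERMANOVA
(pseudo-F from the distance-based partition of sums of squares, labels
permuted) are implemented in-package because the pipeline needs
seed-exact reproducibility, the add-one estimator
`p = (1 + b)/(1 + m)` (never returns 0), an exact enumeration mode
(`method="exact"`, all n! permutations, n ≤ 8) for small-fixture
verification, and a nested design.  The nested PERMANOVA partitions
sequentially (Type I): estuary is fitted first, sites-within-estuaries
second, both tested against the residual mean square; permutation is
unrestricted (no strata).  `skbio`'s implementations serve as
independent cross-checks in the test suite, never as the computation.

Rarefaction uses Hurlbert's closed form
`E[S] = Σᵢ [1 − C(N−Nᵢ, d)/C(N, d)]`, evaluated with log-gamma to avoid
overflow; the resampling estimator (mean observed richness over draws
without replacement, via `Generator.multivariate_hypergeometric`) is
retained for parity with permutation-based workflows and agrees with
the closed form within Monte-Carlo error.  Accumulation curves first
rarefy each sample to the standard depth (one seeded subsample draw;
shallower samples are excluded with a warning, mirroring the depth
filter), then average cumulative richness over random sample orderings;
the endpoint therefore equals the pooled richness of the rarefied
samples and the curve is monotone by construction.

## Synthetic data generator

The generator emulates the multi-estuary survey design: 6 estuaries ×
4 sites, one pooled sediment eDNA sample per site, 3 pooled stomach
samples per site (batches of 8 stomachs), 3 pooled empty-stomach
samples and 3 PCR-negative controls; 30 prey taxa with phylum labels.

* **Communities.** Each estuary draws base prey abundances from a
  log-normal profile (µ = 0, σ = 1.5 — strong rank skew and strong
  between-estuary turnover, as in real benthic eDNA); each site
  perturbs its estuary base with a Dirichlet draw (concentration 200,
  mild within-estuary heterogeneity).
* **Consumption.** Preference acts multiplicatively on availability:
  expected diet composition r ∝ p·w.  This is the simplest generative
  model under which Jacobs' D is a monotone function of the preference
  weight w, which is exactly what makes parameter-recovery testing
  meaningful.  Default weights are log-spaced from 50 to 0.02 across
  the taxa so every taxon has a distinct preference rank (heavy ties
  would cap any rank correlation well below 1 regardless of estimator
  quality); an all-neutral configuration (w ≡ 1) is used for bias
  checks.
* **Reads.** Sediment counts are multinomial at depth 20,000; stomach
  pools are multinomial at depth 50,000 with fixed read fractions of
  28% consumer DNA and 36% fungal DNA (the empirically observed
  stomach-library composition for this consumer), plus 0.2% each of a
  bacterial and a human contaminant.  Empty stomachs are shallow
  (200 reads) and dominated by consumer+fungus.  A per-gut mode
  (Dirichlet-overdispersed guts summed into pools) exists for
  pool-size sensitivity work.
* **Artefacts.** A lab-contaminant MOTU concentrates in negative
  controls (Poisson, mean = rate × stomach depth in controls, 5% of
  that elsewhere).  Tag switching moves a Binomial(total, 0.002)
  portion of each sample's reads, chosen hypergeometrically across its
  MOTUs, to uniformly chosen other samples (controls included); every
  move is recorded and totals are conserved exactly.  One prey species
  is emitted as two MOTU records to exercise same-species merging.
  Contamination and tag-jump rates are synthetic choices (no field
  rates exist to copy) set so that each filter stage acts
  non-trivially.

What the generator does **not** model — PCR/primer bias, digestion-rate
differences between prey, secondary predation, chimeras, sequencing
error at the read level — bounds what passing tests show: they validate
the statistics and the artefact-removal logic under the stated
generative model, not the biological accuracy of read proportions as
diet proportions in real samples.

## Problem sizes and numerical choices

Permutation-test calibration uses 500 replicates of n = 15 samples with
199 permutations each; simulation recovery uses 10 replicate seeds of
the full default design (96 biological samples, depth 5×10⁴).  Exact
enumeration is used up to n = 8.  Permutation statistics compare with a
1e-12 tolerance on the "at least as extreme" side so that
floating-point ties count as ties.  Sub-seeds for multi-part runs are
spawned from the user seed via `numpy.random.SeedSequence` and kept
below 2³¹.  Degenerate inputs fail loudly: zero-depth samples, empty
selections, all-zero TS totals, constant distance matrices and
over-deep rarefaction all raise typed errors.

## Known limitations

* The tag-jump renormalization threshold interacts with sample count
  (see above); for designs with little community turnover, lower it
  toward the expected leak per destination (rate / n_samples).
* Jacobs' D is compositional: strong selection for one taxon
  mechanically depresses D for everything else.  Rank order in w is
  preserved under the generative model, but absolute D values should
  not be read as per-taxon consumption rates.
* The SE attached to mean D treats pairs as independent, though
  stomach pools within a site share the sediment member of their pairs.
* Nested PERMANOVA uses unrestricted permutation; with few sites per
  estuary, restricted (within-stratum) permutation would be more
  conservative for the nested term.
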