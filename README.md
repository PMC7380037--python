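# trophodiet

Diet metabarcoding analysis for consumers sampled alongside their
environment: denoise MOTU-by-sample read-count tables, quantify prey
selectivity against paired environmental DNA (eDNA), rank prey taxa by a
composite trophic-significance score, and compare consumed vs. available
communities with permutation statistics.

The package is aimed at trophic ecologists who have already produced a
MOTU table (e.g. from a COI amplicon pipeline) for stomach-content
samples of a focal consumer together with sediment or water eDNA samples
from the same sites — the design used to characterise the diet of the
brown shrimp *Crangon crangon* across European estuaries, which this
package's defaults emulate.

## The statistics at its core

For a taxon with relative read abundance `r` in a stomach sample and `p`
in the paired sediment sample, **Jacobs' selectivity index**

```
D = (r − p) / (r + p − 2·r·p)
```

maps the diet/availability contrast onto [−1, 1]: −1 total avoidance,
0 passive intake in proportion to availability, +1 exclusive selection.
`D` is evaluated per (stomach, paired-sediment) pair and averaged over
informative pairs (`r + p > 0`).

Each taxon is then scored by its **trophic significance**

```
TS = a · f · (D + 1)        ∈ [0, 2]
```

where `a` is its mean relative abundance over all retained stomach
samples (zeros included) and `f` the fraction of stomach samples in
which it occurs.  Scores are reported as shares of the TS total and
binned **High** (>10%), **Medium** (1–10%), **Low** (<1%).

Upstream of that, a provenance-logged **filter cascade** removes the
standard metabarcoding artefacts: same-species MOTU duplicates are
merged; per-MOTU tag-jump renormalization zeroes cells below 1% of the
MOTU's reads; bacterial/human/terrestrial contaminants are removed;
cells of ≤4 reads are zeroed; MOTUs with >10% of their reads in
PCR-negative controls are dropped; the consumer's own reads (and a
ubiquitous stomach fungus) are removed; and samples with <1,000
remaining diet reads are discarded.  Downstream, Bray–Curtis
dissimilarities feed Mantel and (nested) PERMANOVA permutation tests,
and MOTU richness is standardised by Hurlbert rarefaction with
sample-based accumulation curves.

A synthetic-data generator emulates the full sampling design (estuaries,
sites, pooled stomachs, negative controls, tag switching, contamination)
with known ground truth, so the entire pipeline is testable without any
sequencing data.

## Worked example

```python
import trophodiet as td

table, truth = td.simulate_dataset(td.SimConfig(), seed=1)
filtered, report = td.run_cascade(table)
print(report.summary())

diet = filtered.subset(sample_types={"stomach"})
env = filtered.subset(sample_types={"sediment"})
summary = td.diet_summary(diet, env, report_threshold=0.005)
```

The filter report shows the read flow through the cascade (36 MOTUs and
4,081,364 reads in; the consumer and fungal reads dominate the drop at
the focal-removal stage):

```
                    stage  motus_in  motus_out  reads_in  reads_out
      merge_species_motus        36         35   4081364    4081364
renormalize_tag_switching        35         35   4081364    3735806
      remove_contaminants        35         33   3735806    3721632
         min_reads_filter        33         33   3721632    3721632
  negative_control_filter        33         32   3721632    3721216
        remove_focal_taxa        32         30   3721216    1419822
      sample_depth_filter        30         30   1419822    1419822
```

`summary` is the per-taxon diet table (one row per MOTU at ≥0.5% mean
relative abundance), e.g.:

```
                          species  presence  mean_abund  jacobs_D     TS  rel_TS category
motu_prey_000  Simulatus taxon000     0.528       0.359     1.000  0.378   0.441     High
motu_prey_001  Simulatus taxon001     0.458       0.192     1.000  0.176   0.205     High
motu_prey_002  Simulatus taxon002     0.611       0.125     0.976  0.151   0.176     High
motu_prey_004  Simulatus taxon004     0.403       0.072     0.676  0.049   0.057   Medium
motu_prey_011  Simulatus taxon011     0.167       0.014    -0.736  0.001   0.001      Low
```

The three most-preferred taxa in the generator's ground truth come out
on top with `D ≈ 1` (strong selection), while weakly preferred taxa get
negative `D`; comparing against the truth gives a Spearman rank
correlation of 0.99 between true preference weights and estimated `D`
for this seed.

The same flow is available from the shell:

```sh
trophodiet simulate --seed 1 --out sim
trophodiet filter --counts sim_counts.tsv --taxonomy sim_taxonomy.tsv \
    --metadata sim_metadata.tsv --out filt
trophodiet selectivity --counts filt_counts.tsv --taxonomy filt_taxonomy.tsv \
    --metadata filt_metadata.tsv --out diet_table.tsv
trophodiet run --config pipeline.yaml     # all stages from one YAML
```

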