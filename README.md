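# spikequant

Spike-in anchored quantification for 16S rRNA amplicon OTU tables:
depth filtering, two-stage normalization (total-sum scaling followed by
reference-OTU anchoring), log–log dilution-series calibration with
detection-limit estimation, and genus-level spoilage profiling — together
with a synthetic spike-experiment generator that reproduces the statistical
structure the analysis assumes.

## The problem

Amplicon sequencing counts are compositional: read counts per OTU say
nothing about absolute abundance until they are anchored to something of
known or constant concentration. In food-microbiology surveillance this
matters twice over — one wants to know *how many* bacterial spores
contaminate a processed product, and *how early* a sequencing assay can see
them. The approach implemented here anchors every sample to an internal
standard: an OTU from a species present at the same concentration in all
samples (for example an inactivated water contaminant in a canned food
matrix, or a deliberately added spike). After scaling every sample to a
fixed read total (10⁴) and then rescaling so the reference OTU takes a
fixed value, read counts become comparable across samples, and a spore
dilution series yields a calibration line

```
y = a·x + b,    y = log10(normalized reads/OTU/sample),  x = log10(spores/sample)
```

fitted by ordinary least squares over points with more than a minimum read
count (default >5 reads/sample; zero-read samples are excluded outright).
The **detection limit** is the functional inverse of the fitted line at a
chosen read threshold y\* (one read by default):

```
x* = (log10 y* − b)/a,    detection limit = 10^x*  spores/sample  (÷ volume → spores/ml)
```

The limit scales linearly with the read threshold. Species differ in the
limit by orders of magnitude, driven mostly by >1000-fold differences in
DNA extraction efficiency between spore species and secondarily by 16S
rRNA gene copy number (8–14 in *Bacillus*/*Geobacillus*).

## Who it is for

Food and environmental microbiologists running spike-in or internal-
standard amplicon experiments who need reproducible normalization and
detection-limit estimates from OTU count tables, plus a simulator to plan
designs (dilution ranges, replicate counts, sequencing depth) before
sequencing anything.

## Worked example

Simulate the default canned-food design — five spore species (two of them
carrying two OTUs each) spiked at 8.5×10⁰…8.5×10⁵ spores/sample in tenfold
steps, three replicates per level plus unspiked controls, a dominant
endogenous background OTU (OTU1) and a low-abundance reference OTU (OTU8),
sequencing depth ~ N(6203, 2980²) — then run the full pipeline:

```bash
spikequant simulate --seed 7 --out sim
spikequant run-canned sim_table.tsv sim_metadata.tsv \
    --ref-otu OTU8 --otu-list OTU6,OTU3,OTU5,OTU4,OTU2,OTU7,OTU9 \
    --out-prefix run
```

`run_report.tsv` (seed 7):

```
otu_id  a         b         r_squared  n_points  dl_log10  dl_spores  dl_per_ml
OTU6    1.01498   -1.63039  0.992125   12        1.60633   40.395     47.5235
OTU3    0.999216  -1.28116  0.99245    12        1.28216   19.1496    22.529
OTU5    0.944326  -1.01486  0.990841   14        1.07469   11.8765    13.9724
OTU4    0.921429  -2.27352  0.967037   10        2.46739   293.35     345.118
OTU2    1.22339   -5.26231  0.926227   5         4.30143   20018.6    23551.3
OTU7    1.01734   -3.42489  0.904107   5         3.36652   2325.53    2735.91
OTU9    0.897386  -2.73266  0.935127   7         3.04513   1109.5     1305.3
```

Reading it: each row is one spike OTU's calibration line fitted through the
included dilution points (`n_points`), with slope `a` near 1 (the dose
response is linear on the log–log scale), intercept `b` reflecting that
species' extraction efficiency × copy number, and the detection limit in
log10 spores/sample, spores/sample and spores/ml. High-efficiency species
(OTU3/OTU5/OTU6) are detectable from ~10–40 spores per sample; the
1000-fold-less-efficiently extracted OTU2 needs ~10⁴ spores this run. The
accompanying `run_manifest.json` records the anchor value actually used
(here the control-derived mean, 99.7 normalized reads), every dropped
sample and every excluded point with the rule that excluded it; re-running
with the manifest's parameters reproduces the report byte for byte.

For spoilage profiling, `spikequant simulate --kind rte` generates a
refrigerated ready-to-eat-meal time series (7 timepoints over 12 days,
depth ~ N(4091, 1364²)) and `spikequant run-rte` tabulates the top-k genera
as long-format normalized-read trajectories.

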