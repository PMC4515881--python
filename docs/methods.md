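# Methods

## The quantification model

Counts from amplicon sequencing are draws from a composition: sample j
yields a depth N_j, and each OTU i receives reads in proportion to its
template share p_ij. Absolute quantification requires an anchor. The
procedure implemented here uses an internal-standard OTU r assumed present
at the same template concentration c_r in every sample, and proceeds in two
stages:

1. **Total-sum scaling.** Every sample is rescaled to a fixed total T
   (default 10,000 reads): ŷ_ij = T · y_ij / Σ_i y_ij. This removes depth
   and puts all samples on one relative scale.
2. **Reference anchoring.** Every sample is rescaled so the reference OTU
   equals a fixed value V: ỹ_ij = V · ŷ_ij / ŷ_rj. Because c_r is constant
   across samples, ỹ_ij is proportional to the absolute template amount of
   OTU i in sample j, on a common scale.

Both stages preserve within-sample OTU ratios exactly; only the reference
row is pinned (assigned V outright, avoiding a last-ulp division residue).
The order is fixed — anchoring requires total-sum input — because the
anchor value V is conventionally quoted on the 10⁴-total scale. V defaults
to the arithmetic mean of the reference OTU's total-sum-normalized reads
over the unspiked control samples; a user-supplied constant (e.g. 340)
overrides it. Samples where the reference OTU yielded zero reads cannot be
anchored; they are reported, never imputed — heavy contamination dilutes
the reference below detectability, which is a finding, not a missing value.

Raw tables are depth-filtered first: samples with fewer than 1000 reads
are discarded (strictly fewer — a sample at exactly the threshold is
retained).

## Calibration and detection limits

For a dilution series with known spike levels n (spores/sample), the
anchored counts of a spiked OTU follow, in expectation, a straight line of
slope 1 in log–log space, because template amount is linear in spore count.
The calibration fit is ordinary least squares of y = log10(ỹ) on
x = log10(n) over the **included** points:

- samples yielding zero reads are excluded outright (no log exists, and a
  zero says only "below this sample's floor");
- points at or below `min_reads_for_fit` (default 5, strict: a point at
  exactly 5 is out) are excluded — near the count floor the observable is
  left-censored and single-read flukes are pure noise;
- replicates enter as separate points, never averaged.

R² is the squared Pearson correlation of (x, y); for a two-point series the
line interpolates exactly and R² is set to exactly 1.0 rather than left to
floating-point residue. Fewer than two included points, or no spread in x,
is an error, not a fit.

The detection limit at read threshold y\* is the exact inverse of the
fitted line, x\* = (log10 y\* − b)/a, reported as log10 spores/sample,
spores/sample (10^x\*), and spores/ml (divided by the sample volume,
default 0.85 ml). It is linear in y\* (tenfold higher threshold, tenfold
higher limit, for a = 1). Negative x\* is reported unclamped and flagged
`non_physical`; it arises for matrix-endogenous OTUs whose dose response is
flat (slope ≈ 0 with a large intercept), where the "limit" is an artefact
of the background, and the flag — not a clamp — is the honest output. The
panel summary is the arithmetic mean of per-OTU limits over non-endogenous
spike OTUs, with its formula recorded in the output, since other means are
defensible.

### Two detection thresholds

The analysis threshold y\* lives on the normalized axis (default 1
normalized read, matching how calibration tables are printed). Separately,
one *raw* sequencing read lands at V / (raw reference reads per sample) on
the normalized axis — about 1.6 normalized reads under the canned-food
study's numbers. This one-raw-read equivalent shrinks as depth grows, and
it, not the fixed normalized threshold, carries the depth benefit: expected
anchored counts are depth-independent, so deepening the sequencing lowers
the *attainable* limit only through the raw-read floor. The depth-effect
study therefore evaluates limits at each experiment's one-raw-read
equivalent threshold; the recovery study uses the fixed normalized
threshold, where truth is available in closed form.

## The synthetic spike experiment

The generator emulates the canned-food design. Species s spiked at n
spores/sample contributes template weight

    w_s(n) = n · e_s · k_s,

split over that species' one or two OTUs (default 0.5/0.5 for two-OTU
strains; real strains show unequal pairs, but no ratio is published). Here
e_s is the relative DNA extraction efficiency and k_s the 16S gene copy
number. A constant background adds a dominant endogenous OTU and the
reference OTU. Per sample, depth is drawn from N(μ, σ²), truncated at one
read and rounded; counts are multinomial over the weight vector. Each
sample has its own RNG stream derived from the top-level seed and the
sample index, so changing replicate counts never perturbs earlier samples,
and the same config is bit-reproducible.

Default panel (five species, chosen to span the documented biases):

| species                | OTUs        | e_s   | k_s |
|------------------------|-------------|-------|-----|
| G. thermoglucosidans   | OTU3, OTU5  | 1.0   | 10  |
| G. stearothermophilus  | OTU6        | 0.3   | 9   |
| B. sporothermodurans   | OTU4        | 0.02  | 10  |
| B. subtilis            | OTU7, OTU9  | 0.01  | 10  |
| B. cereus              | OTU2        | 0.001 | 13  |

The efficiency spread is the reported ≥10³-fold range (exact per-species
values are not published); copy numbers sit inside the documented 8–14
band. Background weights are (OTU1: 10⁶, OTU8: 10⁴): the dominant OTU at
100× the reference reproduces the observed pattern of a processed-food
matrix, and the absolute placement puts the reference at ~1 % of reads so
that (i) anchored at the control-derived V ≈ 99, every spike OTU's true
detection limit falls inside the simulated dilution range, and (ii) one raw
read maps to ~3.4 normalized reads, below the >5 fit cutoff — the same
regime as the real calibration, where the cutoff screens single-read
flukes. Study defaults: dilutions 8.5×10⁰…8.5×10⁵ spores/sample (tenfold,
0.85 ml), 3 replicates/level, 3 controls, depth μ=6203, σ=2980.

Because expected anchored counts are V·w_i(n)/w_ref, the generative truth
is available in closed form: the true detection limit of a spiked OTU is

    n* = y* · w_ref / (V · e_s · k_s · split),

linear in the threshold like its empirical counterpart.

What the simulator deliberately does **not** model: PCR chimera/error
processes, amplification dispersion beyond multinomial sampling (an
optional per-OTU efficiency jitter was considered and left out — the
documented bias is systematic, not stochastic), spore germination, and
read-level sequence structure. Passing recovery tests therefore show that
the pipeline inverts the assumed generative structure at realistic depths
and replicate counts — not that real extractions are free of unmodelled
dispersion.

The spoilage-time-series generator is the same multinomial machinery with
per-genus template-weight trajectories over storage timepoints (7
timepoints over 12 days, 2 replicates, depth μ=4091, σ=1364). Default
trajectories emulate a refrigerated ready-to-eat meal: a lactic-acid
bacterium (Leuconostoc) rising first, then Bacillus and especially
Paenibacillus overtaking, against constant plant (Streptophyta) and
Pseudomonas backgrounds; the sorbate variant lets only Leuconostoc grow.
Quantities are strictly relative (normalized reads); no absolute claim is
made for this study type, so no reference anchoring is applied.

## Validation studies and their sizes

- **Recovery**: 20 seeds of the default design (21 samples each). Mean
  fitted slope is compared against the generative slope of 1; per-OTU
  limits are compared with n\* as the geometric mean over seeds (log10
  average), because single-seed limits of the shortest series (two dilution
  levels, three replicates) carry ~0.3 log10 of multinomial noise and a
  per-seed bound would measure that noise rather than calibration bias.
- **Depth effect**: the same 20 seeds at depth μ and 10 μ, limits at the
  one-raw-read equivalent threshold, scored by the per-seed mean log10
  change.
- **Background dilution**: expected anchored background reads decrease
  strictly with spike load at every level (checked exactly on the
  closed-form expectations, both background OTUs). The finite-replicate
  check (25 replicates/level, 150 spiked samples) spans loads 0 and
  8.5×10²…8.5×10⁵, where the effect exceeds multinomial noise: at the
  lowest loads the expected depression is <0.01 % of reads — about 1
  normalized read against a per-sample SD of ~13 for the reference OTU —
  and is unresolvable at any desk-scale replicate count; the reference
  OTU is accordingly checked endpoint-to-endpoint.

## Numerical and design choices

- Genus extraction takes the sixth semicolon-delimited lineage field, with
  `g__`-style rank prefixes stripped; unparseable lineages pool under
  `unclassified`. Column sums are conserved exactly under aggregation
  (integer arithmetic on raw tables).
- "Prominent" genera in profiling are ranked by the maximum normalized read
  count attained in any sample across treatments — an operational proxy for
  the informal "high abundance and diversity" criterion — with
  lexicographic tie-breaks; k is configurable.
- Empty table cells parse as zero (sparse-export convention). Duplicate row
  or column ids, negative and non-numeric cells are structural errors that
  name the offending coordinates.
- Normalized tables serialize with 12 significant digits; round-trips are
  identity to 1e-9 relative tolerance. The TSV dialect carries no
  normalization-state tag, so readers of normalized tables pass the state
  explicitly.
- Pipelines sort rows and columns lexicographically on entry, so no result
  depends on input order; manifests record every parameter and every
  excluded sample/point with its rule, and replaying a manifest's
  parameters reproduces the report exactly.
- Limits are reported at full precision; two-significant-figure display
  rounding is left to report consumers. One published worked example is
  only reproducible at the log10 stage (its printed spore value appears to
  round the log10 limit to one decimal before exponentiation); the log10
  value is the one checked.

## Known limitations

- The reference-OTU assumption (constant concentration, nonzero reads) is
  load-bearing: heavily contaminated samples dilute the anchor below
  detectability and drop out of calibration; the pipeline reports rather
  than rescues them.
- No confidence intervals on detection limits (point estimates only, as in
  the source analyses); no errors-in-variables or weighted regression.
- No rarefaction or model-based size factors (CSS/TMM/DESeq-style); only
  the two schemes above are in scope.
- The simulator's default efficiencies are a documented spread, not
  measured per-species values, so simulated limits are representative, not
  predictive, for any particular species.
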