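# Methods

This note documents the models, thresholds and design choices behind
`mobnet`, in the order the pipeline runs them.

## Differential-expression classification

Input tables carry one row per gene with a log2 fold change (treated over
control) and a multiple-testing-adjusted p-value, the shape produced by
DESeq2-style upstream analyses. A gene is called *up* when
log2FC ≥ log2(t) and p_adj < p, *down* with the mirrored fold cutoff, and
*unchanged* otherwise. Defaults t = 2 (linear fold), p = 0.05. Two
conventions are deliberate and tested:

- the fold cutoff is **inclusive** (a gene at exactly 2-fold is called)
  while the p cutoff is **strict**;
- a missing adjusted p-value is never significant — the gene is classified
  unchanged regardless of its fold change. This is the conservative
  reading; upstream tools emit NA p-values for low-count or outlier genes
  whose fold estimates are unreliable anyway.

A reader flag accepts linear fold-change columns and converts to log2.
Gene identifiers are matched case-sensitively after whitespace stripping;
synonym resolution is out of scope and mismatches are logged.

## Regulon engagement

Engagement of a regulon is the fraction of its member genes that are
differentially expressed under the rule above. The **denominator is the
full regulon size** as given in the regulon definition file, not the
number of members detected in the DE table: members absent from the table
count as not engaged (a warning is logged with the detected count
reported alongside). The alternative convention — dividing by detected
members only — would inflate fractions for sparsely covered regulons;
both counts (`n_total`, `n_detected`) are in the output so either can be
recomputed. The network-inclusion cutoff (default 0.30) is inclusive: a
regulon at exactly 30% engagement appears.

Genes regulated by several regulators count fully toward each regulon; no
apportioning is attempted, since regulon definitions overlap by
construction and shared-gene analyses presuppose double counting. A
regulator gene inside its own regulon is treated like any member. The
fold-change range over engaged genes is reported on the linear scale
(2^|log2FC|).

## Network construction

Nodes are exactly the included regulators. Node attributes: the
engagement fraction (`size_weight`), the raw engaged count (`n_engaged`;
exported separately because a count-weighted rendering is equally
defensible), and the up/down split over engaged genes
(`frac_up` + `frac_down` = 1 when anything engages). An edge joins two
included regulators whose regulons share at least one member and at least
one differentially expressed member; its weight is
n_shared_engaged / n_shared ∈ (0, 1]. Pairs sharing members but no DE
gene would have weight 0 — they are omitted from the graph and written to
an audit table instead, so the graph's edge list equals the set of
DE-supported overlaps. Edges are undirected and unique per pair;
regulatory mode (activation vs. repression) is not modeled.
*Network-independent* regulators are included nodes of degree 0.

Exports: GraphML with all attributes, SIF (topology only; isolated nodes
as bare names), JSON (lossless round-trip), and node/edge attribute TSVs.
Layout and rendering are left to downstream tools.

## Cross-condition comparison

Regulator sets of two networks are partitioned into only-A / shared /
only-B (inclusion–exclusion identities are property-tested). Shared-gene
reports for a regulator pair count common members and how many are DE,
with per-gene directions. Direction switches between timepoints use a
**strict majority** rule over engaged genes: majority-up, majority-down,
balanced (exact tie), or not-engaged; a switch is called only between
majority-up and majority-down. Strictness makes the qualitative notion of
a regulon "reversing direction" testable; ties never switch.

## Isotope-dilution quantitation

Each analyte is quantified as the ratio of its light-channel XIC area to
that of its fully ¹³C/¹⁵N-labeled internal standard:

- the m/z window is mass-relative, mz · (1 ± ppm·10⁻⁶), default 75 ppm
  half-width, around the light [M−H]⁻ mass and around the heavy mass
  computed from the molecular formula using Δ(¹³C−¹²C) = 1.00335484 Da
  and Δ(¹⁵N−¹⁴N) = 0.99703489 Da;
- extraction sums point intensities per retention time inside a fixed
  per-analyte retention window (determined from standards); there is no
  retention-time alignment;
- integration is the trapezoid rule with no baseline subtraction; fewer
  than two points integrate to zero. A zero heavy-channel area leaves the
  ratio undefined; the record is flagged and excluded downstream.

The internal standard is assumed fully labeled; no isotopic-purity
correction is applied. Extracts are assumed pre-normalized (to optical
density or DNA content) before ratios are compared across samples.

Differential filtering compares mean replicate ratios, treated over
control. The fold cutoff is timepoint-specific (defaults 1.5 at 6 h, 2.0
at 24 h) and symmetric: a metabolite passes by increasing ≥ t-fold or
decreasing to ≤ 1/t. The p-value is a two-sided Welch t-test on the
replicate ratios with no multiple-testing correction by default
(matching the simple per-metabolite p < 0.05 rule such heatmaps usually
encode); a Benjamini–Hochberg flag is available. Groups need ≥ 2
replicates with defined ratios; smaller groups are excluded with a
warning, a missing control group is an error.

## Synthetic data generator

The generator exists so every stage runs against known ground truth.

**Regulons.** Gene universe of 4,000 identifiers (the scale of the
*B. subtilis* genome), 20 regulons of 10–60 members by default. Each
regulon after the first draws round(overlap_fraction · size) members from
genes already assigned to earlier regulons (capped by the pool) and the
rest from fresh genes; realized pairwise overlaps are recorded in the
provenance metadata. overlap_fraction = 0 gives provably disjoint
regulons, used by the exact-recovery tests.

**DE tables.** Per regulon and timepoint a planted engagement fraction:
deterministic mode engages exactly round(fraction · size) members, so
recovery tests are exact; a Bernoulli mode engages each member
independently for statistical tests. Genes in several regulons take
their status from the first regulon processed, in regulator-name
lexicographic order (names are zero-padded so lexicographic equals
numeric order); later regulons plant only over their unassigned members —
a documented precedence rule the overlap-aware tests account for.
Engaged genes get |log2FC| drawn log-normal with mean 2.0 (σ_log = 0.25),
clipped below at 1.0 so every planted gene clears the 2-fold cutoff, sign
Bernoulli(up_bias), and p_adj uniform on (0, 0.01]; null genes get
Normal(0, 0.4) log2FC and p_adj uniform on (0.05, 1], so no null gene is
ever significant. The log-normal magnitude model is a parameterized
stand-in — real DE effect-size distributions are heavier-tailed and
correlated within operons, which these tables do not emulate; passing
recovery tests therefore demonstrates correctness of the scoring
arithmetic, not robustness to real-data pathologies.

**Study conditions.** The default two-timepoint study emulates the
antibiotic-exposure pattern: a third of regulons engage strongly early
(0.35–0.7, mostly repressed) and fade late, a third stay engaged at both
times with a direction reversal, a third remain below the cutoff.

**Chromatograms.** Each analyte is a Gaussian peak pair sharing one
retention profile (default σ = 4 s, sampled at 0.4 s over ±5σ), with
amplitudes set so the noiseless trapezoid area equals the specified true
area; reference retention windows cover the same ±5σ span. Noise is
shot-like: per-point Gaussian with standard deviation
noise_sd · √intensity, clipped at zero. A signal-proportional model was
chosen over additive baseline noise because ion-counting detectors behave
this way and because additive noise clipped at nonnegativity inflates
both channels' baselines equally, biasing area ratios toward 1; with
shot noise the recovered ratio is unbiased, which the seeded replicate
test verifies. The default panel is three analytes × two conditions ×
three replicates: an ~8-fold-up purine-catabolism-like analyte, a
~3-fold-up glycolysis-like analyte, and an unchanged control, with
constant heavy-standard areas as for a spiked internal standard. The
generator does not emulate peak tailing, co-elution, isotope envelopes
beyond two channels, or mass-calibration drift.

## Determinism and orchestration

Every generator call derives its stream from an explicit seed combined
with a stage label (CRC32 of the label mixed into the seed sequence);
there is no global random state. Identical configurations produce
byte-identical TSVs. The pipeline runner validates its YAML config and
input files before any stage executes, runs
classify → categories → engage → network → compare → quantify → metdiff,
aborts naming the failing stage on error, and writes a manifest (config
snapshot, SHA-256 input digests, seed, output paths, version). Stage
outputs via the pipeline are identical to running the stages manually —
this equality is itself a test.

## Problem sizes used in the test suite

Oracle-equivalence tests run 100 randomized instances of up to 1,000
genes × 50 regulons against independent loop-based references; Bernoulli
recovery uses 1,000 seeded replicates of an 80-gene regulon; noisy ratio
recovery uses 100 seeded chromatogram pairs. These sizes keep the full
suite under a minute while leaving the checked identities exact.

## Known limitations

- Engagement treats a regulon as a flat gene set: regulatory sign,
  operon structure and indirect regulation are ignored.
- No statistical test accompanies the engagement fraction; the 30% cutoff
  is a visualization threshold, not an enrichment p-value.
- Fixed retention windows presume well-aligned chromatography; drifting
  peaks need realignment upstream of this pipeline.
- The Welch test on ratios assumes approximate normality of replicate
  ratios; with 2–3 replicates its power is limited and the default
  forgoes multiple-testing correction.
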