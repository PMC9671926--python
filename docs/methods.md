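# Methods

This note documents the models, statistics and design choices behind each
module, the synthetic-data generator's assumptions, and the limits of what
the test suite demonstrates.

## qPCR analytics (`expression`)

Mean normalized expression for a target/reference primer pair is
`MNE = E_ref^mean(Ct_ref) / E_target^mean(Ct_target)`. Efficiencies `E`
default to 2.0 (perfect doubling per cycle) and are accepted per primer
pair in [1.5, 2.2]; replicate Cts are averaged before exponentiation, so
MNE is invariant to replicate order, and a common Ct shift applied to both
channels cancels when efficiencies are equal.

Knockdown is summarized as the percent change of treated vs control MNE,
computed per donor and averaged (mean ± SEM). Significance uses a two-way
ANOVA (stimulus × silencing, donors as replicates) with classical sums of
squares, followed by pairwise silencing contrasts within each stimulus
level using the pooled residual mean square and residual degrees of
freedom; each raw two-sided p is multiplied by the contrast-family size and
capped at 1 (Bonferroni). A fully degenerate table (zero residual variance
and zero differences) returns p = 1 rather than NaN.

Subcellular localization divides each fraction's MNE by the sum over
cytoplasm, nucleoplasm and chromatin (an optional separately measured
total-lysate denominator is supported, since the denominator convention
varies between labs); the nuclear share is nucleoplasm + chromatin. RIP
yield adjusts the input-channel Ct for the input dilution
(`Ct_adj = Ct_input − log2(1/input_fraction)`, default input fraction 10%,
a configuration value, not a measured constant) and reports
`100·2^(Ct_adj − Ct_IP)`, plus the ratio over the IgG isotype control. A
zero IgG yield is an error (degenerate control), not infinity.

## Consensus binder selection (`interactome`)

Only proteins scored by both predictors are candidates. The catRAPID-shaped
table contributes the arithmetic mean of interaction score and
discriminative power; the lncPRO-shaped table its single score. Thresholds
are the means of both quantities over the common set, and selection is
strictly-above-both (a literal reading of "higher than the average"; `>=`
is available via `strict=False`). Whether the means should be taken before
or after intersecting the two tables is genuinely ambiguous in the source
procedure; the intersection convention is used because only common proteins
are candidates at all.

Binding-element calling on a per-position interaction profile takes maximal
runs at or above a threshold, merges runs separated by a below-threshold
gap shorter than `merge_gap`, drops merged runs shorter than `min_length`,
and labels elements PBE-1, PBE-2, … by descending mean score. Threshold and
minimum length are configuration values; no universal defaults exist
because profile scales are predictor-specific.

## Triplex search (`triplex`)

The search implements the canonical triplex code only: parallel
(pyrimidine-motif) triplets U·A:T and C·G:C, antiparallel (purine-motif)
triplets A·A:T, G·G:C and U·A:T, RNA U/T-normalized. Dedicated triplex
engines add pairing-rule variants, alignment heuristics and stability
models; none of that is reproduced, so absolute hit counts from such tools
are not comparable — the purpose here is coordinate-level candidate
nomination with fully specified semantics.

A hit is a gapless TFO/TTS window pair on one alignment diagonal of one
(duplex strand, orientation) combination satisfying: length ≥ `min_len`
(default 20 nt; values below 10 are rejected as sub-biological), mismatch
count ≤ `max_mismatch_rate`·length (default 0.1), purine fraction of the
DNA side ≥ `min_purity` (default 0.8), and matching triplets at both
endpoints. Only *maximal* windows are reported (no qualifying window on the
same diagonal strictly contains them). The implementation prefilters
diagonals by the pigeonhole bound on the longest all-match run any
qualifying window must contain, then enumerates windows on surviving
diagonals; on short sequences it equals an exhaustive all-window oracle
exactly (asserted in tests). TTS coordinates are always reported on the
promoter's forward strand; the `strand` field records which duplex strand
served as the purine target.

TFO ranking merges overlapping TFO windows into regions and ranks by
supporting-TTS count, then total score (matches − mismatches), then
position; the top region is TFO1.

## Motif statistics (`motif_stats`)

Scanning uses log2-odds matrices with a background-proportional
pseudocount (`p' = (p + 0.01·bg)/1.01`). Per-window p-values are exact:
scores are discretized at 1e-3 bits (configurable constant) and the null
distribution of the integer window score over background-distributed words
is built by column-wise convolution; the p-value is the tail mass at the
window's integer score. The reverse strand gets its own null because under
an asymmetric background the reverse-complement matrix has a different
score distribution. `N` bases contribute the background expectation of the
affected column, keeping scan length invariant; p-values for N-containing
windows are therefore approximations against the ACGT-word null
(documented behaviour, not an error).

Relative enrichment reduces each promoter to presence/absence (≥ 1 hit at
the scan alpha) and applies a one-sided Fisher's exact test to the 2×2
table, with a Haldane-corrected ratio `((t+0.5)/(T+1))/((b+0.5)/(B+1))`.
This is a declared stand-in for the SEA statistic, whose internals are not
reproduced. TFBS enrichment takes the best log-odds hit per promoter per
library PWM and compares target vs background best scores with a one-sided
Welch t-test — the explicit background promoter set replaces the
organism-wide z-test a tool like PSCAN would use, which matches the stated
comparison better when the background is a curated unaffected-gene set.
Verdicts use raw p < 0.05 (the pipeline convention); Benjamini–Hochberg
adjusted values are reported alongside but do not drive the verdict.

Motif similarity is the best Pearson correlation of aligned probability
columns over all ungapped offsets with ≥ 4 overlapping columns, both
orientations; its p-value is a column-permutation null with the +1
correction. This replaces an exact-null comparison tool; it preserves
ranking and orientation detection but its p-values are Monte-Carlo.

## TF prioritization (`tf_prioritization`)

Evidence per (TF, promoter) pair maps to the ordinal scale 0 (none),
2 (literature-predicted binding site), 6 (literature ChIP), 8 (ENCODE
ChIP), 10 (both ChIP sources). Co-occurring weaker evidence never lowers a
score: the strongest applicable category wins (e.g. predicted + ENCODE =
8). The dense TF×gene matrix (absent pairs 0) is clustered with
agglomerative hierarchical clustering, Euclidean distance, complete linkage
(deterministic, and robust for block recovery; Ward is available via the
`method` argument), cut into k = 4 clusters by default. Rows are clustered
raw (unscaled): the score scale is already ordinal and shared across genes.

"Covers the majority of the target genes" is operationalized as: cluster
coverage = fraction of genes whose within-cluster mean score is > 0; the
winner is the cluster with maximal coverage, ties broken by higher overall
mean score, with a warning if the winner's coverage does not exceed the
configurable 0.5 threshold. Note the pooled mean>0 criterion is weak for
large clusters (many TFs with scattered evidence can cover every gene), so
the mean-score tie-break matters in practice; this is the documented
behaviour of the chosen definition, not an accident. Final candidates are
the intersection (case-insensitive, whitespace-stripped names) of the
winning cluster's TFs with the union of TF names on significant TFBS
enrichment rows.

## Synthetic data (`synthetic`)

All generators are pure functions of (parameters, seed) using a single
`numpy` Generator per call; rerunning with the same seed reproduces files
byte-identically. Default scales mirror a realistic single-lncRNA study:
15 target and 41 background promoters (5,000 nt default for the promoter
generator; the orchestrated demo run uses 1,000 nt to keep end-to-end runs
fast at desk scale), a 1,000-protein interaction table with 50 true binders
shifted by 2.5 SD per catRAPID channel and 25 lncPRO points, 158 TFs with a
34-TF high-evidence block, 4–5 donor qPCR designs, and an 8-fold planted
RIP enrichment.

Specific modelling choices:

* Promoters are i.i.d. letters at the requested GC (0.45 default); each
  promoter receives each motif independently at its set's rate, instances
  sampled from the PWM and planted at non-overlapping uniform positions.
  Real promoters have CpG islands, repeats and positional biases none of
  which are modelled, so enrichment power on real data will differ.
* The evidence block samples each block-cell from score categories
  {10: 0.5, 8: 0.45, 6: 0.05} (ChIP evidence essentially always present on
  block genes) and adds literature-predicted sites across all genes at rate
  0.7 — predicted sites are cheap and ubiquitous for genuinely binding TFs,
  and this floor also makes the block cluster's gene coverage complete.
  Off-block flags fire independently at 0.02.
* In the full simulated study, decoy (non-partner) PWMs are planted
  *background-biased* (rate 0.3 in targets vs 0.8 in background), so the
  one-sided target-enrichment test is structurally null for them rather
  than null-on-average; partner PWMs are planted at 0.95 in targets and
  never in background. This makes end-to-end partner recovery a property of
  the construction, not of a lucky seed.
* qPCR: Ct = base − log2(expression) + Gaussian noise; knockdown scales
  LPS-induced expression by (1 − fraction). Donor effects are i.i.d. noise,
  not donor-specific baselines; no mixed-effects structure is modelled.
* The planted triplex tract is mixed A/G (both present, so only the
  parallel orientation can fire) and is flanked by bases that cannot pair
  under the canonical code, making coordinate recovery exact rather than
  merely overlapping.

`verify_manifest` independently re-checks every planted item against the
emitted files.

Passing tests on this generator demonstrate internal correctness and
recoverability under the stated noise models — not performance on real
sequencing-era data, where predictor score distributions, promoter
composition and evidence sparsity are all less convenient.

## Numerical and orchestration choices

* Coordinates are 0-based half-open everywhere in memory and in BED-like
  outputs; 1-based only in prose.
* Motif columns are validated to sum to 1 within 1e-3 and renormalized
  exactly; parser errors always locate the offending record/position.
* Exact-scan survival functions are clipped at 1 to keep p ≤ 1 under
  floating accumulation; null distributions are memoized per (matrix,
  background).
* `run_all` validates its configuration (unknown keys rejected, thresholds
  range-checked) and checks every input path before any stage executes;
  outputs carry a provenance header (version, config hash excluding the
  output directory, seed) and `summary.json` enumerates every threshold
  applied. Given (inputs, config, seed) the run is deterministic.

## Known limitations

* The triplex module nominates candidates under one canonical rule set; it
  does not estimate thermodynamic stability and is not genome-scale.
* Exact scan p-values assume a 0-order background; no Markov background is
  implemented.
* The Fisher presence test ignores hit multiplicity within a promoter.
* Bonferroni contrasts assume homoscedastic cells (pooled MSE); the
  fractionation analysis assumes the three fractions are exhaustive.
* The functional-class mapping for annotation tables is consumed as input;
  no ontology service is queried.
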