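# Methods

This note documents the models, parameter choices and numerical conventions
behind `refstab`, and what the simulation-based tests do and do not show.

## The screening statistic

The RNA-seq screen works on FRPKM computed against the per-sample column
sum over the *kept* contigs, so each sample's values are invariant to
rescaling that sample's counts. The stability statistic is the coefficient
of variation between the two sexes: FRPKM is averaged within each sex and
CV = sd(m̄, f̄)/mean(m̄, f̄), with the standard deviation over the two sex
means using the n−1 denominator (so sex means 8 and 12 give
CV = (4/√2)/10 ≈ 0.283). A per-sample CV mode (across all individuals) is
available for sensitivity analysis. Contigs with zero mean expression get
CV = NaN and are removed before the quantile is taken; the top set is the
ceil(q·n) lowest-CV contigs (ceiling because 1% of a realistic contig count
is not integral), with boundary ties broken lexicographically by contig id
so the screen is deterministic. "Never reached ≥10 reads" is read as "the
maximum per-sample count is below 10"; a total-count variant is available
by flag.

## Stability estimators

All four estimators run on one shared complete-case matrix: observation
columns (samples, or individual wells in replicate-level mode) are dropped
if any analysed gene is undetermined there, because all four original
methods assume a complete matrix and pairwise-complete variants would rank
genes on incomparable sample sets. Replicate-level input is the default for
the stability stage — validation studies commonly rank on all wells — and
replicate-averaged input is a flag.

Quantities are q = E^(Ct_min − Ct) with the per-gene minimum Ct as
calibrator, bounding q in (0, 1] (the geNorm ecosystem's convention). Each
assay's own efficiency is used by default; a global override (E = 2) exists
and makes the Δct statistic equal the first-pass geNorm M exactly, an
algebraic identity the tests assert at 1e−9.

geNorm excludes the worst gene per pass, with ties on M broken by gene id;
the final pair is inseparable by construction and shares rank 1.5. Each
gene's reported M is its value at the pass in which it was excluded
(`genorm_m`), with the full-panel first-pass M kept alongside. Pairwise
variation V(n/n+1) uses normalization factors that grow from the final pair
outwards in reverse exclusion order.

NormFinder is implemented on sample-centered log2 quantities: per sex,
each gene's within-group variance (n−1 denominator, scaled by I/(I−1) to
undo the centering bias across I genes) and its deviation from the
size-weighted overall mean; the deviation is shrunk by
max(0, 1 − noise/Var_groups(d)) and
ρ = mean over groups of |shrunk bias| + √(variance/n_group). This follows
the published model's intent; numerical identity with the original Excel
add-in is not claimed (its handling of several edge cases is not
documented), and the tests therefore assert structural properties
(zero for noise-free stable genes, symmetry, monotonicity in the planted
effect) rather than add-in output.

BestKeeper is descriptive and runs on raw Ct: the index is the per-sample
geometric mean Ct, and genes are ranked by SD (sample SD by default; the
original tool's mean-absolute-deviation is a flag). A constant gene has an
undefined correlation with the index and reports r = NaN while still being
ranked by SD. BestKeeper is intentionally *not* invariant to per-sample
loading shifts — it operates before normalization — and the scale-invariance
test covers the other three methods only.

The consensus is the geometric mean of the four per-method ranks
(ascending instability, average ranks for ties), with residual ties in the
final ordering broken by gene id.

## Quantification and testing

QC order matters: the cycle cutoff (default 35) is applied first, then the
NTC margin (a template well within 8 cycles of its assay's NTC signal
fails), then the ≥10% missing-data exclusion computed over both kinds of
loss. The replicate SD (default flag level 0.3 cycles) is reported, not
acted on, matching the practice of noting technical noise without deleting
wells. When an outlier sample is removed, `balance_design` removes one
random (seeded) same-tissue sample of the opposite sex so per-sex counts
stay equal.

Normalization uses the qBase conventions: the calibrator is the gene's
arithmetic mean Ct over retained samples (the stability suite's min-Ct
calibrator is internal to stability only — the two stages answer different
questions and the NRQ is invariant to the choice up to a per-gene
constant), NF is the geometric mean of the reference genes' rq, and any
sample in which a reference gene is undetermined is dropped with a log
entry. Reference selection takes the k = 3 most stable genes whose mean Ct
lies within a window (default 3 cycles, widened stepwise with a warning)
of the targets' mean Ct, because a reference should match the targets'
intensity range; the chosen trio is then re-validated with geNorm
(pass iff all M < 0.5 and V < 0.15, both configurable).

The sex-bias test removes outliers per sex on log2 NRQ. The default fence
is Tukey's 1.5·IQR; a literal lower/upper-quartile mode (which by
construction discards about half the replicates) is kept for fidelity
experiments, and the retained sets are provably nested none ⊇ tukey ⊇
literal. The fold change is the difference of per-sex means of log2 NRQ
(a ratio of geometric means, robust at n ≤ 7); its SE combines the per-sex
standard errors. The Wilcoxon rank-sum p is exact (full enumeration, via
scipy) when both groups have ≤10 observations and no ties, asymptotic
otherwise; Benjamini–Hochberg is applied within the tested gene set
(per tissue, since tissues are normalized separately). Calls require both
|FC| ≥ 1.5 and q ≤ 0.05; genes with no determined Ct anywhere are reported
`not_expressed`, and genes with fewer than 3 retained replicates per sex
`untestable`.

## The simulators

**RNA-seq.** Counts are negative binomial around log-normal expression:
log2 relative expression ~ Normal(5, 1.3) for ordinary contigs, lengths
uniform on 500–3000 bp, library sizes uniform on 18–22 million fragments,
NB dispersion 0.03 (biological CV ≈ 17%, appropriate for inbred lines),
and contig-specific sex effects ~ Normal(0, 1.0) in log2 units, shared
across datasets. Planted stable contigs (default 20) are drawn at
log2 expression ~ Normal(12, 0.5) — strongly expressed, as true
housekeeping genes are — with sex effect exactly 0 and near-Poisson
dispersion. Because RNA-seq measures relative abundance, "stable" is
defined in relative units: sex effects redistribute library mass among the
non-stable contigs while the stable contigs' expected library fraction is
held exactly equal between sexes. Planting stability in absolute units
instead would impose a common compositional male/female offset on every
"stable" contig (the heavy-tailed weighted sum of sex effects shifts each
sex's total) and make the planted truth unrecoverable *in principle* by
any relative-abundance screen. Repeat flags (3% of contigs, never on
planted contigs) exercise the repeat filter.

What this does not emulate: real transcriptomes have heavier expression
tails and larger, structured biological variation; mapping artefacts,
multi-mapping and isoform structure are absent. The recovery results
therefore show that the screen's machinery is correct and well-calibrated
under its own assumptions, not that any real dataset will yield ~20 clean
candidates; on real data the CV floor set by compositional and biological
noise is higher, which is exactly why the cross-dataset intersection step
exists.

**qPCR.** Ct(g, s, rep) = mean_ct + loading(s) + effect·[s male] +
biological(g, s) + technical noise, with loading ~ Normal(0, 0.5 cycles)
shared across genes of a sample (the nuisance normalization must remove),
biological noise default 0.15 cycles, technical noise 0.1 cycles over
triplicate wells, 7 biological replicates per sex, and Ct above 35 emitted
as undetermined. One NTC well per gene draws from 38–45 cycles so the
NTC-margin rule can be exercised in both directions. Planted fold changes
enter through each assay's own efficiency, ΔCt = −log2FC/log2(E), keeping
the quantity-scale truth exact (log2FC = 1 at E = 1.89 is a 1.088-cycle
shift). Tissue effects, inter-run calibration and pipetting error
structure are not modelled.

## Problem sizes and numerical conventions

The simulation-based checks use 10,000 contigs × 2 datasets over 20 seeds
for the screen, and 200 seeded replicates each for the ranking and power
studies — sizes at which the statistics of interest are stable while a
full run of the suite plus the acceptance script completes in well under a
minute of compute. All standard deviations are sample SDs (ddof = 1)
unless a method's definition says otherwise; geometric means require
strictly positive input and error otherwise; exact identities are asserted
at 1e−9–1e−12, simulation-based rates at the thresholds stated in the
tests. All randomness flows from a single seed through
`numpy.random.default_rng`; derived seeds stay below 2^31.

## Known limitations

- NormFinder and the RefFinder-style consensus reproduce the published
  algorithms' definitions, not any particular tool's tie conventions or
  web-service output.
- The hairpin/dimer scores are the length of the longest perfectly
  complementary antiparallel run (minimum hairpin loop 3), an integer
  surrogate on the scale of the Primer3-style parameters the thresholds
  were written for; thermodynamic folding is out of scope. Nearest-neighbor
  Tm (SantaLucia parameters, 50 mM Na+, 500 nM oligo) approximates but
  does not reproduce design-tool Tm columns, which rarely state their salt
  and concentration assumptions.
- Three reverse primers in the packaged assay panel (SL_METL1, SL_COQ3,
  SL_AKT6) are 23 nt as printed in the source table although the panel was
  designed at 24–25 nt; they are flagged `truncated_in_source` and stored
  verbatim rather than guessed at.
- The literal lower/upper-quartile outlier rule is preserved only as an
  explicit mode; the default is Tukey fences, since discarding everything
  outside the quartiles halves the replicate count.
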