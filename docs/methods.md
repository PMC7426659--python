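# Methods

This note documents the models implemented in `qmprofiler`, the defaults
and numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Profiling normalizations

**RMP** rarefies every sample to a common read count (default: the minimum
depth across samples) by multivariate hypergeometric subsampling — the
exact distribution of selecting reads without replacement — and divides by
the target, giving proportions.

**QMP** anchors profiles to a per-sample microbial load `L_s` (cells/gram):

1. copy-number correction `C'_st = round(C_st / k_t)` with `k_t` the 16S
   rRNA copies per genome of taxon `t`, converting read counts toward cell
   counts; corrected depth `D_s = Σ_t C'_st`;
2. rarefaction to an even *sampling depth* `SD_s = D_s / L_s` (reads per
   cell): each sample is subsampled to `n_s = floor(SD_min · L_s)` reads,
   where `SD_min = min_s SD_s`;
3. rescaling `abundance_st = rarefied_st / n_s · L_s`.

By construction every column sums to its load exactly, and the realized
sampling depths `n_s / L_s` agree across samples to within `1 / L_s` (the
floor guarantees feasibility; `n_s ≤ D_s` always).  Rounding in the
copy-number correction is half-away-from-zero by default; `floor` and
seeded probabilistic rounding are options.  Taxa whose nonzero counts
collapse to zero are logged.  Taxa missing from the copy-number table fall
back to a configurable default (the table mean when read from file), with a
logged list.

**QMP-PMA** is the identical arithmetic applied to libraries prepared after
propidium-monoazide treatment, which crosslinks DNA not protected inside
intact cells and thereby removes the extracellular/dead compartment from
amplification.

**QMP-qPCR** derives the load from molecular data: the per-sample average
copy number per cell `A_s = R_s / D_s` (raw reads over corrected reads)
converts total 16S copies/gram `Q_s` into `L_s = Q_s / A_s`, after which
the standard QMP normalization runs unchanged.  When `Q_s` is constructed
as `L_s · A_s`, the two routes coincide (bit-for-bit when `A_s` is exactly
representable, e.g. a power of two; to ~1e−12 relative otherwise, because
IEEE multiplication/division round).

Replicate handling: the per-subject load is the mean over that subject's
replicate cell-count measurements, applied to both sequencing replicates;
per-replicate pairing is available by passing a per-sample load series
directly.  All rarefaction uses one user seed; per-sample sub-streams are
spawned deterministically from it in column order, so a profile is a pure
function of (counts, copy numbers, loads, seed).

## Load quantification

*Flow cytometry*: gated events divided by the acquired volume (inferred by
weighing the tube before/after acquisition, default fluid density
1.0 g/ml), times the dilution factor.

*qPCR*: ordinary least squares of Ct on log10(copies) over ≥ 3 standards;
efficiency `10^(−1/slope) − 1`; inversion
`copies = 10^((intercept − Ct)/|slope|)` with explicit template-dilution
and reaction-to-gram factors (assay-specific, never hard-coded).  A flat or
rising fit is rejected rather than returned.

*ddPCR*: Poisson quantification `λ = −ln(1 − p)` from the positive-droplet
fraction `p`, divided by the droplet volume (default 0.00085 µl,
configurable).  A saturated well (`p = 1`) is a hard error — clipping would
silently bias loads — while an all-negative well returns 0 flagged as below
detection.

*Viability differencing*: with paired untreated/PMA loads sharing an
aliquot, `fraction_s = (untreated_s − treated_s)/untreated_s` estimates the
extracellular DNA share; any factor shared by the pair (extraction yield)
cancels exactly.  Significance via the paired Wilcoxon test.

*Delta-Ct arithmetic*: a Ct increase of `d` at efficiency `E` implies a
signal reduction of `(1 − (1+E)^−d)·100` percent.  Because this map is
convex, summarizing several samples by the mean ΔCt or by the mean of
per-sample reductions differ slightly; both modes are provided
(`mean_delta_ct` default).

*Mock community*: the default 12-species even whole-cell mix is a synthetic
illustrative table whose per-species copy numbers average exactly
6.435 copies/genome, the constant used to convert mock qPCR copies into
cells.  Dilution-series evaluation reports per-dilution measured/expected
ratios and the inter-method Pearson correlation on whatever scale each
channel is supplied (Ct channels therefore correlate negatively with
count channels; a constant multiplicative bias leaves r at 1).

## Concordance statistics

Observed richness counts taxa with abundance > 0 (scale invariant).
Bray–Curtis `Σ|x−y| / Σ(x+y)` is computed on the absolute cells/gram
matrices for quantitative profiles by default, with a row-normalizing
option; an all-zero pair returns 0 with a warning.  Bray–Curtis is not a
metric (no triangle inequality), which is why ordination uses classical
PCoA (scikit-bio): negative eigenvalues are reported, not corrected.

Replicate analysis: within-method distance is the BC between a subject's
two replicates under one method; between-method distance is the
replicate-matched BC between the same subject's profiles under two
methods, averaged over replicates (an all-cross pairing was considered and
rejected as the default because it conflates replicate noise with method
effects).  Groups are compared pairwise by the paired Wilcoxon signed-rank
test and BH-adjusted.

Rank concordance selects the top genera (default 15) by mean relative
abundance in a reference profile and reports per-genus Kendall τ-b across
samples between two methods; constant vectors yield NaN.

Wilcoxon signed-rank: zeros dropped; for n ≤ 20 the null distribution of
`W+` is enumerated exactly by convolution over doubled midranks, which
handles ties exactly; above that, normal approximation with tie and
continuity corrections.  Mann–Whitney U: exact enumeration of group
assignments for pooled n ≤ 14 (tie-aware), normal approximation with
corrections otherwise.  Two-sided p-values are
`min(1, 2·min(P(T ≤ t), P(T ≥ t)))` in both.  Spearman p-values are exact
permutation for n ≤ 9 and t-approximate above; Pearson uses the standard
t-distribution.  All tests are two-sided by default.  BH adjustment comes
from statsmodels.

## Dirichlet-multinomial mixture enterotyping

The likelihood of sample `x` (total `N`) under component `k` with
parameters `α_k` (`A_k = Σ_t α_kt`) is
`Γ(A_k)/Γ(N+A_k) · Π_t Γ(x_t+α_kt)/Γ(α_kt)` (multinomial coefficient
omitted; constant across components).  EM: responsibilities by
log-sum-exp; M-step by the Polya fixed-point update
`α_t ← α_t · Σ_s w_s[ψ(x_st+α_t) − ψ(α_t)] / Σ_s w_s[ψ(N_s+A) − ψ(A)]`
(monotone; α floored at 1e−10 against boundary collapse).  Initialization:
k-means on proportion rows, softened to 0.95/0.05 responsibilities; ≥ 3
restarts by default; convergence at relative log-likelihood change < 1e−6
or 500 iterations.  The log-likelihood trace is retained so monotonicity
(within 1e−8) is checkable.

Model selection uses a MAP Laplace approximation of the model evidence,
computed in log-α / additive-log-ratio coordinates under a weak N(0, 3²)
prior on those coordinates.  The prior matters: without it, directions the
data barely constrains (tiny α for rare taxa) have near-zero curvature and
a flat-prior Laplace integral diverges — numerically, flat directions would
*reward* larger K.  The prior contributes `1/τ²` curvature so unidentified
parameters are evidence-neutral.  The Hessian is numeric (central
differences); parameters collapsed to the α floor are treated as pinned and
excluded from both the Hessian and the parameter count.  BIC is available
as a faster alternative (`selection="bic"`).  Hard assignment is argmax
responsibility, ties to the lowest component index with a warning.  Load
differences between the two clusters use the Mann–Whitney U test.

## Synthetic-data generator

The generator emulates a 16-subject cohort sampled in duplicate.  Defaults
(the study conditions): loads uniform on the log10 scale in
[1.2×10^10, 5.3×10^10] cells/gram (only the range is known, so
uniform-on-log was chosen and is flagged here as an assumption);
extracellular DNA fraction Beta-distributed with mean 0.39 (sd 0.05);
sequencing depths uniform in [153527, 282297] reads; FACS counting CV 0.05;
DNA-extraction yield CV 0.5; per-taxon qPCR technical CV 0.1; 40 genera;
16S copy numbers uniform integers in [4, 9] (mean 6.5, matching the
community-average scale of gut mocks) — narrower than the full biological
range so that per-sample average copy numbers vary realistically rather
than being dominated by a single extreme dominant taxon.

Community structure: two templates (*Bacteroides*- vs *Prevotella*-
dominant) with genus abundances decaying geometrically at ~1.2× per rank
(~4 decades over 40 genera, comparable to genus-level fecal profiles).
Per-subject compositions are Dirichlet draws around the template
(concentration 5000, keeping even tail-taxon shapes well above 1 so taxa
are not absent by numerical accident) with lognormal multiplicative jitter
(σ = 0.15) carrying most of the between-subject variation.  These
dispersion values were chosen so that a one-template cohort is
approximately a single Dirichlet-multinomial population — the property
that makes mixture-model recovery a meaningful test.

Moisture and richness: stool moisture is Beta(2,2) scaled to [10, 40]%;
each tail taxon (bottom half of the subject's abundance ranking) drops out
independently with probability `0.6·(moisture−10)/30 + N(0, 0.08)`.
Richness therefore declines monotonically (with noise) as moisture rises,
with rank correlation magnitude ~0.6–0.8 across seeds.  Independent
dropout was chosen over an all-or-nothing rank cut deliberately: a rank
cut imposes a strongly correlated presence/absence factor across taxa that
a DM mixture (correctly) resolves as a second cluster, which is not the
structure the generator is meant to encode.

The extracellular compartment is proportional to each taxon's intact
abundance by default (death evenly distributed across taxa); a `death_bias`
vector biases it toward chosen taxa to simulate the opposite scenario.
The per-sample fraction is defined on copy-weighted DNA mass, the quantity
paired differencing estimates.

Measurement channels: sequencing is multinomial with probabilities
∝ `k_t·(intact+extracellular)` (untreated) or ∝ `k_t·intact` (PMA);
cell counts see only intact cells; molecular loads are
`yield × Σ_t k_t·base_t·ε_t` with the yield factor drawn per aliquot
(shared between a paired untreated/PMA simulation, and shareable between
qPCR and ddPCR on one extract) and ε per-taxon mean-one lognormal technical
noise.  All mean-one lognormal factors return their expectation exactly at
CV 0.

What the generator does *not* emulate: read-level errors, chimeras, primer
bias, OTU/ASV inference and taxonomy assignment, within-subject temporal
variation, aggregation artifacts in cytometry, or saturation of DNA
extraction.  Tests passing on this generator therefore demonstrate the
correctness and statistical behavior of the normalizations and estimators
under the stated noise model — not robustness to upstream bioinformatic
error sources.

## Problem sizes and numerics

The test suite and the reproduction script run cohorts of 16–32 subjects at
sequencing depths of 10^4–2×10^5 reads, DMM selection over K ∈ {1, 2}, and
10^5 draws for rarefaction-distribution checks; these sizes make the exact
oracles (hypergeometric pmf, sign-flip/assignment enumeration) feasible
while keeping each property statistically sharp.  Quantitative-profile
column sums are validated at 1e−6 relative, relative profiles at 1e−9
absolute; EM monotonicity at 1e−8; PCoA round-trips at 1e−6.

## Known limitations

- QMP discards reads from high-depth/low-load samples by design; with very
  unequal `D_s/L_s` ratios the retained depth can be a small fraction of
  the sequenced depth, and rare-taxon ranks below ~3 retained reads are
  not resolvable.
- The Laplace evidence is a local approximation at the EM optimum; for
  strongly overdispersed non-DM data it can still prefer extra components
  (it is approximating a genuinely better fit).
- Exact tests switch to asymptotic approximations above n = 20 (Wilcoxon) /
  pooled n = 14 (Mann–Whitney); p-values near those boundaries differ from
  exact values by up to ~0.01.
- The mock-community species table is illustrative, not a vendor
  specification; only its average copy number is meaningful.
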