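# Methods

## The model

A bulk methylation profile is treated as a linear mixture of region-specific
reference profiles: `m = f × B`, where `B` (probes × regions) holds
region-mean beta values over marker probes and `f` is the vector of
relative region fractions. The system must be overdetermined (more marker
probes than regions); the three default regions are the digestive-tract
surface (DTS), central bulk (CB) and invasive front (IF) of a colorectal
tumor. Linearity assumes beta values mix proportionally with cell content,
which holds approximately for unimodal, non-saturated probes; no
unknown-content or tumor-purity term is modelled — the regions are treated
as an exhaustive basis, and a mixture inconsistent with that basis surfaces
as a high-RMSE fit or a "no admissible composition" error rather than being
absorbed silently.

### Deconvolution

The mixture and the signature columns are z-scored with the pooled mean/SD
of the signature sub-matrix. Because true fractions sum to one, this maps
the mixture onto the same linear combination of the standardized columns,
so the regression coefficients estimate the fractions directly. A
linear-kernel ν-SVR is fitted for each ν in a small grid (default
{0.25, 0.50, 0.75}; C = 1, tolerance 1e−4); ν upper-bounds the fraction of
training errors and lower-bounds the fraction of support vectors, which
here are the CpG loci actively constraining the fit. The fit with the
lowest RMSE between fitted and observed standardized mixture wins, ties
going to the smaller ν. Negative coefficients are truncated to zero and the
remainder normalized to sum to one. If every coefficient is non-positive
the sample is reported as failed. ε-insensitivity makes the estimate robust
to probe-level outliers relative to ordinary least squares; in the
noiseless regime it agrees with non-negative least squares to well under
0.01 per component (measured by the acceptance script).

### DMP ranking

Per-probe one-way F test across region groups, computed on the beta scale
by default; an M-value option (`log2(β/(1−β))`, β clamped to
[1e−6, 1−1e−6]) is exposed because variance stabilization can matter for
extreme betas. p-values come from the F distribution with (G−1, N−G)
degrees of freedom, q-values from Benjamini–Hochberg; ranking is by
ascending p with ties broken by descending F and then probe ID, and
selection is top-n by rank (default n = 3002, the conventional size of a
multiregional DMP profile). Patient pairing is ignored by default (the
unpaired convention of standard array DMP finders); an optional
patient-blocked two-way decomposition is provided for complete
multiregional layouts. Probes that are constant across all samples are
excluded (F undefined) with a log entry; probes with any missing beta among
the analyzed samples are dropped per-operation, never imputed.

### Panel training and the heterogeneity score

A compact panel (default 7 probes) is selected from the top DMPs by
recursive elimination: per-region linear ν-SVR weight models are fitted on
the current probe set, each probe is scored by its maximum per-column-L2-
normalized |weight| over regions, and the lowest-scoring half (at least
one, never past the target size) is dropped; the loop is deterministic,
ties broken by probe ID.

Two weight constructions are shipped, recorded in output metadata:

- **svr-primal** (default of `derive_weights`): for each region, a linear
  ν-SVR of the region-membership indicator on the panel betas; the primal
  weight vector from the support-vector expansion becomes that region's
  weight column. How per-probe-per-region weights are derived from a
  deconvolution model is genuinely open — deconvolution coefficients are
  per-region, not per-probe-per-region — and this discriminative
  construction is one defensible reading. Its signed weights, however,
  routinely produce negative regional sums, which the score rejects (see
  below), so it is most useful for probe ranking.
- **signature**: region-mean betas of the panel probes. Nonnegative by
  construction, hence always score-compatible; this is the construction the
  scoring workflow and the acceptance checks use.

The score for a sample with panel betas βᵢ is the coefficient of variation
of the regional weighted sums S_j = Σᵢ βᵢ·w_{i,j}: population SD over the R
regions (divide by R inside the root, exactly as the formula is printed)
divided by the mean S̄. It is zero iff all S_j coincide, invariant to
positive rescaling of betas or weights, and monotone under mean-preserving
spread of the S_j. Negative regional sums or S̄ ≤ 0 are errors, not
silently absoluted: a CV over sign-mixed scores is meaningless, and
surfacing beats masking. Cohort scoring flags failed samples individually.

Stratification cuts at the linear-interpolation upper quantile (default
0.75) with a strict `>`, so threshold ties fall to the low group. The
four-type grouping with an external MeTIL score cuts MeTIL at its lower
quantile (default 0.25, strict `<`, ties to high): type 1 = score-H/MeTIL-L,
2 = H/H, 3 = L/L, 4 = L/H. MeTIL itself is consumed as a numeric input
only.

### qPCR conversion (QASM)

`ΔCT = CT_meth − CT_unmeth`; `percent = 100/(1 + 2^ΔCT)`. The printed form
of this formula in assay write-ups ("100/(1 + 1/2−ΔCT)") is typographically
mangled; the reading `100/(1 + 1/2^{−ΔCT})` is the only one consistent with
the sign convention — a lower methylated-channel CT must mean more
methylation, given the FAM probe binds the methylated allele. Replicates
are collapsed by averaging CT (the measured quantity) *before* the ratio is
formed; a replicate spread above 0.5 cycles (configurable — no standard
discordance threshold exists) sets a `replicate_spread` QC flag.
"Undetermined" CTs follow a configurable policy: treat as the limit cycle
(default 40, the no-amplification convention) or drop the replicate. A
missing channel leaves the cell missing and flagged, never zero-filled.

### MATH

Per sample: VAF = alt/(alt+ref) per variant; MATH = 100 × MAD/median over
the sample's VAFs, MAD scaled by the normal-consistency constant 1.4826 —
the maftools/Mroz convention. Both the constant and the ×100 are
configurable because printed definitions often omit them. Variant filters
are permissive by default (any depth > 0); a `min_depth` filter is exposed.
Fewer than two usable variants, or a zero median, flags the sample instead
of scoring it.

## The synthetic-data generator

The generator emulates a multiregional tumor methylation study and is the
package's test bed; its defaults are the study conditions of every shipped
check.

**Reference.** Planted DMPs follow a directional progression gradient:
baseline beta drawn from U[0.05, 0.30] at the surface, monotone gains
toward the invasive front, with the CB→IF gap 2.4–3.6× the DTS→CB gap
(each gap at least `separation`, default 0.1; jitter keeps the signature
full-rank). This mirrors the classic picture of progression
hypermethylation accumulating toward the invasive front (the published
panel's loci, e.g. the ZNF154 region, are canonical tumor
hypermethylation markers). Null probes share one mean across regions,
uniform on [0.05, 0.95]. A second layout, `mode="independent"`, assigns
spaced levels to regions in random per-probe order; it is the unstructured,
well-conditioned reference used for deconvolution benchmarks (the
progression layout at high separation concentrates all planted rows on a
nearly common pattern, which ill-conditions the mixture system for reasons
unrelated to the solver).

**Cohorts.** One sample per patient per region; the true fraction vector is
Dirichlet with dominant own-region concentration, the dominance declining
surface → front (5, 3.5, 2): surface samples are near-pure, invasive-front
samples the most admixed, matching the infiltrative biology. Bulk betas are
`B·f` plus truncated Gaussian noise (default SD 0.02) clipped to [0, 1]
(clipping above 1 % of entries is logged). Ground truth (fractions,
admixture entropy, planted probes) is serialized beside the data.

Why the regional score ordering is a *derived* property here, not an
assumption: with panel weights w and mixture fractions f, the regional sums
are affine in f. Under the progression gradient the CB- and IF-deviations
from the surface profile are parallel (Δ ≈ κ·δ with κ > 1), so
S = (S₀, S₀+u, S₀+κu) with u strictly positive and increasing in the
progression load f_CB + κ·f_IF. The CV is therefore monotone in that load,
and the most admixed, front-dominated samples score highest — the ordering
emerges from the generated biology passing through the scorer. Under an
exchangeable (symmetric) reference the same scorer would rank near-pure
samples highest, so passing this check on synthetic data demonstrates the
pipeline propagates a progression signal faithfully; it does not
demonstrate that real tumors follow the gradient model.

**CT plates** invert the conversion formula exactly (ΔCT = log2((1−β)/β),
unmethylated channel at base CT 30) with optional Gaussian replicate
jitter; **MAF tables** draw per-variant clone membership from a weighted
clonal structure, true VAF from a Beta around the clone center, and alt
counts binomially at fixed depth.

What the generator does **not** model: array batch effects, probe
cross-hybridization, FFPE degradation, copy-number distortion of VAFs,
platform transfer of probes between 450k and EPIC (a panel probe absent
from an input matrix is reported, not resolved). Passing tests therefore
say nothing about robustness to those artifacts.

## Problem sizes and numerical choices

The shipped checks use a 200-probe/60-DMP reference with 50 Dirichlet
mixtures for deconvolution; 20 replicate cohorts of 20 patients × 3
regions (400 probes, 60 DMPs) for the regional ordering; 120 probes ×
30 samples for DMP ranking; 100 random instances for the formula-fidelity
oracles; and an 8-patient, 300-probe chain for byte-determinism — sizes
chosen so the full suite runs in seconds while keeping every estimate far
from its decision boundary. Fraction vectors must sum to 1 within 1e−9;
formula oracles agree to 1e−12; the SVR uses deterministic single-threaded
settings throughout, and every CLI output embeds the tool version, config
hash and seed, so identical inputs reproduce byte-identical outputs.

## Known limitations

- The per-probe-per-region weight construction is an interpretation (see
  above); published weight tables cannot be reproduced from first
  principles, so shipped defaults never invent weights — they must be
  trained or supplied.
- The deconvolution basis is assumed exhaustive; no unknown-content or
  purity term.
- The score is undefined for sign-mixed regional sums by design; weight
  matrices with large negative entries will flag many samples rather than
  score them.
- MAF handling consumes only sample, position and tumor read counts; no
  liftover, strand or variant-class logic.
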