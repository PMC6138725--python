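# Methods

This note documents the models behind `coopsyn`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical edge-case policies.

## Effect scale and combination indices

All viability is expressed as a fraction of the vehicle control and
inhibition as E = 1 − viability. Both combination indices are ratios of a
reference effect to the observed combination effect at matched doses:

- HSA: CI = max(E_cur, E_opc) / E_combo
- Bliss: CI = (E_cur + E_opc − E_cur·E_opc) / E_combo

CI < 1 flags cooperativity. The formulas are only meaningful for effects
in [0, 1] (Bliss's product term is a probability argument), so percent
inputs must be divided by 100 upstream and negative inhibition (growth
stimulation) clamps to 0 by default (`clamp=False` disables this, but
then the triples fail validation if outside [0, 1]). Replicates are
averaged (mean) before effects are computed; the choice of averaging
before rather than after the ratio is recorded in the grid output by
construction (one CI per dose pair). A combination effect of exactly zero
raises a typed `UndefinedCombinationEffectError` rather than returning an
infinite CI; dose pairs without matching single-agent anchor rows are
skipped with a logged warning.

Useful identities: the Bliss reference e₁ + e₂ − e₁e₂ ≥ max(e₁, e₂) on
[0, 1]², so Bliss CI ≥ HSA CI everywhere, and both CIs are strictly
decreasing in E_combo.

## Dose-response fitting and DRI₅₀

IC50 estimation uses a four-parameter logistic
v(d) = bottom + (top − bottom) / (1 + (d/IC50)^h), fitted by bounded
trust-region least squares (top ∈ [0, 1.5], bottom ∈ [0, 1], hill ∈
[0.05, 20], IC50 within a ±100× window of the tested doses; tolerances
1e-10; deterministic initialisation from the data — no random restarts).
The initial IC50 guess is the log-linear interpolated 50% crossing. When
fewer than four positive doses are available, the fit does not converge,
or the fitted asymptotes fail to bracket 50% viability, the estimator
falls back to log-linear interpolation between the two doses bracketing
the 50% crossing; `fit_method` records which path ran. Error policy: <2
distinct doses → `InsufficientDataError`; minimum mean viability above
0.5 → `NotReachedError` (no dose reaches 50% inhibition, DRI undefined);
all viabilities below 0.5 → `InsufficientDataError` (the crossing lies
below the tested range and cannot be bracketed).

DRI₅₀ = IC50(single) / concentration in combination at 50% inhibition,
computed along a series in which the partner's dose is held fixed (the
checkerboard design); DRI > 1 is beneficial, with the boundary DRI = 1
not beneficial. Both concentrations are the absolute 50%-viability
crossings of their fitted curves (identical to the IC50 parameter when
top = 1, bottom = 0).

## Stouffer meta-analysis and gene classification

Per cell line and treatment, the DE summary (log2FC, two-sided p) is
converted to a signed z: |z| = Φ⁻¹(1 − p/2), sign(z) = sign(log2FC). This
inverts the usual Wald construction, so when the upstream tool's p came
from a normal statistic the original statistic is recovered exactly; a
precomputed statistic column can be ingested instead (`z_column`).
Combination is unweighted Stouffer, z_meta = Σzᵢ/√k, two-sided p_meta.
Homogeneity of regulation direction demands, by default, that all nonzero
per-line fold-change signs agree (zero contributes nothing); a majority
rule with a configurable agreement fraction is available because
unanimity across a six-line panel is a strict choice.

A gene is *regulated* under a treatment when its Holm-adjusted p_meta is
below α (default 0.05) and it is homogeneous. Venn labels follow set
membership: both single agents → `common`; exactly one single agent →
`opc_only`/`curcumin_only` (regardless of the combination); combination
but neither single → `combination_only`; otherwise `unclassified`.

**Why Holm and not raw p.** Each false discovery lands in one specific
Venn bucket. At 5,000 genes, raw thresholding at α = 0.05 admits ≈ 1.5%
of null genes per treatment — an order of magnitude more than the naive
0.05 × P(unanimous signs) ≈ 0.16% estimate, because sign unanimity and
meta significance are positively correlated under the null (genes whose
per-line signs happen to agree also have inflated |z_meta|). Those nulls
overwhelm the small single-agent-unique buckets (per-class FDR up to
~0.33 on the default planted fixture). Per-treatment Benjamini–Hochberg
controls FDR among each treatment's discoveries but not per bucket
(observed ~0.10–0.13). Holm's family-wise control keeps every bucket's
false-discovery fraction below ~0.07 while costing essentially no power
here, since combining six lines puts true-effect |z_meta| near 6.9.
`adjust="bh"` and `adjust=None` remain available for users who want the
more permissive conventions.

Cooperative genes: a gene qualifies when, in ≥ `min_lines` cell lines
(default 3), |log2FC_combination| strictly exceeds both single-agent
|log2FC| and (by default — `require_line_significance`) the combination
record is significant at α in that line. Output is sorted by gene id and
invariant to row order.

## Enrichment and pathway Venn

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n) — equivalent to one-sided Fisher exact
on the 2×2 table. The universe defaults to all genes present in the
meta-analysis (not the genome); set members outside the universe are
dropped and logged, duplicate query genes dropped with a warning, and
query genes outside the universe are a validation error. Pathway p-values
are unadjusted by default (BH available) since downstream labeling uses a
plain p < α rule; pathways are Venn-labeled exactly like genes.

## Bench metrics

ΔΔCt assumes perfect doubling per cycle (efficiency 2); replicate Cts are
averaged per group × gene before differencing, and fold = 2^(−ΔΔCt) is
relative to the control group after normalisation to the reference gene.
Tumor volume is ½·length·width² (mm³), with width > length rejected as a
caliper-convention violation. The paired t-test uses the n−1 sample SD
with df = n−1; the degenerate zero-variance difference returns t = 0,
p = 1 when the mean difference is also zero and t = ±∞, p = 0 otherwise,
in place of scipy's NaN.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng` seeded explicitly; no
global state. Pipeline stages derive child seeds from the run seed plus a
stage tag, so one integer reproduces a full run byte-for-byte (the
manifest's wall-clock timestamps are the only non-reproducible output).

**Dose-response.** Single-agent truth is Hill-shaped,
v(d) = 1/(1 + (d/IC50)^h) — the curve shape is a modeling choice of this
package, made so that noise-free single-agent curves invert exactly.
Combination truth is the Bliss prediction multiplied by `synergy_factor`
and clamped to [0, 1]; observed viability adds Gaussian noise
(default SD 0.05, a typical WST-1 replicate scatter) and clamps. Dose
grids default to a fine low range for the curcumin-like agent (0.01–5
ng/µl, IC50 0.5) and a coarse high range for the OPC-like agent (10–1000
ng/µl, IC50 200), in triplicate. A multiplicative planted synergy keeps
the Bliss CI of the noise-free surface at exactly 1/`synergy_factor`
wherever unclamped, so the downstream CI recovers the planted factor. A
separate helper (`generate_dri_pair`) plants an exact k-fold potency
shift for DRI validation, because the multiplicative surface's implied
shift is dose-dependent.

**Differential expression.** Summaries are generated directly at the
(log2FC, SE, p) level — count-level simulation is out of scope — with
observed log2FC ~ Normal(true, SE) and p from the two-sided normal test,
so under the null the per-line p-values are exactly Uniform(0, 1) and the
signed-z bridge is exact. Defaults: 6 cell lines (named for a common
colorectal panel), 5,000 genes, planted |log2FC| = 1.5, SE chosen
analytically so one line detects the effect with power 0.8 at α = 0.05
(SE ≈ 0.535). Planted classes: 300 `common` (non-null in all three
treatments), 150 each of `opc_only`, `cur_only`, `combo_only`, and 150
`cooperative`; the rest null. Signs are random per gene but shared across
lines and treatments, so planted genes are homogeneous by construction.
Cooperative genes have zero single-agent effect and a combination effect
of 1.5× the planted magnitude: the class must satisfy the strict
combination-beats-both-singles criterion in most lines *and* map to the
`combination_only` Venn label so the planted cooperative pathway is
recoverable as combination-specific; any single-agent effect large enough
to survive a six-line meta-analysis would re-label it `common`.

**Gene sets.** One set per planted class (50 genes, 90% drawn from the
class, 10% random filler) plus 20 random 50-gene decoys, written as
standard GMT. **Bench fixtures.** Ct tables plant exact fold-changes
(per-sample loading shifts cancel in ΔCt); caliper tables use linear
growth with length ≥ width enforced.

What the generators do *not* emulate: correlated noise between genes or
between cell lines, fold-change-dependent variance (mean–dispersion
trends of count data), composition effects, heterogeneous per-line effect
sizes, non-Hill dose-response shapes, and edge effects of plate layouts.
Passing recovery tests therefore demonstrate the correctness of the
calculus under its own assumptions, not robustness to those real-data
phenomena.

## Problem sizes in the routine checks

The test suite and the reproduction script run the default fixture
(6 × 5,000-gene DE experiment), a 10,000-gene null calibration, 100
replicates of the DRI recovery, and the exhaustive hypergeometric oracle
for all universes N ≤ 25 — sizes chosen to exercise every code path at
full default dimensions while completing in well under a minute on one
core.

## Known limitations

- The HSA/Bliss indices are pointwise ratios; no confidence intervals are
  attached (replicate SD is available upstream but not propagated through
  the ratio).
- Loewe additivity, Chou–Talalay, ZIP and response-surface models are out
  of scope by design.
- The 4PL fit estimates all four parameters; with narrow dose ranges the
  top/bottom asymptotes are weakly identified and the absolute-50%
  crossing should be preferred over the midpoint parameter (the DRI code
  does this).
- Venn labels are hard threshold calls; a gene just above α in one
  treatment and just below in another flips buckets. The Holm default
  makes the buckets conservative, not uncertainty-aware.
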