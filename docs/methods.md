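# Methods

## The model

Bulk tumor expression is treated as a two-compartment mixture. For a gene
*g* and sample *i* with tumor purity *p_i* (fraction of malignant cells,
an input here — typically produced upstream by a purity estimator such as
ESTIMATE):

    e_bulk[g, i] = p_i · ē_T[g] + (1 − p_i) · ē_S[g]

with ē_T and ē_S the average expression of *g* in the tumor and stroma
(all non-malignant) compartments, assumed constant across samples. Each
gene is fit independently by **non-negative least squares** on the design
matrix [p, 1−p] (`scipy.optimize.nnls`); nonnegativity is the natural
constraint for expression levels, and the per-gene fit reflects the
model's lack of cross-gene coupling. The fit is performed in linear
expression space — the mixing equation is linear in expression — and
users working with log-transformed matrices should exponentiate first.
The two design columns are collinear exactly when purity is constant, so
a constant purity vector is rejected rather than silently producing an
arbitrary split; purity values of exactly 0 or 1 are allowed. Samples
lacking a purity value are dropped with a logged count rather than
imputed.

## Relative Crosstalk scores

Under mass action, the concentration of a ligand-receptor complex is
[L][R]/K_D. Taking compartment mean expression as a proxy for
concentration and assuming a uniform K_D, the Relative Crosstalk score of
a pair on the source→target axis X→Y is the share of the total
interaction product attributable to that directionality:

    RC_X,Y = ē_L,X · ē_R,Y / (ē_L,T·ē_R,S + ē_L,T·ē_R,T + ē_L,S·ē_R,S + ē_L,S·ē_R,T)

The four scores (tumor→tumor, tumor→stroma, stroma→tumor, stroma→stroma)
sum to one. Because the denominator factorizes as
(ē_L,T + ē_L,S)(ē_R,T + ē_R,S), each score is the product of a ligand
compartment fraction and a receptor compartment fraction — an algebraic
identity the tests exploit as an internal oracle. The K_D constant
cancels; it is kept as an explicit parameter (`kd_inverse`, default 1) so
the cancellation itself is testable. Pairs whose denominator is zero
(gene absent from both compartments) carry no directional information and
are reported undefined by default (`zero_policy="uniform"` assigns 0.25
to each axis instead). Multi-subunit receptor complexes are not modeled:
catalog entries containing `+` are rejected. Per-axis gene sets take the
top-k pairs (default 15) by descending score, ties broken by ascending
(ligand, receptor) for reproducibility, and return the union of their
gene symbols.

## Consensus, survival, correlation

**Consensus.** Genes appearing in ≥ `min_sets` (default 2) of the named
evidence sets, after uppercasing and whitespace stripping. No alias
resolution is attempted — inputs are expected to use HUGO symbols.

**Survival.** For each gene, samples are split at the median expression;
"high" means strictly above the median, so ties at the median go to the
low group (a deterministic, documented convention). Group survival is
estimated with the Kaplan-Meier product-limit estimator and compared with
the two-group Mantel-Haenszel log-rank test (both via `lifelines`);
median survival is the earliest time the estimate drops to ≤ 0.5 and is
reported as "NR" when the curve never does. P-values are
Benjamini-Hochberg adjusted (`statsmodels`) across the tested gene list
within each endpoint, matching the per-endpoint adjusted columns a
clinical screen reports. Cox regression and covariate adjustment are out
of scope.

**Correlation.** Pairwise Spearman rho with average-rank tie handling and
the t-approximation for p on n−2 df (`scipy.stats.spearmanr`); exact
permutation p-values are impractical at cohort scale. Pairs with
rho > 0.8 are flagged "strong" in the report; the flag never filters.
Constant gene vectors have undefined rank correlation and are reported
missing, not zero.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not a transcriptome-realistic simulator:

- Compartment means ē_T, ē_S are log-normal (location 2, scale 1 on the
  log scale), giving right-skewed, strictly positive profiles.
- Purity is Beta(5, 2) clipped to [0.05, 0.95]: skewed high as in solid
  tumor cohorts, with enough spread for identifiability.
- Bulk values are the exact mixture times exp(ε), ε ~ N(0, σ²), σ = 0.1
  by default — multiplicative log-normal noise keeps values positive and
  heteroskedastic.
- Planted pairs (default 5 per axis, from a 150-pair catalog over 500
  genes) have the ligand's source-compartment fraction and the receptor's
  target-compartment fraction set to `planted_fraction` (default 0.9), so
  the true RC score on the planted axis is 0.9² = 0.81 — far above the
  background, which makes top-15 recovery a sharp test.
- Survival is exponential with hazard h₀·exp(β·Σ_g z_g,i) over the
  designated prognostic genes' standardized bulk expression
  (h₀ = 0.01/month ≈ 69-month baseline median, β = −0.7, i.e.
  protective), censored at Uniform(0, 240) months. The closed-form
  median ln2/h provides an analytic recovery oracle.
- Evidence sets are realized *exactly* from a three-set overlap design
  (defaults: sizes 40/35/30, pairwise overlaps 6/5/4, triple 2, hence a
  designed consensus of 11), so consensus counts are deterministic.
  Prognostic genes are placed into shared regions first, so the planted
  survival signal flows through the consensus step.

Everything derives from one integer seed through spawned PRNG streams;
equal configs give byte-identical bundles.

What the simulation does *not* emulate: count noise and library-size
effects, gene-gene co-expression structure beyond the shared purity
factor, more than two compartments, informative censoring, or
single-cell data. One consequence worth knowing: because every gene's
bulk value shares the purity factor, genes with similar
tumor/stroma balance are correlated with each other — and with the
planted hazard — so a median-split screen on synthetic data can flag
non-prognostic genes that track purity. That is a real property of bulk
cohorts (purity confounding), not an artifact, but passing tests here do
not certify behavior on real transcriptomes.

## Numerical choices

- NNLS residual `residual_ss` is the attained minimum; on noise-free
  mixtures it is zero to machine precision.
- RC normalization and factorization hold to 1e-12; tests assert at that
  tolerance.
- Dense ranks per axis are computed among defined pairs only; undefined
  pairs carry no ranks.
- All file writes are atomic (temp-then-rename), so interrupted runs
  leave no partial artifacts.
- Problem sizes in the test-suite and acceptance checks (500 genes × 100
  samples; 2,000 null replicates of 100-vs-100 for log-rank calibration;
  1,000 draws for RC algebra) were chosen as the smallest cohorts at
  which the recovery statistics are stable.

## Known limitations

- "Negative least-squares" in the source description of this class of
  analysis is read as non-negative least squares; the package documents
  and implements the nonnegative fit.
- The purity input is trusted as-is; errors in purity propagate directly
  into compartment estimates.
- A uniform K_D across pairs is a strong assumption; RC scores are
  relative directionality shares, not binding affinities, and carry no
  significance measure.
- The survival screen is univariable; purity itself is a plausible
  confounder of both expression and outcome.
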