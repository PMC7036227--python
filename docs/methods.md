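# Methods

## Model

A BCR repertoire time course is summarised as a tensor of clonal abundances
x_ist (clone i, individual s, time t; t = 0 is the pre-vaccination sample,
time values are days). Each clone carries a latent class
γᵢ ∈ {bg, ns, vs}, drawn with probabilities Γ. Conditional on the class:

- **Presence.** Per individual, z_is ~ Bernoulli(p_class) says whether the
  clone exists in that person's repertoire at all. Background and
  non-specific clones share one presence probability p_bg;ns; the
  vaccine-specific class has its own p_vs, which is how convergent
  ("public") responses are expressed.
- **Capture.** Per sample, a present clone is captured with probability q
  (sampling is sparse; a present clone usually yields zero reads). An
  absent clone yields zero reads with probability one.
- **Abundance.** A captured clone emits a count ≥ 1 from a two-leaf
  mixture: with weight 1 − ω a zero-truncated negative binomial
  ZTNB(μ, r) (ordinary, low-abundance B cells) and with weight ω a
  discretized generalized Pareto dGPD(ξ, σ, u) (plasma cells or large
  clonal expansions — the heavy tail).

Counts are conditionally independent across samples given (γᵢ, z_is). The
joint probability of data, latent variables and parameters factorises over
clones, individuals and time points accordingly.

The count parameters (q, ω, μ, r, ξ, σ) are not free per (class, time) but
tied through two **regimes**:

| class | t = 0 | t > 0 |
|-------|-------|-------|
| bg    | Q     | Q     |
| ns    | A     | A     |
| vs    | Q     | A     |

Q ("quiescent") and A ("activated") each carry one full set of count
parameters. This encodes three assumptions: background and non-specific
abundances are time-independent; vaccine-specific clones are
indistinguishable from background before vaccination; and post-vaccination
they follow the same abundance law as non-specific responders. Identifying
the vs class therefore rests entirely on the *switch* between regimes at
t = 0 combined with its own presence probability.

### Leaf support and the role of q

The two count leaves live on {1, 2, …} (the dGPD location u defaults to 1)
and the entire conditional mass at zero given presence is carried by the
explicit escape-sampling probability 1 − q. This keeps ω interpretable
exactly as "the probability that an *observed* clone is drawn at high
abundance", matching how the fitted summary tables are usually reported.
The leaves overlap on positive counts; the mixture weight resolves
attribution, with the responsibility for each count split in the E step.

The dGPD is discretized by CDF differencing on unit intervals:
pmf(x) = F(x − u + 1) − F(x − u) with F the continuous generalized Pareto
CDF (computed via survival functions in log space). Its shape ξ is
constrained to [0, 10] during fitting: negative shapes have bounded support
and assign zero probability to tail counts, defeating the leaf's purpose.
The negative binomial is parametrized by mean μ and dispersion r (variance
μ + μ²/r) and computed in log space throughout.

### Priors

Flat: Dirichlet(1,1,1) on Γ, Beta(1,1) on every probability, improper flat
on (μ, r, ξ, σ). MAP therefore coincides with maximum likelihood and the EM
objective is the marginal log likelihood; no prior-smoothing pseudo-counts
enter the updates.

## Inference

Soft EM. The E step computes, in log space with max-subtraction: per-clone
class responsibilities ∝ Γ_c · L_ic; per (clone, individual, class) presence
posteriors (certain whenever any count is positive); and per observed count
the posterior over the low/high leaf. The M step updates Γ, the tied
presence probabilities, q and ω per regime in closed form (weighted
Bernoulli/multinomial MLEs pooled over the tied cells) and the count-leaf
parameters by Nelder–Mead on the expected complete-data log likelihood,
aggregated over *unique* count values — which is what makes iterations on
10⁵-clone tensors take well under a second. A proposed count-leaf update is
accepted only if it improves its own objective, so EM monotonicity is
preserved even if the optimizer stalls.

### Truncation

Only observed clones enter the tensor, so by default the fit maximises the
likelihood conditioned on each clone being observed at least once
(`truncation_correction=True`). Each iteration imputes the expected number
of unobserved clones, m = K·P₀/(1 − P₀) with P₀ the current all-zero
probability, and includes them as weighted pseudo-observations in the Γ, p
and q updates — the classical EM treatment of truncated samples, monotone
in the conditioned likelihood. Without the correction the fit targets the
plain unconditioned objective and inherits a small truncation bias in Γ and
p (of order 10⁻³ in Γ_bg under hepatitis-B-like parameters); the
uncorrected variant is retained as an option and the exhaustive-enumeration
oracle checks the unconditioned quantities, which the correction does not
alter (conditioning on a clone's own data already implies it was observed,
so responsibilities are identical).

### Initialization and label anchoring

Label switching is prevented solely by the starting point: Γ = (.99, .005,
.005), p_bg;ns = 0.2 < p_vs = 0.6, ω_Q = 0.01 < ω_A = 0.2, μ_Q = 1 < μ_A =
5, q_Q = 0.3 < q_A = 0.5. The class that starts more shared and more
abundant post-vaccination stays the vaccine-specific one; no post-hoc
relabelling is done. Convergence is declared when the objective changes by
less than `tol` (default 10⁻⁶ absolute) with a cap of 500 iterations;
non-convergence is reported on the result, not raised. Probabilities are
floored at 10⁻¹² during the M step, except ω which may reach exactly 0 — a
regime can genuinely lack a heavy tail, as the influenza-style fit does.
Exact posterior ties in MAP labelling resolve toward the least specific
claim (bg over ns over vs).

## Clonal identification

Hamming identity (matching positions / length) on same-length sequences,
strict inequality against the threshold (0.85 nucleotide / 0.90 amino
acid). Greedy clustering: among unassigned sequences, the one with the most
unassigned neighbours becomes a centre and claims them; ties break by
higher total read abundance, then lexicographically smaller sequence, so
output is deterministic. Neighbour counts are over distinct sequences, not
reads. Sequences are bucketed by length first; within a bucket comparison
is all-pairs, computed column-wise on byte arrays to bound memory. Clones
are built pooling all individuals and time points; per-sample counts are
kept for the tensor. Assignment of an external sequence picks the
qualifying centre with the highest identity (ties: larger clone, then
lexicographically smaller centre).

## Simulator

`sample_dataset` draws exactly the generative process above, then discards
clones observed nowhere and resamples until the requested number of
*observed* clones exists, recording the discard count. The discard step
mirrors the restriction of the fitted model to observed clones; the induced
gap between Γ and the realised class proportions among observed clones is
deliberately reproduced, not corrected. A single root seed drives one
`numpy` Generator consumed in a fixed order, so output is bit-exact
reproducible. ZTNB draws use rejection of zeros; dGPD draws use
u + ⌊Y⌋ with Y continuous GPD via inverse-survival sampling, which has
exactly the CDF-differenced pmf.

The simulator emits clone-level count tensors only — no CDR3 strings with
mutation structure — because that is all the model consumes; sequence-level
inputs for the similarity module come from small string fixtures in the
tests. Emulated features of real data: sparse capture, presence structure
across individuals, heavy-tailed abundances, regime switching at t = 0.
Not emulated: sequencing error, PCR amplification bias, V(D)J composition,
within-clone sequence diversity, non-stationary post-vaccination dynamics
(all post-vaccination time points are exchangeable in the model). Passing
recovery tests therefore demonstrates correctness of the inference under
the model's own assumptions, not robustness to these real-data features.

### Default count parameters

Published summary tables for this kind of analysis report Γ, p and ω but
not q or the count-leaf parameters. The package's documented defaults —
q_Q = 0.3, q_A = 0.7; ZTNB Q (μ = 0.5, r = 0.7), A (μ = 3.0, r = 0.8);
dGPD u = 1, Q (ξ = 0.5, σ = 10), A (ξ = 0.6, σ = 30) — were chosen once so
that simulated repertoires reproduce the scale of reported real-data
summaries (background clones averaging ~2–3 reads in total across all
samples, activated clones averaging tens to hundreds with a long tail),
and are used wherever a study-style simulation is needed. The q ties follow
the ω ties (one value per regime); the class/time structure of q is not
something the reported tables pin down, and this is the natural choice
consistent with the regime structure.

## Thresholding baseline

Per (individual, time) sample, the threshold is the linear-interpolated
empirical quantile of the *nonzero* clone abundances, so the absolute cut
tracks sequencing depth. A clone is called vaccine-specific iff in at least
one individual it is ≤ threshold at t = 0 (absence counts as below) and
strictly above threshold at ≥ 1 post-vaccination time point in that same
individual (`rise_scope="any"` relaxes the same-individual requirement),
and it is present (any positive count, any time) in ≥ min_shared
individuals. Agreement numbers are sensitive to the quantile convention,
hence it is pinned down here. Note a structural property: the rule is
monotone in min_shared on any input, but *not* in the abundance quantile —
raising the quantile also raises the pre-vaccination threshold, which can
flip the baseline clause from failing to passing. The test suite freezes a
counterexample; quantile monotonicity is guaranteed (and tested
exhaustively) only for clones with no pre-vaccination signal.

## Sequence similarity

Levenshtein distance via `edlib`; within-set similarity is the mean over
all unordered pairs. Significance by bootstrap: n_boot (default 1000)
same-size draws *without replacement* from a pool (default: all clone
centres, including the tested subset; optionally length-matched to the
subset's length multiset), one-sided for the subset being more similar,
with add-one correction p = (1 + #{null ≤ observed}) / (n_boot + 1) — so
the minimum attainable p at 1000 draws is ≈ 0.001 and ties count toward
the null. Petri-plot graphs connect centres at distance < n/denom; for
unequal lengths n is the length of the lexicographically first of the pair
(configurable to min/max/mean).

## Truth-set evaluation

A clone overlaps the truth set iff some truth sequence would be assigned to
it (same length as the centre, identity strictly above the clustering
threshold), so overlap is invariant to duplicated truth sequences. Reported
per class: clone counts, mean ± sd of total abundance overall and within
the overlapping subset, and overlap fractions. "Sensitivity" is the
fraction of vaccine-specific calls overlapping the truth set — a
truth-set-limited quantity, since enrichment-derived truth sets carry
substantial contamination. Enrichment is tested by a two-tailed chi-squared
on the 2×2 table (class ∈ {vs, bg}) × (in truth ∈ {yes, no}), no
continuity correction by default (Yates optional); a table with an empty
row or column yields NaN with a warning rather than a test statistic.

## Known limitations

- Γ is only weakly identified when one class generates nearly all data:
  the other components' free parameters can copy its distribution, so a
  few percent of mixture weight can sit on empty classes even when MAP
  labels are 100% correct.
- All post-vaccination time points are exchangeable; rise-then-decay
  dynamics within t > 0 are not modelled.
- No parameter uncertainty is reported: with 10⁵–10⁶ clones the sampling
  error on Γ, p, ω is negligible next to model misspecification, and
  quoting it would suggest spurious precision.
- Multiple pre-vaccination samples per individual are out of scope; t = 0
  must be the unique baseline level.

## Problem sizes used in the checks

Parameter recovery is exercised at 100,000 observed clones (5 individuals,
5 time points, hepatitis-B-style parameters) and 30,000 clones (7
individuals, 3 time points, influenza-style parameters with ω_Q = 0);
exhaustive latent enumeration oracles run at K ≤ 10, S ≤ 2, T ≤ 2 where
the 2^S · 3^(S·T) configuration space is tractable; clustering oracles at
30 unique sequences; bootstrap calibration at 500 replicates of n_boot =
199. These sizes were chosen so the full check suite completes in minutes
on a single CPU while leaving Monte-Carlo error well inside the asserted
tolerances.
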