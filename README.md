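# bcrmix

Bayesian mixture modelling of B-cell-receptor (BCR) clonal abundance across
individuals and time points, for identifying vaccine-specific clones from
CDR3 repertoire sequencing.

## The problem

Vaccination triggers clonal expansion of the B cells whose receptors bind
the antigen, and — because different people facing the same antigen often
converge on similar receptors — an increase in sequence sharing between
individuals. Both signals are buried in repertoires dominated by millions of
non-responding clones, many seen as a single read in a single sample, plus
clones responding to unrelated stimuli. `bcrmix` models these signals
jointly instead of thresholding them separately.

## The model

Sequences are first grouped into *clones*: greedy clustering in which the
unassigned sequence with the most unassigned same-length neighbours
(positional identity > 85% for nucleotide, > 90% for amino-acid data)
becomes a clonal centre and claims its neighbours. The data are then the
clonal abundances *x_ist* of clone *i* in individual *s* at time *t*
(*t* = 0 pre-vaccination).

Each clone carries a latent class γᵢ ∈ {bg, ns, vs}: background
(non-responding), non-specific responder, vaccine-specific. Per individual,
a latent presence indicator z_is ~ Bernoulli(p_class) models sharing; per
sample, a present clone is captured with probability q and, if captured,
emits a count from a two-leaf mixture — a zero-truncated negative binomial
(low abundance) with weight 1−ω, or a discretized generalized Pareto (high
abundance, heavy tail) with weight ω:

```
p(θ, γ, z, e, x) = p(θ) ∏ᵢ p(γᵢ) ∏ₛ p(z_is | γᵢ) ∏ₜ p(e_ist | γᵢ, z_is, t) p(x_ist | e_ist, θ)
```

Count parameters are tied through two abundance *regimes*: background clones
are quiescent (Q) at all times, non-specific responders are activated (A) at
all times, and vaccine-specific clones are quiescent at *t* = 0 and activated
after — so "looks like background before vaccination, like a responder
afterwards" is built into the parameter space. Background and non-specific
clones share one presence probability; vaccine-specific clones have their
own (convergence across individuals). Inference is by EM with an anchored
initialization that fixes each class's biological identity (no label
switching); by default the likelihood is conditioned on each clone being
observed at least once, since unobserved clones are not in the tensor. The
reported quantities are Γ (class proportions), p (presence probabilities)
and ω (high-abundance weights).

The package also implements the quantile-thresholding baseline (below a
per-sample abundance quantile pre-vaccination, above it post-vaccination,
shared by ≥ m individuals), a bootstrap Levenshtein-distance test for excess
sequence similarity within a class, petri-plot similarity graphs, and
truth-set evaluation (overlap tables, sensitivity, chi-squared enrichment).

## Worked example

Simulate a repertoire from the generative model at the parameter values
fitted to a hepatitis-B booster study (Γ = .992/.005/.003, p = .216/.970,
ω = .006/.277), then refit from scratch:

```python
import bcrmix

truth = bcrmix.make_params((0.992, 0.005, 0.003), 0.216, 0.970, 0.006, 0.277)
sim = bcrmix.sample_dataset(truth, K_target=30_000, S=5, T=5, seed=7)
model = bcrmix.BcrMixtureModel().fit(sim.tensor)
print(f"Gamma_bg = {model.params_.gamma[0]:.4f}")
print(f"p_vs     = {model.params_.p_vs:.4f}")
print(f"omega_A  = {model.params_.omega['A']:.4f}")
print((model.labels_ == sim.true_class).mean())
```

prints

```
Gamma_bg = 0.9931
p_vs     = 0.9586
omega_A  = 0.2826
0.9978666666666667
```

i.e. at 30,000 observed clones the background proportion and activated-regime
high-abundance weight are recovered to within a few thousandths, the
vaccine-specific presence probability to within about 0.01 (it sharpens
with more clones), and 99.8% of clones get their generating class back.
The same model drives the command line:

```bash
bcrmix cluster  --input repertoire.tsv --out-clones clones.tsv --out-tensor tensor.tsv
bcrmix fit      --input tensor.tsv --out-params params.json --out-labels labels.tsv
bcrmix threshold --input tensor.tsv --quantile 0.99 --min-shared 3 --out calls.tsv
bcrmix similarity --labels labels.tsv --class vs --out-report sim.json --out-edges edges.tsv
bcrmix evaluate --labels labels.tsv --tensor tensor.tsv --truth truth.fasta \
                --clones clones.tsv --out table.tsv
```

or end to end from one YAML config: `bcrmix run --config config.yaml --outdir out/`.

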