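# Methods

## The integration model

Candidate positions are produced by merging all calls from J tools; every
position therefore has support count x_i ≥ 1.  This conditioning is what
makes the model well-posed for SV integration: a "negative" position that no
tool reported is never observed, so the model describes the joint law of the
reporting pattern *given that the position exists in the merged set*.

For position i with latent truth z_i ∈ {0, 1}:

* z_i ~ Bernoulli(π).
* x_i | z_i = c ~ Categorical(ω_c) on {1..J}, with ω₁ strictly increasing
  and ω₀ strictly decreasing in k (the voting effect).
* The reporting set given x_i = k is a weighted selection without
  replacement with weights v_{·k} (column-stochastic J×J matrix v),
  independent of z_i.  Consequently p(y | x) is a constant factor in the
  z posterior: the PEPs are provably invariant to v, v is not sampled, and
  `subset_logprob` (exact enumeration over the k! draw orders) exists for
  simulation and optional full-likelihood reporting only.
* For each scoring tool j ∈ A, a latent o_ij ~ N(μ_{z_i j}, σ²_{z_i j})
  with μ₁ⱼ > μ₀ⱼ underlies the observed score:
  s_ij = a_j if o_ij ≤ a_j, b_j if o_ij ≥ b_j, otherwise o_ij.
  An observation at a bound contributes the Gaussian tail mass, interior
  observations the density.  Missing scores (tools outside A, or an absent
  value) contribute no factor, which equals integrating them out.

The posterior error probability is PEP_i = P(z_i = 0 | data); with fixed
parameters it has the closed form

    PEP_i = 1 / (1 + exp(Λ_i)),
    Λ_i = log[π ω₁ₓᵢ Π f₁ⱼ(s_ij)] − log[(1−π) ω₀ₓᵢ Π f₀ⱼ(s_ij)],

implemented in `exact_pep` and used as the oracle for the sampler.

## Sampler

A data-augmented Gibbs sampler with sweep order z → o → (μ, σ) → ω → π:

* **z**: the collapsed full conditional p(z_i | s, θ) (o integrated out) is
  Bernoulli(1 − PEP_i); drawing z marginally and then o | z is a valid
  blocked draw from their joint conditional.
* **o**: interior scores are copied; bound scores are imputed from the
  matching Gaussian tail by a log-space inverse-CDF sampler
  (`ndtri_exp(log u + log Φ(α))`), accurate arbitrarily far into the tail.
* **(μ, σ)**: per tool, both components are proposed jointly from their
  unconstrained Normal–Inverse-Gamma conditionals given the imputed o's and
  accepted iff μ₁ > μ₀ (independence Metropolis on the mean-ordered target;
  an empty component falls back to a prior draw).  Because components
  dominated by censored observations (e.g. a tool left-censored at 0 whose
  false-positive component sits almost entirely below 0) mix very slowly
  through the o-augmentation, each sweep adds a few collapsed random-walk
  Metropolis moves on (μ, log σ) targeting the *observed* censored
  likelihood directly; interleaving kernels with the same stationary law
  keeps the posterior invariant and removes the pathology.
* **ω₁, ω₀**: counts n_{ck} = #{i : z_i = c, x_i = k} give the
  unconstrained Dirichlet(α + n_c) conditional; proposals are drawn from it
  and accepted iff the strict ordering holds (an accepted draw is then an
  exact sample from the order-truncated conditional), retrying up to
  `constraint_retry_cap` times.  When all proposals fail — which is the
  normal situation when the data push against the ordering, as in the
  voting-mis-specification scenario — one exact coordinate-Gibbs pass over
  the truncated Dirichlet is run instead: for each adjacent pair the
  fraction u = w_k/(w_k + w_{k+1}) follows a truncated
  Beta(α_k, α_{k+1}), drawn by inverse CDF.
* **π**: conjugate Beta update.

Initialisation is deterministic: positions with observed scores start at
z = 1{mean tool-centred score > 0}, score-less positions at the majority
vote 1{x ≥ ⌈J/2⌉}; μ, σ from the component-wise score moments under that
split; ω from empirical count frequencies sorted into the ordered region;
π from the initial z mean.  The score-based start matters: a purely
count-based start is uncorrelated with the truth when the count
distributions are uninformative, and occasionally trapped chains in a
spurious mode with inflated σ₀ and deflated π.

PEP_i is the mean of 1{z_i = 0} over retained draws pooled across chains.
Convergence is monitored by split-R̂ and bulk ESS (via arviz) on all scalar
parameters; a single chain is split in halves for R̂.  Any R̂ > 1.1 sets a
non-fatal warning flag on the summary.

## Priors and defaults

| Parameter | Prior | Default |
|---|---|---|
| π | Beta(a, b) | (1, 1) |
| ω₁, ω₀ | Dirichlet(α·1) truncated to the ordered region | α = 1 |
| (μ, σ²) per tool/component | Normal–Inverse-Gamma (m, κ, shape, scale) | (0, 0.01, 1, 1) |

All are exposed in `PriorConfig`.  `McmcConfig` defaults to 5000 iterations,
2000 burn-in, thin 1, 2 chains; a seed is required and makes runs
bit-reproducible.  Strict ordering is enforced with zero tolerance (weak
violations rejected).

## FDR control

Decisions use a strict cutoff: D_i = 1 iff PEP_i < τ.  The estimated FDR of
any selection is its mean PEP (the expected number of false positives is
the PEP sum).  Two constructions are provided: `fdr_at_threshold` for a
given τ, and `threshold_for_target`, which sorts PEPs ascending and takes
the longest prefix with running mean ≤ the target, reporting the implied τ.
A tied boundary value is included or dropped as a whole group so the
selection remains expressible as a strict cutoff, and a PEP of exactly 1 is
never eligible.  Per-tool FDR estimates are the mean PEP over each tool's
own calls; a silent tool yields a missing value, never zero.
`pep_histogram_and_curve` tabulates FDR and selection size along a τ grid.

## Merging

Calls from the same chromosome and (by default) the same SV type are
clustered by single linkage: two calls link when their breakpoints lie
within `max_breakpoint_distance` (default 1000 bp; start distance for
insertions, max of start/end distance otherwise) and their |SVLEN| agree
within `min_length_ratio` (default 0.7; ignored for breakends).  The
defaults are community-standard values for long-read SV comparison and are
fully configurable.  Within a cluster each tool keeps its highest-scoring
call (leftmost on ties); representative coordinates come from the
lowest-index reporting tool; scores are clipped into the tool's declared
bounds so a bound value is read as a censored observation.  Merging is
deterministic and invariant to input record order.

## Synthetic data

`simulate` draws from exactly the generative law above, so the fitted model
is correctly specified in the base scenario.  The three packaged scenarios:

1. **Case 1 (model-true)** — n = 2000, π = 0.7, J = 5 equally weighted
   tools, ω₁ = [.05,.10,.15,.25,.45], ω₀ = [.40,.25,.15,.12,.08]; tools 3–5
   score with μ₁ = 2, μ₀ = −2, σ = 1; tool 4 left-censored at 0, tool 5
   right-censored at 0.
2. **Case 2 (score mis-specification)** — each generated score swaps its
   Gaussian component with probability 0.10, independently per score and
   for every scoring tool (a per-position reading of the swap is the main
   alternative; the per-score reading is this package's declared choice).
3. **Case 3 (voting mis-specification)** — ω₁ and ω₀ drawn fresh per
   replicate from Dirichlet(50·1₅) with *no* ordering imposed, while the
   fitted model keeps its constraints.

What the generator does **not** emulate: breakpoint/length noise in the
merging step (simulated matrices are produced post-merge), caller
correlation beyond the shared count x, genotype errors, and read-level
artefacts.  Passing tests therefore validate the inference and FDR
machinery under the stated stochastic law, not the upstream behaviour of
real callers; the VCF path is exercised separately on toy fixtures.
Simulated matrices carry no genomic coordinates; an optional decorator
(`attach_synthetic_coordinates`) assigns synthetic ones so the VCF writer
can run end-to-end.

## Evaluation and baselines

Vote 1 declares a positive when at least half the tools report
(⌈J/2⌉ = 3 of 5, which reproduces the closed-form Vote-1 cells), Vote 2
requires unanimity.  Single-tool rows use the tool's own calls; their
recall is measured over merged positions, i.e. P(tool reports | true), with
closed form Σ_k ω₁ₖ·k/J = 0.79 under Case 1.  Precision/recall/F1 are
computed against the simulation truth with undefined values reported as
missing, never zero.

`replicate_study` runs simulate→fit→evaluate per replicate and aggregates
mean (SD) per method.  Study fits use 3000 iterations / 1000 burn-in on a
single chain per replicate — the package's chosen budget for the replicate
studies, at which all study quantities are stable to well within replicate
SD; `run_mcmc`'s own default stays at the fuller 5000/2000/2-chain setting.

## Numerical and design notes

* Log-space throughout: tail masses via `log_ndtr`, posterior odds via
  `expit`, so extreme PEPs (≈1e−17) are exact to double precision.
* Constraint enforcement is propose-and-keep-current (a valid move for the
  truncated targets) rather than rejection-until-success, bounding sweep
  cost.
* `threshold_for_target` rather than a direct τ = target cutoff defines the
  named selections ("model at 95%" = target FDR 0.05): the prefix rule
  makes the *estimated* FDR of the selection hug the target, which is the
  natural reading of selecting "at" an FDR level; both constructions are
  exported.
* Degenerate inputs: empty call matrices yield empty summaries/valid empty
  VCFs; a tool with no calls gets a missing FDR; π = 1 forces PEP = 0.

## Limitations

* MCMC cost grows linearly in n and iterations; for very large call sets
  split by chromosome or SV type (also advisable when score quality varies
  across types).
* FDR calibration inherits the score model: when scores are
  mis-specified the per-tool FDR estimates are biased (Case 2 reproduces
  this deliberately), though ranked selections remain useful.
* Breakend pairing, genotype reconciliation across tools, and multi-sample
  merging are out of scope.
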