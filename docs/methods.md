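# Methods

## Model and assumptions

A water sample contains S identifiable species (OTUs at 97% identity);
the sequenced reads are treated as a random sample from a much larger
pool of DNA, so each species' read count is modelled as Poisson with a
species-specific mean λ drawn i.i.d. from a mixing density g(λ; θ) — a
taxon abundance distribution (TAD). Four families are supported:
Poisson log-normal, Poisson log-Student, Poisson inverse Gaussian (PIG)
and the Sichel distribution (Poisson over a generalized inverse
Gaussian, GIG). The GIG density is parameterized as
g(λ) ∝ λ^(γ−1) exp(−(ψλ + χ/λ)/2); PIG is the γ = −1/2 special case,
so the two families are nested. θ lives on the *count* scale: a fitted
model is tied to its sample's depth N, and `TADModel.scaled(s)` maps a
fit to a different depth (μ → μ + log s for the log families;
(χ, ψ) → (sχ, ψ/s) for the GIG families, which are a scale family).

Unseen species enter through the zero-truncated joint likelihood

    log L(S, θ) = log S! − log(S−S_obs)! − Σ_k log F_k!
                  + (S − S_obs) log p₀(θ) + Σ_k F_k log p_k(θ),

with F_k the number of OTUs seen exactly k times and p₀ the zero-count
probability. Independence across species is an approximation to the
single multinomial sequencing draw; at S in the hundreds and depths in
the tens of thousands the induced correlations are negligible.

## Numerical evaluation of the pmfs

The Sichel/PIG pmf is closed-form through modified Bessel functions of
the second kind: p_k ∝ χ^(k/2) (ψ+2)^(−(k+γ)/2) K_{k+γ}(β) / k! with
β = √((ψ+2)χ). Orders up to the largest observed count (10⁵ and more)
are needed; K_v overflows double precision long before that, so the
implementation seeds small orders with scipy's exponentially scaled
`kve` and fills the ladder with the ratio recursion
r_v = 2v/β + 1/r_{v−1} (positive and stable upward for v ≥ ½),
accumulating log K by a cumulative sum of log ratios. Tests verify the
ladder against `kve` at moderate orders and the full pmf against
dense-grid integration of the mixing integral.

The log-normal and log-Student mixtures are integrated in
x = log λ. The log-normal integrand is strictly log-concave, so its
mode is bracketed by bisection, the integration interval extends until
the log-integrand falls 46 nats below the mode (relative truncation
~1e-20), and Gauss–Legendre rules are refined (64 → 1024 nodes) until
successive estimates agree to the requested relative tolerance (default
1e-8; a non-convergent case raises an error naming the family, k and
θ). The log-Student integrand need not be concave, so the bracket comes
from a scanned grid instead; for k ≥ 1 the e^{kx} factor kills the left
tail exponentially, which makes grid bracketing safe. The k = 0
log-Student term is special: the polynomial tails of the Student
density carry mass that no finite x-grid sees, so P(0) = E[e^{−λ}] is
integrated in CDF space, u = T_ν((x−μ)/σ) ∈ (0, 1), with panel knots at
the kernel's transition points — the tails then contribute exactly.

## MCMC sampler

Metropolis-within-Gibbs on (θ, S):

* θ components are updated one at a time by Gaussian random walks on a
  transformed scale (log for σ, ν, χ, ψ; identity for μ and the Sichel
  index γ). Proposal scales adapt by Robbins–Monro towards 30%
  acceptance during burn-in only and are frozen afterwards, preserving
  detailed balance in the retained chain.
* S − S_obs is a Gibbs draw: under the flat prior on S the conditional
  is negative binomial with size S_obs + 1 and failure probability
  p₀(θ). Draws above the cap s_max are rejected and redrawn; if p₀
  underflows towards 1 the sampler falls back to an integer random
  walk. A cap binding in more than 1% of draws raises an error rather
  than silently truncating the posterior.
* Priors: S uniform on [S_obs, s_max] (default s_max = 10⁶);
  transformed θ components independent N(0, 10²) — vague enough that
  the likelihood dominates, and stated rather than hidden.
* Defaults mirror a deep production fit: 100 000 burn-in, 150 000
  samples, thinning 10. The test suite and the acceptance script use
  10 000 / 20 000, which the recovery study shows is enough for
  calibrated credible intervals at S ≤ 1000, N = 3×10⁴.

Per retained draw the deviance −2 log L is recorded. DIC is the mean
deviance plus p_D = mean deviance − deviance at the posterior-mean θ
and round(mean S) (a plug-in point had to be chosen; the posterior mean
is used). AICc is computed from the lowest-deviance draw with k =
dim(θ) + 1 parameters and effective sample size n = S_obs (the number
of observed species, not reads — the frequency table has S_obs
contributing units). DIC ties within 1e-9 select the family with fewer
parameters, which in particular prefers PIG over Sichel when the index
adds nothing.

## Required sequencing effort

RSE for target fraction q is the read index at which the running
distinct-species count first *strictly exceeds* q·S — with integer
counts, the (⌊qS⌋+1)-th first occurrence. Prediction simulates repeat
experiments: draw (S, θ) uniformly with replacement from the chain,
draw community proportions from the TAD, draw multinomial counts for a
horizon of 10× the present effort, and locate the threshold crossing in
a uniformly random read ordering. The ordering is never materialized:
assigning each read an i.i.d. Uniform(0,1) key makes a species' first
occurrence the minimum of c keys — a Beta(1, c) variate — and the RSE
the rank of the t-th smallest minimum, computable with one binomial
draw per species. This O(S) construction is distributionally identical
to an explicit shuffle (verified against shuffle-and-scan in the
tests). Censored simulations (target not reached within the horizon)
are excluded from the point prediction and interval and reported in
`n_censored`; if any are censored the interval should be read as a
lower bound.

## Nonparametric estimators and curves

Chao1 defaults to the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)),
which is always defined; the classical F₁²/(2F₂) form is a flag and
falls back to the bias-corrected form when F₂ = 0. iChao1 adds the
F₃/F₄ correction, substituting F₄+1 when F₄ = 0 (mirroring the
bias-corrected convention) so sparse tails stay defined. ACE uses the
conventional rare cutoff of 10 and coverage 1 − F₁/N_rare; ACE-1
extends the squared CV for highly uneven assemblages. Coverage zero
(all rare reads singletons) is an error, not a number.

Rarefaction is the exact hypergeometric formula evaluated through
log-gamma, with the analytic variance computed over distinct count
values (O(d²) rather than O(S²)). Extrapolation beyond N follows the
sample-size-based asymptotic formula S_obs + F̂₀(1 − exp(−m·F₁/(N·F̂₀ +
F₁))) with F̂₀ from Chao1, m the extra effort. Confidence bands are a
community-composition bootstrap: observed species keep their empirical
proportions scaled by 1 − F₁/N, the unseen mass F₁/N is split equally
among ⌈F̂₀⌉ pseudo-species, and N reads are resampled 200 times; the
2.5/97.5 percentile band is widened, if needed, to contain the point
estimate. Saturating-function fits (Michaelis–Menten, negative
exponential, Weibull, logistic, and a Hill-type rational form) use
least squares on the curve with effort rescaled to O(1), ranked by
AICc with a residual floor so exact fits rank by parsimony;
non-convergent families are dropped with a warning.

## Culture comparison

Reciprocal filtering keeps an isolate–OTU pair when both search
directions pass: identity ≥ 99%, alignment length ≥ 75% of the
*isolate* sequence length (the denominator is the isolate in both
directions), bit-score strictly > 100, e-value < 10⁻⁴; the best forward
bit-score OTU is kept per isolate. The binomial retrieval test uses
p = S_obs/S as the probability that a randomly chosen species was
sequenced and asks for the lower-tail probability of the retrieved
count. The posterior simulation variant draws S from the chain and k
from the induced binomial, with the add-one p-value (b+1)/(n+1) — 3000
simulations with zero exceedances give exactly 1/3001. The
matched-abundance test draws matched-set-sized count samples without
replacement from the observed abundance vector; all three tests are
lower-tailed because the scientific question is a *deficit* of
retrieved or abundant isolates.

## Synthetic data

The generator draws proportions from the TAD, optionally pins one
dominant species at a fixed share (surface preset: 0.36), and performs
one multinomial draw of N reads. Preset parameters were tuned by
simulation (`scripts/tune_presets.py`) because normalizing heavy-tailed
draws shifts the realized count distribution away from the
unnormalized theory; the surface-like preset realizes ~85% of 1600
species observed at 500 262 reads with 11–15% singletons, the
bottom-like preset ~88% of 5100 at 574 960 reads. The desk scale (N/10,
S/3, mixing density rescaled to the implied mean count) exists for
iteration-heavy suites.

What the generator does *not* emulate: sequencing error, chimeras and
denoising artefacts; OTU-clustering distortions; taxonomic filtering;
phylogenetic or spatial structure in abundances; PCR primer bias. A
passing recovery test therefore shows the estimator is correct *under
the model*, not that real amplicon data satisfy the model — the
goodness-of-fit question for real data remains with the analyst.

The synthetic culture experiment draws isolate species with weight
proportional to proportion^bias (negative bias favours rare species,
culturing "selecting for the losers") and emits alignment tables wired
so that exactly the isolates present in the observed table pass the
reciprocal filter — a construction contract, not an alignment
simulation.

## Known limitations

* Single-chain diagnostics only; no Gelman–Rubin machinery or model
  averaging. Model-selection uncertainty is not propagated into the
  richness or RSE intervals.
* The log-Student ν is estimated, not fixed; with few informative
  frequencies it is weakly identified and its posterior largely
  reflects the prior.
* The likelihood treats counts as independent Poisson mixtures; for
  samples where a single OTU holds a large share of reads the
  multinomial constraint is handled in simulation but not in the
  likelihood.
* Heavy-tailed mixing densities can make the pmf's k_max-adaptive
  normalization check expensive or impossible (the tail closes slowly);
  `pmf_vector` raises rather than truncating silently.
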