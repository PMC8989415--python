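# Methods

## Model and inference

The data are M samples of an N-dimensional binary vector σ, assumed drawn
from a stationary joint distribution. Any such distribution can be written
as a log-linear model, log P(σ|θ) = −log Z + Σ_μ θ_μ Π_{i∈V_μ} σ_i, with one
coefficient per nonempty support V_μ. The question the package answers is
not "what are the θ's" but "which θ's are nonzero" — which words belong in
the dictionary. Each word gets an indicator spin s_μ with a flat prior
P(s_μ=1) = 1/2, and θ_μ | s_μ=1 gets a Gaussian prior of precision 1/ε
centered on θ*, the independent model whose marginals equal the empirical
unit frequencies n_i/M. In the strong-regularization limit ε ≪ 1, a saddle
point at the *prior* peak plus a second-order Taylor expansion in ε reduces
the indicator posterior to a pairwise Ising model with fields
h_μ = (1/2)[∂²L/∂θ_μ² + (∂L/∂θ_μ)²] and couplings
J_μν = (1/4)[∂²L/∂θ_μ∂θ_ν(∂²L/∂θ_μ∂θ_ν + 2 ∂L/∂θ_μ ∂L/∂θ_ν)], all evaluated
at θ*. For the log-linear model the likelihood derivatives are moments:
∂L/∂θ_μ = M(σ̄_μ − ⟨σ_μ⟩) and ∂²L/∂θ_μ∂θ_ν = −M·cov(σ_μ, σ_ν), which gives
the closed forms quoted in the README. The test suite verifies both against
numerical differentiation of the exactly enumerated log-likelihood on small
datasets (Richardson-refined central differences, agreement to 1e-6
relative for h); this check pins down, in particular, that the deviation
term inside J carries a factor 2M — which is what makes couplings between
overlapping, as-expected-co-occurring words negative and drives dictionary
irreducibility.

The double sum over indicator pairs excludes the diagonal μ = ν: a
self-term would only shift fields at order ε², and numerically it rescales
magnetizations without changing any detection ranking (we verified this
directly), so it is omitted.

## Mean-field solution and the ε schedule

Marginal magnetizations m_μ = 2⟨s_μ⟩ − 1 solve
atanh(m_μ) = (ε/2)[h_μ + ε Σ_ν J_μν + ε² Σ_ν J_μν m_ν]. Because h ∝ ε and
J ∝ ε², the map is strongly contractive; we iterate to a fixed point
(max-norm tolerance 1e-10, cap 1000 sweeps, damping 0.5 engaged only if the
residual grows) while ε is swept from 0 in steps δε = 1/(20M), warm-starting
each step. The sweep ends at ε_max = min(ε₁, ε₂): ε₁ = 1/M keeps the prior
narrower than the likelihood, and ε₂ is the last grid point at which
mean_μ|h_μ| ≥ mean_μ|ε·h_eff_μ(ε)| (h_eff_μ = Σ_ν J_μν + ε Σ_ν J_μν m_ν),
i.e. second-order terms stay subdominant. ε₂ is resolved only to grid
precision; if even the first grid point violates the bound the solver uses
that single step and warns. TAP corrections are higher order in ε and are
not applied. An exact oracle enumerates all 2^S indicator states for S ≤ 20
candidates; across random small systems built from data, naive mean field
agrees with enumeration to better than 2e-3 absolute at ε ≤ ε_max (the test
asserts the conservative bound 0.05).

A consequence of these scalings worth stating explicitly: at ε ≤ 1/M the
coupling contribution to atanh(m) relative to the field term is bounded by
roughly 2·cov(σ_μ,σ_ν) ≤ 2·var(σ_μ). Competition between overlapping words
is therefore a perturbation of a few percent unless words overlap almost
completely and are individually frequent. Detected words that do not
overlap are ranked essentially by field alone.

## Candidates and filtering

All supports of order ≤ k_max over non-constant units are candidates if
they occur at least once, or if absent with null-expected count
M·⟨σ_μ⟩ ≥ 0.02 (absent-but-expected words can be significantly
under-represented; rarer absent words have vanishing fields and carry no
signal — their posterior stays at 1/2). k_max defaults to 5 because at
activation q ≈ 0.2 and M ≤ ~2000 the expected count q^k·M drops below
detectability near k = 4–5. The n_max = 500 candidates with largest |h| form
the Ising system; ties are broken by lower order, then lexicographic
support, so re-runs are bit-identical. Enumeration is vectorized per order
(each support's sample-conjunction is one bit-packed AND with its prefix
parent), and is tested to agree exactly with per-support brute force.
Constant columns are excluded; entries other than {0,1} are rejected rather
than coerced. An optional preprocessing flag complements any column more
active than 1/2 (strictly), recording a flip mask, which keeps the mean
activation in the regime where absent high-order words are provably
negligible; exactly-half columns are left alone.

## Shuffle calibration

There is no first-principles magnetization threshold. Each column is
independently permuted across samples — preserving every n_i exactly while
destroying dependence — and the full pipeline (enumeration, filtering,
selection, mean field) is re-run on R = 100 such shuffles (R trades
threshold variance against runtime). n_false(m), the mean count of words
with magnetization above m on shuffled data, is inverted on the grid of
observed shuffle magnetizations (exact inversion; a −1 sentinel covers the
admit-everything limit); the dictionary threshold is the smallest grid value
with n_false ≤ 0.5, i.e. about half a falsely detected word per dataset,
chosen conservatively at crossings. The threshold is calibrated per dataset.
Self-consistency is tested: running the whole pipeline on freshly shuffled
data detects on average no more than the target (within two standard errors
over 50 replicates), and n_false(m) is non-increasing on every run.

## Synthetic benchmark

The generator emulates the premotor-recording regime: N = 20 units, biases
θ_i ~ N(−0.7, 0.1²) applied as 2θ_i per active unit so that the
interaction-free marginal is exactly [1 + exp(−2θ_i)]⁻¹ ≈ 0.2 (the factor 2
reconciles the {0,1} parameterization with the ±1-spin bias convention
behind that marginal formula). K = round(αN/3) interactions (α = density
per unit; mean order 3) are planted on distinct uniformly drawn supports,
split as equally as possible across orders 2, 3, 4 (remainder orders drawn
at random); nesting of supports is allowed. Strengths come from an
equal-weight mixture of N(+0.5, 0.1²) and N(−0.5, 0.1²), or from
N(0, 0.5²) — both keep individual effects weak. Sampling enumerates all 2^N
state probabilities exactly for N ≤ 22 (no mixing-time concerns); a Gibbs
sampler (5000-sweep burn-in, thinning 10) covers larger N. Scoring is
strict: a detected support counts as true only if it *equals* a planted
support — sub- and super-words are false positives.

At the n_false = 0.5 operating point with M = 1600 and 25 replicate models
per α ∈ {2, 4} (the acceptance script's configuration; runtime a few
minutes), the pipeline attains mean precision ≈ 0.79 and mean recall ≈ 0.19
(α = 2 alone: ≈ 0.20), with recall rising in M. The benchmark also reports
the fraction of candidates whose field exceeds the smallest field of any
retained word yet were excluded: with couplings entering only at order ε²
(see above), detected words in this generative family rarely overlap
strongly and this fraction is small, ≈ 1–3% — magnetizations are nearly
monotone in the field here, and most of the couplings' effect is a uniform
suppression near the threshold rather than rank inversion. Real spike data,
with bursts and refractoriness producing many strongly overlapping
anomalies, sits in a different regime in this respect. What passing the
synthetic tests shows is that the detector controls false discoveries at
the calibrated rate and recovers planted structure with high precision; it
does not certify behavior under temporal nonstationarity, asymmetric or
non-binary effects, or marginal frequencies far from the q ≈ 0.2 regime the
generator emulates.

## Neural front end

Spike times in the 40 ms premotor window are binarized in 2 ms bins
(1 = at least one spike), half-open [(t−1)Δt, tΔt) so boundary spikes land
in the later bin (boundary ties are measure-zero in real data; the
convention just makes the partition disjoint). The behavior bit is column
0: a median split (value > median = 1, ties to 0, polarity swappable), a
20-percentile window, or terciles; percentile ranks use the nearest-rank
definition (100·#{≤x}/n) for cross-platform reproducibility. Dictionary
statistics summarize codeword order proportions (m-spike = support size
m+1), mean inter-spike interval of codewords vs non-coding significant
words (mean gap between consecutive active bins; single-bin words
excluded), and cross-feature overlap. A deterministic trial generator
injects specified patterns at specified behavior-conditional rates, so the
entire front end is testable without recordings; it does not model
refractoriness or time-varying firing rates.

## Predictive validation

Two logistic models of the behavior bit — features either the 20 time-bin
indicators or the codeword conjunctions — are fit by maximizing the
L2-penalized log-likelihood (λ default 0.1; intercept unpenalized) with
damped Newton iteration, which on this ≤ 21-dimensional concave problem
reaches gradient norms ~1e-10 and makes refits exactly reproducible
(scikit-learn's equivalent fit, C = 1/λ, is used as an independent
cross-check in the tests). Comparison uses twofold cross-validation with a
stratified seeded split (re-drawn if a fold is single-class), reporting
held-out accuracy and mean cross-entropy; datasets with fewer than 4
codewords are skipped. On fixtures with planted behavior-locked patterns
the compact codeword model generalizes better (lower held-out
cross-entropy) than the 20-bin model.

## Determinism and configuration

Every stochastic step draws from a generator derived from a single root
seed; solver iteration, selection tie-breaks, and grid inversion are
deterministic, so identical data + seed give identical dictionaries.
Artifacts are JSON (dictionaries, manifests, model specs) and delimited
text (matrices, curves, fields/couplings); supports are serialized as
0-based indices with index 0 reserved for the behavior bit in
neuro-behavioral data.
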