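# Methods

## The problem

A layer-4 "barrel" in mouse somatosensory cortex contains roughly 2000
neurons (about 90% excitatory, 10% inhibitory) whose pairwise connectivity is
constrained by paired recordings: excitatory neurons contact 15–25% of their
neighbours (nominal p_e = 0.2), inhibitory neurons 50–60% (nominal
p_i = 0.6), and the probability that an excitatory→excitatory connection is
reciprocated lies between 0.15 and 0.35.  Several mutually incompatible
circuit models are consistent with these pairwise numbers.  `barrelabc` asks
whether a *measured connectome* — a binary signed directed graph, possibly
corrupted by reconstruction errors and only partially sampled — can identify
which generative model produced it, and with what posterior confidence.

## Candidate generative models

All seven generators emit signed binary graphs with the adjacency convention
`A[post, pre]`, no self-connections, and per-population connectivities
matched to p_e / p_i.

- **ER-ESN** — directed Erdős–Rényi graph; every excitatory projection with
  probability p_e, every inhibitory projection with p_i.
- **EXP-LSM** — somata placed uniformly in the (300 µm)³ barrel cube;
  connection probability p_t(d) = p₀·exp(−d/λ_t) with
  p₀ = p_t + (1−p_t)·d_EXP.  The decay constants λ_e, λ_i are calibrated so
  the *expected* connectivity over the inter-soma distance distribution of
  two uniform points in the cube equals p_e and p_i.  The expectation is
  evaluated with a 48³-node Gauss–Legendre tensor rule over the three
  coordinate differences (each triangular-distributed), and λ solved by
  Brent's method; `d_EXP` interpolates continuously to the ER limit (λ→∞ at
  d_EXP = 0).
- **LAYERED** — excitatory neurons split into n_l near-equal layers (sizes
  differ by at most one; the layer-size convention is the package's choice);
  within-layer connectivity p_e,l, next-layer connectivity p_e,f, no backward
  or skip connections; inhibitory neurons unstructured.
- **SYNFIRE** — embedded synfire chain: i.i.d. uniform excitatory pools of
  size s_pool (plus proportional inhibitory pools) connected all-to-all from
  pool t to pool t+1 for round(ln(1−p_e)/ln(1−s²/n_e²)) iterations, the
  count that makes the union of pool-to-pool blocks hit p_e.  Overlap
  between consecutive pools is what generates reciprocity.
- **FEVER** — feature-vector recombination on a pre-drawn random graph.
  Each neuron carries a unit feature vector in d_f dimensions; the initial
  graph is ER with connectivity p_t⁰ = p_t − f_r·d_f/n; each neuron's
  outgoing weights are then re-optimised so its feature vector is
  reconstructed by its targets' features under an L1 penalty, solved per
  neuron as a positive lasso (scikit-learn coordinate descent).  Anchoring
  the L1 term at unit-weight initial projections would let the anchor term
  dominate the unit-norm reconstruction target, so the implementation keeps
  the initial (anchor) edges fixed and penalises only added
  feature-reconstruction edges; this preserves the model's defining
  property — elevated excitatory reciprocity from mutual feature alignment —
  while matching the connectivity constraints.  The per-population penalty
  weight is fitted by bisection on a random neuron subset (tolerance 0.005 on
  connectivity) and then applied to all neurons.
- **API** — antiphase inhibition: connection probability
  p_ij = 1 − (1 − ((C_ij·s_j + 1)/2)^n_pow)^n_binomial with C_ij the cosine
  similarity of the postsynaptic and presynaptic feature vectors and s_j = ±1
  the presynaptic sign; the binomial exponents are fitted per network by
  Brent's method so the mean excitatory/inhibitory connection probabilities
  equal p_e / p_i.
- **STDP-SORN** — a random signed graph evolved for τ_end = 10,000 steps of
  binary threshold-unit dynamics (Gaussian input noise σ = 0.05) with
  intrinsic plasticity of the thresholds toward rate f₀ = 0.1,
  per-step renormalisation of incoming excitatory weights to 1, additive
  STDP, pruning of weights below 1/n, and structural plasticity inserting
  (n_e²p_e − n_s)/(1−p_e) candidate synapses of weight 1/n per step.  The
  plastic rules (STDP, pruning, structural insertion) act on the
  excitatory→excitatory block: the insertion rule and synapse count are
  defined over excitatory index pairs, and applying the additive update to
  empty or inhibitory entries would create sign-violating synapses.  STDP
  updates are clipped at zero from below.  Initial weight magnitudes are
  Uniform(0,1) before normalisation (only the support probabilities and
  the normalisation are constrained, so the magnitude distribution is a free
  choice).

### Priors

LAYERED (n_l ∈ {2,3,4}, p_e,f ∈ [0.19, 0.57], p_e,l ∈ [0.26, 0.43]) and API
(n_pow ∈ [4, 6]) use their established supports.  The remaining supports are
package defaults exposed in `default_prior()`: s_pool ~ DU[80, 300],
d_f ~ DU[50, 400], f_r ~ U[0, 1], η_STDP and η_i ~ LogUniform[10⁻³, 10⁻¹],
d_EXP a point mass at 1 for the EXP-LSM candidate.  Pool size and feature
dimension are *scale-bound* parameters: they are stated at the full barrel
scale (1800 excitatory / 2000 total) and rescaled proportionally when
networks are generated at reduced size, which keeps the FEVER precondition
p_t − f_r·d_f/n ≥ 0 and the pool/population ratio invariant.

Note that the structured models' prior boxes extend somewhat beyond the
(p_ee, r_ee) constraint window: roughly half of the LAYERED box and ~80% of
the SYNFIRE support produce analytically compliant statistics, and the
high-feverization corner of FEVER exceeds the reciprocity ceiling.  The
compliance test asserts these observed levels rather than full compliance.

## Summary statistics

Six statistics γ = (rr_ee, rr_ei, rr_ie, rr_ii, r⁽⁵⁾, r_i/o), computed on
binarized graphs:

- **Reciprocity r_xy**: the fraction of directed x→y connections whose
  reverse connection exists — an estimate of P(y→x | x→y).  Ordered
  connections are counted, so a mutual pair within one population
  contributes two connections and two reciprocations; this is the counting
  that makes r_xy the conditional probability and the relative reciprocity
  of a pairwise-random graph equal 1.  If there are no x→y connections,
  r_xy := 0 (and hence rr_xy = 0).
- **Relative reciprocity rr_xy = r_xy / p̂_yx**, the reciprocity divided by
  the *empirical* connectivity of the reverse direction — the value a
  pairwise-random graph of the same connectivity would produce.  Using the
  empirical rather than nominal connectivity makes the statistic
  self-normalising under neuron subsampling, which is what makes fractional
  measurements informative.
- **Relative recurrency r⁽⁵⁾ = tr(C_ee⁵)/(n_e·p̂_e)⁵**: the number of closed
  directed walks of length 5 in the excitatory subgraph over its
  pairwise-random expectation, again with the empirical connectivity.  The
  trace is computed exactly via two integer-valued float32 matrix products
  (entries bounded by n_e² < 2²⁴) with a float64 reduction.
- **In/out-degree correlation r_i/o**: Pearson correlation of excitatory
  in- and out-degrees counted within the excitatory subgraph (negative
  values indicate separated input and output populations, as in layered
  circuits).

A statistic whose denominator degenerates (zero reverse connectivity, zero
degree variance, empty excitatory graph) is marked undefined; vectors with
undefined components are discarded by the inference.

## Measurement model

- **Rewiring noise ξ**: a fraction ξ of edges removed uniformly (signs
  ignored) and the same number reinserted at uniform empty off-diagonal
  slots with the new presynaptic neuron's sign; the edge count is conserved
  exactly.
- **Split / merge errors**: remove-only or add-only variants of strength ξ
  relative to the original edge count.
- **Fractional measurement f_m**: a uniform fraction f_m of neurons kept
  with their induced subgraph (≈ f_m² of the connections).
- **Subvolume restriction**: neurons with somata inside a centred cube
  retained, then each surviving connection kept with probability p_keep
  (default 0.5) to model connections running outside the imaged volume.
  p_keep is the one free, experimentally unquantified parameter of this
  emulation, so subvolume accuracy numbers are checked as directions, not
  values.  Models without stored
  positions receive seeded uniform positions on demand.

The pipeline order is fixed: noise acts on the full graph, then subsampling.

## ABC-SMC

The distance between two connectomes is the L1 sum over the six statistics,
each normalised by the 80th-minus-20th percentile (linear-interpolation
convention) of that statistic over the initial prior sample; degenerate
scales are floored at machine epsilon.  Generation 0 draws n_particles from
the joint prior (flat over models), sets ε to the median distance and keeps
the below-median half with uniform weights.  Each later generation resamples
a model from the current posterior (kept with probability 0.85, otherwise
redrawn uniformly), resamples a particle of that model weight-proportionally,
perturbs it with a diagonal Gaussian kernel of twice the weighted variance of
the model's current particles (integer parameters are perturbed by rounding
the Gaussian step; zero-variance coordinates fall back to 5% of the prior
range), re-simulates through the full measurement pipeline, and accepts
when the distance is below ε (the weighted median of the previous
generation's distances).  The noise level ξ is a latent per-particle
parameter drawn from the configured noise prior (point mass at 0, or
Beta(2,10) when measurement errors are anticipated) and perturbed like any
other parameter.  Termination: a single model holds all mass, 8 generations,
ε ≤ 0.175, or fewer than min_accepted particles in a generation (each of the
n_particles proposal tasks gives up after 2000 attempts).

Accepted particles carry standard sequential-importance weights — prior
density over (model-proposal probability × kernel mixture density) — with a
`weighting="uniform"` switch that reproduces plain acceptance counting
instead.
The posterior over models is the per-model sum of normalised weights.

Proposal tasks are keyed by (root seed, generation, task index) and executed
serially in task order, so results are bit-reproducible for a fixed seed
regardless of host.

## Problem sizes and profiles

The default `ABCConfig` is the full replication profile (2000-neuron
candidates, 2000 particles, 8 generations).  All tests and the acceptance
script use `ABCConfig.reduced()`: 500-neuron candidate networks, 200
particles, 3 generations, min_accepted = 100, with the two expensive
simulators internally scaled further (FEVER at n = 150, STDP-SORN at n = 200
with τ_end = 1000).  The six statistics are ratios normalised by their own
pairwise-random expectations, which is what makes networks of different
sizes comparable; the reduced profile trades posterior sharpness for
simulation cost and is the package's chosen desk-scale operating point.
The noise-free identification experiments at this scale use the four
structurally distinct fast models (ER-ESN, LAYERED, SYNFIRE, API); runs with
all seven candidates (e.g. the interpolation sweep) use 120 particles and 2
generations.

## Analytic expectations

For constraint screening, closed forms for the expected excitatory
connectivity and reciprocity are provided for LAYERED (counting ordered
within-layer and forward pairs; only within-layer edges can be reciprocated)
and SYNFIRE (exact dynamic program over the i.i.d. pool-membership sequence
of an ordered neuron pair, with hypergeometric within-pool joint
probabilities).  Both agree with Monte-Carlo sampling within 3 standard
errors in the test suite.  Under the equal-layer convention the layered
model remains constraint-compatible up to `max_feasible_layers()` ≈ 11
layers at default constraints (the feasible ceiling depends on the layer
size convention, so it is computed rather than hard-coded).

The annotation-budget calculator implements T = V·d/v (volume × path density
/ tracing speed), scaled by the measured neuron fraction, and the synapse
count N·f with N = n(n_e·p_e + n_i·p_i) connected pairs and f = 3.36
synapses per connection: 180,000 h for a full barrel at 10 km/mm³ and
1.5 mm/h, 18,000 h at f_m = 0.1, and ≈ 3.23 million synapses.

## What the synthetic data does and does not emulate

The generators produce connection-level (not synapse-level) binary graphs
with hard population constraints and exactly the error processes above.
Real reconstructions violate several of these idealisations: errors are
spatially correlated (split/merge errors cluster on hard-to-trace neurites),
synapse detection is weight-dependent, neuron types are themselves inferred
with errors, and biological connectivity need not follow any of the seven
candidates.  Passing tests therefore demonstrate that the *inference
machinery* discriminates this model family under this error model at desk
scale — not that a measured barrel connectome will be
classified correctly.

## Numerical choices and degenerate inputs

- Percentile convention: linear interpolation (recorded in
  `DistanceNorms.percentile_convention`).
- Distance-norm floor: machine epsilon for zero-width percentile ranges.
- Decay-constant calibration: quadrature + Brent, |E[p] − p_t| < 10⁻⁴;
  unreachable targets raise; the distance-independent limit returns ∞.
- FEVER/API connectivity fits: bisection/Brent against empirical
  connectivity, tolerances 0.005 / 10⁻⁴; failure to bracket raises and the
  ABC layer discards the particle.
- Kernel density for rounded integer parameters uses the continuous normal
  density at the integer value (an adequate approximation for the 3–220-wide
  integer supports involved).
- Empty populations after subsampling, all-undefined initial samples, and
  undefined target statistics raise immediately rather than propagating NaNs.

## Known limitations

- The FEVER optimisation is implemented in the well-posed formulation
  described above; alternative formulations that re-optimise or remove the
  anchor edges are either ill-posed or destroy the model's defining
  reciprocity signature.
- Reduced-scale statistics have higher variance; at n = 500 the SYNFIRE and
  LAYERED prior boxes produce somewhat more constraint violations than at
  full scale, and STDP-SORN at τ_end = 1000 is closer to the random limit
  than a full 10,000-step run.
- Importance weights use a diagonal kernel; no covariance structure between
  parameters is modelled.
- Focused (spatially biased) error processes are out of scope; the
  `biased_noise` mode parameter is the extension point.
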