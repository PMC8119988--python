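# barrelabc

Bayesian selection of local cortical circuit models from connectomes.

A layer-4 "barrel" of mouse somatosensory cortex contains ~2000 neurons
(90% excitatory) whose pairwise connectivity is known from paired
recordings — excitatory connection probability p_e ≈ 0.2, inhibitory
p_i ≈ 0.6, excitatory reciprocity r_ee ∈ [0.15, 0.35] — yet several
incompatible circuit architectures satisfy those pairwise numbers.
`barrelabc` answers the question: *given a dense (or partial, or noisy)
connectome measurement of such a module, can the generating circuit model be
identified, and with what confidence?*

The package provides:

- **Seven generative circuit models** constrained to the same pairwise
  statistics: pairwise-random (ER-ESN), distance-dependent random (EXP-LSM),
  layered (LAYERED), embedded synfire chain (SYNFIRE), feature-vector
  recombination (FEVER), antiphase inhibition (API), and a
  plasticity-shaped recurrent network (STDP-SORN).
- **Six summary statistics** γ = (rr_ee, rr_ei, rr_ie, rr_ii, r⁽⁵⁾, r_i/o):
  four relative reciprocities (observed reciprocity over the pairwise-random
  expectation at the same empirical connectivity), the relative prevalence
  of directed 5-cycles r⁽⁵⁾ = tr(C_ee⁵)/(n_e·p̂_e)⁵, and the excitatory
  in/out-degree correlation.
- **Measurement corruption**: random rewiring noise ξ, split/merge-biased
  errors, fractional neuron subsampling f_m, and dense-subvolume
  restriction.
- **ABC-SMC model selection**: likelihood-free posterior p(m, θ | C#) with a
  percentile-normalised L1 distance d_γ(C#, Cˢ) = Σₖ |γₖ(C#) − γₖ(Cˢ)| /
  (γₖ,₈₀ − γₖ,₂₀), a shrinking-median ε schedule, hierarchical
  model/parameter perturbation kernels, and importance weighting.
- **Experiment grids**: confusion matrices, noise × measurement-fraction
  accuracy grids, leave-one-out model exclusion, ER↔EXP-LSM interpolation
  sweeps, and an annotation-time/synapse-count budget calculator.

## Worked example

Generate a 500-neuron layered circuit, pretend it is a measured connectome,
and ask which of four candidate models produced it:

```python
import barrelabc as b

config = b.BarrelConfig().scaled(500)          # 450 excitatory + 50 inhibitory
target = b.sample_layered(config, n_l=3, p_e_f=0.40, p_e_l=0.35, seed=7)
print("gamma =", b.summarize(target))

sel = b.ConnectomeModelSelection(
    target,
    prior=b.default_prior(("ER_ESN", "LAYERED", "SYNFIRE", "API")),
    config=config,
    abc_config=b.ABCConfig.reduced(),
)
res = sel.fit(seed=1)
print(res.summary())
```

Output:

```
gamma = SummaryStats(rr_ee=0.9488, rr_ei=1.0102, rr_ie=1.0102, rr_ii=0.9735,
                     r5=0.1675, r_io=-0.4861)
Connectome model selection (ABC-SMC)
============================================
target: n=500 (e=450, i=50), edges=60730
generations: 2   termination: single_model
epsilon: 3.230 -> 2.659 -> 1.739
--------------------------------------------
model          posterior
LAYERED           1.0000
ER_ESN            0.0000
SYNFIRE           0.0000
API               0.0000
--------------------------------------------
MAP model: LAYERED
```

The layered target is betrayed by its statistics — few directed 5-cycles
(r⁽⁵⁾ = 0.17 against 1.0 for a random graph) and a negative in/out-degree
correlation (r_i/o = −0.49, input and output layers are different neurons) —
and ABC-SMC concentrates all posterior mass on the generating model after
two generations.  `res.param_cloud("LAYERED")` returns the accepted
parameter particles (layer count, connectivities, noise level) with their
importance weights, and `res.plot_posterior()` / `res.plot_epsilon()` the
matching figures.

The same machinery is exposed on the command line:

```bash
barrelabc generate --model SYNFIRE --n-e 450 --n-i 50 --params s_pool=40 \
    --seed 3 --out net
barrelabc stats net.mtx --json
barrelabc perturb net.mtx noisy --xi 0.15 --f-m 0.3 --seed 1
barrelabc abc --target noisy.mtx --out results/
barrelabc budget --fraction 0.1     # -> annotation time: 18,000 h
```

Connectomes are stored as Matrix Market sparse matrices with a JSON sidecar
(types, positions, generator provenance, seed), so every artifact is
regenerable.

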