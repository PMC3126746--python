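# betapairhmm

A beta-mixture pair hidden Markov model for methylation-microarray probe
pairs: per-sample maximum-likelihood estimation (EM + Baum-Welch), exact
posterior/Viterbi state decoding with a false annotation rate, leave-one-out
Mahalanobis sample classification on the fitted parameters, and
permutation-tested differential methylation states between sample groups.

## The problem and the model

Genome-wide methylation arrays report, per CpG probe, a *beta-value*
β = M/(M + U + offset) ∈ [0, 1] from methylated (M) and unmethylated (U)
bead intensities — tens of thousands of correlated, noisy numbers per
sample. This package summarises a whole profile by a 37-parameter
generative model, built for designs where most genes carry two probes:

- Each probe is in a hidden methylation state k ∈ {L, M, H} (low, medium,
  high). L/H mean (almost) all cells unmethylated/methylated; M captures
  hemi-methylation or cell-mixture heterogeneity.
- Given its state, a probe in location class a ∈ {I, S, O} (inside a CpG
  island, island shore within 2000 bp, or outside) emits
  x ~ Beta(α_ak, β_ak). The medium state is symmetric (α_aM = β_aM), and
  class I never reaches H — high methylation is essentially absent inside
  islands. That gives 13 free emission parameters.
- A gene's first two probes (by coordinate) form a length-2 Markov chain:
  the pair's class (a₁, a₂) ∈ {(I,I), (S,S), (O,O), (S,I)} selects an
  initial distribution ω over the states of probe 1 (7 free parameters in
  total) and a row-stochastic transition matrix T to probe 2's state (17
  free). (I,S) pairs are swapped into (S,I); rare mixed classes involving O
  are excluded. The pair density is

  f(x₁, x₂) = Σ_{k₁,k₂} ω_{k₁} T_{k₁k₂} f(x₁; α_{a₁k₁}, β_{a₁k₁})
  f(x₂; α_{a₂k₂}, β_{a₂k₂}),

  summed over the allowed joint states (9 for three-state classes, 4 for
  (I,I), 6 for (S,I)).

Fitting is two-stage maximum likelihood per sample: EM for the emission
mixtures of each location class, then Baum-Welch (with emissions fixed) for
each pair class's (ω, T). Decoding enumerates the exact joint posterior per
pair; the Viterbi/MAP state is its argmax, and the **false annotation rate**
FAR = mean(1 − max posterior) is the expected fraction of pairs whose state
annotation is wrong. Samples are classified to the group g minimizing the
diagonal Mahalanobis distance Σ_t (ν_ti − μ_tg)²/σ²_tg over the joint prior
proportions ν = ω ⊗ T, with group moments computed leave-one-out.
Differential pairs between two groups combine differing modal (overall
group) states with a label-permutation test of Fisher's linear discriminant
criterion on per-sample posterior proportions.

## Worked example

```python
import numpy as np
import betapairhmm as bp
from betapairhmm.io_preprocess import sample_probe_table
from betapairhmm.estimation import pairs_from_probe_table

# a synthetic sample from the bundled tumor-like profile
spec = bp.SimSpec(model=bp.default_model("tumor-like"), seed=7, sample_id="tumor01")
betas, ann, truth = bp.simulate_sample(spec)

tbl = sample_probe_table(ann, betas, "tumor01")
result = bp.fit_sample(tbl, bp.FitConfig(seed=0), sample_id="tumor01")
print(bp.count_free_parameters(result.model))
print(np.round(result.model.pair_models["OO"].omega_init, 3))

pairs = pairs_from_probe_table(tbl)
decoded = bp.decode_pairs(pairs, result.model)
print(round(bp.far(decoded["max_prob"].to_numpy()), 4))
```

prints

```
{'emission': 13, 'mixture': 7, 'transition': 17, 'total': 37}
[0.226 0.522 0.252]
0.0312
```

The fitted model has the full 37-parameter budget; the outside-region
initial proportions put most mass on medium methylation (the tumor-like
signature the profile encodes, here ω ≈ (0.23, 0.52, 0.25) against the
generating (0.20, 0.55, 0.25)); and with these well-separated emission
fixtures about 3.1% of probe pairs are expected to carry a wrong state
annotation. Sklearn-style wrappers (`BetaPairHMM`, `MahalanobisClassifier`)
expose the same computations as estimators.

The same pipeline runs from the shell:

```bash
betapairhmm simulate --profile tumor-like --n-pairs 2000 --seed 7 --out-prefix work/t1
betapairhmm fit --input work/t1.betas.tsv --annotation work/t1.annotations.tsv \
    --islands work/t1.islands.bed --out work/t1.model.txt
betapairhmm decode --model work/t1.model.txt --input work/t1.betas.tsv \
    --annotation work/t1.annotations.tsv --islands work/t1.islands.bed \
    --out work/t1.decoded.tsv
betapairhmm classify --models work/models --labels labels.tsv --out predictions.tsv
betapairhmm compare --decoded work/decoded --labels labels.tsv \
    --group-a normal --group-b tumor --out-prefix work/cmp
```

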