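# cdsml

Similarity-regularized matrix factorization for classifying cancer cell
line–drug pairs as **sensitive** or **resistant**.

Precision oncology screens (GDSC, CCLE) measure IC50 — the drug
concentration needed for half-maximal growth inhibition — for thousands
of cell line–drug pairs. For treatment decisions the binary question
matters more than the continuous value: is the line sensitive at a
concentration the patient's plasma can actually reach? `cdsml`
implements that classification pipeline end to end:

1. **Preprocess**: read delimited response/feature matrices, drop drugs,
   features and cell lines that are mostly unobserved, impute the rest
   by expression-distance-weighted k-nearest-neighbour means, and
   binarize IC50 against each drug's maximum plasma concentration
   C_max (sensitive ⇔ IC50 < C_max).
2. **Similarities**: three cell-line similarities (expression Pearson,
   copy-number Pearson, mutation Jaccard) and three drug similarities
   (fingerprint Jaccard, Jaccard of chemical–protein network
   neighbourhoods, and a maximum-weight bipartite matching of
   target-protein sets over a PPI network).
3. **Learn**: factorize the binary response B ≈ X Yᵀ (and Bᵀ, averaging
   the two reconstructions) by damped entry-wise Newton descent on

       ½ Σ_{(i,j)∉Missing} (B_ij − X_i·Y_j)²
       + α/2 (‖X‖² + ‖Y‖²)
       + β/2 (Σ_{ij} ‖X_i−X_j‖² SC_ij + Σ_{ij} ‖Y_i−Y_j‖² SD_ij)

   with scenario flags for double-, single- and no-similarity modes and
   a missing-aware mode that skips unobserved pairs.
4. **Evaluate**: stratified pairwise cross-validation (pairs, not cell
   lines, are folded), AUC/AUPR plus threshold metrics at the
   precision–recall elbow, hyper-parameter grid search, and ranking of
   unobserved pairs as candidate sensitive associations.

A synthetic-data module generates complete, internally consistent
screens (planted low-rank structure, matching C_max tables, similarity
matrices, interaction networks), so every stage is exercisable without
any download. See `docs/methods.md` for the model, the numerical
choices and the known limitations.

## Worked example

```python
from cdsml import (SyntheticSpec, generate, Hyperparameters, Scenario,
                   fit_predict, threshold_scores, rank_unknown, rank_metrics)

bundle = generate(SyntheticSpec(seed=7))          # 60 lines x 30 drugs
B = bundle.binary_response
print("sensitive fraction:", round(B.sensitive_fraction(), 3))

hp = Hyperparameters(alpha=3.5, beta=4.5, k_prime=0.7, seed=7)
scen = Scenario.from_name("none", missing_aware=True)
scores = fit_predict(B, None, None, hp, scen)

labels, thr = threshold_scores(scores, B)
print("elbow threshold:", round(thr, 4))

held_out = B.missing_mask                          # the 20% unobserved pairs
auc, _ = rank_metrics(scores.scores[held_out],
                      bundle.truth["B_clean"][held_out])
print("held-out AUC vs planted labels:", round(auc, 4))
for cell, drug, s in rank_unknown(scores, B, top_n=3):
    print(cell, drug, round(s, 3))
```

prints

```
sensitive fraction: 0.488
elbow threshold: 0.3819
held-out AUC vs planted labels: 0.9105
CL051 DR015 0.829
CL045 DR020 0.804
CL006 DR023 0.792
```

The generator hides 20% of the pairs; the factorization, fitted
missing-aware on the noisy observed labels, ranks the hidden pairs with
AUC ≈ 0.91 against the noiseless planted labels, and the top-ranked
unknown pairs are the model's proposed novel sensitive associations.

The same pipeline is available from the shell:

```
cdsml simulate --out demo --seed 7
cdsml cv --response demo/binary_response.tsv --scenario none \
         --missing-aware --n-reps 3 --seed 7 --out demo/cv
```

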